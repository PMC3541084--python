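import numpy as np
import pytest

import vfrkit.forward as fwd
from vfrkit.geometry import ElectrodeLayout


@pytest.fixture(scope="session")
def model():
    return fwd.ThoraxModel()


@pytest.fixture(scope="session")
def sources():
    return fwd.default_sources()  # (atrial, ventricular)


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout()


@pytest.fixture(scope="session")
def fingerprints(model, sources, layout):
    """Electrode-level fingerprint pair from the default simulated anatomy."""
    atrial, ventric = sources
    return fwd.electrode_fingerprints(model, atrial, ventric, layout, calib_volume=50.0)


@pytest.fixture(scope="session")
def fingerprint_grids(model, sources):
    """Before/after skin grids on a wide matrix covering the full layout."""
    atrial, ventric = sources
    spec = fwd.GridSpec(x0=-157.5, z0=-262.5, nx=10, nz=10)
    return fwd.simulate_fingerprint_experiment(model, atrial, ventric, spec, calib_volume=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
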