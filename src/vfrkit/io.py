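"""File formats: CSV streams and grids, JSON fingerprints and configs.

All tabular I/O is CSV with explicit headers and units in the column
names; times are ms, volumes ml, potentials volts.  Writers prepend
comment headers carrying the package version, the seed and a config hash
so every artifact records its provenance; readers ignore comment lines.
Round-trips are lossless to 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout, FingerprintVector, PotentialGrid

__all__ = [
    "config_hash",
    "write_streams",
    "read_streams",
    "write_markers",
    "read_markers",
    "write_grid",
    "read_grids",
    "write_fingerprint",
    "read_fingerprint",
    "write_layout",
    "read_layout",
    "write_frame",
]

_FLOAT_FMT = "%.12g"


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable config."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed=None, extra=None) -> str:
    from . import __version__

    lines = [f"# vfrkit {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if extra:
        lines.append(f"# config_hash: {config_hash(extra)}")
    return "\n".join(lines) + "\n"


def write_frame(frame: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config))
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_streams(path, time_ms, phi, seed=None, config=None) -> None:
    """Voltage streams: columns time_ms, ch1_volts .. ch6_volts."""
    phi = np.asarray(phi, dtype=float)
    frame = pd.DataFrame({"time_ms": np.asarray(time_ms, dtype=float)})
    for k in range(6):
        frame[f"ch{k + 1}_volts"] = phi[k]
    write_frame(frame, path, seed, config)


def read_streams(path):
    frame = _read_csv(path)
    cols = [f"ch{k + 1}_volts" for k in range(6)]
    missing = [c for c in ["time_ms"] + cols if c not in frame.columns]
    if missing:
        raise ValueError(f"stream file {path} is missing columns: {missing}")
    return frame["time_ms"].to_numpy(), frame[cols].to_numpy().T


def write_markers(path, r_peaks_ms) -> None:
    """R-peak marker file: one time (ms) per line."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for t in np.asarray(r_peaks_ms, dtype=float):
            fh.write(f"{t:.12g}\n")


def read_markers(path) -> np.ndarray:
    vals = [float(line) for line in Path(path).read_text().split() if line and not line.startswith("#")]
    return np.asarray(vals, dtype=float)


def write_grid(path, grid: PotentialGrid, append: bool = False, seed=None, config=None) -> None:
    """Potential grid rows: x_mm, z_mm, value_volts, label (long format)."""
    X, Z = np.meshgrid(grid.x, grid.z, indexing="ij")
    frame = pd.DataFrame(
        {
            "x_mm": X.ravel(),
            "z_mm": Z.ravel(),
            "value_volts": grid.values.ravel(),
            "label": grid.label,
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if append and path.exists():
        frame.to_csv(path, mode="a", header=False, index=False, float_format=_FLOAT_FMT)
    else:
        with open(path, "w") as fh:
            fh.write(_header_lines(seed, config))
            frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_grids(path) -> dict:
    """Read all labelled grids from a grid CSV; returns {label: PotentialGrid}."""
    frame = _read_csv(path)
    needed = {"x_mm", "z_mm", "value_volts", "label"}
    if not needed.issubset(frame.columns):
        raise ValueError(f"grid file {path} must have columns {sorted(needed)}")
    grids = {}
    for label, sub in frame.groupby("label"):
        x = np.unique(sub["x_mm"].to_numpy())
        z = np.unique(sub["z_mm"].to_numpy())
        values = np.full((len(x), len(z)), np.nan)
        xi = np.searchsorted(x, sub["x_mm"].to_numpy())
        zi = np.searchsorted(z, sub["z_mm"].to_numpy())
        values[xi, zi] = sub["value_volts"].to_numpy()
        if np.any(np.isnan(values)):
            raise ValueError(f"grid {label!r} in {path} has missing nodes")
        grids[str(label)] = PotentialGrid(x=x, z=z, values=values, label=str(label))
    return grids


def write_fingerprint(path, f: FingerprintVector, layout_id: str = "default") -> None:
    payload = {
        "compartment": f.compartment,
        "mu": [float(v) for v in f.mu],
        "calib_volume_ml": f.calib_volume,
        "layout_id": layout_id,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fingerprint(path) -> FingerprintVector:
    payload = json.loads(Path(path).read_text())
    for key in ("compartment", "mu", "calib_volume_ml"):
        if key not in payload:
            raise ValueError(f"fingerprint file {path} is missing field {key!r}")
    return FingerprintVector(
        mu=np.asarray(payload["mu"], dtype=float),
        compartment=payload["compartment"],
        calib_volume=float(payload["calib_volume_ml"]),
    )


def write_layout(path, layout: ElectrodeLayout) -> None:
    payload = {
        "positions_mm": [list(p) for p in layout.positions],
        "reference_distance_mm": layout.reference_distance,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_layout(path) -> ElectrodeLayout:
    payload = json.loads(Path(path).read_text())
    if "positions_mm" not in payload:
        raise ValueError(f"layout file {path} is missing field 'positions_mm'")
    return ElectrodeLayout(
        positions=tuple(tuple(p) for p in payload["positions_mm"]),
        reference_distance=float(payload.get("reference_distance_mm", 30.0)),
    )
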