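"""Electrode geometry, skin potential grids, and fingerprint construction.

The atrial and ventricular "fingerprints" are 2D patterns of normalized
voltage change on the frontal thoracic skin, measured (or simulated) as the
response to a standardized filling of one cardiac compartment with a known
calibration volume.  Sampling a fingerprint map at the seven electrode
positions and differencing adjacent pairs yields the 6-component fingerprint
vectors f_A and f_V that drive the decomposition.

Coordinates are planar skin coordinates (x, z) in millimetres with the
origin at the incisura jugularis (top of the sternum); z is negative in the
caudal direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "ElectrodeLayout",
    "PotentialGrid",
    "FingerprintMap",
    "FingerprintVector",
    "OutOfDomainError",
    "DegenerateGradientError",
    "interpolate_potential",
    "compute_m_map",
    "fingerprint_from_map",
    "virtual_displacement_fit",
]

#: Default electrode positions e0..e6 in skin coordinates (mm).
DEFAULT_ELECTRODE_POSITIONS = (
    (0.0, 0.0),
    (0.0, -60.0),
    (-30.0, -90.0),
    (-30.0, -120.0),
    (0.0, -157.0),
    (35.0, -187.0),
    (-92.0, -197.0),
)


class OutOfDomainError(ValueError):
    """A query point or electrode lies outside the grid/map domain."""


class DegenerateGradientError(ValueError):
    """The vertical potential differential vanishes at an evaluation point."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Seven measuring electrodes and the six adjacent pairs between them.

    Pair ``k`` (k = 1..6) measures the voltage between electrodes ``e_k``
    and ``e_{k-1}``.  ``reference_distance`` is the vertical separation
    (mm) to which the fingerprint normalization refers: the m-maps express
    voltage change per ``reference_distance`` of vertical potential drop.
    """

    positions: tuple = DEFAULT_ELECTRODE_POSITIONS
    reference_distance: float = 30.0
    pairs: tuple = field(default=tuple((k, k - 1) for k in range(1, 7)))

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (7, 2):
            raise ValueError(f"expected 7 planar electrode positions, got shape {pos.shape}")
        if len(self.pairs) != 6:
            raise ValueError(f"expected 6 electrode pairs, got {len(self.pairs)}")
        for k, (a, b) in enumerate(self.pairs, start=1):
            if (a, b) != (k, k - 1):
                raise ValueError(f"pair {k} must connect electrodes {k} and {k - 1}")
        seps = np.linalg.norm(pos[1:] - pos[:-1], axis=1)
        if np.any(seps <= 0):
            raise ValueError("all pair separations must be strictly positive")
        if self.reference_distance <= 0:
            raise ValueError("reference_distance must be positive")

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)

    def pair_vertical_separations(self) -> np.ndarray:
        """Signed vertical drop z_{k-1} - z_k for each pair (positive caudally)."""
        z = self.xy[:, 1]
        return np.array([z[b] - z[a] for a, b in self.pairs])


@dataclass(frozen=True)
class PotentialGrid:
    """Rectangular grid of skin potentials referenced to the incisura jugularis.

    The ex-vivo calibration setup uses a 5 x 5 electrode matrix with a 35 mm
    pitch; the container is general so that denser or wider grids (e.g. a
    simulated grid covering the full measuring layout) use the same type.
    """

    x: np.ndarray  # strictly increasing node x coordinates, mm
    z: np.ndarray  # strictly increasing node z coordinates, mm
    values: np.ndarray  # potentials, volts; shape (len(x), len(z))
    label: str = ""

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "values", v)
        if x.ndim != 1 or z.ndim != 1 or len(x) < 2 or len(z) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        if np.any(np.diff(x) <= 0) or np.any(np.diff(z) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        for ax in (x, z):
            steps = np.diff(ax)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("grid pitch must be uniform")
        if v.shape != (len(x), len(z)):
            raise ValueError(f"values shape {v.shape} does not match axes ({len(x)}, {len(z)})")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid values must be finite")

    def congruent_with(self, other: "PotentialGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.x, other.x)
            and np.allclose(self.z, other.z)
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        eps = 1e-9
        return (
            (p[:, 0] >= self.x[0] - eps)
            & (p[:, 0] <= self.x[-1] + eps)
            & (p[:, 1] >= self.z[0] - eps)
            & (p[:, 1] <= self.z[-1] + eps)
        )


@dataclass(frozen=True)
class FingerprintMap:
    """Continuous dimensionless fingerprint field m(x, z) over a grid domain.

    ``m`` is the normalized voltage change per ``reference`` mm of vertical
    baseline potential drop; evaluation is bilinear between nodes and an
    error outside the sampled domain (no extrapolation: skin measurements
    were confined to the thoracic chest).
    """

    x: np.ndarray
    z: np.ndarray
    m_values: np.ndarray
    compartment: str = ""  # "atrial" | "ventricular"

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "m_values", np.asarray(self.m_values, dtype=float))

    def _interp(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.x, self.z), self.m_values, method="linear", bounds_error=True
        )

    def __call__(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        inside = (
            (p[:, 0] >= self.x[0] - 1e-9)
            & (p[:, 0] <= self.x[-1] + 1e-9)
            & (p[:, 1] >= self.z[0] - 1e-9)
            & (p[:, 1] <= self.z[-1] + 1e-9)
        )
        if not np.all(inside):
            bad = p[~inside][0]
            raise OutOfDomainError(f"point ({bad[0]:g}, {bad[1]:g}) mm outside fingerprint map domain")
        q = np.clip(p, [self.x[0], self.z[0]], [self.x[-1], self.z[-1]])
        return self._interp()(q)

    def extremum_position(self) -> tuple:
        """Node position of the largest |m| value (the map's 'epicenter')."""
        i, j = np.unravel_index(np.argmax(np.abs(self.m_values)), self.m_values.shape)
        return float(self.x[i]), float(self.z[j])


@dataclass(frozen=True)
class FingerprintVector:
    """6-component fingerprint vector with its calibration volume (ml)."""

    mu: np.ndarray
    compartment: str
    calib_volume: float = 50.0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if mu.shape != (6,):
            raise ValueError(f"fingerprint vector must have 6 components, got shape {mu.shape}")
        if not np.all(np.isfinite(mu)):
            raise ValueError("fingerprint components must be finite")
        if self.calib_volume <= 0:
            raise ValueError("calib_volume must be positive")


def interpolate_potential(grid: PotentialGrid, point) -> float:
    """Bilinear interpolation of a potential grid at a skin point (mm)."""
    p = np.asarray(point, dtype=float)
    if not grid.contains(p)[0]:
        raise OutOfDomainError(f"point ({p[0]:g}, {p[1]:g}) mm outside grid domain")
    interp = RegularGridInterpolator((grid.x, grid.z), grid.values, method="linear")
    q = np.clip(p, [grid.x[0], grid.z[0]], [grid.x[-1], grid.z[-1]])
    return float(interp(q)[0])


def compute_m_map(
    before: PotentialGrid,
    after: PotentialGrid,
    half_step: float = 15.0,
    compartment: str = "",
    denom_floor: float | None = None,
) -> FingerprintMap:
    """Normalized voltage-change map m(x,z) from before/after potential grids.

    m(x, z) = [Phi_after(x,z) - Phi_before(x,z)]
              / [Phi_before(x, z - half_step) - Phi_before(x, z + half_step)]

    The denominator is the baseline vertical potential drop over
    2*half_step mm, so m is the voltage change per that reference span; the
    map is evaluated on the interior node set where (x, z -+ half_step)
    remain inside the hull.  The ratio is invariant to global scaling of the
    applied field.
    """
    if not before.congruent_with(after):
        raise ValueError("before/after grids must be congruent")
    if denom_floor is None:
        denom_floor = 1e-6 * float(np.max(np.abs(before.values)))

    interp_b = RegularGridInterpolator((before.x, before.z), before.values, method="linear")
    z_ok = (before.z - half_step >= before.z[0] - 1e-9) & (before.z + half_step <= before.z[-1] + 1e-9)
    if not np.any(z_ok):
        raise OutOfDomainError("no grid rows admit the +-half_step vertical differential")
    zs = before.z[z_ok]

    numer = after.values[:, z_ok] - before.values[:, z_ok]
    X, Z = np.meshgrid(before.x, zs, indexing="ij")
    lo = np.stack([X.ravel(), np.clip(Z.ravel() - half_step, before.z[0], before.z[-1])], axis=1)
    hi = np.stack([X.ravel(), np.clip(Z.ravel() + half_step, before.z[0], before.z[-1])], axis=1)
    denom = (interp_b(lo) - interp_b(hi)).reshape(X.shape)

    small = np.abs(denom) < denom_floor
    if np.any(small):
        i, j = np.argwhere(small)[0]
        raise DegenerateGradientError(
            f"vertical baseline gradient below floor ({denom_floor:g} V) at "
            f"({before.x[i]:g}, {zs[j]:g}) mm"
        )
    return FingerprintMap(x=before.x, z=zs, m_values=numer / denom, compartment=compartment)


def fingerprint_from_map(
    fmap: FingerprintMap,
    layout: ElectrodeLayout,
    calib_volume: float = 50.0,
    shift: tuple = (0.0, 0.0),
) -> FingerprintVector:
    """Sample a fingerprint map at the electrode pairs to build f_A or f_V.

    mu^(k) = [m(e_k) - m(e_{k-1})] * reference_distance / (z_{k-1} - z_k)

    The scaling by the pair's vertical separation keeps mu^(k) equal to the
    relative pair-voltage change under a vertical incident field: the pair
    baseline voltage is proportional to the vertical electrode separation,
    and m is normalized per ``reference_distance`` of vertical drop.  Pairs
    whose vertical separation equals ``reference_distance`` (pairs 2 and 3
    in the default layout) reduce to the plain m difference.

    ``shift`` translates the sampling positions by (-dx, -dz), emulating a
    heart displaced by (+dx, +dz) relative to the electrode sticker.
    """
    pts = layout.xy - np.asarray(shift, dtype=float)
    m_at = fmap(pts)
    dz = layout.pair_vertical_separations()
    mu = np.array(
        [(m_at[a] - m_at[b]) * layout.reference_distance / dz[k] for k, (a, b) in enumerate(layout.pairs)]
    )
    return FingerprintVector(mu=mu, compartment=fmap.compartment, calib_volume=calib_volume)


def default_search_grid(extent: float = 30.0, step: float = 5.0) -> list:
    """Virtual-displacement candidates: dx, dz in [-extent, +extent], given step."""
    offsets = np.arange(-extent, extent + step / 2, step)
    return [(float(dx), float(dz)) for dx, dz in itertools.product(offsets, offsets)]


def virtual_displacement_fit(
    atrial_map: FingerprintMap,
    ventricular_map: FingerprintMap,
    layout: ElectrodeLayout,
    calib_beats,
    search_grid=None,
    calib_volume: float = 50.0,
):
    """Match fingerprints to a subject by searching over virtual heart shifts.

    For each candidate displacement (dx, dz) of the heart relative to the
    electrode sticker, fingerprints are rebuilt from the maps sampled at
    electrode positions translated by (-dx, -dz), and the mean squared
    least-squares residual of the two-source decomposition over the
    calibration beats is evaluated.  Returns ``(best_shift, f_A, f_V)`` for
    the residual-minimizing shift; ties break to the smallest shift norm,
    then lexicographically.
    """
    from .decomposition import compute_weights, solve_alpha_psi

    beats = [np.asarray(b, dtype=float) for b in calib_beats]
    if len(beats) == 0:
        raise ValueError("virtual displacement fit requires at least one calibration beat")
    for b in beats:
        if b.shape != (6,):
            raise ValueError("calibration beats must be 6-component measurement vectors")
    if search_grid is None:
        search_grid = default_search_grid()

    best = None
    for dx, dz in search_grid:
        try:
            f_a = fingerprint_from_map(atrial_map, layout, calib_volume, shift=(dx, dz))
            f_v = fingerprint_from_map(ventricular_map, layout, calib_volume, shift=(dx, dz))
            weights = compute_weights(f_a, f_v)
        except (OutOfDomainError, ValueError):
            continue
        sq = 0.0
        for v in beats:
            alpha, psi = solve_alpha_psi(v, weights)
            resid = v - (alpha * f_a.mu + psi * f_v.mu)
            sq += float(resid @ resid)
        sq /= len(beats)
        key = (sq, float(np.hypot(dx, dz)), dx, dz)
        if best is None or key < best[0]:
            best = (key, (dx, dz), f_a, f_v)
    if best is None:
        raise OutOfDomainError("no feasible shift: every candidate leaves the map domain")
    return best[1], best[2], best[3]
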