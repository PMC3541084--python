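"""Quasi-static dipole forward model of cardiac volume changes.

A weak AC current applied over the thorax creates a locally uniform
incident field E0 near the heart.  A change dV in the blood volume of a
cardiac compartment perturbs the field; to first order the perturbation
equals the field of a set of boundary dipoles: the volume change is
discretized into thin rods parallel to E0 (height h_i, cross-section A_i,
sum h_i A_i = dV), each carrying an effective dipole whose charge is

    q_i / eps = 2 E0 A_i (sigma_blood - sigma_tissue) / (sigma_blood + sigma_tissue)

The permittivity eps never appears on its own: all moments are carried as
q h / eps, which cancels between the dipole Green function and the charge
expression.  The insulating skin-air boundary is handled with image
dipoles (zero normal current through the skin).  On top of this the module
synthesizes full 6-channel electrode recordings over trains of beats, with
seeded noise and respiration-modulated baselines, together with the
ground-truth decomposition coefficients — the synthetic stand-in for the
ex-vivo fingerprint measurements and in-vivo recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ElectrodeLayout, FingerprintVector, PotentialGrid

__all__ = [
    "ThoraxModel",
    "SphereSource",
    "DipoleSet",
    "BeatWaveformSpec",
    "GridSpec",
    "SimulatedRecording",
    "dipole_potential",
    "dipole_set_potential",
    "volume_change_to_dipoles",
    "sphere_perturbation_exact",
    "mirror_sources",
    "electrode_fingerprints",
    "simulate_fingerprint_experiment",
    "simulate_recording",
    "ventricular_waveform",
    "default_sources",
]

_MM = 1e-3  # mm -> m
_ML = 1e-6  # ml -> m^3


@dataclass(frozen=True)
class ThoraxModel:
    """Volume-conductor parameters of the thorax.

    Skin lies in the y = 0 plane; y increases into the thorax, so sources
    must have y > 0.  ``e0_direction`` is the unit direction of the incident
    field (craniocaudal by default, i.e. -z); its magnitude ``e0`` (V/m) is
    arbitrary because the relative differential measurement cancels it.
    ``skin_mirror`` enables image dipoles for the insulating skin boundary.
    """

    sigma_tissue: float = 0.35  # S/m
    sigma_blood: float = 0.70  # S/m
    e0: float = 1.0  # V/m
    e0_direction: tuple = (0.0, 0.0, -1.0)
    skin_mirror: bool = True
    skin_plane_y: float = 0.0  # mm

    def __post_init__(self):
        if self.sigma_tissue <= 0 or self.sigma_blood <= 0:
            raise ValueError("conductivities must be positive")
        d = np.asarray(self.e0_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0):
            raise ValueError("e0_direction must be a unit vector")

    @property
    def e0_vec(self) -> np.ndarray:
        return self.e0 * np.asarray(self.e0_direction, dtype=float)

    @property
    def flat_contrast(self) -> float:
        """(sigma_b - sigma_t) / (sigma_b + sigma_t): flat-boundary dipole factor."""
        return (self.sigma_blood - self.sigma_tissue) / (self.sigma_blood + self.sigma_tissue)

    @property
    def sphere_contrast(self) -> float:
        """(sigma_b - sigma_t) / (sigma_b + 2 sigma_t): conducting-sphere factor."""
        return (self.sigma_blood - self.sigma_tissue) / (self.sigma_blood + 2 * self.sigma_tissue)


@dataclass(frozen=True)
class SphereSource:
    """Spherical cardiac compartment: center (x, y, z) mm, baseline volume ml."""

    center: tuple
    volume_ml: float
    compartment: str  # "atrial" | "ventricular"

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError("sphere volume must be positive")
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,):
            raise ValueError("sphere center must be a 3D point (x, y, z) in mm")

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.volume_ml * 1e3 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DipoleSet:
    """Point dipoles: positions in mm, moments (q h / eps) * e0_hat in V m^2."""

    positions: np.ndarray  # (n, 3) mm
    moments: np.ndarray  # (n, 3) V m^2

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.positions, dtype=float)).reshape(-1, 3)
        m = np.atleast_2d(np.asarray(self.moments, dtype=float)).reshape(-1, 3)
        if p.shape != m.shape:
            raise ValueError("positions and moments must have matching shapes")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "moments", m)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def total_moment(self) -> np.ndarray:
        return self.moments.sum(axis=0) if len(self) else np.zeros(3)


def default_sources() -> tuple:
    """Default two-compartment geometry (atrial, ventricular spheres).

    Both centers 60 mm deep; the ventricular sphere sits ~120 mm caudal of
    the atrial one, reproducing the caudal displacement of the ventricular
    fingerprint epicenter relative to the atrial epicenter.
    """
    atrial = SphereSource(center=(-10.0, 60.0, -40.0), volume_ml=120.0, compartment="atrial")
    ventric = SphereSource(center=(0.0, 60.0, -160.0), volume_ml=280.0, compartment="ventricular")
    return atrial, ventric


def dipole_potential(moment, source_pos_mm, field_pos_mm) -> float:
    """Potential (volts) of one point dipole; moment carries q h / eps (V m^2).

    phi(x) = moment . x_hat / (4 pi |x|^2), x = field - source, in metres.
    """
    x = (np.asarray(field_pos_mm, dtype=float) - np.asarray(source_pos_mm, dtype=float)) * _MM
    r = np.linalg.norm(x)
    if r == 0:
        raise ValueError("field point coincides with the dipole position")
    return float(np.asarray(moment, dtype=float) @ x / (4.0 * np.pi * r**3))


def dipole_set_potential(dipoles: DipoleSet, field_points_mm) -> np.ndarray:
    """Summed dipole potentials (volts) at one or more field points (mm)."""
    pts = np.atleast_2d(np.asarray(field_points_mm, dtype=float))
    if len(dipoles) == 0:
        return np.zeros(pts.shape[0])
    dx = (pts[:, None, :] - dipoles.positions[None, :, :]) * _MM  # (npts, ndip, 3)
    r = np.linalg.norm(dx, axis=2)
    if np.any(r == 0):
        raise ValueError("field point coincides with a dipole position")
    num = np.einsum("pdk,dk->pd", dx, dipoles.moments)
    return (num / (4.0 * np.pi * r**3)).sum(axis=1)


def volume_change_to_dipoles(
    source: SphereSource, dv_ml: float, model: ThoraxModel, n_rods: int = 12
) -> DipoleSet:
    """Discretize a compartment volume change into boundary rod dipoles.

    Rods run parallel to e0 through the baseline sphere; the rod through
    lateral offset rho carries the elongation of a uniformly inflating
    sphere (h proportional to dL/dR = 2R/chord), with the heights rescaled
    so that sum h_i A_i equals dv exactly.  Rod geometry (positions, areas)
    depends only on the baseline sphere, so the far-field scales exactly
    linearly with dv — the regularity assumption that underpins the linear
    superposition model.  Each rod contributes a half-height dipole at each
    spherical cap.
    """
    if n_rods < 1:
        raise ValueError("n_rods must be >= 1")
    if abs(dv_ml) > source.volume_ml:
        raise ValueError(
            f"unphysical volume change: |dV| = {abs(dv_ml):g} ml exceeds the "
            f"{source.volume_ml:g} ml sphere volume"
        )
    if dv_ml == 0:
        return DipoleSet(positions=np.zeros((0, 3)), moments=np.zeros((0, 3)))

    e0_hat = np.asarray(model.e0_direction, dtype=float)
    # orthonormal basis (u, w) perpendicular to the rod axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(e0_hat[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(e0_hat, helper)
    u /= np.linalg.norm(u)
    w = np.cross(e0_hat, u)

    R = source.radius_mm
    step = 2.0 * R / n_rods
    centers = -R + step * (np.arange(n_rods) + 0.5)
    uu, ww = np.meshgrid(centers, centers, indexing="ij")
    rho2 = uu**2 + ww**2
    inside = rho2 < R**2
    uu, ww, rho2 = uu[inside], ww[inside], rho2[inside]

    half_chord = np.sqrt(R**2 - rho2)  # mm
    area = (step * _MM) ** 2  # m^2 per rod
    h_raw = 2.0 * R / (2.0 * half_chord)  # elongation shape, d(chord)/dR
    total = np.sum(h_raw * _MM * area)  # m^3 at unit shape scale
    h = h_raw * (dv_ml * _ML / total)  # mm-scaled below via _MM in moments

    c = np.asarray(source.center, dtype=float)
    top = c + uu[:, None] * u + ww[:, None] * w + half_chord[:, None] * e0_hat
    bot = c + uu[:, None] * u + ww[:, None] * w - half_chord[:, None] * e0_hat
    positions = np.vstack([top, bot])

    q_over_eps = 2.0 * model.e0 * area * model.flat_contrast  # V m
    half_moment = q_over_eps * (h * _MM / 2.0)  # V m^2
    moments = np.outer(np.concatenate([half_moment, half_moment]), e0_hat)
    return DipoleSet(positions=positions, moments=moments)


def bookkeeping_volume_ml(source: SphereSource, dipoles: DipoleSet, model: ThoraxModel) -> float:
    """Recover sum h_i A_i (ml) from a rod dipole set (volume bookkeeping check)."""
    if len(dipoles) == 0:
        return 0.0
    e0_hat = np.asarray(model.e0_direction, dtype=float)
    s = float((dipoles.moments @ e0_hat).sum())  # sum of (q/eps) h = 2 E0 kappa * sum h A
    return s / (2.0 * model.e0 * model.flat_contrast) / _ML


def sphere_perturbation_exact(source: SphereSource, model: ThoraxModel, field_pos_mm) -> float:
    """Exact perturbation-to-incident field ratio |E~| / |E0| outside a sphere.

    A homogeneous conducting sphere in a uniform field perturbs the outside
    field exactly like a central dipole; the ratio peaks at 2k on the polar
    surface (axis parallel to E0) and is k at the equatorial surface, with
    k the sphere conductivity contrast.
    """
    x = (np.asarray(field_pos_mm, dtype=float) - np.asarray(source.center, dtype=float))
    r = np.linalg.norm(x)
    R = source.radius_mm
    if r < R:
        raise ValueError("field point lies inside the sphere")
    e0_hat = np.asarray(model.e0_direction, dtype=float)
    cos_t = float(x @ e0_hat) / r if r > 0 else 1.0
    k = model.sphere_contrast
    return abs(k) * (R / r) ** 3 * np.sqrt(4.0 * cos_t**2 + (1.0 - cos_t**2))


def mirror_sources(dipoles: DipoleSet, skin_plane_y: float | None = 0.0) -> DipoleSet:
    """Add image dipoles enforcing zero normal current through the skin plane.

    For an insulating boundary the image of a charge has the same sign, so
    an image dipole keeps its tangential moment components and flips the
    normal (y) component.  ``skin_plane_y=None`` disables the boundary and
    returns the input unchanged.
    """
    if skin_plane_y is None:
        return dipoles
    if len(dipoles) == 0:
        return dipoles
    if np.any(dipoles.positions[:, 1] <= skin_plane_y):
        raise ValueError("all sources must lie strictly on the thorax side of the skin plane")
    mirrored_pos = dipoles.positions.copy()
    mirrored_pos[:, 1] = 2.0 * skin_plane_y - mirrored_pos[:, 1]
    mirrored_mom = dipoles.moments.copy()
    mirrored_mom[:, 1] *= -1.0
    return DipoleSet(
        positions=np.vstack([dipoles.positions, mirrored_pos]),
        moments=np.vstack([dipoles.moments, mirrored_mom]),
    )


# ---------------------------------------------------------------------------
# static baseline field


def _static_equivalent_dipoles(model: ThoraxModel, sources) -> DipoleSet:
    """Central response dipoles of the baseline spheres in the incident field.

    Moment magnitude chosen so the potential matches the exact sphere
    solution k R^3 E0 cos(theta) / r^2 (converted to the q h / eps carrier
    used by :func:`dipole_set_potential`).
    """
    pos, mom = [], []
    e0_hat = np.asarray(model.e0_direction, dtype=float)
    for s in sources:
        scale = 4.0 * np.pi * model.sphere_contrast * (s.radius_mm * _MM) ** 3 * model.e0
        pos.append(np.asarray(s.center, dtype=float))
        mom.append(scale * e0_hat)
    return DipoleSet(positions=np.array(pos), moments=np.array(mom))


def _apply_mirror(model: ThoraxModel, dipoles: DipoleSet) -> DipoleSet:
    return mirror_sources(dipoles, model.skin_plane_y if model.skin_mirror else None)


def baseline_potential(model: ThoraxModel, sources, field_points_mm) -> np.ndarray:
    """Baseline (tau = 0) potential: incident field plus static sphere responses."""
    pts = np.atleast_2d(np.asarray(field_points_mm, dtype=float))
    phi = -(pts * _MM) @ model.e0_vec
    if sources:
        phi = phi + dipole_set_potential(_apply_mirror(model, _static_equivalent_dipoles(model, sources)), pts)
    return phi


def perturbation_potential(
    model: ThoraxModel, source: SphereSource, dv_ml: float, field_points_mm, n_rods: int = 12
) -> np.ndarray:
    """Potential change at field points caused by a compartment volume change."""
    rods = volume_change_to_dipoles(source, dv_ml, model, n_rods=n_rods)
    return dipole_set_potential(_apply_mirror(model, rods), field_points_mm)


# ---------------------------------------------------------------------------
# electrode-level quantities


def _electrode_points3d(layout: ElectrodeLayout) -> np.ndarray:
    xy = layout.xy
    return np.column_stack([xy[:, 0], np.zeros(len(xy)), xy[:, 1]])


def _pair_diff(values: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Pair voltages Phi^(k) = Phi(e_k) - Phi(e_{k-1}) for k = 1..6."""
    return np.array([values[a] - values[b] for a, b in layout.pairs])


def electrode_baselines(model: ThoraxModel, sources, layout: ElectrodeLayout) -> np.ndarray:
    """Baseline pair voltages Phi^(k)(0) (volts)."""
    return _pair_diff(baseline_potential(model, sources, _electrode_points3d(layout)), layout)


def unit_pair_responses(
    model: ThoraxModel, source: SphereSource, layout: ElectrodeLayout, n_rods: int = 12
) -> np.ndarray:
    """Pair-voltage change per ml of compartment volume change (V/ml)."""
    dphi = perturbation_potential(model, source, 1.0, _electrode_points3d(layout), n_rods=n_rods)
    return _pair_diff(dphi, layout)


def electrode_fingerprints(
    model: ThoraxModel,
    atrial: SphereSource,
    ventricular: SphereSource,
    layout: ElectrodeLayout,
    calib_volume: float = 50.0,
    n_rods: int = 12,
) -> tuple:
    """Fingerprint pair (f_A, f_V) measured directly at the electrode pairs.

    Emulates the ex-vivo calibration at the level of the six measuring
    pairs: fill one compartment with ``calib_volume`` ml (the other
    compartment's exchange is electrically annulled) and form the relative
    pair-voltage changes of eq-(2) form.
    """
    base = electrode_baselines(model, (atrial, ventricular), layout)
    mu_a = unit_pair_responses(model, atrial, layout, n_rods) * calib_volume / base
    mu_v = unit_pair_responses(model, ventricular, layout, n_rods) * calib_volume / base
    f_a = FingerprintVector(mu=mu_a, compartment="atrial", calib_volume=calib_volume)
    f_v = FingerprintVector(mu=mu_v, compartment="ventricular", calib_volume=calib_volume)
    return f_a, f_v


# ---------------------------------------------------------------------------
# fingerprint-experiment grids


@dataclass(frozen=True)
class GridSpec:
    """Rectangular skin electrode matrix: origin (x0, z0) mm, pitch mm, node counts."""

    x0: float = -70.0
    z0: float = -180.0
    nx: int = 5
    nz: int = 5
    pitch: float = 35.0

    def axes(self) -> tuple:
        return (
            self.x0 + self.pitch * np.arange(self.nx),
            self.z0 + self.pitch * np.arange(self.nz),
        )


def simulate_fingerprint_experiment(
    model: ThoraxModel,
    atrial: SphereSource,
    ventricular: SphereSource,
    grid_spec: GridSpec = GridSpec(),
    calib_volume: float = 50.0,
    n_rods: int = 12,
) -> dict:
    """Before/after skin potential grids for ventricle-only and atria-only filling.

    The filled compartment receives ``calib_volume`` ml of blood-equivalent
    solution while the other compartment exchanges thorax-equivalent
    solution, which is electrically invisible — so each 'after' grid
    contains the perturbation of exactly one compartment.  All node values
    are referenced to the reference electrode at the incisura jugularis
    (the coordinate origin).
    """
    gx, gz = grid_spec.axes()
    X, Z = np.meshgrid(gx, gz, indexing="ij")
    nodes = np.column_stack([X.ravel(), np.zeros(X.size), Z.ravel()])
    ref = np.array([[0.0, 0.0, 0.0]])

    base = baseline_potential(model, (atrial, ventricular), nodes)
    base_ref = baseline_potential(model, (atrial, ventricular), ref)[0]
    before = (base - base_ref).reshape(X.shape)

    grids = {}
    for src, tag in ((ventricular, "ventric"), (atrial, "atrial")):
        if calib_volume == 0:
            after = before
        else:
            dphi = perturbation_potential(model, src, calib_volume, nodes, n_rods=n_rods)
            dphi_ref = perturbation_potential(model, src, calib_volume, ref, n_rods=n_rods)[0]
            after = before + (dphi - dphi_ref).reshape(X.shape)
        grids[f"{tag}_before"] = PotentialGrid(x=gx, z=gz, values=before, label=f"{tag}_before")
        grids[f"{tag}_after"] = PotentialGrid(x=gx, z=gz, values=after, label=f"{tag}_after")
    return grids


# ---------------------------------------------------------------------------
# beat waveforms and full recordings


@dataclass(frozen=True)
class BeatWaveformSpec:
    """Ventricular volume-time template and recording conditions.

    Phase fractions split the RR interval into the six classical phases:
    isovolumetric contraction, ejection, isovolumetric relaxation, rapid
    filling, diastasis, atrial kick.  The atrial compartment follows the
    ventricular curve in anti-phase with amplitude ``atrial_amplitude_ml``.
    ``noise_sd`` is the per-channel additive noise SD as a fraction of the
    channel's baseline voltage; respiration multiplies the baselines with a
    sinusoid of the given depth and period.
    """

    heart_rate_bpm: float = 72.0
    sv_ml: float = 75.0
    phase_fractions: tuple = (0.05, 0.30, 0.05, 0.25, 0.25, 0.10)
    atrial_amplitude_ml: float = 30.0
    noise_sd: float = 0.0
    respiration_period_s: float = 4.0
    respiration_depth: float = 0.0
    sample_step_ms: float = 5.0

    def __post_init__(self):
        if self.heart_rate_bpm <= 0 or self.sv_ml < 0 or self.atrial_amplitude_ml < 0:
            raise ValueError("rates and amplitudes must be non-negative (heart rate positive)")
        if len(self.phase_fractions) != 6 or not np.isclose(sum(self.phase_fractions), 1.0):
            raise ValueError("the six phase fractions must sum to 1")
        if self.noise_sd < 0 or self.respiration_depth < 0:
            raise ValueError("noise and respiration depth must be non-negative")


def ventricular_waveform(frac, sv_ml: float, phase_fractions=(0.05, 0.30, 0.05, 0.25, 0.25, 0.10)):
    """Ventricular volume change dV(tau) (ml, <= 0) at beat fractions in [0, 1).

    Piecewise template over the six phases: flat at 0 during isovolumetric
    contraction, cosine ejection down to -SV, flat isovolumetric
    relaxation, cosine rapid filling to -0.30 SV, linear diastasis to
    -0.10 SV, cosine atrial kick back to 0.
    """
    f = np.atleast_1d(np.asarray(frac, dtype=float))
    edges = np.concatenate([[0.0], np.cumsum(phase_fractions)])
    dv = np.zeros_like(f)

    def seg(lo, hi, fn):
        m = (f >= lo) & (f < hi)
        if np.any(m):
            u = (f[m] - lo) / (hi - lo)
            dv[m] = fn(u)

    seg(edges[0], edges[1], lambda u: np.zeros_like(u))
    seg(edges[1], edges[2], lambda u: -sv_ml * 0.5 * (1 - np.cos(np.pi * u)))
    seg(edges[2], edges[3], lambda u: np.full_like(u, -sv_ml))
    seg(edges[3], edges[4], lambda u: -sv_ml + 0.70 * sv_ml * 0.5 * (1 - np.cos(np.pi * u)))
    seg(edges[4], edges[5], lambda u: -0.30 * sv_ml + 0.20 * sv_ml * u)
    seg(edges[5], 1.0 + 1e-12, lambda u: -0.10 * sv_ml * 0.5 * (1 + np.cos(np.pi * u)))
    return dv if np.ndim(frac) else float(dv[0])


@dataclass(frozen=True)
class SimulatedRecording:
    """Synthetic 6-channel recording with beat markers and ground truth."""

    time_ms: np.ndarray
    phi: np.ndarray  # (6, N) voltage amplitudes, volts
    r_peaks_ms: np.ndarray
    psi_true: np.ndarray  # ground-truth ventricular coefficient per sample
    alpha_true: np.ndarray
    sv_true_per_beat: np.ndarray
    baselines: np.ndarray  # static pair voltages (6,)
    calib_volume: float
    seed: int
    sample_step_ms: float = 5.0


def simulate_recording(
    spec: BeatWaveformSpec,
    model: ThoraxModel,
    sources,
    layout: ElectrodeLayout,
    n_beats: int,
    seed: int,
    sv_per_beat=None,
    calib_volume: float = 50.0,
    n_rods: int = 12,
) -> SimulatedRecording:
    """Synthesize a beat train of 6-channel voltage amplitudes at 200 Hz.

    Channel k follows
    Phi^(k)(t) = B_k [1 + d sin(2 pi t / T_resp)]
                 + u_V^(k) dV_V(t) + u_A^(k) dV_A(t) + noise,
    with B_k the static baseline pair voltage, u^(k) the per-ml unit pair
    responses of the two compartments, and seeded Gaussian noise of SD
    ``noise_sd * |B_k|``.  R-peaks lie on the sample grid; the ground-truth
    coefficients are psi = dV_V / V_calib and alpha = dV_A / V_calib.
    """
    atrial = next(s for s in sources if s.compartment == "atrial")
    ventric = next(s for s in sources if s.compartment == "ventricular")

    base = electrode_baselines(model, (atrial, ventric), layout)
    u_a = unit_pair_responses(model, atrial, layout, n_rods=n_rods)
    u_v = unit_pair_responses(model, ventric, layout, n_rods=n_rods)

    step = spec.sample_step_ms
    rr_ms = max(step, round(60000.0 / spec.heart_rate_bpm / step) * step)
    per_beat = int(round(rr_ms / step))
    n_samples = n_beats * per_beat + 1
    t_ms = step * np.arange(n_samples)

    if sv_per_beat is None:
        sv_per_beat = np.full(n_beats, spec.sv_ml)
    else:
        sv_per_beat = np.asarray(sv_per_beat, dtype=float)
        if sv_per_beat.shape != (n_beats,):
            raise ValueError("sv_per_beat must supply one stroke volume per beat")

    frac = (t_ms % rr_ms) / rr_ms
    beat_of = np.minimum((t_ms // rr_ms).astype(int), n_beats - 1)
    shape = ventricular_waveform(frac, 1.0, spec.phase_fractions)  # unit-SV template
    dv_v = shape * sv_per_beat[beat_of]
    atrial_scale = spec.atrial_amplitude_ml / spec.sv_ml if spec.sv_ml > 0 else 0.0
    dv_a = -atrial_scale * dv_v

    resp = 1.0 + spec.respiration_depth * np.sin(2.0 * np.pi * t_ms / (spec.respiration_period_s * 1e3))
    phi = base[:, None] * resp[None, :] + np.outer(u_v, dv_v) + np.outer(u_a, dv_a)

    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        phi = phi + spec.noise_sd * np.abs(base)[:, None] * rng.standard_normal(phi.shape)

    r_peaks = rr_ms * np.arange(n_beats + 1)
    return SimulatedRecording(
        time_ms=t_ms,
        phi=phi,
        r_peaks_ms=r_peaks,
        psi_true=dv_v / calib_volume,
        alpha_true=dv_a / calib_volume,
        sv_true_per_beat=sv_per_beat,
        baselines=base,
        calib_volume=calib_volume,
        seed=seed,
        sample_step_ms=step,
    )
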