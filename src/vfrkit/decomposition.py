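"""Two-source least-squares decomposition of thoracic voltage changes.

The measured per-beat pattern of relative voltage changes v_meas(tau) is
modelled as a superposition of two fixed spatial patterns, the atrial and
ventricular fingerprint vectors:

    v_meas(tau) = alpha(tau) f_A + psi(tau) f_V + noise

Solving the normal equations once yields time-independent "weight vectors"

    W_A = [(f_V.f_V) f_A - (f_A.f_V) f_V] / det
    W_V = [(f_A.f_A) f_V - (f_V.f_A) f_A] / det
    det = (f_A.f_A)(f_V.f_V) - (f_A.f_V)^2

after which decomposition is two inner products per time sample:
alpha = W_A.v, psi = W_V.v.  The ventricular volume-time curve follows as
V(tau) - V(0) = K_volunteer * psi(tau) * V_calib, anchored by the
calibration volume injected during the ex-vivo fingerprint measurement.

The core is exposed both as a scikit-learn transformer
(:class:`FingerprintDecomposer`) and as plain functions wrapping it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import FingerprintVector

__all__ = [
    "BeatSegment",
    "WeightVectors",
    "VolumeTimeCurve",
    "CalibrationScale",
    "FingerprintDecomposer",
    "CollinearFingerprintsError",
    "DegenerateBaselineError",
    "relative_change",
    "compute_weights",
    "solve_alpha_psi",
    "volume_curve",
    "stroke_volume",
    "calibrate_scale",
    "cardiac_output",
    "beat_volume_curve",
]

#: Scale-free collinearity threshold on the Gram determinant.
COLLINEARITY_RTOL = 1e-12


class CollinearFingerprintsError(ValueError):
    """f_A and f_V are (nearly) collinear; the decomposition is impossible."""


class DegenerateBaselineError(ValueError):
    """A channel's baseline voltage is zero; eq-(2) normalization undefined."""


@dataclass(frozen=True)
class BeatSegment:
    """One cardiac cycle of 6-channel voltage amplitudes, anchored at the R-peak.

    ``tau_grid`` holds milliseconds since the R-peak (5 ms step in the
    reference instrument); ``phi_abs`` the raw amplitudes (6 x T, volts);
    ``phi_rel`` the dimensionless relative changes of eq (2), which vanish
    identically at tau = 0.
    """

    beat_index: int
    tau_grid: np.ndarray
    phi_abs: np.ndarray
    phi_rel: np.ndarray
    baseline: np.ndarray
    r_peak_ms: float = 0.0

    def __post_init__(self):
        for name in ("tau_grid", "phi_abs", "phi_rel", "baseline"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.phi_abs.shape[0] != 6 or self.phi_rel.shape != self.phi_abs.shape:
            raise ValueError("beat segment must carry 6 x T voltage matrices")
        if self.tau_grid[0] != 0:
            raise ValueError("tau grid must start at the R-peak (tau = 0)")
        if np.any(self.baseline == 0):
            raise DegenerateBaselineError("zero baseline component in beat segment")
        if not np.allclose(self.phi_rel[:, 0], 0.0):
            raise ValueError("relative changes must vanish at tau = 0")


@dataclass(frozen=True)
class WeightVectors:
    """Dual vectors of the fingerprint pair: W_A.f_A = W_V.f_V = 1, W_A.f_V = W_V.f_A = 0."""

    w_a: np.ndarray
    w_v: np.ndarray
    gram_det: float
    f_a: np.ndarray
    f_v: np.ndarray


@dataclass(frozen=True)
class VolumeTimeCurve:
    """Per-beat decomposition result and ventricular volume-time curve (ml)."""

    tau_grid: np.ndarray
    alpha: np.ndarray
    psi: np.ndarray
    dv: np.ndarray
    sv: float
    residual_norm: np.ndarray
    beat_index: int = 0
    r_peak_ms: float = 0.0


@dataclass(frozen=True)
class CalibrationScale:
    """Per-subject scale K mapping psi * V_calib to absolute volume change."""

    k_volunteer: float = 1.0
    source: str = "unit"

    def __post_init__(self):
        if not (self.k_volunteer > 0):
            raise ValueError("k_volunteer must be positive")


class FingerprintDecomposer(TransformerMixin, BaseEstimator):
    """Project 6-channel measurement vectors onto a fingerprint pair.

    fit(X) takes the fingerprint matrix X of shape (2, 6) — row 0 the
    atrial fingerprint f_A, row 1 the ventricular fingerprint f_V — and
    precomputes the weight vectors.  transform(V) maps measurement vectors
    of shape (n_samples, 6) to coefficients (n_samples, 2) with columns
    (alpha, psi); this is the exact least-squares solution of the two-source
    model per sample.

    Attributes
    ----------
    weights_a_, weights_v_ : ndarray of shape (6,)
        Dual (weight) vectors of the fingerprint pair.
    gram_det_ : float
        Gram determinant (f_A.f_A)(f_V.f_V) - (f_A.f_V)^2.
    components_ : ndarray of shape (2, 6)
        The fitted fingerprint pair (rows f_A, f_V).
    """

    def __init__(self, collinearity_rtol: float = COLLINEARITY_RTOL):
        self.collinearity_rtol = collinearity_rtol

    def fit(self, X, y=None):
        F = np.asarray(X, dtype=float)
        if F.shape != (2, 6):
            raise ValueError(f"expected fingerprint matrix of shape (2, 6), got {F.shape}")
        f_a, f_v = F
        aa = float(f_a @ f_a)
        vv = float(f_v @ f_v)
        av = float(f_a @ f_v)
        det = aa * vv - av * av
        if det <= self.collinearity_rtol * aa * vv or aa == 0.0 or vv == 0.0:
            raise CollinearFingerprintsError(
                f"fingerprints are collinear within tolerance (gram det {det:.3e}); "
                "atrial and ventricular patterns cannot be separated"
            )
        self.components_ = F.copy()
        self.gram_det_ = det
        self.weights_a_ = (vv * f_a - av * f_v) / det
        self.weights_v_ = (aa * f_v - av * f_a) / det
        self.n_features_in_ = 6
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_a_")
        V = np.asarray(X, dtype=float)
        one_d = V.ndim == 1
        V = np.atleast_2d(V)
        if V.shape[1] != 6:
            raise ValueError(f"measurement vectors must have 6 channels, got {V.shape[1]}")
        coef = np.column_stack([V @ self.weights_a_, V @ self.weights_v_])
        return coef[0] if one_d else coef

    def inverse_transform(self, X):
        """Reconstruct measurement vectors from (alpha, psi) coefficients."""
        check_is_fitted(self, "components_")
        C = np.atleast_2d(np.asarray(X, dtype=float))
        return C @ self.components_

    def weight_vectors(self) -> WeightVectors:
        check_is_fitted(self, "weights_a_")
        return WeightVectors(
            w_a=self.weights_a_,
            w_v=self.weights_v_,
            gram_det=self.gram_det_,
            f_a=self.components_[0],
            f_v=self.components_[1],
        )


def _as_mu(f) -> np.ndarray:
    return f.mu if isinstance(f, FingerprintVector) else np.asarray(f, dtype=float)


def relative_change(phi_abs: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Dimensionless relative voltage change phi = (Phi(tau) - Phi(0)) / Phi(0).

    The division by the channel's own baseline factors out the applied
    current strength; the tau = 0 column is exactly zero.
    """
    phi_abs = np.asarray(phi_abs, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    zero = np.flatnonzero(baseline == 0)
    if zero.size:
        raise DegenerateBaselineError(f"zero baseline voltage on channel {zero[0] + 1}")
    return (phi_abs - baseline[:, None]) / baseline[:, None]


def compute_weights(f_a, f_v) -> WeightVectors:
    """Weight vectors W_A, W_V from a fingerprint pair (see module docstring)."""
    dec = FingerprintDecomposer().fit(np.vstack([_as_mu(f_a), _as_mu(f_v)]))
    return dec.weight_vectors()


def solve_alpha_psi(v_meas: np.ndarray, weights: WeightVectors):
    """Least-squares coefficients alpha = W_A.v, psi = W_V.v per time sample.

    ``v_meas`` may be a single 6-vector or a (6, T) matrix; returns scalars
    or length-T arrays accordingly.  The residual v - (alpha f_A + psi f_V)
    is orthogonal to both fingerprints.
    """
    v = np.asarray(v_meas, dtype=float)
    if v.shape[0] != 6:
        raise ValueError(f"measurement vector must have 6 channels, got shape {v.shape}")
    alpha = weights.w_a @ v
    psi = weights.w_v @ v
    return alpha, psi


def volume_curve(psi, calib_volume: float, scale: CalibrationScale | None = None) -> np.ndarray:
    """Ventricular volume change dV(tau) = K * psi(tau) * V_calib (ml)."""
    if calib_volume <= 0:
        raise ValueError("calib_volume must be positive")
    k = 1.0 if scale is None else scale.k_volunteer
    return k * np.asarray(psi, dtype=float) * calib_volume


def stroke_volume(curve) -> float:
    """Stroke volume as the end-diastolic minus end-systolic volume (ml).

    With tau = 0 anchored at the R-peak (end-diastole), the end-systolic
    volume is the curve minimum, so SV = -min dV, floored at zero.
    """
    dv = curve.dv if isinstance(curve, VolumeTimeCurve) else np.asarray(curve, dtype=float)
    if dv.size == 0:
        raise ValueError("empty volume curve")
    return max(0.0, -float(np.min(dv)))


def calibrate_scale(sv_method, sv_reference, source: str = "reference") -> CalibrationScale:
    """Per-subject scale from baseline stroke volumes: K = mean(ref) / mean(method)."""
    m = np.asarray(sv_method, dtype=float)
    r = np.asarray(sv_reference, dtype=float)
    if m.size == 0 or r.size == 0:
        raise ValueError("calibration requires non-empty SV lists")
    if m.mean() <= 0:
        raise ValueError("calibration error: mean method SV must be positive")
    return CalibrationScale(k_volunteer=float(r.mean() / m.mean()), source=source)


def cardiac_output(sv_ml: float, heart_rate_bpm: float) -> float:
    """Cardiac output in l/min from stroke volume (ml) and heart rate (bpm)."""
    if sv_ml < 0:
        raise ValueError("stroke volume must be non-negative")
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return round(sv_ml * heart_rate_bpm / 1000.0, 1)


def beat_volume_curve(
    beat: BeatSegment,
    weights: WeightVectors,
    calib_volume: float,
    scale: CalibrationScale | None = None,
    smooth_samples: int = 1,
) -> VolumeTimeCurve:
    """Decompose one beat into (alpha, psi) and its volume-time curve.

    ``smooth_samples`` > 1 applies a centred moving average to the volume
    curve before the stroke-volume minimum is taken, suppressing the upward
    SV bias that sample noise induces in the minimum; the stored alpha/psi
    series stay unsmoothed.
    """
    alpha, psi = solve_alpha_psi(beat.phi_rel, weights)
    recon = np.outer(weights.f_a, alpha) + np.outer(weights.f_v, psi)
    residual = np.linalg.norm(beat.phi_rel - recon, axis=0)
    dv = volume_curve(psi, calib_volume, scale)
    dv_for_sv = dv
    if smooth_samples > 1 and dv.size >= smooth_samples:
        kernel = np.ones(smooth_samples) / smooth_samples
        dv_for_sv = np.convolve(dv, kernel, mode="same")
    return VolumeTimeCurve(
        tau_grid=beat.tau_grid,
        alpha=np.atleast_1d(alpha),
        psi=np.atleast_1d(psi),
        dv=dv,
        sv=stroke_volume(dv_for_sv),
        residual_norm=residual,
        beat_index=beat.beat_index,
        r_peak_ms=beat.r_peak_ms,
    )
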