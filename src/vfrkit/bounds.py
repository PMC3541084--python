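"""Worst-case deviation-from-linearity bounds for the superposition model.

The decomposition assumes the relative voltage change scales linearly with
the volume change ratio lambda = V~(n)/V~(0).  Self-interaction of the
perturbed field (a sphere shadowing itself via a neighbouring sphere, the
skin-air image, or atrial counter-filling) adds higher-order terms; with
interaction strength eta and cross-term coefficient zeta the worst-case
second-order voltage-change ratio is

    ratio(lambda) = lambda (1 + eta zeta + eta lambda) / (1 + eta zeta + eta)

normalized so ratio(1) = 1 at the calibration point.  Closing the full
perturbation series geometrically on the self-interaction term replaces
eta lambda by eta lambda / (1 - eta lambda).

Reference eta values for the anatomical features: non-spherical ventricle
-0.033, skin boundary +0.035, skin boundary combined with atrial
counter-filling +0.142 (worst case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ETA_FEATURES",
    "BoundConfig",
    "ratio_second_order",
    "ratio_full_series",
    "deviation_pct",
    "figure_curves",
]

#: Interaction strengths per anatomical feature.
ETA_FEATURES = {
    "non_spherical_ventricle": -0.033,
    "skin_boundary": 0.035,
    "skin_boundary_plus_atrial": 0.142,
}


@dataclass(frozen=True)
class BoundConfig:
    """Evaluation grid and mode for one bound curve."""

    eta: float
    zeta: float = 0.0
    mode: str = "second_order"  # or "full_series"
    lambda_grid: tuple = field(default=tuple(np.round(np.linspace(0.25, 2.5, 46), 4)))

    def __post_init__(self):
        if self.mode not in ("second_order", "full_series"):
            raise ValueError("mode must be 'second_order' or 'full_series'")
        lam = np.asarray(self.lambda_grid, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("volume ratios lambda must be positive")


def ratio_second_order(lam, eta: float, zeta: float = 0.0):
    """Second-order worst-case voltage-change ratio at volume ratio(s) lam."""
    lam = np.asarray(lam, dtype=float)
    denom = 1.0 + eta * zeta + eta
    if np.isclose(denom, 0.0):
        raise ValueError("singular parameters: 1 + eta*zeta + eta = 0")
    out = lam * (1.0 + eta * zeta + eta * lam) / denom
    return out if out.ndim else float(out)


def ratio_full_series(lam, eta: float, zeta: float = 0.0):
    """Geometric-series closure of the self-interaction term.

    The eta*lambda self-interaction is summed to all orders as
    eta lambda / (1 - eta lambda); the eta*zeta cross term stays first
    order.  Requires |eta lambda| < 1 (and |eta| < 1 for the calibration
    denominator); truncating the series after its first term reproduces the
    second-order ratio.
    """
    lam = np.asarray(lam, dtype=float)
    if abs(eta) >= 1.0 or np.any(np.abs(eta * lam) >= 1.0):
        raise ValueError("perturbation series diverges: |eta * lambda| must stay below 1")
    denom = 1.0 + eta * zeta + eta / (1.0 - eta)
    if np.isclose(denom, 0.0):
        raise ValueError("singular parameters: series-closed denominator is 0")
    out = lam * (1.0 + eta * zeta + eta * lam / (1.0 - eta * lam)) / denom
    return out if out.ndim else float(out)


def deviation_pct(lam, eta: float, zeta: float = 0.0, mode: str = "second_order"):
    """Deviation from linearity, percent of the linear prediction: 100 (ratio - lam)/lam."""
    fn = ratio_second_order if mode == "second_order" else ratio_full_series
    lam_arr = np.asarray(lam, dtype=float)
    out = 100.0 * (np.asarray(fn(lam, eta, zeta)) - lam_arr) / lam_arr
    return out if out.ndim else float(out)


def figure_curves(configs=None) -> dict:
    """Bound curves per feature, plus the identity line; all pass through (1, 1).

    Returns a dict mapping curve name to an (n, 2) array of (lambda, ratio)
    pairs.  With no configs the three reference features are evaluated:
    second order for the skin boundary, full series for each feature, as in
    the canonical bound plot.
    """
    if configs is None:
        configs = {
            "identity": None,
            "skin_boundary_2nd": BoundConfig(eta=ETA_FEATURES["skin_boundary"]),
            "skin_boundary_full": BoundConfig(eta=ETA_FEATURES["skin_boundary"], mode="full_series"),
            "non_spherical_full": BoundConfig(
                eta=ETA_FEATURES["non_spherical_ventricle"], mode="full_series"
            ),
            "worst_case_full": BoundConfig(
                eta=ETA_FEATURES["skin_boundary_plus_atrial"], mode="full_series"
            ),
        }
    curves = {}
    for name, cfg in configs.items():
        if cfg is None:
            lam = np.asarray(BoundConfig(eta=0.0).lambda_grid)
            curves[name] = np.column_stack([lam, lam])
            continue
        lam = np.asarray(cfg.lambda_grid, dtype=float)
        fn = ratio_second_order if cfg.mode == "second_order" else ratio_full_series
        curves[name] = np.column_stack([lam, fn(lam, cfg.eta, cfg.zeta)])
    return curves
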