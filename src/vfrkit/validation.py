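"""Reference-method agreement statistics and the G-suit validation scenario.

Stroke-volume readings from the decomposition are compared against a
reference method (LVot Doppler in the validation study) with Pearson
correlation and Bland-Altman statistics; the G-suit scenario generator
produces a reference stroke-volume trajectory with the four protocol
stages (baseline, inflation, inflated, deflated) for end-to-end demos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "STAGES",
    "PairedSV",
    "AgreementReport",
    "GSuitTimings",
    "bland_altman",
    "pearson",
    "gsuit_scenario",
    "pair_windows",
]

STAGES = ("baseline", "inflation", "inflated", "deflated")


@dataclass(frozen=True)
class PairedSV:
    """One paired stroke-volume reading: method vs reference, with stage label."""

    sv_method: float
    sv_reference: float
    stage: str = "baseline"
    subject: str = ""
    time_s: float = 0.0

    def __post_init__(self):
        if self.sv_method < 0 or self.sv_reference < 0:
            raise ValueError("stroke volumes must be non-negative")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary: bias, spread and limits of agreement (ml)."""

    pearson_r: float
    mean_bias: float
    sd: float

    @property
    def two_sd(self) -> float:
        return 2.0 * self.sd

    @property
    def upper_loa(self) -> float:
        return self.mean_bias + self.two_sd

    @property
    def lower_loa(self) -> float:
        return self.mean_bias - self.two_sd

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mean_bias_ml": self.mean_bias,
            "sd_ml": self.sd,
            "two_sd_ml": self.two_sd,
            "upper_loa_ml": self.upper_loa,
            "lower_loa_ml": self.lower_loa,
        }


def _columns(pairs):
    m = np.array([p.sv_method for p in pairs], dtype=float)
    r = np.array([p.sv_reference for p in pairs], dtype=float)
    return m, r


def bland_altman(pairs) -> AgreementReport:
    """Bland-Altman agreement of method vs reference stroke volumes.

    Differences are method minus reference; bias is their mean, the spread
    is the sample SD (n-1), and the limits of agreement are bias +- 2 SD
    (exactly 2, not 1.96).  Pearson r is included when >= 3 pairs with
    non-degenerate variance are available, else NaN.
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman analysis requires at least 2 pairs")
    m, r = _columns(pairs)
    d = m - r
    sd = float(np.std(d, ddof=1))
    try:
        r_val = pearson(pairs)
    except ValueError:
        r_val = float("nan")
    return AgreementReport(pearson_r=r_val, mean_bias=float(d.mean()), sd=sd)


def pearson(pairs) -> float:
    """Pearson product-moment correlation of method vs reference SV."""
    if len(pairs) < 3:
        raise ValueError("Pearson correlation requires at least 3 pairs")
    m, r = _columns(pairs)
    if np.var(m) == 0 or np.var(r) == 0:
        raise ValueError("degenerate input: a column has zero variance")
    return float(sps.pearsonr(m, r).statistic)


@dataclass(frozen=True)
class GSuitTimings:
    """Stage durations (s) of the G-suit protocol.

    Defaults follow the validation protocol: inflation 0 -> 70 mmHg over
    150 s, 120 s at constant pressure, deflation within 5 s; the scenario
    starts at inflation onset, so an explicit baseline dwell (and a
    post-deflation recovery) must be requested when needed.
    """

    baseline_s: float = 0.0
    inflation_s: float = 150.0
    inflated_s: float = 120.0
    deflation_s: float = 5.0
    recovery_s: float = 85.0

    def __post_init__(self):
        for name in ("baseline_s", "inflation_s", "inflated_s", "deflation_s", "recovery_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.inflation_s == 0 or self.deflation_s == 0:
            raise ValueError("inflation and deflation must have positive duration")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.inflation_s + self.inflated_s + self.deflation_s + self.recovery_s

    def boundaries(self) -> dict:
        """Stage start times (s) from scenario start."""
        t0 = self.baseline_s
        return {
            "baseline": 0.0,
            "inflation": t0,
            "inflated": t0 + self.inflation_s,
            "deflated": t0 + self.inflation_s + self.inflated_s + self.deflation_s,
        }


def gsuit_scenario(
    seed: int,
    timings: GSuitTimings = GSuitTimings(),
    dt_s: float = 1.0,
    sv_baseline_ml: float = 75.0,
    sv_inflated_ml: float = 90.0,
    sv_deflated_ml: float = 62.0,
    recovery_tau_s: float = 60.0,
    wander_sd_ml: float = 1.0,
):
    """Reference stroke-volume trajectory over the G-suit protocol.

    SV rises smoothly during inflation (leg compression raises venous
    return), plateaus while inflated, drops abruptly within the deflation
    interval, and relaxes back toward baseline during recovery.  A seeded
    slow physiological wander (smoothed Gaussian, ``wander_sd_ml``) is
    superposed.  Returns ``(t_s, sv_ml, stages)`` with one stage label per
    sample.
    """
    t = np.arange(0.0, timings.total_s, dt_s)
    b = timings.boundaries()
    sv = np.empty_like(t)
    stages = np.empty(t.shape, dtype=object)

    for i, ti in enumerate(t):
        if ti < b["inflation"]:
            sv[i] = sv_baseline_ml
            stages[i] = "baseline"
        elif ti < b["inflated"]:
            u = (ti - b["inflation"]) / timings.inflation_s
            sv[i] = sv_baseline_ml + (sv_inflated_ml - sv_baseline_ml) * 0.5 * (1 - np.cos(np.pi * u))
            stages[i] = "inflation"
        elif ti < b["deflated"] - timings.deflation_s:
            sv[i] = sv_inflated_ml
            stages[i] = "inflated"
        elif ti < b["deflated"]:
            u = (ti - (b["deflated"] - timings.deflation_s)) / timings.deflation_s
            sv[i] = sv_inflated_ml + (sv_deflated_ml - sv_inflated_ml) * u
            stages[i] = "deflated"
        else:
            dt_rec = ti - b["deflated"]
            sv[i] = sv_baseline_ml + (sv_deflated_ml - sv_baseline_ml) * np.exp(-dt_rec / recovery_tau_s)
            stages[i] = "deflated"

    rng = np.random.default_rng(seed)
    wander = rng.standard_normal(t.size)
    # ~0.02 Hz smoothing: physiological beat-to-beat drift, not sample noise
    kernel = np.exp(-0.5 * (np.arange(-30, 31) / (10.0 / dt_s)) ** 2)
    kernel /= kernel.sum()
    wander = np.convolve(wander, kernel, mode="same")
    if wander.std() > 0:
        wander = wander / wander.std() * wander_sd_ml
    return t, sv + wander, stages


def pair_windows(
    t_method_s,
    sv_method,
    t_reference_s,
    sv_reference,
    stages=None,
    max_gap_s: float = 15.0,
) -> list:
    """Match method windows to nearest-in-time reference readings (+-max_gap_s)."""
    t_m = np.asarray(t_method_s, dtype=float)
    t_r = np.asarray(t_reference_s, dtype=float)
    sv_m = np.asarray(sv_method, dtype=float)
    sv_r = np.asarray(sv_reference, dtype=float)
    pairs = []
    for i, tm in enumerate(t_m):
        j = int(np.argmin(np.abs(t_r - tm)))
        if abs(t_r[j] - tm) > max_gap_s:
            continue
        stage = stages[j] if stages is not None else "baseline"
        pairs.append(
            PairedSV(
                sv_method=float(sv_m[i]),
                sv_reference=float(sv_r[j]),
                stage=str(stage),
                time_s=float(tm),
            )
        )
    return pairs
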