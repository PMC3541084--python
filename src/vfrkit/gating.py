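"""Band splitting, beat segmentation, and respiration (Phi-) gating.

The instrument splits every channel into a slow 'average' component V_avg
(below 0.072 Hz) and a fluctuation component V_fluct (0.072-34 Hz); the
absolute baseline voltage at each R-peak tracks the air volume in the
lungs, so selecting beats whose baselines match in amplitude and trend
within each 20 s measurement window gates the analysis to a fixed
respiratory phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .decomposition import BeatSegment, relative_change

__all__ = [
    "FilterSpec",
    "GatingConfig",
    "GatedWindow",
    "split_bands",
    "segment_beats",
    "phi_gate",
]


@dataclass(frozen=True)
class FilterSpec:
    """Digital stand-in for the analog channel filters (zero-phase Butterworth)."""

    lowpass_cutoff_hz: float = 0.072
    bandpass_high_hz: float = 34.0
    sample_rate_hz: float = 200.0
    order: int = 2

    def __post_init__(self):
        if not (0 < self.lowpass_cutoff_hz < self.bandpass_high_hz < self.sample_rate_hz / 2):
            raise ValueError("cutoffs must satisfy 0 < low < high < Nyquist")


@dataclass(frozen=True)
class GatingConfig:
    """Phi-gating parameters.

    ``amplitude_tolerance`` is the relative half-width of the 'same lung
    volume' band around the window's median baseline; the trend rule keeps
    beats whose baseline first difference matches the window's modal sign.
    ``channel`` selects the pair whose baseline drives the gate (the top
    sternal pair by default).
    """

    window_s: float = 20.0
    amplitude_tolerance: float = 0.02
    min_beats: int = 3
    channel: int = 0
    #: the trend rule engages only when the window's baseline peak-to-peak
    #: range exceeds this fraction of the amplitude tolerance band — with no
    #: respiratory modulation the baseline 'trend' is sensor noise and
    #: filtering on it would discard half the beats for nothing
    trend_activation_fraction: float = 0.5

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0 < self.amplitude_tolerance < 1):
            raise ValueError("amplitude_tolerance must lie in (0, 1)")
        if self.min_beats < 1:
            raise ValueError("min_beats must be >= 1")


@dataclass
class GatedWindow:
    """Beats of one measurement window with the gated selection."""

    start_s: float
    beats: list
    selected: list
    gated: bool  # False when the window had to fall back to all beats

    @property
    def n_total(self) -> int:
        return len(self.beats)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def split_bands(raw: np.ndarray, spec: FilterSpec = FilterSpec()):
    """Split channel series into (V_avg, V_fluct) with zero-phase filters.

    V_avg is the sub-0.072 Hz content, V_fluct the 0.072-34 Hz band; their
    sum reconstructs the sub-34 Hz content of the input.  Zero-phase
    (forward-backward) filtering preserves the tau alignment of the beats.
    """
    x = np.asarray(raw, dtype=float)
    n = x.shape[-1]
    nyq = spec.sample_rate_hz / 2.0
    min_len = 3 * (2 * spec.order + 1)
    if n <= 3 * min_len:
        raise ValueError(f"series of {n} samples is shorter than the filter warm-up")
    sos_lo = signal.butter(spec.order, spec.lowpass_cutoff_hz / nyq, btype="low", output="sos")
    sos_bp = signal.butter(
        spec.order,
        [spec.lowpass_cutoff_hz / nyq, spec.bandpass_high_hz / nyq],
        btype="band",
        output="sos",
    )
    v_avg = signal.sosfiltfilt(sos_lo, x, axis=-1)
    v_fluct = signal.sosfiltfilt(sos_bp, x, axis=-1)
    return v_avg, v_fluct


def segment_beats(
    phi: np.ndarray,
    r_peaks_ms,
    sample_step_ms: float = 5.0,
    min_rr_ms: float = 250.0,
    max_rr_ms: float = 2500.0,
) -> list:
    """Cut 6-channel streams into per-beat segments anchored at the R-peaks.

    One segment per RR interval, tau on the sample grid, baseline taken at
    the tau = 0 sample.  RR intervals outside [min_rr_ms, max_rr_ms] are
    rejected as marker artefacts.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != 6:
        raise ValueError("streams must form a 6 x N matrix")
    peaks = np.asarray(r_peaks_ms, dtype=float)
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("R-peak markers must be strictly increasing")
    n = phi.shape[1]
    beats = []
    for i in range(len(peaks) - 1):
        rr = peaks[i + 1] - peaks[i]
        if not (min_rr_ms <= rr <= max_rr_ms):
            continue
        i0 = int(round(peaks[i] / sample_step_ms))
        i1 = int(round(peaks[i + 1] / sample_step_ms))
        if i0 < 0 or i1 > n:
            continue  # stream does not cover this beat
        seg = phi[:, i0:i1]
        baseline = seg[:, 0]
        beats.append(
            BeatSegment(
                beat_index=len(beats),
                tau_grid=sample_step_ms * np.arange(seg.shape[1]),
                phi_abs=seg,
                phi_rel=relative_change(seg, baseline),
                baseline=baseline,
                r_peak_ms=float(peaks[i]),
            )
        )
    return beats


def _modal_sign(diffs: np.ndarray) -> float:
    signs = np.sign(diffs)
    pos = np.sum(signs > 0)
    neg = np.sum(signs < 0)
    if pos == 0 and neg == 0:
        return 0.0
    return 1.0 if pos >= neg else -1.0


def phi_gate(beats, config: GatingConfig = GatingConfig()) -> list:
    """Select beats at a fixed respiratory phase within each measurement window.

    Within each window (assignment by R-peak time) a beat survives when its
    gating-channel baseline lies within ``amplitude_tolerance`` of the
    window's median baseline (same lung volume) and its baseline
    first-difference sign matches the window's modal sign (same trend).  If
    fewer than ``min_beats`` survive, the tolerance is relaxed once by a
    factor 2; failing that the window is flagged ungated and keeps all its
    beats.  Gating is a pure selection and never alters beat contents.
    """
    windows: dict[int, list] = {}
    for b in beats:
        windows.setdefault(int(b.r_peak_ms / 1000.0 // config.window_s), []).append(b)

    out = []
    for w_idx in sorted(windows):
        wbeats = sorted(windows[w_idx], key=lambda b: b.r_peak_ms)
        base = np.array([b.baseline[config.channel] for b in wbeats])
        diffs = np.diff(base, prepend=base[0])
        med = np.median(base)
        modulated = (base.max() - base.min()) > (
            config.trend_activation_fraction * config.amplitude_tolerance * abs(med)
        )
        modal = _modal_sign(np.diff(base)) if (modulated and len(base) > 1) else 0.0

        def survivors(tol):
            keep = []
            for b, amp, d in zip(wbeats, base, diffs):
                amp_ok = abs(amp - med) <= tol * abs(med) if med != 0 else amp == 0
                trend_ok = modal == 0.0 or np.sign(d) == modal or d == 0
                if amp_ok and trend_ok:
                    keep.append(b)
            return keep

        sel = survivors(config.amplitude_tolerance)
        gated = True
        if len(sel) < config.min_beats:
            sel = survivors(2.0 * config.amplitude_tolerance)
        if len(sel) < config.min_beats:
            sel = list(wbeats)
            gated = False
        out.append(
            GatedWindow(start_s=w_idx * config.window_s, beats=wbeats, selected=sel, gated=gated)
        )
    return out
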