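# vfrkit

Non-invasive, operator-free monitoring of ventricular stroke volume (SV)
and per-beat ventricular volume–time curves from multi-channel voltage
recordings on the frontal thoracic skin — the *ventricular field
recognition* approach, in which cardiac volume changes are read from 2D
spatial voltage-change patterns rather than from a bulk impedance.

## The method

A weak AC current applied over the thorax produces a quasi-static field;
six electrode pairs (seven electrodes e₀…e₆ along the sternal line) record
voltage amplitudes Φ⁽ᵏ⁾(τ) every 5 ms, with τ the time since the last
R-peak. Each channel is normalized to a dimensionless relative change

    φ⁽ᵏ⁾(τ) = [Φ⁽ᵏ⁾(τ) − Φ⁽ᵏ⁾(0)] / Φ⁽ᵏ⁾(0),

which removes the applied current strength. The measurement vector
v(τ) ∈ ℝ⁶ is modelled as a superposition of two fixed spatial patterns —
the atrial and ventricular *fingerprint vectors* f_A and f_V, measured
ex-vivo by filling one cardiac compartment with a known calibration volume
Ṽ_calib (50 ml):

    v(τ) = α(τ) f_A + ψ(τ) f_V + noise.

Least squares gives time-independent weight vectors

    W_A = [(f_V·f_V) f_A − (f_A·f_V) f_V] / D,
    W_V = [(f_A·f_A) f_V − (f_V·f_A) f_A] / D,
    D   = (f_A·f_A)(f_V·f_V) − (f_A·f_V)²,

so decomposition is two inner products per sample: α = W_A·v, ψ = W_V·v,
and the ventricular volume–time curve is

    V(τ) − V(0) = K · ψ(τ) · Ṽ_calib,

with K a per-subject scale calibrated once against a reference SV. Stroke
volume is the end-diastolic minus end-systolic volume, i.e. −min_τ dV(τ).

The package also provides

- a **dipole forward simulator** (boundary rod dipoles of a spherical
  compartment in a uniform incident field, with image dipoles for the
  insulating skin boundary) that generates electrode recordings, skin
  potential grids and ground truth;
- **respiration (Φ-) gating**: beats are selected per 20 s window by the
  amplitude and trend of their baseline voltages, a surrogate for lung
  volume and respiratory phase;
- **non-linearity bounds**: worst-case deviation of the voltage–volume
  relation from linearity, ratio(λ) = λ(1+ηζ+ηλ)/(1+ηζ+η) at second order
  and its geometric-series closure;
- **agreement statistics**: Pearson correlation and Bland-Altman limits
  (bias ± 2·SD), plus a G-suit inflation/deflation scenario generator.

The decomposition core is a scikit-learn transformer
(`FingerprintDecomposer`: `fit` on the 2×6 fingerprint matrix, `transform`
measurement vectors to (α, ψ) coefficients).

## Worked example

```python
import numpy as np
from vfrkit import (ThoraxModel, ElectrodeLayout, BeatWaveformSpec,
                    electrode_fingerprints, simulate_recording,
                    compute_weights, solve_alpha_psi, cardiac_output)
from vfrkit.forward import default_sources
from vfrkit.gating import segment_beats

model, layout = ThoraxModel(), ElectrodeLayout()
atrial, ventric = default_sources()
f_A, f_V = electrode_fingerprints(model, atrial, ventric, layout, calib_volume=50.0)

spec = BeatWaveformSpec(heart_rate_bpm=69.0, sv_ml=73.0,
                        noise_sd=0.0, respiration_depth=0.0)
rec = simulate_recording(spec, model, (atrial, ventric), layout, n_beats=3, seed=7)
beat = segment_beats(rec.phi, rec.r_peaks_ms)[0]
_, psi = solve_alpha_psi(beat.phi_rel, compute_weights(f_A, f_V))
dv = psi * 50.0
sv = -dv.min()
print(f"SV = {sv:.1f} ml, CO = {cardiac_output(sv, 69.0):.1f} l/min")
```

prints

```
SV = 73.0 ml, CO = 5.0 l/min
```

— the programmed 73 ml stroke volume is recovered exactly from the
noise-free synthetic recording, and at 69 bpm corresponds to a cardiac
output of 5.0 l/min.

The command-line entry point `vfr` exposes the same pipeline
(`vfr simulate`, `vfr fingerprint`, `vfr decompose`, `vfr bounds`,
`vfr validate`); every simulation command requires `--seed` and outputs
carry the seed and a config hash in their headers.

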