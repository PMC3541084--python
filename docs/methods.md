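# Methods

## Model

The package treats the thorax as a quasi-static volume conductor. An
applied AC current (58–90 kHz in the reference instrument) creates an
incident field **E₀** that is locally uniform near the heart; at these
frequencies the capacitive term 2πfε is negligible against tissue
conductivity differences, so only voltage amplitudes are modelled. A
change dV in the blood volume of a cardiac compartment perturbs the field;
to first order the perturbation is the field of surface charge dipoles on
the moving blood–tissue boundary. The linear superposition model for the
six relative pair voltages,

    v(τ) = α(τ) f_A + ψ(τ) f_V + noise,

follows from this first-order picture together with a regularity
assumption: the spatial pattern of the volume change scales with its
amplitude (every boundary rod elongates proportionally), so a compartment
contributes a fixed 6-channel pattern whose coefficient is proportional to
its volume change. ψ is anchored to absolute volume by the calibration
volume Ṽ_calib = 50 ml used when the ventricular fingerprint is measured:
ψ = 1 corresponds to a 50 ml ventricular volume increase.

The decomposition solves the two-parameter least-squares problem per
5 ms sample via precomputed dual ("weight") vectors; the residual is
orthogonal to both fingerprints by construction, and ψ is a linear
function of the six measured voltages. The pair must be non-collinear:
the Gram determinant is checked against a scale-free threshold
(10⁻¹² × (f_A·f_A)(f_V·f_V)) and a collinear pair is a hard error, since
atrial and ventricular contributions are then indistinguishable.

## Coordinates, electrodes and fingerprint normalization

Skin coordinates (x, z) are millimetres with the origin at the incisura
jugularis; z is negative caudally; y runs into the thorax with the skin at
y = 0. The default layout places e₀…e₆ at (0,0), (0,−60), (−30,−90),
(−30,−120), (0,−157), (35,−187), (−92,−197) mm; pair k measures
Φ⁽ᵏ⁾ = Φ(e_k) − Φ(e_{k−1}).

The fingerprint field m(x,z) is the potential change per 30 mm of vertical
baseline potential drop (the denominator is the baseline potential
difference between (x, z−15) and (x, z+15)). When m is sampled at the
electrodes to build a fingerprint vector, the pair difference is rescaled
by 30 mm over the pair's **vertical** separation |z_{k−1} − z_k|. Under a
(craniocaudally directed) uniform incident field the baseline pair voltage
is proportional to the vertical separation, so this choice makes μ⁽ᵏ⁾ from
the map agree exactly with the relative pair-voltage change; pairs 2 and 3
(vertical span 30 mm) reduce to the plain m difference. Euclidean-distance
scaling was considered and rejected: pair 2's oblique 42.4 mm separation
would then break that agreement. The oblique pair e₅–e₆ (Δz = 10 mm) gets
a factor 3 under this convention, which amplifies its noise; this is the
price of keeping the map route and the direct electrode route consistent.

Interpolation on potential grids is bilinear and confined to the sampled
hull — extrapolation is an error, because skin measurements exist only on
the thoracic chest. The m-map denominator is guarded by a configurable
floor (default 10⁻⁶ × max|Φ_before|); a vanishing vertical gradient raises
an error naming the offending point. The grid container is a general
rectangular grid: the classical ex-vivo matrix is 5×5 at 35 mm pitch, but
that 140 mm span cannot cover the 197 mm vertical extent of the electrode
layout, so map-based fingerprints for the full layout require a wider
grid (the simulator's `GridSpec` makes this a one-line change).

Virtual-displacement matching handles inter-subject anatomical offsets:
candidate heart displacements (default ±30 mm, 5 mm step — finer than the
electrode pitch and of the order of the atrial–ventricular epicenter
separation) shift the electrode sampling positions, fingerprints are
rebuilt per shift, and the shift minimizing the mean squared decomposition
residual over calibration beats wins; ties break to the smallest shift,
then lexicographically.

## Forward simulator

The synthetic-data generator implements the dipole physics directly:

- **Rod dipoles.** A compartment is a sphere (atrial 120 ml centered at
  (−10, 60, −40) mm; ventricular 280 ml at (0, 60, −160) mm — both 60 mm
  deep, ~120 mm apart so the simulated fingerprint epicenters reproduce
  the observed caudal displacement). A volume change dV is discretized
  into rods parallel to ê₀ through the baseline sphere; rod heights follow
  the uniform-inflation profile and are rescaled so Σ hᵢAᵢ = dV exactly.
  Rod geometry depends only on the baseline sphere, so the far field is
  exactly linear in dV — the simulator realizes the regularity assumption
  by construction, which is what makes noise-free pipeline closure exact
  to machine precision (and is also why closure alone cannot probe
  non-linear errors; the bounds module exists for that).
- **Charges.** Each rod carries q/ε = 2E₀A(σ_b−σ_t)/(σ_b+σ_t) (flat
  boundary factor); the exact sphere-in-uniform-field solution uses
  (σ_b−σ_t)/(σ_b+2σ_t). Both contrasts are exposed; rod dipoles default to
  the flat factor and `sphere_perturbation_exact` to the sphere factor.
  ε never appears alone — moments are carried as q·h/ε throughout.
- **Skin boundary.** The insulating skin–air interface is enforced by
  image dipoles (tangential moment preserved, normal component flipped),
  giving zero normal potential derivative on the plane.
- **Defaults.** σ_blood = 0.70 S/m, σ_tissue = 0.35 S/m (literature-typical
  at the instrument's frequencies); E₀ = 1 V/m directed craniocaudally
  (−z). The E₀ magnitude cancels in the relative differential measurement
  and is therefore arbitrary.
- **Recordings.** Channel k is synthesized as
  Φ⁽ᵏ⁾(t) = B_k·[1 + d·sin(2πt/T_resp)] + u_V⁽ᵏ⁾ dV_V(t) + u_A⁽ᵏ⁾ dV_A(t) + noise,
  with B_k the static baseline (incident field plus the spheres' static
  dipole responses), u⁽ᵏ⁾ the per-ml unit responses, additive Gaussian
  noise of SD = noise_sd × |B_k| per sample, and multiplicative sinusoidal
  respiration on the baseline only. All randomness comes from one seeded
  generator; equal seeds give bit-identical streams.
- **Beat template.** The ventricular volume–time curve is piecewise
  cosine/linear over the six classical phases with default RR fractions
  A 5 %, B 30 %, C 5 %, D 25 %, E 25 %, F 10 % (isovolumetric contraction,
  ejection to −SV, isovolumetric relaxation, rapid filling to −0.30 SV,
  diastasis to −0.10 SV, atrial kick to 0); the curves in the literature
  are given only graphically, so the template encodes their shape, not
  exact data. The atrial compartment moves in anti-phase with default
  amplitude 30 ml.

What the generator emulates: the spatial separability of atrial and
ventricular patterns, baseline respiration artifacts, sensor noise, and
beat-to-beat SV modulation. What it does not emulate: non-linear
field–volume coupling (first-order model), electrode motion and contact
artifacts, inhomogeneous tissue (lungs, bone), ECG morphology, and
arrhythmias. Passing the closure and end-to-end tests therefore
demonstrates correctness of the algorithmic chain under the stated model,
not clinical performance on real recordings.

## Gating and the windowed SV estimator

Streams are split into V_avg (below 0.072 Hz) and V_fluct (0.072–34 Hz)
with zero-phase 2nd-order Butterworth filters — the digital stand-in for
the instrument's analog sections; zero phase preserves τ alignment. Beats
are cut at the R-peak markers on the 5 ms grid; RR intervals outside
250–2500 ms are rejected as artefacts.

Φ-gating selects, per 20 s window, beats whose gating-channel baseline
(default: the top sternal pair, configurable — the reference description
does not fix the channel) lies within ±2 % of the window median (same
lung volume) and whose baseline trend sign matches the window's modal sign
(same respiratory phase). The trend rule engages only when the window's
baseline peak-to-peak range exceeds half the tolerance band: without
respiratory modulation the "trend" is sensor noise and would discard half
the beats for nothing. If fewer than 3 beats survive, the tolerance is
relaxed once by ×2; failing that the window keeps all beats and is flagged
ungated. Gating is a pure selection and commutes with decomposition.

The per-window stroke volume is taken from the **ensemble mean** of the
gated beats' volume curves: curves are truncated to the shortest beat,
averaged, re-anchored on the isovolumetric-contraction samples (first 5 %
of the beat, where the ventricular volume cannot have changed — this
removes the offset that noise in the single τ = 0 baseline sample imprints
on a whole beat), and SV = −min of the result. Averaging before the
minimum matters: the minimum of a noisy curve is biased downward, so a
mean of per-beat minima overestimates SV and inflates its variance,
while the gated beats share a respiratory phase and are therefore
commensurable for averaging. For the same reason the per-beat
`stroke_volume` reading is unbiased only where end-systole is located
independently of the noise; the unbiasedness test reads the curve at the
known end-systolic sample.

For SV estimation the pipeline additionally band-limits the streams to
5 Hz (zero-phase, 2nd order) on top of the 34 Hz instrument band: the
end-systolic trough that carries SV has spectral content well below 5 Hz,
so the narrower band rejects noise without biasing the trough depth (any
constant fractional trimming is absorbed by the per-subject scale K).
Disable `sv_bandwidth_hz` to inspect full-bandwidth curve morphology
(e.g. the atrial kick). K itself is the ratio of mean reference SV to mean
method SV over the baseline (pre-intervention) windows, mirroring the
single-constant calibration against a Doppler reference.

## Non-linearity bounds

With interaction strength η (a sphere's incident field altered by a
neighbouring sphere, its skin-boundary image, or atrial counter-filling)
and cross-term coefficient ζ, the worst-case voltage-change ratio at
volume ratio λ is λ(1+ηζ+ηλ)/(1+ηζ+η) at second order; the full-series
variant closes the self-interaction term geometrically
(ηλ → ηλ/(1−ηλ), valid for |ηλ| < 1) while keeping the ηζ cross term first
order — one defensible reading of the series; applying the closure to both
terms is the documented alternative. Reference η values: −0.033
(non-spherical ventricle), +0.035 (skin boundary), +0.142 (skin boundary
plus atrial counter-filling, worst case). ζ defaults to 0 with a config
override, and results are reported with a sensitivity sweep over
ζ ∈ [0, 0.5]: the source value of ζ is typographically corrupted, so any
fixed non-zero choice would be a guess presented as fact. Consequently the
reported 14 % (λ = 2) and 6 % (λ = 0.5) extremes are treated as ceilings
and a sensitivity band, not as point values to reproduce. All curves pass
through (1, 1) — the calibration point — and η = 0 collapses every mode to
the identity line.

## Agreement statistics and the G-suit scenario

Bland-Altman differences are method − reference; bias is their mean,
spread the sample SD (n−1 — the reference analysis does not state its
normalization; sample SD is the safer small-n choice), and the limits of
agreement are bias ± exactly 2·SD, matching the "2SD" convention rather
than 1.96·SD. Pearson r uses the standard product-moment form. Method
windows are paired to the nearest-in-time reference reading within ±15 s
(reference readings arrive every 20–30 s in the emulated protocol).

The G-suit scenario raises SV smoothly during a 150 s inflation to
70 mmHg, holds it for 120 s, drops it within a 5 s deflation, and relaxes
back with a 60 s time constant; a seeded, slowly-varying physiological
wander (1 ml SD) is superposed. Default stage boundaries start at
inflation onset; the end-to-end demo prepends a 180 s baseline (so K can
be calibrated) and sizes the recovery leg to span 40 twenty-second
windows. Demo conditions: 72 bpm, 75 ml baseline SV, 1 % channel noise,
1 % respiration modulation with a 4 s period.

## Numerical choices and degenerate inputs

- Collinearity: Gram determinant ≤ 10⁻¹² × (f_A·f_A)(f_V·f_V) → error.
- Zero baseline voltage on any channel → error naming the channel (the
  relative measurement is undefined).
- m-map denominator below the floor → error naming the grid point.
- Rod discretization: default 12 rods per sphere diameter; heights are
  rescaled so volume bookkeeping is exact at every discretization level,
  and the far field converges under refinement.
- |dV| larger than the source sphere's volume → error (unphysical).
- Virtual displacement ties: smallest shift norm, then lexicographic.
- Empty gated windows keep their beats and carry an explicit flag; they
  are never silently dropped.

## Known limitations

- The forward model is first order; simulated data cannot exhibit the
  non-linear effects the bounds module quantifies.
- The sphere geometry and conductivities are stylized; absolute
  fingerprint magnitudes are order-of-magnitude realistic (m extrema of a
  few times 10⁻², like the reported maps) but not subject-specific.
- The atrial waveform is exactly anti-phase with the ventricular one;
  real atrial mechanics lag and deform.
- Respiration is a pure multiplicative sinusoid on the baselines; real
  respiratory artifacts also modulate the cardiac signal path.
- R-peaks are taken as given markers; no ECG detection is performed.
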