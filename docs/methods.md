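# Methods

This note records the models behind `optopace`, the parameter choices that
matter, and what the synthetic-data generators do and do not emulate. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Heart model and ECG synthesis

The heart is reduced to two competing pacemakers gated by a single absolute
refractory period (ERP):

* **Sinus oscillator** — fires every `1/sinus_rate` seconds; each interval is
  multiplied by `1 + cv·N(0,1)` (default CV 0.02, a typical anesthetized
  beat-to-beat variability). Default rate 7.5 Hz, the middle of the 7–8-Hz
  resting range for isoflurane-anesthetized mice.
* **Optical stimulus** — a pulse whose irradiance is at or above
  `capture_threshold_irradiance` (default 1.0 mW/mm²; protocols default to
  1.6 mW/mm², comfortably supra-threshold) triggers an ectopic beat with a
  conduction latency of `latency_ms` (default 15 ms) **iff** the resulting
  R–R interval would be at least the ERP.

A sinus firing inside the ERP produces no beat (the node fired but did not
capture the ventricle); its phase advances normally. A light-captured beat
resets the sinus phase, and the first post-reset interval is stretched by
`overdrive_suppression` (default 0.05, i.e. 5%). This small post-ectopic
suppression is the one free ingredient beyond the plain reset, and its size
is set by two regimes that must coexist:

* at 14-Hz pacing with a 100-ms ERP the response is a stable 2:1 block
  (captures every 142.9 ms); the reset sinus (7.5 Hz, next firing +133 ms)
  would otherwise squeeze in ahead of every second capture;
* at 6-Hz pacing the ~7.5-Hz sinus must still escape between pulses, giving
  the sustained mixed sinus/light rhythm and elevated arrhythmia index of
  bradypacing; a strong suppression would abolish that competition.

Five percent (together with the 15-ms head start the conduction latency gives
the light pathway in the race) satisfies both with several standard
deviations of jitter margin. `reset_sinus_on_ectopic=False` disables reset
and suppression together.

ERP defaults to 80 ms (mouse ventricle scale; individual analyses pass their
own value). An optional `opsin_off_time_ms` gate can additionally require a
minimum spacing between consecutive *light* captures (channel off time); it
defaults to disabled because a 100-ms gate would force 2:1 block already at
11 Hz, whereas full capture is achievable up to the ERP limit.

**Long pulses and continuous light.** While the light is on in these modes,
the ventricle is re-excited when the ERP expires, with per-cycle capture
probability `exp(-t_on/desens_tau_s)` (`desens_tau_s` = 1 s), modelling opsin
desensitization: a 5-s pulse starts light-driven and degrades into random
sinus escapes; continuous light captures only a brief transient and then
returns to sinus rhythm. The decay constant is a free parameter — no
quantitative calibration target exists for the escape statistics — so only
the qualitative behaviour (transient capture, later escapes) should be read
from it.

**Rendering.** Each beat is a Mexican-hat (Ricker) template scaled so its
main-lobe FWHM equals `qrs_fwhm_sinus_ms` (4 ms) or `qrs_fwhm_paced_ms`
(8 ms) — light-driven beats are ventricular and roughly twice as broad, which
is the classifier's entire feature. Only the FWHM is meaningful; the
morphology (no P or T waves, fixed 1-mV R amplitude, a 0.6× second lead) is a
free choice. Additive Gaussian noise (default 0.02 mV, 2% of R) and a 0.5-Hz
0.1-mV sinusoidal wander are included; the trigger channel is a 5-V copy of
the pulse train at exactly the optical onset (no trigger/light skew is
modelled). All randomness flows from one recorded seed through two
independent streams (event engine, rendering noise), so a zero-irradiance
protocol is bit-identical to an unpaced run.

## ECG analysis numerics

* **Detrending** — running median (default window 200 ms) in two stages: the
  second, 3×-longer median pass on the residual removes the slope-coupled
  bias that the asymmetric QRS value distribution induces in a single median
  under steep drift; a short moving average then stabilises the baseline at
  the sample scale. A window equal to a whole number of beat periods passes a
  beat-rate sinusoid exactly.
* **R-peak detection** — 10–250-Hz Butterworth band-pass (zero-phase), peaks
  above 40% of a rolling 2-s maximum (amplitude-invariant) and above a
  5-robust-SD noise floor, 50-ms lockout, then refinement to the raw-lead
  maximum with parabolic sub-sample interpolation. Localisation on synthetic
  traces is within ±1 ms at a 2-kHz sampling rate (the trace container
  enforces ≥1 kHz).
* **QRS FWHM** — measured on the dominant-polarity deflection relative to the
  median of a pre-QRS window 20–35 ms before the R peak (far enough that the
  template's negative side lobes do not bias the baseline), with linear
  interpolation at the half-maximum crossings; unmeasurable widths are NaN
  and the beat is left unclassified.
* **Capture classification** — `captured = (FWHM > threshold)`, default
  5.5 ms, strict inequality (a width exactly at threshold is not captured).
  The threshold is configurable; it is an empirical operating point, not
  derived from an ROC analysis.
* **Capture rate** — two denominators are provided because they answer
  different questions. `capture_rate` is the percentage of *beats* that are
  light-initiated. `pulse_capture_fraction` is the percentage of *light
  pulses* that initiate a beat. They agree under full capture but diverge
  under 2:1 block, where every beat is light-driven (per-beat 100%) while
  only alternate pulses succeed (per-pulse 50%); the 50% figure quoted for
  14-Hz tachypacing is the pulse-referenced one.
* **Rhythm statistics** — instantaneous HR = 1/RR (reported in Hz and bpm,
  bpm = 60·Hz); windowed HR uses 1-s sliding windows with 0.1-s steps;
  AI = sample SD (n−1) of instantaneous HR over an interval divided by its
  median. Phases (rest/pacing/recovery) are segmented from the recorded
  trigger channel, falling back to the protocol schedule with a warning.
* **Strength–duration fit** — weighted least squares (weights 1/threshold,
  matching multiplicative measurement noise) of the Lapicque hyperbola
  `I(t) = I_rh (1 + t_ch/t)`, which makes `I(t_ch) = 2 I_rh` an identity; the
  Weiss linear-charge form `Q(t) = I_rh (t + t_ch)` is available via
  `model="weiss"`. At least four distinct widths are required. Because a
  single six-point table at 5% noise can miss a parameter by slightly more
  than its own noise level, recovery claims are stated as the median error
  over replicate tables.

## Photon transport

Standard variance-reduced random walk in a homogeneous cube (default 30 mm,
0.2-mm voxels): exponential free paths with μt = μa + μs, Henyey–Greenstein
deflection, implicit-capture deposition of μa/μt per interaction, Russian
roulette below weight 1e-4 (survival 0.1). The top surface applies Fresnel
reflection/refraction (tissue n against air, including total internal
reflection); lateral and bottom boundaries absorb — at 3-mm query depths in a
30-mm cube the boundary choice is negligible. Fluence is deposited
weight/(μa·V·N) per launched joule. The energy audit
`absorbed + escaped + roulette_balance = launched` is tracked exactly
(roulette kills and boosts are ledgered) and asserted to 1e-6 on every run.

Mouse-skin properties: μs' = 90 cm⁻¹, n = 1.37, μa = 0.9 cm⁻¹ at 617 nm and
1.1 cm⁻¹ at 590 nm. The default configuration runs the reduced-scattering
similarity form (μs = 90 cm⁻¹, g = 0); the exact anisotropic form
(μs = 900 cm⁻¹, g = 0.9) is selectable and agrees with the similarity form in
deep plane-integrated fluence to within Monte Carlo error, which is the basis
for using the ~10× faster default.

Sources: isotropic point emitter just below the surface (nominal area
0.01 mm², the single fiber/LED geometry; photons entering upward may escape
through the Fresnel boundary), a downward pencil beam, and a Lambertian disk
(positions uniform on the disk, directions cosine-weighted). Source
comparisons are made at equal *surface irradiance*, so launched power scales
with illuminated area; plane-integrated and on-axis fluence ratios are
reported with batch-wise Monte Carlo standard errors.

Desk-scale photon counts are 1e5–1e6 per run in the tests (standard errors
are reported so scaled runs are interpretable); the pencil-beam
plane-integral is used for the diffusion-asymptote check because
plane-integration reduces any lateral source distribution to the equivalent
1-D broad-beam problem, whose deep log-slope is
μeff = sqrt(3 μa (μa + μs')).

**ANSI skin MPE** (visible/near-IR single pulses): radiant exposure
1.1 C_A t^0.25 J/cm² for 1e-7 s < t < 10 s, returned as average irradiance
over the pulse; 0.2 C_A W/cm² for 10 s ≤ t ≤ 3e4 s; C_A = 1 in 400–700 nm,
10^{0.002(λ−700)} in 700–1050 nm, 5 in 1050–1400 nm. Other regimes raise an
error naming the limit. For a 100-ms visible pulse the formula evaluates to
61.86 mW/mm² (61.9 at one decimal).

## Intrinsic-signal spectroscopy

**Extinction matrix.** Hemoglobin molar extinction coefficients are a
compiled approximate tabulation (Prahl-style) interpolated at the system
wavelengths (green 525 nm, red 637 nm — the measured LED peaks of a
530/625-nm pair), converted to base-e mm⁻¹ per μM. When a measured LED
spectrum is supplied the tabulated values are spectrally weighted by it. The
matrix condition number is exposed; the default pair conditions at ~18.
Because the exact published constants vary between compilations, quantitative
claims in this package rest on forward/inverse self-consistency on synthetic
data, not on third-decimal agreement of these coefficients.

**Pathlength factors.** L(λ) = −∂lnR/∂μa of the semi-infinite diffusion
total reflectance R = (a′/2)[e^{−μeff z0} + e^{−μeff(z0+2zb)}]
(extrapolated-boundary dipole solution integrated over the surface),
evaluated by complex-step differentiation (exact to machine precision; the
finite-difference oracle in the tests is independent). Default baseline
cortical optics — μa = 0.77 mm⁻¹ (green), 0.047 mm⁻¹ (red), μs' ≈ 1 mm⁻¹,
n = 1.4 — correspond to a hemoglobin-dominated cortex near 100 μM total
hemoglobin at ~60% saturation and give L ≈ 1 mm (green) and ≈ 7.5 mm (red).
They are configurable; recovered concentration *scales* track any error in L
linearly, which is one reason absolute in-vivo magnitudes are out of scope.

**Baseline intensity Φ₀.** Default: the fitted fifth-order polynomial trend
per pixel, so detrending (LED drift removal) and ratiometric normalisation
are a single step. This choice absorbs a small fraction of slow hemodynamic
signal into the baseline — harmless for stimulus-locked epoch analysis
(per-epoch baselines are re-subtracted) but a bias floor for raw recovery.
The alternative `phi0="prestim"` (mean of a pre-stimulus window) is exact in
expectation and is what the forward/inverse recovery checks use.

**Inversion.** Per pixel and frame, Δμa,λ = −ln(Φ/Φ₀)/L_λ and
[ΔHbO, ΔHbR] = E⁻¹ Δμa; ΔHbT is computed as the sum, never stored, so the
additivity identity is exact. Nonpositive intensities (after dark
subtraction) null the pixel with a count rather than clipping, to avoid
biasing the logarithm. Smoothing uses an explicitly normalised, truncated
5×5 Gaussian kernel (σ 1.3 px, reflective borders). Binning sums 4×4 blocks
(counts are preserved, SNR doubles). Atlas registration is out of scope;
parcel/ROI analyses accept any user-supplied label mask, and camera-to-camera
alignment uses an exact 4-landmark homography.

**Epoch analysis.** Epochs span [−5 s, +25 s] around each pacing-block onset
(the 30-s block design: 5 s light, 25 s rest); the pre-onset 5-s mean is the
epoch baseline (the whole rest period is an alternative, but the pre-onset
window is least contaminated by the previous block's recovery). Truncated
blocks are dropped with a warning; means, SDs and SEs across blocks are
returned. Peak maps are pixelwise time-means over the pacing window. Group
(across-animal) averaging is out of scope.

## Echo metrics

FS and CO are plain algebra on tabulated scalars. The one genuine ambiguity
is the VTI bookkeeping: integrating aortic velocity over one second already
multiplies in the heart rate, whereas a per-beat VTI needs HR explicitly.
Both conventions are supported behind an explicit flag (default
`per_second`), a table carrying mixed conventions is rejected, and the unit
chain is mm × mm² (× Hz) → mm³/s → ml/min (factor 0.06). The aortic
cross-section is a single static value per animal.

## Synthetic scenes: what they do and do not emulate

The imaging scene generator reproduces the acquisition geometry (128×128
after binning, 20 Hz per contrast, ten 30-s pacing blocks), cortex-wide
responses of −1.8 μM ΔHbO and +0.8 μM ΔHbR at the response peak with a 2×
amplified midline venous-sinus stripe, saturating-rise/exponential-recovery
block dynamics, ~1% linear LED drift, a flat dark offset, and Poisson shot
noise at a configurable photon budget. It does **not** emulate vascular
texture, heartbeat/respiration pulsation, motion, scattering changes, or
inter-animal variability — so passing round trips demonstrate the
correctness and noise behaviour of the estimator chain, not in-vivo accuracy.
Similarly, the ECG generator's clean template morphology makes classification
easier than real electrograms; the classifier-agreement figures should be
read as algorithm-correctness, not field performance. The in-vivo-scale
hemodynamic magnitudes are intentionally *inputs* to the scene generator,
never outputs claimed by the package.

Test and acceptance problem sizes are deliberately desk-scale: 32–64-px
fields with 3–4 pacing blocks for imaging round trips, 40-s single-protocol
ECG runs, 2–8×10⁵-photon transport runs (10⁶ for the source-comparison
check). These sizes keep the full suite around a minute while leaving every
quantitative tolerance intact.

## Known limitations

* The heart model has no relative refractory period, no rate adaptation, no
  AV conduction structure; capture is binary at a fixed irradiance threshold
  rather than a stochastic dose–response.
* Photon transport is steady-state, unpolarised, homogeneous; no rib/lung
  anatomy, no fluorescence.
* The spectroscopic inversion assumes two chromophores and fixed baseline
  optics; flow, oxygen extraction, and scattering-change separation are out
  of scope.
* Statistical inference (ANOVA families, mixed models) is deliberately left
  to general-purpose packages; `optopace` stops at per-phase descriptive
  summaries.
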