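# optopace

Analysis toolkit for **noninvasive optogenetic cardiac pacing** experiments in
mice. Transthoracic illumination of a heart expressing a red-shifted opsin
(e.g. ReaChR) can drive ectopic ventricular beats through the closed chest;
the downstream questions — *did the light capture the heart, at what rate, how
arrhythmic is the rhythm, how much light reaches the heart, and what does the
altered rhythm do to cardiac output and cortical oxygenation* — are answered
from four data streams: ECG, photon-transport dosimetry, echocardiographic
tables, and dual-wavelength intrinsic-signal imaging of the cortex.

`optopace` implements each analysis and a matching synthetic-data generator
with exact ground truth, so the entire pipeline is testable without any
animal data.

## What it computes

**ECG (`optopace.ecg`).** Baseline removal (two-stage running median), R-peak
detection (band-pass + adaptive threshold at 40% of a rolling 2-s maximum),
QRS width by full width at half maximum with local-baseline interpolation, and
classification of each beat as light-captured when the QRS FWHM exceeds a
threshold (default 5.5 ms — optically induced beats are ventricular and
broad). From the beat table: capture rate (per beat, and per light pulse),
instantaneous and windowed heart rate, the arrhythmia index
AI = SD(HR)/median(HR), pulse-to-R latency, and protocol phase segmentation
from the recorded trigger channel. The strength-duration relation is fitted
with the Lapicque hyperbola *I*(*t*) = *I*<sub>rh</sub>(1 + *t*<sub>ch</sub>/*t*)
(rheobase *I*<sub>rh</sub>, chronaxie *t*<sub>ch</sub>).

**Light dosimetry (`optopace.mc`).** Monte Carlo photon transport in a 30-mm
homogeneous mouse-skin cube (Henyey–Greenstein scattering, implicit capture,
Russian roulette, Fresnel top boundary), comparing an isotropic point source
(single fiber/LED) with a broad Lambertian disk at equal surface irradiance,
plus the ANSI skin maximum permissible exposure
(1.1 *C*<sub>A</sub> *t*<sup>0.25</sup> J/cm² for visible single pulses).

**Hemoglobin imaging (`optopace.oisi`).** Dark subtraction and 4×4 binning,
landmark homography coregistration, fifth-order polynomial detrending (the
fitted trend is the baseline intensity Φ₀), 5×5 Gaussian smoothing, and
modified Beer–Lambert inversion
Φ = Φ₀ e<sup>−Δμ<sub>a</sub>L</sup>, Δμ<sub>a,λ</sub> = Σ<sub>i</sub> E<sub>λ,i</sub> Δ[Hb<sub>i</sub>]
into ΔHbO/ΔHbR/ΔHbT maps, with pacing-locked epoch averages, peak maps and
ROI time courses. Pathlength factors L(λ) come from the semi-infinite
diffusion reflectance model.

**Echo metrics (`optopace.echo`).** FS(%) = (LVIDd − LVIDs)/LVIDd × 100 and
CO = VTI × Area × HR from tabulated M-mode/Doppler measurements (both
per-beat and per-second VTI conventions supported).

**Synthetic data (`optopace.synth`).** An event-driven two-pacemaker heart
model (sinus oscillator vs. light pulses, gated by one absolute refractory
period, with overdrive-style sinus reset) rendering ECG traces with known
per-beat labels; a forward Beer–Lambert reflectance simulator with LED drift,
dark offset and shot noise; strength-duration and echo tables with prescribed
parameters.

## Worked example

```python
from optopace import PacingProtocol, HeartModelParams, simulate_ecg
from optopace import ecg

params = HeartModelParams(sinus_rate_hz=7.5, erp_ms=80.0, seed=0)
protocol = PacingProtocol.tachypacing(8.5)   # 15 s rest, 10 s light, 15 s recovery
trace, truth = simulate_ecg(params, protocol)

beats = ecg.build_beat_table(trace, protocol=protocol)
onsets, _ = ecg.trigger_onsets(trace)
summary = ecg.rhythm_summary(beats, onsets=onsets)
for phase in ("rest", "pacing", "recovery"):
    s = summary[phase]
    print(f"{phase:9s} HR {s['mean_hr_hz']:5.2f} Hz ({s['mean_hr_bpm']:5.0f} bpm)  "
          f"AI {s['arrhythmia_index']:.3f}  capture {s['capture_rate_pct']:5.1f} %")

from optopace.mc import ansi_skin_mpe
print(f"ANSI skin MPE, 100-ms pulse at 590 nm: {ansi_skin_mpe(0.1, 590):.1f} mW/mm^2")
```

prints

```
rest      HR  7.49 Hz (  450 bpm)  AI 0.019  capture   0.0 %
pacing    HR  8.45 Hz (  507 bpm)  AI 0.028  capture  96.4 %
recovery  HR  7.50 Hz (  450 bpm)  AI 0.021  capture   0.0 %
ANSI skin MPE, 100-ms pulse at 590 nm: 61.9 mW/mm^2
```

At rest the animal sits at its intrinsic ~7.5-Hz sinus rhythm; during the
8.5-Hz light train every steady-state beat is light-initiated (the sub-100%
window figure only reflects the rest/pacing boundary beats), the measured
heart rate follows the programmed frequency, and the rhythm stays regular
(low AI). The MPE line confirms that the few-mW/mm² irradiances needed for
capture sit far below the skin safety limit for a 100-ms pulse.

A command-line front end mirrors the main entry points:

```sh
optopace mpe --t 0.1 --wl 590
optopace ecg --in trace.csv --out-beats beats.csv --out-summary summary.json
optopace sdcurve --in thresholds.csv --out fit.json
optopace mc --source disk:5 --photons 1e6 --out fluence.npz
optopace echo --in measures.csv --out echo.json
optopace oisi --in run_dir/ --out hemomaps.npz
```

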