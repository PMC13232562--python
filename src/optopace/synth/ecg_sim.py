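"""Event-driven heart model and synthetic ECG rendering.

The heart is reduced to two competing pacemakers gated by a single absolute
refractory period (ERP):

* a sinus oscillator firing every ``1/sinus_rate`` seconds with multiplicative
  jitter, and
* the optical stimulus, which triggers an ectopic (ventricular) beat whenever
  the surface irradiance exceeds the capture threshold and the heart is out of
  its refractory period.

A light-captured beat optionally resets the sinus phase (overdrive-style); the
first post-reset sinus interval is additionally lengthened by
``overdrive_suppression`` to emulate transient sinus-node suppression after an
ectopic beat — without it the sinus escapes between 2:1 captures during rapid
pacing, which is not what is observed electrocardiographically.  Long-pulse and
continuous illumination re-excite the ventricle once the ERP expires, with a
per-cycle capture probability that decays exponentially with time under
illumination (opsin desensitization), so long pulses start light-driven and
degrade into random sinus escapes while continuous light captures only a brief
transient.

Each beat is rendered onto the voltage trace as a Mexican-hat (Ricker) template
whose full width at half maximum equals the sinus or paced QRS width; only the
FWHM is meaningful downstream, the exact morphology is a free choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ..protocols import PacingProtocol

__all__ = ["HeartModelParams", "GroundTruthBeats", "ECGTrace", "simulate_ecg",
           "make_strength_duration_samples"]

# Half-max half-width of the Ricker main lobe in units of its sigma:
# solve (1 - u^2) exp(-u^2/2) = 1/2 for u > 0.
_RICKER_HALF_U = brentq(lambda u: (1.0 - u * u) * np.exp(-u * u / 2.0) - 0.5,
                        0.1, 1.0)
RICKER_FWHM_PER_SIGMA = 2.0 * _RICKER_HALF_U


@dataclass(frozen=True)
class HeartModelParams:
    """Parameters of the two-pacemaker heart model.

    Notes
    -----
    ``erp_ms`` is the absolute refractory period separating any two beats.
    ``opsin_off_time_ms`` optionally gates consecutive *light* captures (the
    channel off time); it defaults to disabled so that full capture is
    possible up to the refractory limit.  ``latency_ms`` is the conduction
    delay from optical pulse onset to the ectopic R peak.
    """

    sinus_rate_hz: float = 7.5
    sinus_jitter_cv: float = 0.02
    erp_ms: float = 80.0
    opsin_off_time_ms: float | None = None
    qrs_fwhm_sinus_ms: float = 4.0
    qrs_fwhm_paced_ms: float = 8.0
    capture_threshold_irradiance: float = 1.0  # mW/mm^2
    reset_sinus_on_ectopic: bool = True
    overdrive_suppression: float = 0.05
    latency_ms: float = 15.0
    latency_jitter_ms: float = 0.0
    desens_tau_s: float = 1.0
    noise_sd_mv: float = 0.02
    wander_amp_mv: float = 0.1
    wander_freq_hz: float = 0.5
    r_amp_mv: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.erp_ms > 0:
            raise ValueError("erp must be positive")
        if not self.qrs_fwhm_paced_ms > self.qrs_fwhm_sinus_ms:
            raise ValueError("paced QRS FWHM must exceed the sinus FWHM")
        if not 0.0 <= self.sinus_jitter_cv < 0.5:
            raise ValueError("sinus jitter CV must be in [0, 0.5)")
        if not self.sinus_rate_hz > 0:
            raise ValueError("sinus rate must be positive")


@dataclass
class GroundTruthBeats:
    """Simulator truth: beat times and their origin (``sinus`` or ``light``)."""

    beat_times: np.ndarray          # s, strictly increasing R-peak times
    sources: np.ndarray             # array of "sinus"/"light" strings
    pulse_onsets: np.ndarray        # s, optical pulse onsets
    protocol: PacingProtocol
    params: HeartModelParams

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.sources = np.asarray(self.sources, dtype=object)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.beat_times.size and np.any(
                np.diff(self.beat_times) < self.params.erp_ms / 1000.0 - 1e-9):
            raise ValueError("beat intervals violate the refractory period")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    def captured_mask(self) -> np.ndarray:
        return self.sources == "light"


@dataclass
class ECGTrace:
    """Uniformly sampled multichannel ECG record with the light-trigger channel."""

    voltage_mv: np.ndarray        # (n_samples, n_leads)
    trigger_v: np.ndarray         # (n_samples,)
    sample_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.voltage_mv = np.atleast_2d(np.asarray(self.voltage_mv, dtype=float))
        if self.voltage_mv.shape[0] < self.voltage_mv.shape[1]:
            # accept (n_leads, n) layout too
            self.voltage_mv = self.voltage_mv.T
        self.trigger_v = np.asarray(self.trigger_v, dtype=float)
        if self.sample_rate_hz < 1000.0:
            raise ValueError("sample rate must be at least 1000 Hz for QRS-width "
                             "resolution")
        if not (np.all(np.isfinite(self.voltage_mv))
                and np.all(np.isfinite(self.trigger_v))):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.voltage_mv.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz

    def lead(self, i: int = 0) -> np.ndarray:
        return self.voltage_mv[:, i]


# --------------------------------------------------------------------------
# event engine
# --------------------------------------------------------------------------
def _generate_beats(params: HeartModelParams, protocol: PacingProtocol,
                    duration: float, rng: np.random.Generator):
    erp = params.erp_ms / 1000.0
    period = 1.0 / params.sinus_rate_hz
    cv = params.sinus_jitter_cv
    spans = protocol.pulse_spans()
    spans = spans[spans[:, 0] < duration] if spans.size else spans.reshape(0, 2)
    lit = spans if protocol.irradiance_mw_mm2 > 0 else spans[:0]

    if erp >= period and (protocol.mode != "pulsed" or not spans.size
                          or erp >= 1.0 / protocol.frequency_hz):
        # refractory period swallows every competing period: nothing can beat
        raise ValueError("ERP is at least as long as every competing period; "
                         "no beats can be generated")

    def jittered(base):
        if cv == 0:
            return base
        return base * max(0.1, 1.0 + cv * rng.standard_normal())

    def latency():
        lat = params.latency_ms / 1000.0
        if params.latency_jitter_ms > 0:
            lat += params.latency_jitter_ms / 1000.0 * rng.standard_normal()
        return max(lat, 0.0)

    beat_t, beat_src = [], []
    last_beat = -np.inf
    last_light_beat = -np.inf
    next_sinus = rng.uniform(0.0, period)

    can_capture = protocol.irradiance_mw_mm2 >= params.capture_threshold_irradiance

    # light attempt queue: for pulsed mode one attempt per pulse onset; for
    # long_pulse/continuous the onset attempt plus post-beat re-excitations.
    if protocol.mode == "pulsed":
        attempts = list(lit[:, 0])
    else:
        attempts = list(lit[:, 0])
    attempts = [t for t in attempts if t < duration]
    ai = 0
    pending_retry = None  # single scheduled re-excitation time (LP/CW)

    def span_onset_of(t):
        """Onset of the illuminated span containing time t, else None."""
        for s0, s1 in lit:
            if s0 - 1e-12 <= t < s1:
                return s0
        return None

    while True:
        t_light = np.inf
        if pending_retry is not None:
            t_light = pending_retry
        if ai < len(attempts):
            t_light = min(t_light, attempts[ai])
        t_next = min(next_sinus, t_light)
        if t_next >= duration:
            break

        if t_light <= next_sinus:  # light has priority on exact ties
            is_retry = pending_retry is not None and t_light == pending_retry
            if is_retry:
                pending_retry = None
            else:
                ai += 1
            if can_capture:
                r = t_light + latency()
                ok = (r - last_beat >= erp - 1e-12)
                if ok and params.opsin_off_time_ms is not None:
                    ok = r - last_light_beat >= params.opsin_off_time_ms / 1000.0 - 1e-12
                if ok and protocol.mode in ("long_pulse", "continuous"):
                    onset = span_onset_of(t_light)
                    if onset is None:
                        ok = False
                    else:
                        p = np.exp(-(t_light - onset) / params.desens_tau_s)
                        ok = rng.uniform() < p
                if ok and r < duration:
                    beat_t.append(r)
                    beat_src.append("light")
                    last_beat = r
                    last_light_beat = r
                    if params.reset_sinus_on_ectopic:
                        next_sinus = r + jittered(
                            period * (1.0 + params.overdrive_suppression))
                    if protocol.mode in ("long_pulse", "continuous"):
                        t_retry = r + erp
                        if span_onset_of(t_retry) is not None:
                            pending_retry = t_retry
        else:
            t_s = next_sinus
            if t_s - last_beat >= erp - 1e-12:
                beat_t.append(t_s)
                beat_src.append("sinus")
                last_beat = t_s
                if protocol.mode in ("long_pulse", "continuous") and can_capture:
                    t_retry = t_s + erp
                    if span_onset_of(t_retry) is not None:
                        pending_retry = t_retry
            next_sinus = t_s + jittered(period)

    return (np.asarray(beat_t), np.asarray(beat_src, dtype=object),
            spans)


def _ricker(t, fwhm_s):
    sigma = fwhm_s / RICKER_FWHM_PER_SIGMA
    u = t / sigma
    return (1.0 - u * u) * np.exp(-u * u / 2.0)


def simulate_ecg(params: HeartModelParams, protocol: PacingProtocol,
                 duration: float | None = None, sample_rate: float = 2000.0):
    """Simulate an ECG trace under an optical pacing protocol.

    Returns ``(trace, truth)`` where ``truth`` carries the exact beat times and
    per-beat sources used to render the trace.  The trigger channel reproduces
    the optical pulse train (5 V while the light is on).
    """
    if duration is None:
        duration = protocol.total_s
    if duration < protocol.total_s - 1e-9:
        raise ValueError("duration does not cover the protocol schedule")
    if sample_rate < 1000.0:
        raise ValueError("sample rate must be at least 1000 Hz")

    ss = np.random.SeedSequence(params.seed)
    rng_engine, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    beat_times, sources, spans = _generate_beats(params, protocol, duration,
                                                 rng_engine)

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    lead1 = np.zeros(n)
    half_support = 4.0 * (params.qrs_fwhm_paced_ms / 1000.0) / RICKER_FWHM_PER_SIGMA
    for bt, src in zip(beat_times, sources):
        fwhm = (params.qrs_fwhm_paced_ms if src == "light"
                else params.qrs_fwhm_sinus_ms) / 1000.0
        i0 = max(0, int((bt - half_support) * sample_rate))
        i1 = min(n, int((bt + half_support) * sample_rate) + 1)
        lead1[i0:i1] += params.r_amp_mv * _ricker(t[i0:i1] - bt, fwhm)

    wander = params.wander_amp_mv * np.sin(2 * np.pi * params.wander_freq_hz * t)
    volts = np.empty((n, 2))
    volts[:, 0] = lead1 + wander
    volts[:, 1] = 0.6 * lead1 + wander
    if params.noise_sd_mv > 0:
        volts += params.noise_sd_mv * rng_noise.standard_normal((n, 2))

    trigger = np.zeros(n)
    for s0, s1 in spans:
        trigger[int(np.ceil(s0 * sample_rate)):int(np.ceil(s1 * sample_rate))] = 5.0

    trace = ECGTrace(voltage_mv=volts, trigger_v=trigger,
                     sample_rate_hz=sample_rate)
    truth = GroundTruthBeats(beat_times=beat_times, sources=sources,
                             pulse_onsets=spans[:, 0] if spans.size else
                             np.empty(0), protocol=protocol, params=params)
    return trace, truth


# --------------------------------------------------------------------------
# strength-duration samples
# --------------------------------------------------------------------------
def make_strength_duration_samples(rheobase: float, chronaxie_ms: float,
                                   widths_ms, noise_cv: float = 0.0,
                                   seed: int = 0):
    """Draw capture thresholds from the hyperbolic strength-duration law.

    ``I(t) = I_rh * (1 + t_ch / t)`` with multiplicative log-normal-free noise
    (``threshold *= 1 + noise_cv * N(0,1)``).  Returns a pandas DataFrame with
    columns ``width_ms`` and ``threshold_mw_mm2``.
    """
    import pandas as pd

    widths = np.asarray(widths_ms, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("pulse widths must be positive")
    rng = np.random.default_rng(seed)
    thr = rheobase * (1.0 + chronaxie_ms / widths)
    if noise_cv > 0:
        thr = thr * np.clip(1.0 + noise_cv * rng.standard_normal(widths.size),
                            0.05, None)
    return pd.DataFrame({"width_ms": widths, "threshold_mw_mm2": thr})
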