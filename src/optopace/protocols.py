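"""Light-stimulation protocol descriptions.

A :class:`PacingProtocol` specifies when the pacing LED is on, how the light is
pulsed while it is on, and at what surface irradiance.  Protocols are built from
an ordered schedule of ``("on"|"off", duration_s)`` segments; convenience
constructors cover the stimulation designs used throughout the package:
short tachypacing runs (rest / 10-s pulsed stimulation / rest), long-pulse
trains (5-s pulses at 0.1 Hz), continuous illumination, and block designs for
stimulus-locked imaging (5 s on / 25 s off).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

VALID_MODES = ("pulsed", "long_pulse", "continuous")


@dataclass(frozen=True)
class PacingProtocol:
    """Optical pacing protocol.

    Parameters
    ----------
    mode:
        ``"pulsed"`` (brief pulses at ``frequency_hz`` during "on" segments),
        ``"long_pulse"`` (each "on" segment is a single long pulse) or
        ``"continuous"`` (light held on for the whole "on" segment).
    frequency_hz:
        Pulse repetition rate, used only in ``pulsed`` mode.
    pulse_width_ms:
        Optical pulse duration in ``pulsed`` mode.
    irradiance_mw_mm2:
        Surface irradiance while the light is on (mW/mm^2).
    schedule:
        Ordered ``(state, duration_s)`` segments with ``state`` in
        ``{"on", "off"}``.  Leading/trailing "off" segments play the role of
        rest and recovery periods.
    """

    mode: str = "pulsed"
    frequency_hz: float = 8.5
    pulse_width_ms: float = 20.0
    irradiance_mw_mm2: float = 1.6
    schedule: tuple = (("off", 15.0), ("on", 10.0), ("off", 15.0))

    def __post_init__(self):
        if self.mode not in VALID_MODES:
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "pulsed":
            if not self.frequency_hz > 0:
                raise ValueError("pulsed mode requires frequency > 0")
            if not self.pulse_width_ms < 1000.0 / self.frequency_hz:
                raise ValueError("pulse width must be shorter than the pulse period")
        if self.irradiance_mw_mm2 < 0:
            raise ValueError("irradiance must be non-negative")
        norm = []
        for state, dur in self.schedule:
            if state not in ("on", "off"):
                raise ValueError(f"schedule state must be 'on'/'off', got {state!r}")
            if not dur > 0:
                raise ValueError("schedule segment durations must be positive")
            norm.append((state, float(dur)))
        object.__setattr__(self, "schedule", tuple(norm))

    # ------------------------------------------------------------------ timing
    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.schedule))

    def on_segments(self):
        """Yield (start_s, stop_s) for every "on" segment."""
        t = 0.0
        for state, dur in self.schedule:
            if state == "on":
                yield (t, t + dur)
            t += dur

    def pulse_spans(self):
        """Return (onset_s, offset_s) of every optical pulse as an (n, 2) array."""
        spans = []
        for start, stop in self.on_segments():
            if self.mode == "pulsed":
                period = 1.0 / self.frequency_hz
                width = self.pulse_width_ms / 1000.0
                n = int(np.floor((stop - start) / period + 1e-9))
                for k in range(n):
                    onset = start + k * period
                    if onset + width <= stop + 1e-12:
                        spans.append((onset, onset + width))
            else:  # long_pulse / continuous: the whole segment is lit
                spans.append((start, stop))
        return np.asarray(spans, dtype=float).reshape(-1, 2)

    def pulse_onsets(self):
        return self.pulse_spans()[:, 0]

    # ------------------------------------------------------------ constructors
    @classmethod
    def tachypacing(cls, frequency_hz, *, pulse_width_ms=20.0,
                    irradiance_mw_mm2=1.6, rest_pre_s=15.0, stim_s=10.0,
                    rest_post_s=15.0):
        """Rest / pulsed stimulation / recovery run (default 15 s + 10 s + 15 s)."""
        return cls(mode="pulsed", frequency_hz=frequency_hz,
                   pulse_width_ms=pulse_width_ms,
                   irradiance_mw_mm2=irradiance_mw_mm2,
                   schedule=(("off", rest_pre_s), ("on", stim_s),
                             ("off", rest_post_s)))

    @classmethod
    def long_pulse(cls, *, pulse_s=5.0, period_s=10.0, stim_s=600.0,
                   irradiance_mw_mm2=1.9, rest_pre_s=30.0, rest_post_s=30.0):
        """Long-pulse train: ``pulse_s``-second pulses repeated every ``period_s``."""
        if pulse_s >= period_s:
            raise ValueError("pulse duration must be shorter than the period")
        segs = [("off", rest_pre_s)]
        n = int(np.floor(stim_s / period_s + 1e-9))
        for _ in range(n):
            segs.append(("on", pulse_s))
            segs.append(("off", period_s - pulse_s))
        segs.append(("off", rest_post_s))
        return cls(mode="long_pulse", irradiance_mw_mm2=irradiance_mw_mm2,
                   schedule=tuple(segs))

    @classmethod
    def continuous(cls, *, stim_s=600.0, irradiance_mw_mm2=1.9,
                   rest_pre_s=30.0, rest_post_s=30.0):
        return cls(mode="continuous", irradiance_mw_mm2=irradiance_mw_mm2,
                   schedule=(("off", rest_pre_s), ("on", stim_s),
                             ("off", rest_post_s)))

    @classmethod
    def block_design(cls, frequency_hz, *, n_blocks=10, on_s=5.0, off_s=25.0,
                     lead_in_s=5.0, pulse_width_ms=20.0, irradiance_mw_mm2=1.9):
        """Stimulus-locked imaging design: ``on_s`` s of pacing then ``off_s`` s rest."""
        segs = [("off", lead_in_s)]
        for _ in range(n_blocks):
            segs.append(("on", on_s))
            segs.append(("off", off_s))
        return cls(mode="pulsed", frequency_hz=frequency_hz,
                   pulse_width_ms=pulse_width_ms,
                   irradiance_mw_mm2=irradiance_mw_mm2, schedule=tuple(segs))

    # -------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = [list(s) for s in self.schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PacingProtocol":
        d = dict(d)
        d["schedule"] = tuple((s[0], float(s[1])) for s in d["schedule"])
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PacingProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
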