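"""On-disk formats: ECG CSV + JSON sidecar, reflectance TIFFs + JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocols import PacingProtocol
from .synth.ecg_sim import ECGTrace, GroundTruthBeats, HeartModelParams
from .synth.imaging_sim import ReflectanceStack
from .oisi import PathlengthModel

__all__ = ["write_ecg", "read_ecg", "write_reflectance", "read_reflectance"]

ECG_COLUMNS = ("time_s", "lead_I_mV", "lead_II_mV", "trigger_V")


def write_ecg(path, trace: ECGTrace, truth: GroundTruthBeats | None = None):
    """Write a trace as CSV (time, lead I/II, trigger) plus a JSON sidecar.

    The sidecar records the sample rate and, when truth is available, the
    protocol, model parameters, seed and the truth-beat table.
    """
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time_s,
        "lead_I_mV": trace.voltage_mv[:, 0],
        "lead_II_mV": (trace.voltage_mv[:, 1]
                       if trace.voltage_mv.shape[1] > 1
                       else trace.voltage_mv[:, 0]),
        "trigger_V": trace.trigger_v,
    })
    df.to_csv(path, index=False)
    meta = {"sample_rate_hz": trace.sample_rate_hz, "t0_s": trace.t0_s}
    if truth is not None:
        meta["protocol"] = truth.protocol.to_dict()
        meta["seed"] = truth.params.seed
        meta["truth_beats"] = {
            "beat_times_s": truth.beat_times.tolist(),
            "sources": list(truth.sources),
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_ecg(path):
    """Read a trace written by :func:`write_ecg`.

    Returns ``(trace, meta)`` where ``meta`` includes the parsed protocol
    (as :class:`PacingProtocol`) when present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    trace = ECGTrace(
        voltage_mv=df[["lead_I_mV", "lead_II_mV"]].to_numpy(),
        trigger_v=df["trigger_V"].to_numpy(),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        t0_s=float(meta.get("t0_s", 0.0)))
    if "protocol" in meta:
        meta["protocol"] = PacingProtocol.from_dict(meta["protocol"])
    return trace, meta


def write_reflectance(outdir, stack: ReflectanceStack):
    """Write per-wavelength multi-page TIFFs, dark-frame TIFFs and metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for wl in stack.wavelengths_nm:
        tifffile.imwrite(outdir / f"reflectance_{int(wl)}nm.tif",
                         stack.frames[wl].astype(np.float32))
        tifffile.imwrite(outdir / f"dark_{int(wl)}nm.tif",
                         stack.dark_frames[wl].astype(np.float32))
    meta = {
        "wavelengths_nm": list(stack.wavelengths_nm),
        "rate_hz": stack.rate_hz,
        "phi0": stack.phi0,
        "pathlengths_mm": stack.pathlengths.L_mm.tolist(),
        "times_s": np.asarray(stack.times_s).tolist(),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta))


def read_reflectance(outdir):
    """Read the movie pair written by :func:`write_reflectance`.

    Returns ``(frames, dark_frames, meta)`` with frames keyed by wavelength.
    """
    outdir = Path(outdir)
    meta = json.loads((outdir / "metadata.json").read_text())
    frames, darks = {}, {}
    for wl in meta["wavelengths_nm"]:
        frames[float(wl)] = tifffile.imread(
            outdir / f"reflectance_{int(wl)}nm.tif").astype(float)
        darks[float(wl)] = tifffile.imread(
            outdir / f"dark_{int(wl)}nm.tif").astype(float)
    return frames, darks, meta
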