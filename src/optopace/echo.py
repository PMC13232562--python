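"""Echocardiographic function metrics from tabulated M-mode/Doppler measures.

Fractional shortening of the left-ventricular internal diameter,

    FS(%) = (LVIDd - LVIDs) / LVIDd x 100,

and cardiac output from the aortic velocity-time integral,

    CO = VTI x Area x HR,

are computed from scalar measurements (image segmentation is upstream).  Two
VTI bookkeeping conventions exist in practice and both are supported
explicitly: ``per_beat`` (mm of integrated velocity per cardiac cycle, so HR
multiplies in) and ``per_second`` (velocity integrated over one second, which
already absorbs HR — the default).  Units: LVID in mm, VTI in mm (per beat or
per second), aortic area in mm^2, HR in Hz; CO is returned in ml/min
(1 mm^3/s = 0.06 ml/min).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["fractional_shortening", "cardiac_output", "phase_summary",
           "summarize_table", "make_echo_table"]

MM3_PER_S_TO_ML_PER_MIN = 60.0 / 1000.0


def fractional_shortening(lvidd_mm, lvids_mm):
    """FS (%) from diastolic/systolic LV internal diameters."""
    lvidd = np.asarray(lvidd_mm, dtype=float)
    lvids = np.asarray(lvids_mm, dtype=float)
    if np.any(lvids <= 0) or np.any(lvidd <= 0):
        raise ValueError("LV internal diameters must be positive")
    if np.any(lvids > lvidd + 1e-12):
        raise ValueError("LVIDs cannot exceed LVIDd")
    out = (lvidd - lvids) / lvidd * 100.0
    return float(out) if out.ndim == 0 else out


def cardiac_output(vti_mm, aortic_area_mm2, hr_hz=None,
                   convention: str = "per_second"):
    """CO (ml/min) from the aortic VTI, cross-sectional area and HR.

    With ``convention="per_beat"`` the HR is required and multiplies in;
    with ``"per_second"`` the VTI already integrates one second of flow and
    ``hr_hz`` must be omitted.
    """
    vti = np.asarray(vti_mm, dtype=float)
    area = np.asarray(aortic_area_mm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("aortic area must be positive")
    if convention == "per_beat":
        if hr_hz is None:
            raise ValueError("per-beat VTI requires the heart rate")
        flow_mm3_s = vti * area * np.asarray(hr_hz, dtype=float)
    elif convention == "per_second":
        if hr_hz is not None:
            raise ValueError("per-second VTI already absorbs HR; "
                             "omit hr_hz or use convention='per_beat'")
        flow_mm3_s = vti * area
    else:
        raise ValueError(f"unknown VTI convention {convention!r}")
    out = flow_mm3_s * MM3_PER_S_TO_ML_PER_MIN
    return float(out) if out.ndim == 0 else out


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append FS and CO columns to a measurement table.

    Expected columns: ``LVIDd_mm``, ``LVIDs_mm``, ``VTI_mm``,
    ``aortic_area_mm2``, ``HR_hz`` and optionally a single-valued
    ``vti_convention`` column (mixed conventions are an error).
    """
    conv = "per_second"
    if "vti_convention" in table:
        u = table["vti_convention"].unique()
        if len(u) != 1:
            raise ValueError("mixed VTI conventions in one table")
        conv = str(u[0])
    out = table.copy()
    out["fs_pct"] = fractional_shortening(table["LVIDd_mm"], table["LVIDs_mm"])
    out["co_ml_min"] = cardiac_output(
        table["VTI_mm"], table["aortic_area_mm2"],
        hr_hz=table["HR_hz"] if conv == "per_beat" else None,
        convention=conv)
    return out


def phase_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Plain per-phase means of FS and CO (inferential statistics upstream)."""
    t = table if "fs_pct" in table else summarize_table(table)
    return (t.groupby("phase")[["fs_pct", "co_ml_min"]].mean()
            .rename(columns={"fs_pct": "mean_fs_pct",
                             "co_ml_min": "mean_co_ml_min"}))


def make_echo_table(true_fs_pct: float, true_co_ml_min: float, *,
                    lvidd_mm: float = 4.0, aortic_area_mm2: float = 2.0,
                    hr_hz: float = 8.0, phases=("rest", "pacing", "recovery"),
                    times_per_phase=(1.0, 2.5, 4.0),
                    vti_convention: str = "per_second") -> pd.DataFrame:
    """Emit a measurement table consistent with prescribed FS and CO.

    Inverts the two formulas: ``LVIDs = LVIDd (1 - FS/100)`` and
    ``VTI = CO / (0.06 Area [HR])``.  Serves as ground truth for round-trip
    tests of the metric computations.
    """
    if not 0.0 <= true_fs_pct < 100.0:
        raise ValueError("FS must lie in [0, 100) %")
    lvids = lvidd_mm * (1.0 - true_fs_pct / 100.0)
    if lvids > lvidd_mm:
        raise ValueError("impossible geometry: LVIDs exceeds LVIDd")
    flow_mm3_s = true_co_ml_min / MM3_PER_S_TO_ML_PER_MIN
    if vti_convention == "per_second":
        vti = flow_mm3_s / aortic_area_mm2
    elif vti_convention == "per_beat":
        vti = flow_mm3_s / (aortic_area_mm2 * hr_hz)
    else:
        raise ValueError(f"unknown VTI convention {vti_convention!r}")
    rows = []
    t0 = 0.0
    for phase in phases:
        for dt in times_per_phase:
            rows.append({"time_s": t0 + dt, "phase": phase,
                         "LVIDd_mm": lvidd_mm, "LVIDs_mm": lvids,
                         "VTI_mm": vti, "aortic_area_mm2": aortic_area_mm2,
                         "HR_hz": hr_hz, "vti_convention": vti_convention})
        t0 += max(times_per_phase) + 1.0
    return pd.DataFrame(rows)
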