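"""Forward Beer-Lambert simulation of dual-wavelength reflectance movies.

A :class:`HemoScene` prescribes ground-truth hemoglobin-change fields
dHbO(x, y, t) and dHbR(x, y, t) in uM, a venous-sinus mask with amplified
responses, per-wavelength LED drift polynomials, a dark offset and a photon
budget.  :func:`simulate_reflectance` applies the forward model

    Phi_lambda = phi0 * exp(-(E_lambda,HbO dHbO + E_lambda,HbR dHbR) L_lambda)
                 * drift_lambda(t) + dark,

adds Poisson shot noise at the photon budget, and emits dark frames, so the
spectroscopic inversion can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..oisi import ExtinctionTable, PathlengthModel

__all__ = ["HemoScene", "ReflectanceStack", "make_hemo_scene",
           "simulate_reflectance"]


@dataclass
class HemoScene:
    """Prescribed hemoglobin dynamics plus acquisition nuisance parameters."""

    dhbo: np.ndarray            # (t, y, x), uM
    dhbr: np.ndarray            # (t, y, x), uM
    times_s: np.ndarray
    sinus_mask: np.ndarray      # bool (y, x)
    block_onsets_s: np.ndarray
    drift_coeffs: dict          # wavelength -> polynomial coefficients (t in [0,1])
    dark_level: float = 100.0
    photon_budget: float = 1e5  # mean detected counts/pixel/frame
    seed: int = 0

    def __post_init__(self):
        self.dhbo = np.asarray(self.dhbo, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        if not (np.all(np.isfinite(self.dhbo)) and np.all(np.isfinite(self.dhbr))):
            raise ValueError("prescribed hemoglobin fields must be finite")
        if self.dhbo.shape != self.dhbr.shape:
            raise ValueError("dHbO and dHbR shapes differ")
        self.sinus_mask = np.asarray(self.sinus_mask, dtype=bool)
        if self.sinus_mask.shape != self.dhbo.shape[1:]:
            raise ValueError("sinus mask does not match the field shape")

    @property
    def shape(self):
        return self.dhbo.shape


@dataclass
class ReflectanceStack:
    """Per-wavelength reflectance movies with dark frames and timing."""

    wavelengths_nm: tuple
    frames: dict                 # wavelength -> (t, y, x) counts
    dark_frames: dict            # wavelength -> (n_dark, y, x) counts
    times_s: np.ndarray
    rate_hz: float
    phi0: float
    pathlengths: PathlengthModel
    scene: HemoScene | None = None   # ground truth retained alongside

    def __post_init__(self):
        spans = {self.frames[w].shape[0] for w in self.wavelengths_nm}
        if len(spans) != 1:
            raise ValueError("wavelength movies must cover the same time span")


def _block_response(t_rel, on_s, rise_s=1.5, decay_s=3.0):
    """Unit-amplitude response to one pacing block: saturating rise while the
    light is on, exponential recovery afterwards."""
    r = np.zeros_like(t_rel)
    on = (t_rel >= 0) & (t_rel < on_s)
    r[on] = 1.0 - np.exp(-t_rel[on] / rise_s)
    after = t_rel >= on_s
    peak = 1.0 - np.exp(-on_s / rise_s)
    r[after] = peak * np.exp(-(t_rel[after] - on_s) / decay_s)
    return r


def make_hemo_scene(shape=(128, 128), n_blocks=10, block_s=30.0, on_s=5.0,
                    rate_hz=20.0, lead_in_s=5.0, amp_hbo_um=-1.8,
                    amp_hbr_um=0.8, sinus_gain=2.0,
                    drift_frac=(0.01, -0.008), dark_level=100.0,
                    photon_budget=1e5, seed=0) -> HemoScene:
    """Build a pacing-locked cortical hemodynamic scene.

    Defaults emulate the imaging study conditions: 128x128 field, 20 Hz per
    contrast, ten 30-s blocks of 5-s pacing, cortex-wide dHbO ~= -1.8 uM and
    dHbR ~= +0.8 uM at the response peak, with responses ``sinus_gain`` times
    larger along a midline venous-sinus stripe, linear LED drift of about 1%
    over the run, and shot noise at ``photon_budget`` counts/pixel/frame.
    """
    ny, nx = shape
    duration = lead_in_s + n_blocks * block_s
    nt = int(round(duration * rate_hz))
    t = np.arange(nt) / rate_hz
    onsets = lead_in_s + np.arange(n_blocks) * block_s

    resp = np.zeros(nt)
    for onset in onsets:
        resp += _block_response(t - onset, on_s)

    sinus = np.zeros((ny, nx), dtype=bool)
    half_w = max(1, nx // 16)
    sinus[:, nx // 2 - half_w:nx // 2 + half_w] = True
    gain = np.where(sinus, sinus_gain, 1.0)

    dhbo = amp_hbo_um * resp[:, None, None] * gain[None]
    dhbr = amp_hbr_um * resp[:, None, None] * gain[None]
    drift = {525.0: np.array([1.0, drift_frac[0]]),
             637.0: np.array([1.0, drift_frac[1]])}
    return HemoScene(dhbo=dhbo, dhbr=dhbr, times_s=t, sinus_mask=sinus,
                     block_onsets_s=onsets, drift_coeffs=drift,
                     dark_level=dark_level, photon_budget=photon_budget,
                     seed=seed)


def simulate_reflectance(scene: HemoScene, extinction: ExtinctionTable,
                         pathlengths: PathlengthModel, phi0: float = 1e4,
                         n_dark: int = 20, rate_hz: float = 20.0
                         ) -> ReflectanceStack:
    """Generate the dual-wavelength reflectance movie for a scene.

    Shot noise is Poisson at the scene's ``photon_budget`` mean counts per
    pixel/frame (rescaled to the ``phi0`` intensity scale); a nonpositive
    budget disables noise only when exactly zero and is otherwise an error.
    Dark frames carry the dark offset plus the same relative shot noise.
    """
    if scene.photon_budget < 0:
        raise ValueError("photon budget must be non-negative")
    wls = extinction.wavelengths_nm
    rng = np.random.default_rng(scene.seed)
    nt = scene.shape[0]
    t01 = np.linspace(0.0, 1.0, nt)

    frames, darks = {}, {}
    for i, wl in enumerate(wls):
        e_hbo, e_hbr = extinction.matrix[i]
        dmua = e_hbo * scene.dhbo + e_hbr * scene.dhbr        # mm^-1
        intensity = phi0 * np.exp(-dmua * pathlengths.L_mm[i])
        coeffs = scene.drift_coeffs.get(float(wl))
        if coeffs is not None:
            drift = np.polynomial.polynomial.polyval(t01, coeffs)
            intensity = intensity * drift[:, None, None]
        total = intensity + scene.dark_level
        if scene.photon_budget > 0:
            scale = scene.photon_budget / phi0
            total = rng.poisson(total * scale) / scale
            dark = rng.poisson(
                np.full((n_dark,) + scene.shape[1:],
                        scene.dark_level * scale)) / scale
        else:
            dark = np.full((n_dark,) + scene.shape[1:], scene.dark_level)
        frames[float(wl)] = np.asarray(total, dtype=float)
        darks[float(wl)] = np.asarray(dark, dtype=float)

    return ReflectanceStack(wavelengths_nm=tuple(float(w) for w in wls),
                            frames=frames, dark_frames=darks,
                            times_s=scene.times_s, rate_hz=rate_hz,
                            phi0=phi0, pathlengths=pathlengths, scene=scene)
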