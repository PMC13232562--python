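"""Imaging pipeline: preprocessing, pathlengths, spectroscopic inversion."""

import numpy as np
import pytest

from optopace import oisi, synth
from optopace.oisi import (ExtinctionTable, PathlengthModel,
                           _semiinf_total_reflectance)


# --------------------------------------------------------- dark + binning
def test_dark_subtract_and_bin_constant_frames():
    frames = np.full((3, 8, 8), 10.0)
    dark = np.full((5, 8, 8), 3.0)
    out = oisi.dark_subtract_and_bin(frames, dark, bin_factor=4)
    assert out.shape == (3, 2, 2)
    assert np.allclose(out, 16 * (10.0 - 3.0))
    # zero dark with bin 1 is the identity
    same = oisi.dark_subtract_and_bin(frames, np.zeros((8, 8)), bin_factor=1)
    assert np.array_equal(same, frames)


def test_binning_matches_brute_force_block_sums():
    rng = np.random.default_rng(0)
    frames = rng.uniform(size=(2, 12, 8))
    out = oisi.dark_subtract_and_bin(frames, np.zeros((12, 8)), bin_factor=4)
    for ti in range(2):
        for i in range(3):
            for j in range(2):
                assert out[ti, i, j] == pytest.approx(
                    frames[ti, 4 * i:4 * i + 4, 4 * j:4 * j + 4].sum())
    with pytest.raises(ValueError):
        oisi.dark_subtract_and_bin(frames, np.zeros((12, 8)), bin_factor=5)


# ------------------------------------------------------------- coregister
def test_coregister_identity_and_translation():
    rng = np.random.default_rng(1)
    stack = rng.uniform(size=(2, 32, 32))
    pts = np.array([[4.0, 4.0], [28.0, 5.0], [27.0, 27.0], [5.0, 26.0]])
    same = oisi.coregister(pts, pts, stack)
    assert np.allclose(same, stack, atol=1e-9)
    shifted = oisi.coregister(pts, pts + [3.0, 0.0], stack)
    # pure x-translation by 3: interior pixels move, edge strip is NaN
    assert np.allclose(shifted[:, :, :-4], stack[:, :, 3:-1], atol=1e-6)
    assert np.isnan(shifted[:, :, -1]).all()


def test_homography_parameters_recovered_from_landmarks():
    """Forward-generate landmark pairs from a known projective transform and
    solve: the estimated matrix matches to 1e-6."""
    from skimage.transform import ProjectiveTransform
    true = np.array([[1.01, 0.02, -1.5],
                     [-0.015, 0.99, 2.0],
                     [1e-4, -5e-5, 1.0]])
    tf = ProjectiveTransform(true)
    fixed_pts = np.array([[8.0, 8.0], [56.0, 9.0], [55.0, 55.0], [9.0, 54.0]])
    moving_pts = tf(fixed_pts)
    est = oisi.estimate_homography(fixed_pts, moving_pts)
    assert np.max(np.abs(est.params - true)) < 1e-6
    # and the mapping reproduces arbitrary points, not just the landmarks
    probe = np.array([[20.0, 30.0], [44.0, 18.0]])
    assert np.allclose(est(probe), tf(probe), atol=1e-9)


def test_coregister_degenerate_landmarks_rejected():
    pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])  # collinear
    with pytest.raises(ValueError):
        oisi.coregister(pts, pts + 1.0, np.zeros((1, 8, 8)))


# ------------------------------------------------------------- detrending
def test_polynomial_detrend_exact_and_noise_projection():
    n = 400
    x = np.linspace(-1, 1, n)
    poly = 3 + x - 2 * x ** 3 + 0.5 * x ** 5
    resid, fitted = oisi.detrend_polynomial(poly, order=5)
    assert np.allclose(resid, 0.0, atol=1e-9)
    assert np.allclose(fitted, poly)
    # white noise loses exactly the 6-parameter projection in expectation
    rng = np.random.default_rng(3)
    noise = rng.standard_normal((n, 50))
    r, _ = oisi.detrend_polynomial(noise, order=5)
    ratio = r.var(axis=0).mean() / noise.var(axis=0).mean()
    assert ratio == pytest.approx(1 - 6 / n, abs=0.01)


def test_polynomial_detrend_keeps_step_response():
    n = 600
    y = np.zeros(n)
    y[n // 2:] = 1.0
    resid, _ = oisi.detrend_polynomial(y, order=5)
    jump = resid[n // 2] - resid[n // 2 - 1]
    assert jump == pytest.approx(1.0, abs=0.05)


# -------------------------------------------------------------- smoothing
def test_gaussian_smoothing_kernel_properties():
    const = np.full((16, 16), 4.2)
    assert np.allclose(oisi.smooth_gaussian(const), 4.2)
    impulse = np.zeros((15, 15))
    impulse[7, 7] = 1.0
    out = oisi.smooth_gaussian(impulse)
    assert out.sum() == pytest.approx(1.0)
    k = out[5:10, 5:10]
    assert np.argmax(out) == 7 * 15 + 7
    # matches brute-force convolution with the explicit 5x5 kernel
    from optopace.oisi import _gaussian_kernel
    kern = _gaussian_kernel(5, 1.3)
    assert np.allclose(k, kern, atol=1e-12)


# ------------------------------------------------------------- pathlength
def test_pathlength_monotone_in_absorption():
    """Numeric-derivative oracle: L = -dlnR/dmu_a decreases as mu_a grows."""
    musp = 1.0
    L = []
    for mua in (0.02, 0.05, 0.2, 0.8):
        model = oisi.pathlength_semiinfinite(
            {525.0: {"mu_a_mm": mua, "mu_s_prime_mm": musp},
             637.0: {"mu_a_mm": mua, "mu_s_prime_mm": musp}})
        # cross-check against a central finite difference of the reflectance
        h = 1e-6
        num = -(np.log(_semiinf_total_reflectance(mua + h, musp))
                - np.log(_semiinf_total_reflectance(mua - h, musp))) / (2 * h)
        assert model.L_mm[0] == pytest.approx(num, rel=1e-5)
        L.append(model.L_mm[0])
    assert L[0] > L[1] > L[2] > L[3]


def test_pathlength_low_absorption_scaling():
    """In the mu_a << mu_s' limit L scales as 1/sqrt(mu_a)."""
    def L(mua):
        m = oisi.pathlength_semiinfinite(
            {525.0: {"mu_a_mm": mua, "mu_s_prime_mm": 1.0},
             637.0: {"mu_a_mm": mua, "mu_s_prime_mm": 1.0}})
        return m.L_mm[0]
    assert L(1e-4) / L(4e-4) == pytest.approx(2.0, rel=0.05)


def test_pathlength_equal_props_equal_L_and_validation():
    model = oisi.pathlength_semiinfinite(
        {525.0: {"mu_a_mm": 0.1, "mu_s_prime_mm": 1.0},
         637.0: {"mu_a_mm": 0.1, "mu_s_prime_mm": 1.0}})
    assert model.L_mm[0] == pytest.approx(model.L_mm[1])
    with pytest.raises(ValueError):
        oisi.pathlength_semiinfinite(
            {525.0: {"mu_a_mm": 0.0, "mu_s_prime_mm": 1.0},
             637.0: {"mu_a_mm": 0.1, "mu_s_prime_mm": 1.0}})


# -------------------------------------------------------------- inversion
def test_null_scene_inverts_to_zero(spectro):
    ext, pl = spectro
    stacks = {wl: np.full((40, 8, 8), 1e4) for wl in ext.wavelengths_nm}
    maps = oisi.mbll_invert(stacks, ext, pl, phi0="prestim", prestim_frames=10)
    assert np.allclose(maps.dhbo, 0.0, atol=1e-12)
    assert np.allclose(maps.dhbr, 0.0, atol=1e-12)


def test_identity_extinction_inverts_log_ratio_directly():
    ext = ExtinctionTable(wavelengths_nm=(525.0, 637.0), matrix=np.eye(2))
    pl = PathlengthModel(wavelengths_nm=(525.0, 637.0),
                         L_mm=np.array([1.0, 1.0]),
                         mu_a_mm=np.array([0.1, 0.1]),
                         mu_s_prime_mm=np.array([1.0, 1.0]))
    nt = 30
    drop = np.ones(nt)
    drop[10:] = 0.9
    stacks = {525.0: 1e4 * drop[:, None, None] * np.ones((nt, 4, 4)),
              637.0: np.full((nt, 4, 4), 1e4)}
    maps = oisi.mbll_invert(stacks, ext, pl, phi0="prestim", prestim_frames=5,
                            smooth=False)
    assert np.allclose(maps.dhbo[10:], -np.log(0.9), atol=1e-9)
    assert np.allclose(maps.dhbo[:10], 0.0, atol=1e-12)
    assert np.allclose(maps.dhbr, 0.0, atol=1e-12)


def test_forward_inverse_round_trip_and_budget_monotonicity(spectro):
    """Prescribed hemoglobin fields are recovered through the full chain
    (forward model -> binning -> smoothing -> inversion); the error falls
    monotonically as the photon budget grows."""
    ext, pl = spectro

    def rmse_at(budget, seed=1):
        scene = synth.make_hemo_scene(shape=(32, 32), n_blocks=3,
                                      lead_in_s=10.0, drift_frac=(0.0, 0.0),
                                      photon_budget=budget, seed=seed)
        stack = synth.simulate_reflectance(scene, ext, pl, phi0=1e4)
        binned = {wl: oisi.dark_subtract_and_bin(stack.frames[wl],
                                                 stack.dark_frames[wl], 4)
                  for wl in ext.wavelengths_nm}
        maps = oisi.mbll_invert(binned, ext, pl, phi0="prestim",
                                prestim_frames=200)

        def binmean(a):
            t, y, x = a.shape
            return a.reshape(t, y // 4, 4, x // 4, 4).mean(axis=(2, 4))

        out = {}
        for name, rec, tru in (("hbo", maps.dhbo, binmean(scene.dhbo)),
                               ("hbr", maps.dhbr, binmean(scene.dhbr))):
            out[name] = np.sqrt(np.nanmean((rec - tru) ** 2)) / np.ptp(tru)
        return out

    r5 = rmse_at(1e5)
    assert r5["hbo"] < 0.05
    assert r5["hbr"] < 0.05
    r3, r4 = rmse_at(1e3), rmse_at(1e4)
    for c in ("hbo", "hbr"):
        assert r3[c] > r4[c] > r5[c]


def test_inversion_is_linear_in_the_small_signal_regime(spectro):
    ext, pl = spectro
    scene1 = synth.make_hemo_scene(shape=(16, 16), n_blocks=2, lead_in_s=5.0,
                                   amp_hbo_um=-0.5, amp_hbr_um=0.25,
                                   drift_frac=(0.0, 0.0), photon_budget=0.0)
    scene2 = synth.make_hemo_scene(shape=(16, 16), n_blocks=2, lead_in_s=5.0,
                                   amp_hbo_um=-1.0, amp_hbr_um=0.5,
                                   drift_frac=(0.0, 0.0), photon_budget=0.0)
    maps = []
    for scene in (scene1, scene2):
        st = synth.simulate_reflectance(scene, ext, pl, phi0=1e4)
        stacks = {wl: st.frames[wl] - st.dark_frames[wl].mean(axis=0)
                  for wl in ext.wavelengths_nm}
        maps.append(oisi.mbll_invert(stacks, ext, pl, phi0="prestim",
                                     prestim_frames=90, smooth=False))
    assert np.allclose(maps[1].dhbo, 2 * maps[0].dhbo, atol=2e-3)
    assert np.allclose(maps[1].dhbr, 2 * maps[0].dhbr, atol=2e-3)


def test_hbt_identity_holds_exactly(spectro):
    ext, pl = spectro
    scene = synth.make_hemo_scene(shape=(16, 16), n_blocks=2, lead_in_s=5.0,
                                  photon_budget=1e4, seed=4)
    st = synth.simulate_reflectance(scene, ext, pl, phi0=1e4)
    stacks = {wl: st.frames[wl] - st.dark_frames[wl].mean(axis=0)
              for wl in ext.wavelengths_nm}
    maps = oisi.mbll_invert(stacks, ext, pl)
    assert np.array_equal(maps.dhbt, maps.dhbo + maps.dhbr)


def test_nonpositive_intensities_are_nulled_not_clipped(spectro):
    ext, pl = spectro
    stacks = {wl: np.full((20, 4, 4), 1e4) for wl in ext.wavelengths_nm}
    stacks[525.0][:, 0, 0] = -5.0
    with pytest.warns(UserWarning):
        maps = oisi.mbll_invert(stacks, ext, pl, phi0="prestim",
                                prestim_frames=5, smooth=False)
    assert np.isnan(maps.dhbo[:, 0, 0]).all()
    assert maps.n_invalid_pixels == 1


# --------------------------------------------------------- evoked responses
def test_epoch_average_identical_epochs_and_se_shrinkage():
    rng = np.random.default_rng(5)
    rate = 10.0
    nt = int(20 * 8 * rate)
    t = np.arange(nt) / rate
    onsets = 5.0 + np.arange(18) * 8.0
    sig = np.zeros(nt)
    for o in onsets:
        m = (t >= o) & (t < o + 2.0)
        sig[m] = 1.0
    clean = np.tile(sig[:, None, None], (1, 2, 2))
    from optopace.oisi import HemoMaps
    maps = HemoMaps(dhbo=clean, dhbr=np.zeros_like(clean), times_s=t)
    ev = oisi.epoch_average(maps, onsets, pre_s=2.0, post_s=6.0)
    sel = (ev["time_s"] >= 0.5) & (ev["time_s"] < 1.95)
    assert np.allclose(ev["hbo"]["mean"][sel], 1.0)
    assert np.allclose(ev["hbo"]["sd"], 0.0)

    # SE shrinks as 1/sqrt(n) for pure-noise epochs
    ses = []
    for n_ep in (4, 16):
        noisy = rng.standard_normal((nt, 2, 2))
        maps_n = HemoMaps(dhbo=noisy, dhbr=np.zeros_like(noisy), times_s=t)
        ev_n = oisi.epoch_average(maps_n, onsets[:n_ep], pre_s=2.0, post_s=6.0)
        ses.append(ev_n["hbo"]["se"].mean())
    assert ses[1] / ses[0] == pytest.approx(0.5, rel=0.15)


def test_epoch_average_drops_truncated_blocks():
    from optopace.oisi import HemoMaps
    t = np.arange(200) / 10.0
    maps = HemoMaps(dhbo=np.zeros((200, 2, 2)), dhbr=np.zeros((200, 2, 2)),
                    times_s=t)
    with pytest.warns(UserWarning):
        ev = oisi.epoch_average(maps, [5.0, 12.0, 19.5], pre_s=2.0, post_s=5.0)
    assert ev["n_epochs"] == 2
    with pytest.raises(ValueError):
        oisi.epoch_average(maps, [19.5], pre_s=2.0, post_s=5.0)


def test_peak_map_and_roi_timecourse():
    from optopace.oisi import HemoMaps
    t = np.arange(100) / 10.0
    data = np.ones((100, 4, 4)) * 2.0
    maps = HemoMaps(dhbo=data, dhbr=np.zeros_like(data), times_s=t)
    ev = oisi.epoch_average(maps, [3.0, 6.0], pre_s=1.0, post_s=3.0)
    pm = oisi.peak_map(ev, pacing_window_s=(0.0, 2.0), contrast="hbo")
    assert np.allclose(pm, 0.0)   # constant movie: baseline-subtracted is flat
    labels = np.zeros((4, 4), dtype=int)
    labels[:2] = 1
    labels[2:] = 2
    tc = oisi.roi_timecourse(data, labels)
    assert set(tc) == {1, 2}
    assert np.allclose(tc[1], 2.0)


def test_sinus_versus_cortex_amplitude_ratio_recovered(spectro):
    """The venous-sinus stripe is prescribed a 2x response; the full pipeline
    with polynomial baseline, epoch averaging and peak maps recovers the
    sinus/cortex amplitude ratio within 10%.  Region cores a couple of pixels
    from the stripe boundary are compared so the 5x5 spatial smoothing kernel
    does not mix the two compartments."""
    from scipy import ndimage as ndi
    ext, pl = spectro
    scene = synth.make_hemo_scene(shape=(64, 64), n_blocks=4, lead_in_s=5.0,
                                  sinus_gain=2.0, photon_budget=1e5, seed=6)
    st = synth.simulate_reflectance(scene, ext, pl, phi0=1e4)
    stacks = {wl: st.frames[wl] - st.dark_frames[wl].mean(axis=0)
              for wl in ext.wavelengths_nm}
    maps = oisi.mbll_invert(stacks, ext, pl, times_s=scene.times_s)
    ev = oisi.epoch_average(maps, scene.block_onsets_s, pre_s=5.0, post_s=25.0)
    pm = oisi.peak_map(ev, pacing_window_s=(1.0, 5.0), contrast="hbo")
    sinus_core = ndi.binary_erosion(scene.sinus_mask, iterations=3)
    cortex_core = ~ndi.binary_dilation(scene.sinus_mask, iterations=3)
    ratio = pm[sinus_core].mean() / pm[cortex_core].mean()
    assert ratio == pytest.approx(2.0, rel=0.10)


def test_extinction_table_condition_and_singularity():
    ext = oisi.default_extinction()
    assert ext.condition_number < 100.0
    with pytest.raises(ValueError):
        ExtinctionTable(wavelengths_nm=(525.0, 637.0),
                        matrix=np.array([[1.0, 1.0], [1.0, 1.0]]) * 1e-20)
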