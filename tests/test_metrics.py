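"""Image- and trace-quality metrics against closed forms and oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.metrics import structural_similarity

from fiberdl.metrics import (
    MSSSIM_WEIGHTS,
    RoiMask,
    annulus_background,
    dff_trace,
    evaluate_sweep,
    ms_ssim,
    nrmse_image,
    nrmse_trace,
    snr_db,
)
from fiberdl.phantom import ActivityModel, PhantomSpec, generate_scene, simulate_activity
from fiberdl.scanmodel import build_ring_map, radial_downsample


def _roi_for(scene, i=0):
    exclude = ~scene.background_mask
    return RoiMask(
        mask=scene.roi_masks[i],
        background_mask=annulus_background(scene.roi_masks[i], exclude=exclude),
    )


class TestSnr:
    def test_unity_ratio_is_zero_db(self):
        frame = np.full((16, 16), 50.0)
        roi = RoiMask(mask=np.eye(16, dtype=bool), background_mask=~np.eye(16, dtype=bool))
        assert snr_db(frame, roi) == pytest.approx(0.0, abs=1e-12)

    def test_decade_ratio_is_ten_db(self):
        frame = np.full((16, 16), 5.0)
        mask = np.zeros((16, 16), bool)
        mask[:4] = True
        frame[mask] = 50.0
        roi = RoiMask(mask=mask, background_mask=~mask)
        assert snr_db(frame, roi) == pytest.approx(10.0, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        frame = rng.uniform(1, 255, (32, 32))
        mask = rng.random((32, 32)) > 0.7
        bg = (~mask) & (rng.random((32, 32)) > 0.5)
        roi = RoiMask(mask=mask, background_mask=bg)
        # independently coded mean-and-log computation
        expected = 10.0 * np.log10(
            np.sum(frame * mask) / mask.sum() / (np.sum(frame * bg) / bg.sum())
        )
        assert snr_db(frame, roi) == pytest.approx(expected, abs=1e-12)

    def test_zero_background_rejected(self):
        frame = np.zeros((8, 8))
        mask = np.zeros((8, 8), bool)
        mask[0] = True
        roi = RoiMask(mask=mask, background_mask=~mask)
        with pytest.raises(ValueError, match="background"):
            snr_db(frame, roi)


class TestDffTrace:
    def test_constant_stack_gives_zero_trace(self, small_scene):
        stack = np.repeat(small_scene.structure_map[None], 20, axis=0)
        trace = dff_trace(stack, _roi_for(small_scene))
        assert np.all(trace == 0)

    def test_peak_normalised_to_one(self, small_scene):
        stack = np.repeat(small_scene.structure_map[None], 30, axis=0)
        m = small_scene.roi_masks[0]
        stack[12][m] *= 1.8  # one synthetic transient
        trace = dff_trace(stack, _roi_for(small_scene))
        assert trace[12] == pytest.approx(1.0)
        assert trace.max() == pytest.approx(1.0)

    def test_recovers_generative_truth_noise_free(self):
        scene = generate_scene(PhantomSpec(image_size=64, n_somas=3, seed=21))
        movie, truth = simulate_activity(
            scene, ActivityModel(spike_rate=0.05, n_frames=200, seed=22)
        )
        for i in range(3):
            rec = dff_trace(movie, _roi_for(scene, i))
            rho = spearmanr(rec, truth[i]).statistic
            assert rho > 0.9

    def test_nonpositive_baseline_rejected(self):
        stack = np.zeros((10, 16, 16))
        mask = np.zeros((16, 16), bool)
        mask[:2] = True
        bg = np.zeros((16, 16), bool)
        bg[4:6] = True
        with pytest.raises(ValueError, match="percentile"):
            dff_trace(stack, RoiMask(mask=mask, background_mask=bg))


class TestNrmse:
    def test_identity_is_zero(self, rng):
        x = rng.uniform(0, 1, 50)
        assert nrmse_trace(x, x) == 0.0
        img = rng.uniform(0, 255, (16, 16))
        assert nrmse_image(img, img) == 0.0

    def test_constant_offset_closed_form(self, rng):
        f = rng.uniform(0, 1, 100)
        c = 0.07
        assert nrmse_trace(f, f + c) == pytest.approx(c / (f.max() - f.min()))

    def test_hand_computed_toy_image(self):
        I = np.array([[0.0, 255.0], [0.0, 255.0]])
        I0 = I.copy()
        I0[0, 0] += 51.0
        assert nrmse_image(I, I0) == pytest.approx(0.1)  # RMSE 25.5 / range 255

    def test_matches_independent_oracle(self, rng):
        F = rng.uniform(0, 1, 64)
        F0 = rng.uniform(0, 1, 64)
        expected = np.sqrt(((F - F0) ** 2).sum() / 64) / (max(F) - min(F))
        assert nrmse_trace(F, F0) == pytest.approx(expected, abs=1e-12)
        I = rng.uniform(0, 255, (64, 64))
        I0 = rng.uniform(0, 255, (64, 64))
        expected = np.sqrt(((I - I0) ** 2).mean()) / (I.max() - I.min())
        assert nrmse_image(I, I0) == pytest.approx(expected, abs=1e-12)

    def test_normalisation_uses_evaluated_range_not_reference(self):
        # deliberate asymmetry of the definition: the denominator is the
        # evaluated signal's range
        F = np.array([0.0, 1.0, 0.5])
        F0 = np.array([0.0, 2.0, 1.0])
        assert nrmse_trace(F, F0) != pytest.approx(nrmse_trace(F0, F))

    def test_constant_evaluated_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nrmse_trace(np.ones(10), np.zeros(10))


def _brute_force_ms_ssim(x, y, n_scales, data_range=255.0):
    """Independent multi-scale SSIM: explicit sliding-window loops."""
    w = np.asarray(MSSSIM_WEIGHTS[:n_scales], float)
    if n_scales != len(MSSSIM_WEIGHTS):
        w = w / w.sum()
    ax = np.arange(11.0) - 5.0
    g = np.exp(-(ax**2) / (2 * 1.5**2))
    kern = np.outer(g, g)
    kern /= kern.sum()
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    result = 1.0
    for s in range(n_scales):
        H, W = x.shape
        lum_cs, cs_only = [], []
        for i in range(H - 10):
            for j in range(W - 10):
                px = x[i : i + 11, j : j + 11]
                py = y[i : i + 11, j : j + 11]
                mx = (kern * px).sum()
                my = (kern * py).sum()
                sxx = (kern * px * px).sum() - mx * mx
                syy = (kern * py * py).sum() - my * my
                sxy = (kern * px * py).sum() - mx * my
                lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
                cs = (2 * sxy + c2) / (sxx + syy + c2)
                lum_cs.append(lum * cs)
                cs_only.append(cs)
        term = np.mean(lum_cs) if s == n_scales - 1 else np.mean(cs_only)
        result *= max(term, 0.0) ** w[s]
        if s < n_scales - 1:
            if H % 2 or W % 2:
                x = np.pad(x, ((0, H % 2), (0, W % 2)), mode="edge")
                y = np.pad(y, ((0, H % 2), (0, W % 2)), mode="edge")
            x = 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])
            y = 0.25 * (y[0::2, 0::2] + y[1::2, 0::2] + y[0::2, 1::2] + y[1::2, 1::2])
    return result


class TestMsSsim:
    def test_self_similarity_is_one(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        assert ms_ssim(img, img, n_scales=3) == pytest.approx(1.0, abs=1e-12)

    def test_luminance_shift_invariance(self, rng):
        x = rng.uniform(40, 200, (64, 64))
        y = x + rng.normal(0, 10, (64, 64))
        a = ms_ssim(x, y, n_scales=3)
        b = ms_ssim(x + 10, y + 10, n_scales=3)
        assert a == pytest.approx(b, abs=5e-3)

    def test_single_scale_matches_skimage_reference(self, rng):
        # our single-scale value is plain SSIM; the independent reference is
        # scikit-image with the same window conventions
        for _ in range(3):
            x = rng.uniform(0, 255, (48, 48))
            y = np.clip(x + rng.normal(0, 20, (48, 48)), 0, 255)
            ours = ms_ssim(x, y, n_scales=1)
            ref = structural_similarity(
                x, y, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=255.0,
            )
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_multi_scale_matches_brute_force_oracle(self, rng):
        x = rng.uniform(0, 255, (48, 48))
        y = np.clip(x + rng.normal(0, 25, (48, 48)), 0, 255)
        ours = ms_ssim(x, y, n_scales=2)
        assert ours == pytest.approx(_brute_force_ms_ssim(x, y, 2), abs=1e-6)

    def test_bounded_on_nonnegative_inputs(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 255, (64, 64))
            y = rng.uniform(0, 255, (64, 64))
            v = ms_ssim(x, y, n_scales=3)
            assert 0.0 <= v <= 1.0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="scales"):
            ms_ssim(np.zeros((32, 32)), np.zeros((32, 32)), n_scales=5)


class TestEvaluateSweep:
    def test_single_frame_row(self, rng):
        ref = rng.uniform(0, 255, (1, 64, 64))
        table = evaluate_sweep({4: ref + 1.0}, ref, n_scales=3)
        assert len(table) == 1
        assert table.loc[0, "M"] == 4
        assert table.loc[0, "n_frames"] == 1
        assert table.loc[0, "msssim_sd"] == 0.0

    def test_reports_frame_count(self, rng):
        ref = rng.uniform(0, 255, (7, 64, 64))
        table = evaluate_sweep({2: np.clip(ref + 1, 0, 255)}, ref, n_scales=3)
        assert table.loc[0, "n_frames"] == 7

    def test_degradation_monotone_in_m_without_restoration(self, small_scene):
        # raw decimation quality decreases as rings are dropped
        rings = build_ring_map(64, 40)
        ref = np.repeat(small_scene.structure_map[None], 3, axis=0)
        degraded = {
            M: np.stack([radial_downsample(f, rings, M) for f in ref])
            for M in (2, 4, 8)
        }
        table = evaluate_sweep(degraded, ref, n_scales=3).sort_values("M")
        vals = table["msssim_mean"].to_numpy()
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_mismatched_shapes_rejected(self, rng):
        ref = rng.uniform(0, 255, (3, 64, 64))
        with pytest.raises(ValueError, match="match"):
            evaluate_sweep({2: ref[:2]}, ref, n_scales=3)
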