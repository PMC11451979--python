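"""White balance, MVGD transfer, DNIL histogram regression, full pipeline."""

import numpy as np
import pytest

from chromacard.card_model import extract_patches, patch_mask
from chromacard.colorspace import Encoding, ImageF32, delta_e_2000
from chromacard.correction import (
    ChannelLUT,
    DnilConfig,
    MvgdTransform,
    PipelineConfig,
    TransferModel,
    apply_mvgd,
    apply_mvgd_array,
    apply_white_balance,
    fit_dnil,
    fit_mvgd,
    fit_white_balance,
    run_pipeline,
)
from chromacard.illumination_sim import IlluminantSpec, simulate_illumination
from chromacard.metrics_qc import ground_truth_report


class TestWhiteBalance:
    def test_gains_are_componentwise_ratio(self):
        g = fit_white_balance(np.array([0.8, 1.0, 0.9]))
        assert g.gains == pytest.approx((1.25, 1.0, 1.0 / 0.9))

    def test_identity_when_measured_equals_reference(self):
        g = fit_white_balance(np.ones(3))
        assert g.gains == (1.0, 1.0, 1.0)

    def test_dead_channel_rejected(self):
        with pytest.raises(ValueError, match="white patch unusable"):
            fit_white_balance(np.array([0.0, 0.5, 0.5]))

    def test_apply_scales_and_clips(self):
        img = ImageF32(np.full((2, 2, 3), 0.6, np.float32), Encoding.LINEAR_RGB)
        out, n_clipped = apply_white_balance(img, fit_white_balance(np.full(3, 0.5)))
        assert np.all(out.pixels == 1.0)
        assert n_clipped == 12

    def test_identity_gains_leave_image_unchanged(self):
        img = ImageF32(np.random.default_rng(0).uniform(0, 1, (3, 3, 3)), Encoding.LINEAR_RGB)
        out, n = apply_white_balance(img, fit_white_balance(np.ones(3)))
        assert np.allclose(out.pixels, img.pixels) and n == 0


class TestMvgd:
    def test_identical_samples_give_identity_map(self, rng):
        x = rng.normal([50, 0, 0], [10, 5, 5], size=(500, 3))
        t = fit_mvgd(x, x)
        assert t.T == pytest.approx(np.eye(3), abs=1e-4)
        assert t.mu_src == pytest.approx(t.mu_tgt)

    def test_halving_spread_gives_half_identity(self, rng):
        src = rng.normal(size=(20000, 3))
        src = (src - src.mean(0)) / src.std(0) * 2.0
        tgt = rng.normal(size=(20000, 3))
        tgt = (tgt - tgt.mean(0)) / tgt.std(0)
        t = fit_mvgd(src, tgt, reg_lambda=0.0)
        assert np.diag(t.T) == pytest.approx([0.5, 0.5, 0.5], abs=0.01)

    def test_moment_matching_monte_carlo(self, rng):
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        src = rng.multivariate_normal([50, 5, -10], a @ a.T + 0.5 * np.eye(3), 100000)
        tgt = rng.multivariate_normal([60, -5, 15], b @ b.T + 0.5 * np.eye(3), 100000)
        mapped = apply_mvgd_array(src, fit_mvgd(src, tgt))
        assert mapped.mean(0) == pytest.approx(tgt.mean(0), abs=1e-6)
        cov_m, cov_t = np.cov(mapped.T), np.cov(tgt.T)
        assert np.abs(cov_m - cov_t).max() / np.abs(cov_t).max() < 0.02

    def test_transform_is_symmetric_psd(self, rng):
        src = rng.normal([50, 0, 0], [20, 10, 10], size=(1000, 3))
        tgt = rng.normal([60, 5, -5], [5, 15, 2], size=(1000, 3))
        t = fit_mvgd(src, tgt)
        assert np.allclose(t.T, t.T.T)
        assert np.linalg.eigvalsh(t.T).min() >= 0

    def test_apply_identity_and_translation(self):
        img = ImageF32(np.random.default_rng(1).uniform(0, 60, (4, 4, 3)), Encoding.CIELAB)
        out = apply_mvgd(img, MvgdTransform.identity())
        assert np.allclose(out.pixels, img.pixels)
        shift = MvgdTransform(np.zeros(3), np.array([5.0, -2.0, 1.0]), np.eye(3))
        out = apply_mvgd(img, shift)
        assert np.allclose(out.pixels - img.pixels, [5.0, -2.0, 1.0], atol=1e-5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mvgd(np.zeros((3, 3)), np.zeros((10, 3)))

    def test_nonfinite_rejected(self):
        bad = np.full((10, 3), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fit_mvgd(bad, np.zeros((10, 3)))


def _flat_score(_lut):
    return 0.0


class TestDnil:
    def test_identity_when_source_equals_target(self, rng):
        x = rng.normal(50, 10, 5000)
        lut = fit_dnil(x, x, DnilConfig(), _flat_score, (0.0, 100.0))
        assert np.max(np.abs(lut(lut.knots_src) - lut.knots_src)) < 1e-6

    def test_exact_shift_map(self):
        src = np.array([0.0, 1.0, 2.0, 3.0])
        tgt = np.array([10.0, 11.0, 12.0, 13.0])
        lut = fit_dnil(src, tgt, DnilConfig(), _flat_score, (0.0, 100.0))
        assert lut(src) == pytest.approx(tgt)

    def test_larger_candidate_set_never_scores_worse(self, rng):
        src = rng.normal(50, 10, 8000)
        tgt = 20 + 0.012 * rng.normal(50, 10, 8000) ** 2  # smooth nonlinear distortion
        probe = rng.normal(50, 10, 2000)
        target_probe = 20 + 0.012 * probe**2

        def score(lut):
            return -float(np.mean(np.abs(lut(probe) - target_probe)))

        lut_lin = fit_dnil(
            src, tgt, DnilConfig(candidates=("piecewise_linear",)), score, (0.0, 130.0)
        )
        lut_all = fit_dnil(src, tgt, DnilConfig(), score, (0.0, 130.0))
        assert score(lut_all) >= score(lut_lin)

    @pytest.mark.parametrize("interpolant", ["piecewise_linear", "monotone_cubic", "smoothing_spline"])
    def test_luts_monotone_over_knot_range(self, rng, interpolant):
        src = rng.normal(50, 12, 5000)
        tgt = np.sort(rng.gamma(4.0, 5.0, 5000))
        lut = fit_dnil(
            src, tgt, DnilConfig(candidates=(interpolant,)), _flat_score, (0.0, 200.0)
        )
        assert lut.is_monotone()

    def test_constant_channel_maps_to_target_median(self):
        with pytest.warns(UserWarning, match="constant source channel"):
            lut = fit_dnil(
                np.full(100, 7.0), np.arange(100.0), DnilConfig(), _flat_score, (0.0, 100.0)
            )
        assert lut(np.array([7.0]))[0] == pytest.approx(np.median(np.arange(100.0)))

    def test_extrapolation_clamped_to_bounds(self, rng):
        x = rng.uniform(20, 80, 4000)
        lut = fit_dnil(x, x, DnilConfig(), _flat_score, (0.0, 100.0))
        assert lut(np.array([-500.0]))[0] >= 0.0
        assert lut(np.array([500.0]))[0] <= 100.0


class TestPipeline:
    def test_ideal_card_identity_and_determinism(self, ideal_card, layout, palette):
        out1, _, rep = run_pipeline(ideal_card, layout, palette)
        out2, _, _ = run_pipeline(ideal_card, layout, palette)
        final = ground_truth_report(extract_patches(out1, layout), palette)
        assert final.mean < 0.5
        assert np.array_equal(out1.pixels, out2.pixels)
        assert not rep.uncorrectable_warning

    def test_recovery_from_warm_illuminant(self, ideal_card, layout, palette):
        degraded = simulate_illumination(ideal_card, IlluminantSpec(cct_K=3000, seed=0))
        uncorrected = ground_truth_report(extract_patches(degraded, layout), palette)
        corrected_img, _, _ = run_pipeline(degraded, layout, palette)
        corrected = ground_truth_report(extract_patches(corrected_img, layout), palette)
        assert uncorrected.mean > 5.0
        assert corrected.mean < 1.0
        assert corrected.mean < 0.3 * uncorrected.mean

    def test_stage_means_non_increasing_for_noise_free_shift(self, ideal_card, layout, palette):
        degraded = simulate_illumination(ideal_card, IlluminantSpec(cct_K=2700, seed=0))
        _, _, rep = run_pipeline(degraded, layout, palette)
        means = [s.mean_delta_e for s in rep.stages]
        assert all(b <= a + 0.05 for a, b in zip(means, means[1:]))

    def test_model_fit_ignores_pixels_outside_masks(self, ideal_card, layout, palette):
        degraded = simulate_illumination(ideal_card, IlluminantSpec(cct_K=3500, seed=0))
        _, model1, _ = run_pipeline(degraded, layout, palette)
        tampered = degraded.copy()
        mask = patch_mask(layout, tampered.pixels.shape[:2], shrink=0.2)
        tampered.pixels[~mask] = 0.9
        _, model2, _ = run_pipeline(tampered, layout, palette)
        assert model1.wb.gains == pytest.approx(model2.wb.gains)
        assert np.allclose(model1.mvgd1.T, model2.mvgd1.T)
        assert np.allclose(model1.mvgd2.T, model2.mvgd2.T)
        for l1, l2 in zip(model1.luts, model2.luts):
            assert l1.interpolant == l2.interpolant
            assert np.allclose(l1.knots_tgt, l2.knots_tgt)

    def test_idempotence_in_the_limit(self, ideal_card, layout, palette):
        degraded = simulate_illumination(
            ideal_card, IlluminantSpec(cct_K=3000, noise_sd=0.003, seed=4)
        )
        once, _, _ = run_pipeline(degraded, layout, palette)
        twice, _, _ = run_pipeline(once, layout, palette)
        m1 = extract_patches(once, layout).lab_array()
        m2 = extract_patches(twice, layout).lab_array()
        assert np.max(delta_e_2000(m1, m2)) < 0.5

    def test_8bit_linear_ablation_never_beats_full_pipeline(self, ideal_card, layout, palette):
        conditions = [
            IlluminantSpec(cct_K=2700, brightness=0.5, gradient_amplitude=0.1, noise_sd=0.004, seed=10),
            IlluminantSpec(cct_K=3000, brightness=0.7, gradient_amplitude=0.05, noise_sd=0.004, seed=11),
            IlluminantSpec(cct_K=4000, brightness=0.85, gradient_amplitude=0.1, noise_sd=0.004, seed=12),
            IlluminantSpec(cct_K=5800, brightness=1.0, gradient_amplitude=0.05, noise_sd=0.004, seed=13),
        ]
        ablated_cfg = PipelineConfig(bit_depth=8, dnil=DnilConfig(candidates=("piecewise_linear",)))
        full, ablated = [], []
        for spec in conditions:
            degraded = simulate_illumination(ideal_card, spec)
            img32, _, _ = run_pipeline(degraded, layout, palette)
            img8, _, _ = run_pipeline(degraded, layout, palette, ablated_cfg)
            full.append(ground_truth_report(extract_patches(img32, layout), palette).mean)
            ablated.append(ground_truth_report(extract_patches(img8, layout), palette).mean)
        assert np.mean(ablated) >= np.mean(full)

    def test_gradient_image_reported_uncorrectable(self, ideal_card, layout, palette):
        shaded = simulate_illumination(
            ideal_card, IlluminantSpec(cct_K=4000, gradient_amplitude=0.25, seed=0)
        )
        _, _, rep = run_pipeline(shaded, layout, palette)
        assert rep.uncorrectable_warning and rep.mirror_flags

    def test_transfer_model_json_roundtrip_reapplies_identically(
        self, ideal_card, layout, palette, tmp_path
    ):
        degraded = simulate_illumination(ideal_card, IlluminantSpec(cct_K=3200, seed=2))
        _, model, _ = run_pipeline(degraded, layout, palette)
        path = tmp_path / "model.json"
        model.to_json(path)
        import json

        model2 = TransferModel.from_dict(json.loads(path.read_text()))
        out1 = model.apply(degraded)
        out2 = model2.apply(degraded)
        assert np.array_equal(out1.pixels, out2.pixels)
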