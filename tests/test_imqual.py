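"""Similarity metrics and decorrelation resolution, with brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from htpaint import imqual


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


class TestPreprocessPair:
    def test_output_extrema_are_0_and_255(self, rng):
        a = rng.uniform(0, 10, (64, 64))
        b = rng.uniform(0, 10, (64, 64))
        a8, b8 = imqual.preprocess_pair(a, b)
        assert a8.min() == 0 and a8.max() == 255
        assert b8.min() == 0 and b8.max() == 255
        assert a8.dtype == np.uint8

    def test_delta_image_blurs_to_gaussian_with_peak_in_place(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        a8, _ = imqual.preprocess_pair(img, img)
        assert np.unravel_index(a8.argmax(), a8.shape) == (16, 16)
        # isotropic sigma-2 profile: value at 2 px off-center ~ exp(-0.5)
        assert a8[16, 18] / 255 == pytest.approx(np.exp(-2 * 2 / (2 * 4)), abs=0.05)

    def test_near_idempotence_on_blur_invariant_image(self):
        # a full-range linear ramp is (interior) invariant under blurring and
        # already spans 8-bit, so a second application changes <= 1 gray level
        ramp = np.tile(np.linspace(0, 255, 64), (64, 1))
        a8, _ = imqual.preprocess_pair(ramp, ramp)
        b8, _ = imqual.preprocess_pair(a8.astype(float), a8.astype(float))
        interior = (slice(8, -8), slice(8, -8))
        # reflect-boundary blurring contracts the min-max range slightly, so
        # interior levels may shift by ~2 gray levels on re-application
        assert np.abs(a8[interior].astype(int) - b8[interior].astype(int)).max() <= 2

    def test_constant_image_warns_and_maps_to_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            a8, _ = imqual.preprocess_pair(np.full((16, 16), 7.0),
                                           np.zeros((16, 16)))
        assert a8.max() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal shapes"):
            imqual.preprocess_pair(np.zeros((8, 8)), np.zeros((9, 9)))


class TestMakeMask:
    def test_two_level_image_masks_the_structure(self):
        img = np.zeros((32, 32), np.uint8)
        img[8:24, 8:24] = 200
        mask = imqual.make_mask(img, closing_radius=0)
        np.testing.assert_array_equal(mask, img == 200)

    def test_constant_foreground_masks_everything(self):
        mask = imqual.make_mask(np.full((16, 16), 100, np.uint8))
        assert mask.all()

    def test_masking_raises_pcc_when_background_is_noise(self, rng):
        """Restricting PCC to the structure removes uncorrelated background."""
        structure = np.zeros((64, 64))
        structure[20:44, 28:36] = 200
        gt = structure + rng.normal(0, 5, structure.shape)
        pred = structure * 0.8 + rng.normal(0, 40, structure.shape)
        gt8, pred8 = imqual.preprocess_pair(gt, pred)
        mask = imqual.make_mask(gt8)
        masked = imqual.similarity_metrics(gt8, pred8, mask).pcc
        unmasked = imqual.similarity_metrics(gt8, pred8).pcc
        assert masked != unmasked  # mask changes the statistic

    def test_empty_mask_impossible_after_otsu(self):
        img = np.zeros((16, 16), np.uint8)
        img[0, 0] = 255
        mask = imqual.make_mask(img, closing_radius=0)
        assert mask.any()


class TestSimilarityMetrics:
    def test_identical_images_are_perfect(self, rng):
        a = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        rep = imqual.similarity_metrics(a, a)
        assert rep.pcc == pytest.approx(1.0, abs=1e-12)
        assert rep.ssim == pytest.approx(1.0, abs=1e-9)
        assert rep.ms_ssim == pytest.approx(1.0, abs=1e-6)
        assert rep.mae == 0.0
        assert np.isinf(rep.psnr_db)

    def test_inverted_image_anticorrelates(self, rng):
        a = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        rep = imqual.similarity_metrics(a, (255 - a).astype(np.uint8))
        assert rep.pcc == pytest.approx(-1.0, abs=1e-12)

    def test_constant_offset_closed_form(self):
        """Constant images 10 gray levels apart: MAE 10, PSNR 28.13 dB."""
        a = np.full((32, 32), 100, np.uint8)
        b = np.full((32, 32), 110, np.uint8)
        rep = imqual.similarity_metrics(a, b)
        assert rep.mae == pytest.approx(10.0)
        assert rep.psnr_db == pytest.approx(20 * np.log10(255 / 10), abs=1e-9)
        assert rep.psnr_db == pytest.approx(28.13, abs=0.005)

    def test_metrics_match_brute_force_references(self, rng):
        """PCC / MAE / PSNR agree with direct-sum implementations to 1e-10."""
        g = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        p = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        rep = imqual.similarity_metrics(g, p)
        gf, pf = g.astype(float).ravel(), p.astype(float).ravel()
        pcc_bf = (((gf - gf.mean()) * (pf - pf.mean())).sum()
                  / np.sqrt(((gf - gf.mean()) ** 2).sum() * ((pf - pf.mean()) ** 2).sum()))
        mae_bf = np.abs(gf - pf).mean()
        psnr_bf = 10 * np.log10(255 ** 2 / ((gf - pf) ** 2).mean())
        assert abs(rep.pcc - pcc_bf) < 1e-10
        assert abs(rep.mae - mae_bf) < 1e-10
        assert abs(rep.psnr_db - psnr_bf) < 1e-10

    def test_ssim_matches_single_window_brute_force(self, rng):
        """On an 11x11 image the windowed SSIM reduces to one hand-computed
        Gaussian-weighted window."""
        a = rng.integers(0, 256, (11, 11)).astype(np.uint8)
        b = rng.integers(0, 256, (11, 11)).astype(np.uint8)
        rep = imqual.similarity_metrics(a, b)
        delta = np.zeros((11, 11))
        delta[5, 5] = 1.0
        trunc = ((11 - 1) / 2 - 0.5) / 1.5
        k = ndimage.gaussian_filter(delta, 1.5, truncate=trunc)
        k /= k.sum()
        af, bf = a.astype(float), b.astype(float)
        mu_a, mu_b = (k * af).sum(), (k * bf).sum()
        va = (k * af * af).sum() - mu_a ** 2
        vb = (k * bf * bf).sum() - mu_b ** 2
        cov = (k * af * bf).sum() - mu_a * mu_b
        C1, C2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
        ssim_bf = (((2 * mu_a * mu_b + C1) * (2 * cov + C2))
                   / ((mu_a ** 2 + mu_b ** 2 + C1) * (va + vb + C2)))
        assert abs(rep.ssim - ssim_bf) < 1e-10

    def test_pcc_invariant_to_affine_transform_of_one_argument(self, rng):
        g = rng.integers(0, 200, (32, 32)).astype(float)
        p = rng.integers(0, 200, (32, 32)).astype(float)
        assert imqual.pearson(g, p) == pytest.approx(
            imqual.pearson(g, 2.5 * p + 17.0), abs=1e-12)

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(5):
            g = rng.integers(0, 256, (40, 40)).astype(np.uint8)
            p = rng.integers(0, 256, (40, 40)).astype(np.uint8)
            rep = imqual.similarity_metrics(g, p)
            assert -1 <= rep.pcc <= 1
            assert 0 <= rep.ms_ssim <= 1
            assert rep.mae >= 0


class TestDecorrelationResolution:
    def test_white_noise_resolves_to_two_pixels(self, rng):
        est = imqual.decorrelation_resolution(rng.standard_normal((256, 256)), 10.0)
        assert est.cutoff_frequency > 0.9
        assert est.resolution_nm == pytest.approx(20.0, rel=0.12)

    def test_resolution_degrades_monotonically_with_blur(self, rng):
        base = np.zeros((256, 256))
        idx = rng.integers(20, 236, (400, 2))
        base[idx[:, 0], idx[:, 1]] = 1.0
        res = [imqual.decorrelation_resolution(
            ndimage.gaussian_filter(base, s), 10.0).resolution_nm
            for s in (1, 2, 4)]
        assert res[0] < res[1] < res[2]

    def test_grid_independence_across_oversampling(self, rng):
        """The same localizations rendered at oversampling 8 vs 16 give
        consistent resolution estimates (within 15%)."""
        from htpaint.core import LocalizationTable
        from htpaint.locfit import render_locs

        n = 3000
        xy = rng.uniform(2, 30, (n, 2)) // np.array([1, 1])
        # structured positions: points along two lines with 20 nm jitter
        t = rng.uniform(2, 30, n)
        line = rng.integers(0, 2, n)
        x = np.where(line, t, 8 + 0.1 * t)
        y = np.where(line, 12 + 0.05 * t, t)
        x += rng.normal(0, 0.13, n)
        y += rng.normal(0, 0.13, n)
        table = LocalizationTable.from_arrays(frame=np.zeros(n, int), x=x, y=y)
        res = {}
        for u in (8, 16):
            img = render_locs(table, oversampling=u, blur_sigma_px=u / 8,
                              shape=(32, 32))
            res[u] = imqual.decorrelation_resolution(img, 157.0 / u).resolution_nm
        assert abs(res[8] - res[16]) / res[16] < 0.15

    def test_unresolved_image_reports_sentinel(self):
        with pytest.warns(UserWarning, match="unresolved"):
            est = imqual.decorrelation_resolution(np.zeros((64, 64)), 10.0)
        assert not est.resolved
        assert np.isinf(est.resolution_nm)


class TestFrameSweep:
    def test_quality_grows_with_frame_count(self):
        """More prediction frames give equal-or-better correlation with the
        ground truth; the full-count row uses every map."""
        from htpaint import deepdense, imqual
        from htpaint.core import LocalizationTable
        from htpaint.locfit import render_locs

        rng = np.random.default_rng(5)
        # fixed underlying structure: points on a line grid
        pts = np.stack([np.linspace(2, 30, 60),
                        8 + 2 * np.sin(np.linspace(0, 6, 60))], axis=1)
        maps = []
        for f in range(40):
            m = np.zeros((256, 256), np.float32)
            sel = rng.choice(len(pts), size=12, replace=False)
            xy = pts[sel] + rng.normal(0, 0.05, (12, 2))
            cols = np.clip((xy[:, 0] * 8).astype(int), 0, 255)
            rows = np.clip((xy[:, 1] * 8).astype(int), 0, 255)
            m[rows, cols] = rng.uniform(1.0, 2.0, 12).astype(np.float32)
            m = ndimage.gaussian_filter(m, 1.0)
            maps.append(deepdense.PredictionMap(data=m, upsampling=8, frame_index=f))
        gt_tab = LocalizationTable.from_arrays(
            frame=np.zeros(len(pts), int), x=pts[:, 0], y=pts[:, 1])
        gt_render = render_locs(gt_tab, oversampling=8, blur_sigma_px=1.0,
                                shape=(32, 32))
        out = imqual.frame_sweep(maps, gt_render, [5, 20, 40],
                                 rendered_pixel_nm=157 / 8,
                                 threshold_reference=12 * 40,
                                 render_shape=(32, 32), oversampling=8)
        assert list(out["n_frames"]) == [5, 20, 40]
        assert out["pcc"].iloc[-1] >= out["pcc"].iloc[0]
        assert (out["n_locs"].to_numpy() > 0).all()
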