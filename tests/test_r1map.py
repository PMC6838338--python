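"""R1 mapping chain: registration, averaging, smoothing, normalization, fit."""

import numpy as np
import pytest
from scipy import signal as scipy_signal

from questmri import r1map as r1
from questmri.synthetic import (AcquisitionProtocol, CoilFieldSpec, NoiseSpec,
                                cochlea_phantom, generate_series, signal_model,
                                two_region_phantom)

NORMALIZED_TRS = np.array([0.25, 0.35, 0.5, 1.0, 1.9, 2.7, 3.5])


def grid_search_oracle(y, trs, c_lo=0.01, c_hi=5.0, step=1e-4):
    """Profile the SSE over a dense c grid, solving (a, b) linearly at each c."""
    cgrid = np.arange(c_lo, c_hi + step / 2, step)
    E = np.exp(-np.outer(cgrid, trs))
    n = trs.size
    s12 = E.sum(axis=1)
    s22 = (E * E).sum(axis=1)
    b1 = y.sum()
    b2 = E @ y
    det = n * s22 - s12 ** 2
    a = (s22 * b1 - s12 * b2) / det
    b = (n * b2 - s12 * b1) / det
    sse = (y * y).sum() - (a * b1 + b * b2)
    return float(cgrid[np.argmin(sse)])


@pytest.fixture(scope="module")
def noisy_normalized():
    """Normalized series from a noisy cochlea phantom (fixed seed)."""
    phantom = cochlea_phantom((32, 32))
    protocol = AcquisitionProtocol(matrix=(32, 32))
    series, truth = generate_series(
        phantom, protocol, CoilFieldSpec("low-order-polynomial", (0.8, 1.2)),
        NoiseSpec(sigma=0.03, jitter_sigma=0.0, seed=1))
    avg = r1.average_by_tr(series)
    norm = r1.normalize(avg, r1.smooth_reference(avg))
    return norm, truth


class TestRegistration:
    def test_zero_shift_is_identity(self, noiseless_setup):
        phantom, protocol, coil, noise = noiseless_setup
        series, _ = generate_series(phantom, protocol, coil, noise)
        reg, info = r1.register_rigid(series, "within_tr")
        assert np.array_equal(reg.images, series.images)
        assert np.all(info["shifts"] == 0)

    def test_known_shift_recovered(self, noiseless_setup):
        phantom, protocol, coil, _ = noiseless_setup
        noise = NoiseSpec(model="none", sigma=0.0, jitter_sigma=0.8, seed=3)
        series, truth = generate_series(phantom, protocol, coil, noise)
        _, info = r1.register_rigid(series, "within_tr")
        for tr in series.distinct_trs:
            idx = np.flatnonzero(series.tr == tr)
            ref = idx[np.argsort(series.repeat_index[idx])][0]
            for i in idx:
                if i == ref:
                    continue
                expected = truth.shifts[ref] - truth.shifts[i]
                assert np.max(np.abs(info["shifts"][i] - expected)) < 0.1

    def test_single_image_groups_identity(self):
        rng = np.random.default_rng(0)
        images = rng.random((4, 16, 16))
        series = r1.ImageSeries(images, [0.2, 0.5, 1.0, 2.0], [0, 0, 0, 0])
        reg, info = r1.register_rigid(series, "within_tr")
        assert np.array_equal(reg.images, images)

    def test_degenerate_images_flagged(self):
        images = np.ones((4, 8, 8))
        series = r1.ImageSeries(images, [0.2, 0.2, 0.5, 1.0], [0, 1, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            _, info = r1.register_rigid(series, "within_tr")
        assert info["degenerate"].any()


class TestAveraging:
    def test_default_series_averages_to_8(self, noiseless_setup):
        phantom, protocol, coil, noise = noiseless_setup
        series, _ = generate_series(phantom, protocol, coil, noise)
        avg = r1.average_by_tr(series)
        assert len(avg) == 8
        assert np.all(np.diff(avg.tr) > 0)

    def test_identical_repeats_average_to_repeat(self):
        img = np.random.default_rng(1).random((12, 12))
        series = r1.ImageSeries(
            np.stack([img] * 3 + [img * 2, img * 3, img * 4]),
            [0.2, 0.2, 0.2, 0.5, 1.0, 2.0], [0, 1, 2, 0, 0, 0])
        avg = r1.average_by_tr(series)
        assert np.allclose(avg.images[0], img)

    def test_noise_reduction_scales_with_sqrt_n(self):
        # averaging n repeats of N(0, sigma) noise gives sd sigma / sqrt(n)
        rng = np.random.default_rng(2)
        sigma, n_rep = 1.0, 6
        base = np.zeros((120, 120))
        images = [base + rng.normal(0, sigma, base.shape)
                  for _ in range(n_rep)]
        images += [base + s for s in (1.0, 2.0, 3.0)]
        series = r1.ImageSeries(np.stack(images),
                                [0.15] * n_rep + [0.5, 1.0, 2.0],
                                list(range(n_rep)) + [0, 0, 0])
        avg = r1.average_by_tr(series)
        observed = avg.images[0].std()
        expected = sigma / np.sqrt(n_rep)
        assert observed == pytest.approx(expected, rel=0.05)

    def test_too_few_trs_rejected(self):
        series = r1.ImageSeries(np.random.default_rng(0).random((3, 8, 8)),
                                [0.2, 0.5, 1.0], [0, 0, 0])
        with pytest.raises(ValueError, match="at least 4"):
            r1.average_by_tr(series)


class TestSmoothing:
    def _avg(self, image):
        stack = np.stack([image, image])
        return r1.AveragedSeries(stack, [0.15, 1.0])

    def test_constant_image_unchanged(self):
        out = r1.smooth_reference(self._avg(np.full((16, 16), 3.7)))
        assert np.allclose(out, 3.7)

    def test_impulse_support_and_mass(self):
        impulse = np.zeros((21, 21))
        impulse[10, 10] = 1.0
        out = r1.smooth_reference(self._avg(impulse))
        nz_rows, nz_cols = np.nonzero(out > 1e-15)
        assert nz_rows.max() - nz_rows.min() == 6     # 7x7 support
        assert nz_cols.max() - nz_cols.min() == 6
        assert out.sum() == pytest.approx(1.0)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(3)
        image = rng.random((20, 20))
        out = r1.smooth_reference(self._avg(image))
        oracle = image.copy()
        for _ in range(3):
            oracle = scipy_signal.convolve2d(oracle, r1.GAUSSIAN_3X3,
                                             mode="same", boundary="symm")
        assert np.allclose(out, oracle)

    def test_smooth_field_nearly_unchanged(self):
        # a slowly varying coil profile passes through almost untouched
        field = CoilFieldSpec("gaussian-bump", (0.8, 1.2), 60.0).render(
            (48, 48), np.random.default_rng(0))
        out = r1.smooth_reference(self._avg(field))
        err = np.abs(out - field) / field
        assert np.max(err[3:-3, 3:-3]) < 0.01   # inside the 7x7 support

    def test_missing_reference_tr_names_available(self):
        avg = r1.AveragedSeries(np.ones((2, 8, 8)), [0.5, 1.0])
        with pytest.raises(ValueError, match="0.5"):
            r1.smooth_reference(avg)


class TestNormalization:
    def test_default_yields_seven_images(self, noiseless_setup):
        phantom, protocol, coil, noise = noiseless_setup
        series, _ = generate_series(phantom, protocol, coil, noise)
        avg = r1.average_by_tr(series)
        norm = r1.normalize(avg, r1.smooth_reference(avg))
        assert len(norm) == 7
        assert 0.15 not in norm.tr

    def test_uniform_field_ratio_algebra(self, noiseless_setup):
        # ratio = (1 - exp(-TR R1)) / (1 - exp(-0.15 R1)) for uniform coil
        phantom, protocol, coil, noise = noiseless_setup
        series, truth = generate_series(phantom, protocol, coil, noise)
        avg = r1.average_by_tr(series)
        norm = r1.normalize(avg, r1.smooth_reference(avg))
        # restrict to pixels whose 7x7 smoothing support is single-region
        from scipy import ndimage
        core = np.zeros(phantom.shape, dtype=bool)
        for cls in (1, 2):
            region = phantom.label_map == cls
            core |= ndimage.distance_transform_edt(region) > 4.5
        for img, tr in zip(norm.images, norm.tr):
            c = truth.r1_map[core]
            expected = (1 - np.exp(-tr * c)) / (1 - np.exp(-0.15 * c))
            assert np.allclose(img[core], expected, rtol=1e-10)

    def test_field_cancels_in_normalized_series(self, small_protocol):
        phantom = two_region_phantom((48, 48))
        noise = NoiseSpec(model="none", sigma=0.0, jitter_sigma=0.0)
        flat, _ = generate_series(phantom, small_protocol, CoilFieldSpec(),
                                  noise)
        bump, _ = generate_series(
            phantom, small_protocol,
            CoilFieldSpec("gaussian-bump", (0.8, 1.2), 30.0), noise)
        norms = []
        for series in (flat, bump):
            avg = r1.average_by_tr(series)
            norms.append(r1.normalize(avg, r1.smooth_reference(avg)))
        from scipy import ndimage
        core = np.zeros(phantom.shape, dtype=bool)
        for cls in (1, 2):
            region = phantom.label_map == cls
            core |= ndimage.distance_transform_edt(region) > 4.5
        sel = norms[0].mask & core & (norms[0].images[0] > 0)
        ratio = norms[1].images[:, sel] / norms[0].images[:, sel]
        assert np.max(np.abs(ratio - 1)) < 0.01

    def test_all_masked_rejected(self):
        avg = r1.AveragedSeries(np.ones((5, 8, 8)),
                                [0.15, 0.5, 1.0, 2.0, 3.5])
        with pytest.raises(ValueError, match="mask"):
            r1.normalize(avg, np.zeros((8, 8)))


class TestPixelFit:
    def test_exact_recovery_from_noiseless_model(self):
        y = 1.5 - 1.5 * np.exp(-0.3 * NORMALIZED_TRS)
        a, b, c, rms, ok = r1.fit_t1_pixel(y, NORMALIZED_TRS)
        assert ok
        assert a == pytest.approx(1.5, rel=1e-6)
        assert b == pytest.approx(-1.5, rel=1e-6)
        assert c == pytest.approx(0.3, rel=1e-6)

    def test_exact_recovery_low_rate(self):
        # slow rate typical of cochlear tissue at 7 T
        y = 2.0 - 2.0 * np.exp(-0.236 * NORMALIZED_TRS)
        a, b, c, rms, ok = r1.fit_t1_pixel(y, NORMALIZED_TRS)
        assert ok and c == pytest.approx(0.236, abs=1e-6)

    def test_matches_grid_search_oracle_on_noisy_pixels(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            c_true = rng.uniform(0.1, 1.5)
            a_true = rng.uniform(0.5, 3.0)
            y = a_true * (1 - np.exp(-c_true * NORMALIZED_TRS))
            y = y + rng.normal(0, 0.02, y.shape)
            _, _, c, _, ok = r1.fit_t1_pixel(y, NORMALIZED_TRS)
            assert ok
            assert abs(c - grid_search_oracle(y, NORMALIZED_TRS)) < 1e-3

    def test_nonfinite_input_flags_nonconverged(self):
        y = np.array([1.0, np.nan, 1.2, 1.3, 1.4, 1.5, 1.6])
        a, b, c, rms, ok = r1.fit_t1_pixel(y, NORMALIZED_TRS)
        assert not ok and np.isnan(c)

    def test_too_few_trs_rejected(self):
        with pytest.raises(ValueError):
            r1.fit_t1_pixel([1, 2, 3], [0.1, 0.2, 0.3])


class TestMapFit:
    def test_two_region_noiseless_exact(self, noiseless_setup):
        phantom, protocol, coil, noise = noiseless_setup
        series, truth = generate_series(phantom, protocol, coil, noise)
        r1map = r1.compute_r1_map(series, register=False)
        for roi, c_true in (("left", 0.2), ("right", 0.4)):
            sel = phantom.roi_masks[roi] & r1map.converged
            assert np.median(np.abs(r1map.c[sel] - c_true)) < 1e-6

    def test_engines_agree(self, noisy_normalized):
        norm, truth = noisy_normalized
        fast = r1.fit_t1_map(norm, engine="vectorized")
        slow = r1.fit_t1_map(norm, engine="per_pixel")
        tissue = truth.s0_map > 0
        both = fast.converged & slow.converged & tissue
        assert both.sum() > 300
        d = np.abs(fast.c[both] - slow.c[both])
        assert np.median(d) < 1e-6
        assert np.quantile(d, 0.99) < 1e-3

    def test_order_invariance(self, noiseless_setup):
        phantom, protocol, coil, noise = noiseless_setup
        series, _ = generate_series(phantom, protocol, coil, noise)
        perm = np.random.default_rng(5).permutation(len(series))
        shuffled = r1.ImageSeries(series.images[perm], series.tr[perm],
                                  series.repeat_index[perm])
        m1 = r1.compute_r1_map(series, register=False)
        m2 = r1.compute_r1_map(shuffled, register=False)
        assert np.array_equal(m1.converged, m2.converged)
        assert np.allclose(m1.c[m1.converged], m2.c[m2.converged],
                           equal_nan=True)

    def test_empty_mask_rejected(self):
        norm = r1.NormalizedSeries(np.ones((7, 8, 8)), NORMALIZED_TRS,
                                   np.zeros((8, 8), dtype=bool), 0.15)
        with pytest.raises(ValueError):
            r1.fit_t1_map(norm)


class TestRoiMean:
    def _map(self, c):
        c = np.asarray(c, dtype=float)
        conv = np.isfinite(c)
        return r1.R1Map(np.zeros_like(c), np.zeros_like(c), c, conv,
                        np.zeros_like(c))

    def test_constant_map(self):
        m = self._map(np.full((4, 4), 0.3))
        mean, n, sd = r1.roi_mean_r1(m, r1.RoiMask("all", np.ones((4, 4),
                                                                  bool)))
        assert (mean, n, sd) == (pytest.approx(0.3), 16, 0.0)

    def test_two_pixel_mean(self):
        c = np.full((2, 2), np.nan)
        c[0, 0], c[0, 1] = 0.2, 0.4
        mask = np.zeros((2, 2), bool)
        mask[0] = True
        mean, n, sd = r1.roi_mean_r1(self._map(c), r1.RoiMask("pair", mask))
        assert mean == pytest.approx(0.3) and n == 2

    def test_empty_overlap_rejected(self):
        c = np.full((2, 2), np.nan)
        c[0, 0] = 0.2
        mask = np.zeros((2, 2), bool)
        mask[1, 1] = True
        with pytest.raises(ValueError, match="no converged"):
            r1.roi_mean_r1(self._map(c), r1.RoiMask("off", mask))

    def test_subject_roi_mean_near_truth(self, small_protocol):
        phantom = cochlea_phantom((48, 48), cochlea_r1=(0.24, 0.30))
        series, truth = generate_series(
            phantom, small_protocol, CoilFieldSpec(),
            NoiseSpec(sigma=0.03, jitter_sigma=0.0, seed=6))
        r1map = r1.compute_r1_map(series, register=False)
        roi = r1.RoiMask("right-cochlea", phantom.roi_masks["right-cochlea"])
        mean, n, sd = r1.roi_mean_r1(r1map, roi)
        assert abs(mean - 0.30) < 2 * sd / np.sqrt(n) + 0.01


class TestIO:
    def test_series_nifti_roundtrip(self, tmp_path, noiseless_setup):
        phantom, protocol, coil, noise = noiseless_setup
        series, _ = generate_series(phantom, protocol, coil, noise)
        path = tmp_path / "series.nii"
        r1.save_series_nifti(series, path)
        back = r1.load_series_nifti(path)
        assert np.allclose(back.images, series.images, atol=1e-6)
        assert np.array_equal(back.tr, series.tr)

    def test_roi_csv(self, tmp_path):
        import pandas as pd
        pd.DataFrame({"row": [0, 1], "col": [1, 1]}).to_csv(
            tmp_path / "roi.csv", index=False)
        roi = r1.load_roi_mask(tmp_path / "roi.csv", shape=(3, 3))
        assert roi.pixels.sum() == 2 and roi.pixels[0, 1]
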