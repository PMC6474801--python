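"""Segmentation oracles: DoG algebra, Renyi thresholds, components, measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tagbright.segment import (
    DegenerateHistogramError,
    DoGParams,
    ThresholdSpec,
    difference_of_gaussians,
    extract_signal_mask,
    measure_signal_background,
    quantify_image,
    renyi_entropy_threshold,
)
from tagbright.synmicro import NO_NOISE, egg_chamber_config, generate_scene


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def renyi_cut_oracle(p: np.ndarray, alpha: float) -> int:
    """Exhaustive search over every cut, straight from the entropy definition."""
    p = p / p.sum()
    best_t, best_h = None, -np.inf
    for t in range(len(p)):
        pb, pf = p[: t + 1], p[t + 1 :]
        Pb, Pf = pb.sum(), pf.sum()
        if Pb <= 0 or Pf <= 0:
            continue
        if abs(alpha - 1.0) < 1e-9:
            qb, qf = pb[pb > 0] / Pb, pf[pf > 0] / Pf
            h = -(qb * np.log(qb)).sum() - (qf * np.log(qf)).sum()
        else:
            h = (
                np.log(((pb / Pb) ** alpha).sum()) + np.log(((pf / Pf) ** alpha).sum())
            ) / (1.0 - alpha)
        if h > best_h:
            best_h, best_t = h, t
    return best_t


def flood_fill_components(binary: np.ndarray) -> list[set]:
    """8-connected components by explicit BFS flood fill."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    comps = []
    for sy, sx in zip(*np.nonzero(binary)):
        if seen[sy, sx]:
            continue
        comp, queue = set(), [(sy, sx)]
        seen[sy, sx] = True
        while queue:
            y, x = queue.pop()
            comp.add((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < binary.shape[0]
                        and 0 <= nx < binary.shape[1]
                        and binary[ny, nx]
                        and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# difference of Gaussians
# ---------------------------------------------------------------------------


class TestDoG:
    def test_constant_image_cancels_to_zero(self):
        out = difference_of_gaussians(np.full((64, 64), 37.2), DoGParams(4, 1.4))
        assert np.max(np.abs(out)) < 1e-10

    def test_impulse_response_is_kernel_difference(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        params = DoGParams(sigma=3.0, k=1.5)
        out = difference_of_gaussians(img, params)
        yy, xx = np.mgrid[:65, :65]
        r2 = (yy - 32.0) ** 2 + (xx - 32.0) ** 2

        def g(s):
            k = np.exp(-r2 / (2 * s * s))
            return k / k.sum()

        expected = g(3.0) - g(4.5)
        assert np.max(np.abs(out - expected)) < 1e-4

    def test_coarse_sigma_is_k_times_fine(self):
        assert DoGParams(4.0, 1.4).sigma_coarse == pytest.approx(5.6)

    def test_shift_invariance_to_added_constant(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (48, 48))
        a = difference_of_gaussians(img)
        b = difference_of_gaussians(img + 55.0)
        assert np.max(np.abs(a - b)) < 1e-9

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            difference_of_gaussians(np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# Renyi thresholding
# ---------------------------------------------------------------------------


class TestRenyiThreshold:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=4, max_value=32),
        st.sampled_from([0.5, 1.0, 2.0, 3.5]),
    )
    def test_single_alpha_matches_exhaustive_oracle(self, seed, n_bins, alpha):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, n_bins)
        p[p < 0.2] = 0.0  # sprinkle empty bins
        if np.count_nonzero(p) < 2:
            p[:2] = 1.0
        spec = ThresholdSpec(method="renyi_single", alpha=alpha, n_bins=n_bins)
        t_impl = renyi_entropy_threshold(p, spec)
        t_oracle = renyi_cut_oracle(p, alpha)
        if t_impl != t_oracle:
            # differing cuts are only acceptable on a numerical near-tie
            q = p / p.sum()

            def objective(t):
                pb, pf = q[: t + 1], q[t + 1 :]
                Pb, Pf = pb.sum(), pf.sum()
                if abs(alpha - 1.0) < 1e-9:
                    qb, qf = pb[pb > 0] / Pb, pf[pf > 0] / Pf
                    return -(qb * np.log(qb)).sum() - (qf * np.log(qf)).sum()
                return (
                    np.log(((pb / Pb) ** alpha).sum())
                    + np.log(((pf / Pf) ** alpha).sum())
                ) / (1.0 - alpha)

            assert objective(t_impl) == pytest.approx(objective(t_oracle), abs=1e-9)

    def test_bimodal_histogram_separates_populations(self):
        p = np.zeros(256)
        p[10] = 0.5
        p[200] = 0.5
        for method in ("renyi_single", "renyi_combined"):
            t = renyi_entropy_threshold(p, ThresholdSpec(method=method))
            assert 10 <= t < 200

    def test_symmetric_histogram_cut_near_midpoint(self):
        rng = np.random.default_rng(5)
        half = rng.uniform(0.1, 1, 16)
        p = np.concatenate([half, half[::-1]])
        t = renyi_entropy_threshold(p, ThresholdSpec(method="renyi_single", alpha=1.0))
        assert abs(t - 15.5) <= 1.5
        assert t == renyi_cut_oracle(p, 1.0)

    def test_single_populated_bin_is_degenerate(self):
        p = np.zeros(64)
        p[7] = 1.0
        with pytest.raises(DegenerateHistogramError):
            renyi_entropy_threshold(p, ThresholdSpec())


# ---------------------------------------------------------------------------
# mask extraction
# ---------------------------------------------------------------------------


class TestExtractMask:
    def test_minimum_area_is_inclusive(self):
        img = np.zeros((80, 80))
        img[1:21, 1:26] = 1.0  # 500 px
        img[40:60, 1:26] = 1.0
        img[59, 25] = 0.0  # 499 px
        res = extract_signal_mask(img, 0.5, min_area_px=500, pixel_size_nm=100)
        assert len(res.regions) == 1
        assert res.regions[0][1] == 500

    def test_500px_at_180nm_pixel_is_16_24_um2(self):
        img = np.zeros((64, 64))
        img[10:30, 10:35] = 1.0  # 500 px
        res = extract_signal_mask(img, 0.5, 500, pixel_size_nm=180.2)
        assert res.regions[0][2] == pytest.approx(16.24, abs=0.01)

    def test_components_match_flood_fill_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            binary = rng.uniform(0, 1, (40, 40)) > 0.7
            res = extract_signal_mask(binary.astype(float), 0.5, 1, 100.0)
            oracle = flood_fill_components(binary)
            assert len(res.regions) == len(oracle)
            assert sorted(a for _, a, _ in res.regions) == sorted(
                len(c) for c in oracle
            )

    def test_area_conservation(self):
        rng = np.random.default_rng(23)
        binary = rng.uniform(0, 1, (60, 60)) > 0.6
        res = extract_signal_mask(binary.astype(float), 0.5, 5, 100.0)
        assert sum(a for _, a, _ in res.regions) == int(res.mask.sum())

    def test_empty_is_flag_not_exception(self):
        res = extract_signal_mask(np.zeros((64, 64)), 0.5, 10, 100.0)
        assert res.empty and not res.mask.any()


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


class TestMeasurement:
    def test_piecewise_constant_arithmetic(self):
        img = np.full((20, 20), 4.0)
        mask = np.zeros((20, 20), bool)
        mask[:10] = True
        img[mask] = 10.0
        assert measure_signal_background(img, mask) == (10.0, 4.0, 6.0)

    def test_half_gradient_means_are_analytic(self):
        img = np.tile(np.arange(100.0), (10, 1))
        mask = np.zeros_like(img, bool)
        mask[:, :50] = True
        s, b, c = measure_signal_background(img, mask)
        assert s == pytest.approx(np.mean(np.arange(50)))
        assert b == pytest.approx(np.mean(np.arange(50, 100)))
        assert c == pytest.approx(s - b)

    def test_constant_image_gives_zero_corrected(self):
        img = np.full((16, 16), 3.3)
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True
        assert measure_signal_background(img, mask)[2] == 0.0

    @pytest.mark.parametrize("mask_value", [False, True])
    def test_empty_and_full_masks_rejected(self, mask_value):
        img = np.ones((8, 8))
        with pytest.raises(ValueError):
            measure_signal_background(img, np.full((8, 8), mask_value))


# ---------------------------------------------------------------------------
# end-to-end quantifier
# ---------------------------------------------------------------------------


class TestQuantifyImage:
    def test_uniform_image_reports_empty(self):
        res = quantify_image(np.full((128, 128), 9.0))
        assert res.empty

    def test_scaling_image_scales_corrected_signal(self):
        cfg = egg_chamber_config(seed=21, noise=NO_NOISE)
        stack, _ = generate_scene(cfg)
        img = stack.frame(0, 0)
        r1 = quantify_image(img, pixel_size_nm=cfg.pixel_size_nm)
        r3 = quantify_image(3.0 * img, pixel_size_nm=cfg.pixel_size_nm)
        np.testing.assert_array_equal(r1.mask, r3.mask)
        assert r3.corrected_signal == pytest.approx(3 * r1.corrected_signal, rel=1e-9)

    def test_offset_leaves_mask_unchanged(self):
        cfg = egg_chamber_config(seed=22, noise=NO_NOISE)
        stack, _ = generate_scene(cfg)
        img = stack.frame(0, 0)
        r1 = quantify_image(img, pixel_size_nm=cfg.pixel_size_nm)
        r2 = quantify_image(img + 40.0, pixel_size_nm=cfg.pixel_size_nm)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r2.corrected_signal == pytest.approx(r1.corrected_signal, rel=1e-9)

    def test_band_quantification_tracks_generator_truth(self):
        cfg = egg_chamber_config(seed=23, noise=NO_NOISE, base_intensity=200.0)
        stack, truth = generate_scene(cfg)
        res = quantify_image(stack.frame(0, 0), pixel_size_nm=cfg.pixel_size_nm)
        assert not res.empty
        # the mapped mask covers the band (plus a PSF/DoG skirt), so the
        # corrected mean lies between half the plateau level and the plateau
        assert 0.5 * 200.0 < res.corrected_signal <= 200.0
        overlap = (res.mask & truth.structure_mask).sum()
        assert overlap / truth.structure_mask.sum() > 0.9
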