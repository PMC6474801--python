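"""Per-cell analyses: detection, co-labeling, efficiency, fits, statistics."""

import numpy as np
import pytest

from tagbright.cellquant import (
    EfficiencyResult,
    background_stats,
    classify_colabeled,
    detect_reporter_cells,
    fit_intensity_distribution,
    fold_ratio,
    labeling_efficiency,
    measure_cells,
    significance_stars,
    unpaired_t_test,
)
from tagbright.synmicro import NO_NOISE, generate_scene, hela_field_config


@pytest.fixture(scope="module")
def noiseless_field():
    cfg = hela_field_config(
        seed=9, noise=NO_NOISE, n_cells=24, transfected_fraction=0.5
    )
    stack, truth = generate_scene(cfg)
    return stack, truth


class TestDetection:
    def test_detects_every_transfected_cell(self, noiseless_field):
        stack, truth = noiseless_field
        cells = detect_reporter_cells(stack.frame(0, 0))
        assert len(cells) == len(truth.objects)

    def test_blank_channel_yields_empty_list(self):
        assert detect_reporter_cells(np.zeros((128, 128))) == []

    def test_detected_centroids_match_truth(self, noiseless_field):
        stack, truth = noiseless_field
        cells = detect_reporter_cells(stack.frame(0, 0))
        found = np.array(sorted(c.centroid for c in cells))
        expected = np.array(
            sorted(zip(truth.objects.centroid_y, truth.objects.centroid_x))
        )
        assert np.max(np.abs(found - expected)) < 3.0


class TestClassification:
    def test_zero_corrected_marker_is_not_colabeled(self, noiseless_field):
        stack, _ = noiseless_field
        cells = detect_reporter_cells(stack.frame(0, 0))
        flat = np.full(stack.frame_shape, 7.0)
        colabeled, _, corrected = classify_colabeled(cells[0], flat, (7.0, 1.0))
        assert corrected == pytest.approx(0.0)
        assert not colabeled

    def test_false_positive_rate_at_3_sigma(self):
        # marker identical to background noise: <= 1% of cells may classify
        # as co-labeled at k = 3
        cfg = hela_field_config(
            seed=31, n_cells=30, transfected_fraction=1.0,
            labeled_fraction_above_limit=0.0,
        )
        n_false = n_total = 0
        for i in range(8):
            stack, _ = generate_scene(
                hela_field_config(
                    seed=31 + i, n_cells=30, transfected_fraction=1.0,
                    labeled_fraction_above_limit=0.0,
                )
            )
            records = measure_cells(stack.frame(0, 0), stack.frame(0, 1))
            n_total += len(records)
            n_false += sum(r.colabeled for r in records)
        assert n_total > 150
        assert n_false / n_total <= 0.01

    def test_classification_invariant_to_intensity_rescaling(self):
        cfg = hela_field_config(seed=33, n_cells=20, labeled_fraction_above_limit=0.6)
        stack, _ = generate_scene(cfg)
        rep, mark = stack.frame(0, 0), stack.frame(0, 1)
        flags = [r.colabeled for r in measure_cells(rep, mark)]
        flags_scaled = [r.colabeled for r in measure_cells(rep, mark * 5.0)]
        assert flags == flags_scaled


class TestEfficiency:
    def test_matches_hand_arithmetic(self):
        eff = EfficiencyResult(n_reporter_positive=740, n_colabeled=688)
        assert eff.efficiency_pct == pytest.approx(93.0, abs=0.05)

    @pytest.mark.parametrize("n_co,expected", [(0, 0.0), (50, 100.0)])
    def test_boundary_values(self, n_co, expected):
        records = [
            type("R", (), {"colabeled": i < n_co})() for i in range(50)
        ]
        assert labeling_efficiency(records).efficiency_pct == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            labeling_efficiency([])


class TestDistributionFit:
    def test_recovers_gaussian_parameters(self):
        rng = np.random.default_rng(8)
        fit = fit_intensity_distribution(rng.normal(100, 15, 500))
        assert fit.mu == pytest.approx(100, abs=2)
        assert fit.sigma == pytest.approx(15, abs=2)
        assert fit.adequate

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_intensity_distribution([5.0] * 20)

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_intensity_distribution([1.0, 2.0])

    def test_two_population_mixture_flagged(self):
        rng = np.random.default_rng(9)
        mixture = np.concatenate(
            [rng.normal(50, 5, 300), rng.normal(200, 5, 300)]
        )
        assert not fit_intensity_distribution(mixture).adequate


class TestFoldRatio:
    def test_identical_groups(self):
        rng = np.random.default_rng(10)
        x = rng.normal(100, 10, 50)
        fr = fold_ratio(x, x, seed=0)
        assert fr.ratio == pytest.approx(1.0)
        assert fr.ci_low <= 1.0 <= fr.ci_high

    def test_simple_arithmetic(self):
        assert fold_ratio([2, 4], [1, 1], seed=0).ratio == pytest.approx(3.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(80, 5, 40), rng.normal(30, 5, 40)
        assert fold_ratio(a, b, seed=1).ratio * fold_ratio(b, a, seed=1).ratio == (
            pytest.approx(1.0)
        )

    def test_non_positive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_ratio([1.0, 2.0], [-1.0, 0.5])


class TestTTest:
    def test_identical_samples_give_p_one(self):
        res = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_matches_pooled_variance_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        res = unpaired_t_test(a, b)
        # hand-computed pooled t: sp2 = 1, t = -1/sqrt(2/3), df = 4
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert res.t_stat == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(4)
        assert res.p_two_tailed == pytest.approx(p_hand, rel=1e-12)

    def test_welch_equals_student_for_balanced_equal_variance(self):
        rng = np.random.default_rng(12)
        a = rng.normal(10, 2, 30)
        b = a + 1.0  # same variance, same n
        s = unpaired_t_test(a, b, welch=False)
        w = unpaired_t_test(a, b, welch=True)
        assert s.t_stat == pytest.approx(w.t_stat, abs=1e-9)
        assert s.p_two_tailed == pytest.approx(w.p_two_tailed, abs=1e-9)

    def test_widely_separated_groups_get_four_stars(self):
        rng = np.random.default_rng(13)
        res = unpaired_t_test(rng.normal(0, 1, 20), rng.normal(10, 1, 20))
        assert res.stars == "****"

    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "ns"), (0.04, "*"), (0.005, "**"), (5e-4, "***"), (5e-5, "****")],
    )
    def test_star_map(self, p, stars):
        assert significance_stars(p) == stars


def test_background_stats_excludes_cells(noiseless_field):
    stack, truth = noiseless_field
    cells = detect_reporter_cells(stack.frame(0, 0))
    mean, sd = background_stats(stack.frame(0, 1), cells)
    # background of the noiseless marker channel is (almost) exactly zero
    assert mean == pytest.approx(0.0, abs=0.5)
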