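"""ELISA calibration, cutoffs, positivity, correlations, group tests."""

import math

import numpy as np
import pandas as pd
import pytest

from pepzone.errors import (
    ConstantInput,
    DegenerateTable,
    MissingAssay,
    NoFeasibleSplit,
    TooFewReference,
    UncalibratedAssay,
)
from pepzone.serology import (
    Calibration,
    CutoffSet,
    classify_positivity,
    group_compare,
    hinkle_label,
    od_to_units,
    pearson_ci,
    percentile_cutoff,
    split_correlation,
)
from pepzone.synth import ElisaMixtureSpec, gen_elisa


class TestCalibration:
    def test_linear_midpoint(self):
        cal = Calibration(points=((0.05, 0.0), (1.05, 100.0)))
        assert od_to_units(0.55, cal) == pytest.approx(50.0)

    def test_blank_maps_to_zero(self):
        cal = Calibration(points=((0.05, 0.0), (1.05, 100.0)))
        assert od_to_units(0.05, cal) == pytest.approx(0.0)
        assert od_to_units(0.01, cal) == 0.0  # clamped below blank

    def test_three_point_collinear_equals_two_point(self):
        two = Calibration(points=((0.1, 0.0), (1.1, 100.0)))
        three = Calibration(points=((0.1, 0.0), (0.6, 50.0), (1.1, 100.0)))
        for od in (0.1, 0.35, 0.8, 1.1):
            assert od_to_units(od, three) == pytest.approx(od_to_units(od, two))

    def test_single_point_raises(self):
        with pytest.raises(UncalibratedAssay):
            Calibration(points=((0.5, 50.0),))


class TestPercentileCutoff:
    def test_constant_vector(self):
        assert percentile_cutoff([7.0] * 30) == pytest.approx(7.0)

    def test_interpolated_order_statistics(self):
        assert percentile_cutoff(list(range(1, 101)), q=0.99) == pytest.approx(99.01)

    def test_values_below_cutoff_never_push_above_max(self):
        values = list(np.random.default_rng(0).normal(10, 2, 50))
        assert percentile_cutoff(values) <= max(values)

    def test_too_few_raises(self):
        with pytest.raises(TooFewReference):
            percentile_cutoff([1.0] * 10)


class TestClassifyPositivity:
    def test_strict_boundary(self):
        panel = pd.DataFrame({"anti_b2gp1_iga": [20.0, 20.01]})
        flags = classify_positivity(panel)
        assert flags["anti_b2gp1_iga"].tolist() == [False, True]

    def test_domain_cutoffs(self):
        panel = pd.DataFrame(
            {"anti_d1_iga": [23.9, 23.8], "anti_d45_iga": [22.1, 22.0]}
        )
        flags = classify_positivity(panel)
        assert flags["anti_d1_iga"].tolist() == [True, False]
        assert flags["anti_d45_iga"].tolist() == [True, False]

    def test_all_zero_panel_negative(self):
        panel = pd.DataFrame({"anti_b2gp1_iga": [0.0] * 5})
        assert not classify_positivity(panel).any().any()

    def test_raising_cutoff_is_monotone(self):
        rng = np.random.default_rng(2)
        panel = pd.DataFrame({"anti_b2gp1_iga": rng.uniform(0, 60, 50)})
        low = classify_positivity(panel, CutoffSet({"anti_b2gp1_iga": 20.0}))
        high = classify_positivity(panel, CutoffSet({"anti_b2gp1_iga": 30.0}))
        assert (high.values <= low.values).all()

    def test_unknown_assay_raises(self):
        with pytest.raises(MissingAssay):
            classify_positivity(pd.DataFrame({"mystery": [1.0]}))


class TestPearsonCI:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.label == "very high"

    def test_independent_large_n(self):
        rng = np.random.default_rng(9)
        res = pearson_ci(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(res.r) < 0.08

    def test_fisher_z_interval_closed_form(self):
        # construct a sample with r exactly 0.5 at n = 20
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        e = rng.normal(size=20)
        e = e - e.mean() - ((e - e.mean()) @ (x - x.mean())) / (
            (x - x.mean()) @ (x - x.mean())
        ) * (x - x.mean())
        r0 = 0.5
        y = r0 * (x - x.mean()) / x.std() + math.sqrt(1 - r0**2) * e / e.std()
        res = pearson_ci(x, y)
        assert res.r == pytest.approx(0.5)
        z, half = math.atanh(0.5), 1.959963984540054 / math.sqrt(17)
        assert res.ci_low == pytest.approx(math.tanh(z - half))
        assert res.ci_high == pytest.approx(math.tanh(z + half))
        assert res.ci_low < res.r < res.ci_high

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = pearson_ci(x, y)
        b = pearson_ci(3.2 * x - 7, 0.5 * y + 100)
        assert a.r == pytest.approx(b.r)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_constant_input_raises(self):
        with pytest.raises(ConstantInput):
            pearson_ci([1.0] * 10, list(range(10)))

    def test_hinkle_labels(self):
        assert hinkle_label(-0.95) == "very high"
        assert hinkle_label(0.6) == "moderate"
        assert hinkle_label(0.1) == "negligible"


class TestSplitCorrelation:
    def test_two_regime_mixture_recovery(self):
        panel, truth = gen_elisa(ElisaMixtureSpec(seed=0))
        x = panel["anti_b2gp1_iga"].to_numpy()
        y = panel["anti_d45_iga"].to_numpy()
        res = split_correlation(x, y)
        # recovered high-regime r matches the realized within-group r
        realized = pearson_ci(x[truth["correlated"]], y[truth["correlated"]]).r
        assert res.corr_a.r == pytest.approx(realized, abs=0.1)
        # the two regimes are clearly separated (strong vs practically null)
        assert res.corr_a.r - res.corr_b.r >= 0.5
        agreement = np.mean(res.group_b == ~truth["correlated"])
        assert agreement >= 0.8
        assert res.informative

    def test_homogeneous_cloud_non_informative(self):
        rng = np.random.default_rng(10)
        x = rng.normal(50, 10, 93)
        y = 5 + 0.8 * x + rng.normal(0, 2, 93)
        res = split_correlation(x, y)
        assert not res.informative

    def test_infeasible_min_frac_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(NoFeasibleSplit):
            split_correlation(rng.normal(size=30), rng.normal(size=30), min_frac=0.6)

    def test_deterministic(self):
        panel, _ = gen_elisa(ElisaMixtureSpec(seed=3))
        x, y = panel["anti_b2gp1_iga"].to_numpy(), panel["anti_d45_iga"].to_numpy()
        r1, r2 = split_correlation(x, y), split_correlation(x, y)
        assert r1.boundary == r2.boundary
        assert (r1.group_b == r2.group_b).all()


class TestGroupCompare:
    def test_identical_groups_fisher_p_one(self):
        name, _, p = group_compare(np.array([[5, 5], [5, 5]]), kind="fisher")
        assert name == "fisher" and p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # perfectly separated 2x2: only the two diagonal tables are as extreme
        name, _, p = group_compare(np.array([[10, 0], [0, 10]]), kind="fisher")
        assert name == "fisher"
        assert p == pytest.approx(2 / math.comb(20, 10))

    def test_small_expected_counts_switch_to_fisher(self):
        name, _, _ = group_compare(np.array([[8, 1], [2, 7]]))
        assert name == "fisher"  # expected counts below 5

    def test_chi2_used_for_large_counts(self):
        name, stat, p = group_compare(np.array([[30, 10], [12, 28]]))
        assert name == "chi2" and p < 0.001

    def test_identical_samples_mannwhitney_null_mean(self):
        a = list(range(10))
        name, u, p = group_compare((a, a))
        assert name == "mannwhitney"
        assert u == pytest.approx(10 * 10 / 2)

    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateTable):
            group_compare(np.array([[0, 0], [1, 2]]))


class TestNullAntiD1Property:
    def test_independent_assays_rarely_correlate(self):
        """With no generative link between anti-β2GP1 and anti-D1, |r| > 0.3
        should occur in well under 5% of cohorts at n = 93."""
        exceed = 0
        for seed in range(60):
            panel, _ = gen_elisa(ElisaMixtureSpec(seed=seed))
            r = pearson_ci(
                panel["anti_b2gp1_iga"].to_numpy(), panel["anti_d1_iga"].to_numpy()
            ).r
            exceed += abs(r) > 0.3
        assert exceed / 60 < 0.05
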