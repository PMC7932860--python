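"""Method-comparison statistics against independent oracles.

Passing-Bablok is validated against a deliberately naive loop-based
implementation of the shifted-median estimator; Pearson and Levene are
cross-checked against scipy.stats, which plays no part in the package's own
computation beyond the F-distribution tail.
"""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from vacuoquant.comparison import (
    MethodComparisonReport,
    PairedMeasurements,
    bland_altman,
    compare_methods,
    levene_test,
    passing_bablok,
    pearson_r,
)
from vacuoquant.errors import DegenerateDataError, ParameterError


def _oracle_pb_slope_intercept(x, y):
    """Naive shifted-median Passing-Bablok estimator (independent oracle)."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] == x[i]:
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    count = len(slopes)
    offset = sum(1 for s in slopes if s < -1)
    if count % 2:
        slope = slopes[(count - 1) // 2 + offset]
    else:
        slope = 0.5 * (slopes[count // 2 - 1 + offset] + slopes[count // 2 + offset])
    intercept = float(np.median([yi - slope * xi for xi, yi in zip(x, y)]))
    return slope, intercept


class TestPassingBablok:
    def test_identity_line(self):
        x = tuple(range(1, 11))
        fit = passing_bablok(PairedMeasurements(x, x), bootstrap_samples=199, seed=0)
        assert fit.slope == 1.0
        assert fit.intercept == 0.0

    def test_affine_line(self):
        x = np.arange(1.0, 9.0)
        fit = passing_bablok(
            PairedMeasurements(tuple(x), tuple(2 * x + 1)), bootstrap_samples=199, seed=0
        )
        assert fit.slope == 2.0
        assert fit.intercept == 1.0

    def test_four_point_hand_computation(self):
        # pairwise slopes {0.8, 1.05, 0.9333, 1.3, 1.0, 0.7}; even-count
        # shifted median -> (0.9333 + 1.0)/2; intercept = median residual
        fit = passing_bablok(
            PairedMeasurements((1, 2, 3, 4), (1.1, 1.9, 3.2, 3.9)),
            bootstrap_samples=199,
            seed=0,
        )
        assert fit.slope == pytest.approx(0.96667, abs=1e-4)
        assert fit.intercept == pytest.approx(0.08333, abs=1e-4)
        assert fit.n_pairwise_slopes == 6

    def test_matches_bruteforce_oracle_on_random_data(self):
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n = int(rng.integers(3, 31))
            x = np.round(rng.uniform(0, 50, n), 2)
            y = np.round(0.5 + 1.2 * x + rng.normal(0, 3, n), 2)
            if np.all(x == x[0]):
                continue
            fit = passing_bablok(
                PairedMeasurements(tuple(x), tuple(y)), bootstrap_samples=9, seed=trial
            )
            slope, intercept = _oracle_pb_slope_intercept(list(x), list(y))
            assert fit.slope == pytest.approx(slope, abs=1e-12)
            assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 30, 15)
        y = 2 + 0.8 * x + rng.normal(0, 1, 15)
        base = passing_bablok(PairedMeasurements(tuple(x), tuple(y)), 99, seed=1)
        c = 3.7
        scaled = passing_bablok(PairedMeasurements(tuple(c * x), tuple(c * y)), 99, seed=1)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(c * base.intercept, rel=1e-9)

    def test_parameter_recovery_under_symmetric_noise(self):
        rng = np.random.default_rng(7)
        n = 200
        truth = rng.uniform(0, 60, n)
        x = truth + rng.normal(0, 2, n)
        y = 5 + 1.5 * truth + rng.normal(0, 3, n)
        fit = passing_bablok(PairedMeasurements(tuple(x), tuple(y)), 99, seed=3)
        assert fit.slope == pytest.approx(1.5, abs=0.05)

    def test_bootstrap_is_seeded(self):
        pm = PairedMeasurements((1, 2, 3, 4, 5), (1.2, 2.1, 2.8, 4.3, 5.1))
        a = passing_bablok(pm, 199, seed=9)
        b = passing_bablok(pm, 199, seed=9)
        assert a == b

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            passing_bablok(PairedMeasurements((1, 2), (1, 2)), 99, seed=0)

    def test_constant_x_rejected(self):
        with pytest.raises(ParameterError):
            passing_bablok(PairedMeasurements((2, 2, 2), (1, 2, 3)), 99, seed=0)


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman(PairedMeasurements((1, 2, 3), (1, 2, 3)))
        assert res.mean_difference == 0
        assert res.loa_low == res.loa_high == 0

    def test_constant_offset(self):
        res = bland_altman(PairedMeasurements((2, 3, 4), (1, 2, 3)))
        assert res.mean_difference == 1
        assert res.sd_difference == 0
        assert (res.loa_low, res.loa_high) == (1, 1)

    def test_two_point_hand_computation(self):
        # differences (0, 2): mean 1, sample SD sqrt(2), limits 1 ± 1.96*sqrt(2)
        res = bland_altman(PairedMeasurements((1, 3), (1, 1)))
        assert res.mean_difference == 1
        assert res.sd_difference == pytest.approx(np.sqrt(2))
        assert res.loa_low == pytest.approx(1 - 1.96 * np.sqrt(2))
        assert res.loa_high == pytest.approx(1 + 1.96 * np.sqrt(2))

    def test_antisymmetry_of_mean_difference(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10), rng.random(10)
        fwd = bland_altman(PairedMeasurements(tuple(x), tuple(y)))
        rev = bland_altman(PairedMeasurements(tuple(y), tuple(x)))
        assert fwd.mean_difference == pytest.approx(-rev.mean_difference)

    def test_single_pair_rejected(self):
        with pytest.raises(ParameterError):
            bland_altman(PairedMeasurements((1,), (2,)))


class TestPearson:
    def test_perfect_lines(self):
        x = (1.0, 2.0, 3.0, 4.0)
        assert pearson_r(PairedMeasurements(x, x)) == pytest.approx(1.0)
        assert pearson_r(PairedMeasurements(x, tuple(-v for v in x))) == pytest.approx(-1.0)

    def test_hand_computation_and_scipy_agreement(self):
        pm = PairedMeasurements((1, 2, 3), (1, 2, 4))
        ours = pearson_r(pm)
        assert ours == pytest.approx(0.981981, abs=1e-5)
        assert ours == pytest.approx(scipy_stats.pearsonr([1, 2, 3], [1, 2, 4])[0])

    def test_constant_variable_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_r(PairedMeasurements((1, 1, 1), (1, 2, 3)))


class TestLevene:
    def test_identical_groups_give_zero_statistic(self):
        res = levene_test([(1.0, 2.0, 4.0), (1.0, 2.0, 4.0)])
        assert res.W_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example_and_scipy_agreement(self):
        res = levene_test([(1, 2, 4), (2, 3, 9)])
        assert res.W_statistic == pytest.approx(4.1290, abs=1e-3)
        assert (res.df_between, res.df_within) == (1, 4)
        w, p = scipy_stats.levene(np.array([1, 2, 4.0]), np.array([2, 3, 9.0]), center="mean")
        assert res.W_statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p)

    def test_shift_invariance_per_group(self):
        groups = [(1.0, 2.0, 4.0), (2.0, 3.0, 9.0)]
        shifted = [tuple(v + 100 for v in groups[0]), groups[1]]
        assert levene_test(groups).W_statistic == pytest.approx(
            levene_test(shifted).W_statistic
        )

    def test_singleton_group_rejected(self):
        with pytest.raises(ParameterError):
            levene_test([(1, 2), (5,)])

    def test_zero_deviation_everywhere_degenerate(self):
        with pytest.raises(DegenerateDataError):
            levene_test([(1, 1), (2, 2)])


class TestCompareMethods:
    def test_full_agreement_surfaces_degeneracies(self):
        rep = compare_methods([1, 2, 3], [1, 2, 3], [1, 2, 3], bootstrap_samples=99, seed=1)
        assert rep.passing_bablok_auto_vs_consensus.slope == 1.0
        assert rep.passing_bablok_auto_vs_consensus.intercept == 0.0
        assert "levene_degenerate" in rep.flags

    def test_equal_variance_raters_pass_levene(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(0, 70, 40)
        auto = np.clip(truth + rng.normal(0, 2, 40), 0, 100)
        m1 = np.clip(truth + rng.normal(0, 2, 40), 0, 100)
        m2 = np.clip(truth + rng.normal(0, 2, 40), 0, 100)
        rep = compare_methods(auto, m1, m2, bootstrap_samples=199, seed=1)
        assert rep.levene is not None
        assert rep.levene.p_value > 0.05
        assert rep.pearson_r_auto_vs_consensus > 0.99

    def test_report_round_trips_through_json(self):
        rep = compare_methods(
            [1, 2, 3, 4, 5], [1.2, 2.1, 2.8, 4.3, 5.1], [0.9, 1.8, 3.2, 4.0, 4.8],
            bootstrap_samples=99, seed=2,
        )
        assert MethodComparisonReport.from_json(rep.to_json()) == rep

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            compare_methods([1, 2, 3], [1, 2], [1, 2, 3])
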