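import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_cohort
from titertime.errors import DataError
from titertime.subgroups import (
    CartParams,
    best_split,
    chi_square_detection,
    detection_rate_ci,
    duration_balance_check,
    fit_cart,
    fold_change,
    spearman_check,
    subgroup_compare,
    subgroup_report,
)

# ---------------------------------------------------------------------------
# brute-force split oracle
# ---------------------------------------------------------------------------


def oracle_best_split(x, y):
    """Exhaustive SSE-optimal split, written independently of the tree code."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    uniq = np.sort(np.unique(x))
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        thr = (lo + hi) / 2.0
        left, right = y[x <= thr], y[x > thr]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        total = ((y - y.mean()) ** 2).sum()
        red = total - sse
        if best is None or red > best[0] + 1e-12:
            best = (red, thr)
    return best


class TestBestSplit:
    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = rng.integers(10, 200)
            x = rng.integers(0, 10, n).astype(float)
            y = rng.normal(0, 1, n)
            if np.unique(x).size < 2:
                continue
            got = best_split(x, y)
            want = oracle_best_split(x, y)
            assert got is not None
            assert got[1] == pytest.approx(want[1])
            assert got[0] == pytest.approx(want[0], rel=1e-9)

    def test_integer_hours_split_at_half(self):
        x = np.array([7, 8, 8, 9, 9, 10], dtype=float)
        y = np.array([5.0, 5.0, 5.0, 1.0, 1.0, 1.0])
        red, thr = best_split(x, y)
        assert thr == 8.5  # partitions {<=8} from {>=9}

    def test_constant_predictor_gives_none(self):
        assert best_split(np.full(10, 3.0), np.arange(10.0)) is None

    def test_min_bucket_respected(self):
        x = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        y = np.array([100.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        assert best_split(x, y, min_bucket=2) is None


class TestFitCart:
    def test_constant_response_root_only(self):
        cohort = make_cohort([10, 20, 30] * 10, [8, 9, 10] * 10, [5.0] * 30)
        tree = fit_cart(cohort, "A", CartParams(min_split=5, min_bucket=2))
        assert tree.is_leaf

    def test_constant_predictors_root_only(self):
        rng = np.random.default_rng(1)
        cohort = make_cohort([20] * 30, [9] * 30, rng.lognormal(1, 1, 30))
        tree = fit_cart(cohort, "A", CartParams(min_split=5, min_bucket=2))
        assert tree.is_leaf

    def test_planted_rule_recovered_noise_free(self):
        # signal = 1 iff age <= 16 and tod <= 8; with hours mostly early and
        # ages mostly above 16, the age split is SSE-optimal at the root
        ages, tods = zip(*itertools.product(range(10, 31), (7, 8, 9)))
        y = [1.0 if a <= 16 and t <= 8 else 0.0 for a, t in zip(ages, tods)]
        cohort = make_cohort(ages, tods, np.exp(y))
        tree = fit_cart(cohort, "A", CartParams(min_split=4, min_bucket=2, cp=0.001))
        assert tree.predictor == "age_years"
        assert tree.threshold == 16.5
        assert tree.left.predictor == "tod_hour"
        assert tree.left.threshold == 8.5
        # the signal leaf has mean exactly 1
        assert tree.left.left.mean == pytest.approx(1.0)

    def test_depth_limit(self):
        rng = np.random.default_rng(5)
        n = 400
        ages = rng.integers(5, 60, n).astype(float)
        tods = rng.integers(7, 17, n)
        y = rng.lognormal(0, 1, n)
        tree = fit_cart(
            make_cohort(ages, tods, y),
            "A",
            CartParams(max_depth=3, min_split=10, min_bucket=3, cp=0.0),
        )

        def max_depth(node):
            if node.is_leaf:
                return node.depth
            return max(max_depth(node.left), max_depth(node.right))

        assert max_depth(tree) <= 3

    def test_every_split_reduces_sse_by_cp_fraction(self):
        rng = np.random.default_rng(6)
        n = 300
        ages = rng.integers(5, 60, n).astype(float)
        tods = rng.integers(7, 17, n)
        y = np.exp(rng.normal(0, 1, n) + (ages < 20) * 1.0)
        params = CartParams(cp=0.01)
        tree = fit_cart(make_cohort(ages, tods, y), "A", params)
        root_sse = tree.sse

        def walk(node):
            if node.is_leaf:
                return
            assert node.improvement >= params.cp * root_sse
            assert node.left.n >= params.min_bucket
            assert node.right.n >= params.min_bucket
            walk(node.left)
            walk(node.right)

        walk(tree)


class TestFoldChange:
    @pytest.mark.parametrize(
        "diff,expected",
        [(1.25, 3.49), (0.71, 2.03), (0.70, 2.01), (0.97, 2.64), (-0.82, 0.44), (-1.17, 0.31)],
    )
    def test_printed_values(self, diff, expected):
        assert round(fold_change(diff), 2) == expected

    def test_zero_is_unity(self):
        assert fold_change(0.0) == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            fold_change(float("nan"))

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_identity_on_ratios(self, a, b):
        assert fold_change(math.log(a) - math.log(b)) == pytest.approx(a / b, rel=1e-12)


class TestSubgroupCompare:
    def test_equal_means_degenerate(self):
        cohort = make_cohort(
            [10, 10, 10, 10],
            [8, 8, 10, 10],
            np.exp([1.0, 3.0, 2.0, 2.0]),
        )
        cmp_ = subgroup_compare(cohort, "A", (0, 20), 8)
        assert cmp_.diff == pytest.approx(0.0)
        assert cmp_.fold_change == pytest.approx(1.0)
        assert cmp_.anova_f == pytest.approx(0.0)
        assert cmp_.anova_p == pytest.approx(1.0)

    def test_fixed_cohort_matches_anova_oracle(self):
        rng = np.random.default_rng(11)
        ln_titers = rng.normal(2.0, 1.0, 12)
        tods = [7, 7, 8, 8, 8, 8, 10, 10, 11, 12, 13, 14]
        cohort = make_cohort([20.0] * 12, tods, np.exp(ln_titers))
        cmp_ = subgroup_compare(cohort, "A", (0, 99), 8)
        a = ln_titers[:6]
        b = ln_titers[6:]
        grand = ln_titers.mean()
        ssb = 6 * (a.mean() - grand) ** 2 + 6 * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f = (ssb / 1) / (ssw / 10)
        assert cmp_.anova_f == pytest.approx(f, rel=1e-10)
        from scipy import stats

        assert cmp_.anova_p == pytest.approx(stats.f.sf(f, 1, 10), rel=1e-10)
        assert cmp_.fold_change == pytest.approx(
            math.exp(a.mean() - b.mean()), rel=1e-12
        )

    def test_side_too_small_errors(self):
        cohort = make_cohort([10, 10, 10], [7, 10, 11], [1.0, 2.0, 3.0])
        with pytest.raises(DataError):
            subgroup_compare(cohort, "A", (0, 20), 7)

    def test_empty_side_errors(self):
        cohort = make_cohort([10, 10], [10, 11], [1.0, 2.0])
        with pytest.raises(DataError):
            subgroup_compare(cohort, "A", (0, 20), 7)


class TestDetectionRateCI:
    def test_zero_successes(self):
        rate, lo, hi = detection_rate_ci(0, 10)
        assert rate == 0.0 and lo == 0.0 and hi > 0.0

    def test_all_successes(self):
        rate, lo, hi = detection_rate_ci(10, 10)
        assert rate == 1.0 and hi == 1.0 and lo < 1.0

    def test_frozen_binomial_tail_oracle(self):
        # bounds solve the exact binomial tail equations; values frozen from
        # a brentq solve of sum_{j>=k} C(n,j) p^j (1-p)^(n-j) = alpha/2
        rate, lo, hi = detection_rate_ci(8, 10)
        assert rate == pytest.approx(0.8)
        assert lo == pytest.approx(0.4439045376923585, rel=1e-9)
        assert hi == pytest.approx(0.9747892736731666, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            detection_rate_ci(1, 0)
        with pytest.raises(DataError):
            detection_rate_ci(5, 3)

    def test_coverage_exceeds_nominal(self):
        rng = np.random.default_rng(2024)
        n, p = 50, 0.6
        covered = 0
        reps = 2000
        ks = rng.binomial(n, p, size=reps)
        for k in ks:
            _, lo, hi = detection_rate_ci(int(k), n)
            covered += lo <= p <= hi
        assert covered / reps >= 0.95


class TestChiSquare:
    def test_equal_proportions(self):
        stat, p = chi_square_detection(10, 20, 10, 20)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_frozen_hand_oracle(self):
        # sum (O-E)^2/E over the 2x2 table for (29/32 vs 160/252)
        stat, p = chi_square_detection(29, 32, 160, 252)
        assert stat == pytest.approx(9.390247665017924, rel=1e-10)
        assert p == pytest.approx(0.0021814273415004647, rel=1e-9)

    def test_symmetry(self):
        assert chi_square_detection(29, 32, 160, 252) == pytest.approx(
            chi_square_detection(160, 252, 29, 32)
        )

    def test_zero_margin_undefined(self):
        with pytest.raises(DataError):
            chi_square_detection(0, 5, 0, 7)

    def test_yates_flag_reduces_statistic(self):
        plain, _ = chi_square_detection(29, 32, 160, 252)
        corrected, _ = chi_square_detection(29, 32, 160, 252, yates=True)
        assert corrected < plain


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_check(x, -x)[0] == pytest.approx(-1.0)
        assert spearman_check(x, x)[0] == pytest.approx(1.0)

    def test_tied_data_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0, 5.0, 7.0, 8.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rho_oracle = np.corrcoef(avg_ranks(x), avg_ranks(y))[0, 1]
        rho, _ = spearman_check(x, y)
        assert rho == pytest.approx(rho_oracle, rel=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(DataError):
            spearman_check([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDurationBalance:
    def test_identical_durations(self):
        cohort = make_cohort(
            [10, 10, 20, 20] * 3,
            [7, 10, 7, 10] * 3,
            np.arange(1.0, 13.0),
            durations=[4.0] * 12,
        )
        out = duration_balance_check(cohort, "A", [((0, 15), 8), ((16, 30), 8)])
        assert out["anova_f"] == 0.0
        assert out["anova_p"] == 1.0

    def test_balanced_synthetic_usually_nonsignificant(self):
        rng = np.random.default_rng(3)
        n = 200
        ages = rng.integers(5, 60, n).astype(float)
        tods = rng.integers(7, 17, n)
        cohort = make_cohort(
            ages, tods, rng.lognormal(0, 1, n), durations=rng.normal(6, 3, n).clip(0)
        )
        out = duration_balance_check(cohort, "A", [((0, 20), 9), ((21, 60), 9)])
        assert out["anova_p"] > 0.05

    def test_single_group_errors(self):
        cohort = make_cohort([10, 10], [7, 7], [1.0, 2.0], durations=[1.0, 2.0])
        with pytest.raises(DataError):
            duration_balance_check(cohort, "A", [((0, 15), 8)])

    def test_missing_duration_column(self):
        cohort = make_cohort([10, 10], [7, 10], [1.0, 2.0])
        with pytest.raises(DataError):
            duration_balance_check(cohort, "A", [((0, 15), 8)])


class TestSubgroupReport:
    def test_report_contains_tree_and_comparisons(self):
        rng = np.random.default_rng(9)
        n = 500
        ages = rng.uniform(4, 70, n)
        tods = rng.integers(7, 17, n)
        ln_y = (ages <= 16) * 2.0 + ((ages <= 16) & (tods <= 8)) * 1.25
        ln_y = ln_y + rng.normal(0, 0.5, n)
        cohort = make_cohort(ages, tods, np.exp(ln_y), threshold=3.0)
        rep = subgroup_report(cohort, "A")
        assert rep["tree"]["predictor"] == "age_years"
        assert rep["comparisons"], "expected at least one TOD comparison"
        best = max(rep["comparisons"], key=lambda c: c["improvement"])
        assert best["comparison"].fold_change == pytest.approx(math.exp(1.25), rel=0.25)
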