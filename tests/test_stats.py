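"""Statistics suite against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from renalperf import (
    chi_square_2x2,
    compare_groups_over_time,
    hedges_g,
    mann_whitney,
    median_iqr,
    roc,
    stepwise_logistic,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def mw_enumeration_oracle(x, y):
    """Two-sided exact Mann-Whitney p by brute force over label permutations.

    Counts pairwise wins + half-ties directly (no ranks), over every way of
    choosing which observations belong to the first group.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(group1, group2):
        u = 0.0
        for a in group1:
            for b in group2:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mu = n1 * len(y) / 2.0
    observed = abs(u_stat(x, y) - mu)
    hits = total = 0
    indices = range(len(pooled))
    for combo in itertools.combinations(indices, n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in indices if i not in combo]
        total += 1
        if abs(u_stat(g1, g2) - mu) >= observed - 1e-9:
            hits += 1
    return hits / total


def auc_pair_count_oracle(pos, neg):
    """AUC as the concordant-pair fraction, ties counting one half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def chi2_summation_oracle(a, b, c, d):
    """Pearson chi-square via observed-vs-expected summation."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


# ---------------------------------------------------------------------------
# median / IQR
# ---------------------------------------------------------------------------

class TestMedianIqr:
    def test_even_n_midpoint(self):
        med, _, _ = median_iqr([1, 2, 3, 4])
        assert med == 2.5

    def test_singleton(self):
        assert median_iqr([5]) == (5, 5, 5)

    def test_linear_interpolation_quartiles(self):
        _, q1, q3 = median_iqr([1, 2, 3, 4, 5, 6, 7, 8])
        assert (q1, q3) == (2.75, 6.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        cmp_ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert cmp_.u_statistic == 0
        assert cmp_.p_value == pytest.approx(0.10)  # 2 of C(6,3)=20 labelings
        assert cmp_.method == "exact"

    def test_identical_multisets(self):
        cmp_ = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert cmp_.p_value == pytest.approx(1.0)

    def test_all_tied_p_is_one(self):
        assert mann_whitney([5, 5, 5], [5, 5]).p_value == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            # mix of continuous and tied data
            x = np.round(rng.normal(0, 1, n1), 1)
            y = np.round(rng.normal(0.5, 1, n2), 1)
            got = mann_whitney(x, y, mode="exact")
            assert got.p_value == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)

    def test_exact_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.8, 1, 5)
            ours = mann_whitney(x, y, mode="exact").p_value
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_normal_approx_close_to_exact_at_n7(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, 7)
            y = rng.normal(0.6, 1, 7)
            p_exact = mann_whitney(x, y, mode="exact").p_value
            p_approx = mann_whitney(x, y, mode="approx").p_value
            assert abs(p_exact - p_approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_sepsis_table(self):
        chi2, p = chi_square_2x2(3, 42, 16, 23)
        assert chi2 == pytest.approx(14.09, abs=0.01)
        assert p < 0.001

    def test_independence(self):
        chi2, p = chi_square_2x2(10, 10, 10, 10)
        assert chi2 == 0
        assert p == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        assert chi_square_2x2(3, 42, 16, 23)[0] == pytest.approx(
            chi_square_2x2(3, 16, 42, 23)[0]
        )

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=100, derandomize=True)
    def test_closed_form_equals_summation(self, a, b, c, d):
        assert chi_square_2x2(a, b, c, d)[0] == pytest.approx(
            chi2_summation_oracle(a, b, c, d), abs=1e-9
        )

    def test_yates_never_exceeds_uncorrected(self):
        plain, _ = chi_square_2x2(3, 42, 16, 23)
        yates, _ = chi_square_2x2(3, 42, 16, 23, correction="yates")
        assert yates <= plain

    def test_zero_margin_named(self):
        with pytest.raises(ValueError, match="column 1"):
            chi_square_2x2(0, 10, 0, 10)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfect_separation(self):
        scores = [(v, "pos") for v in (5, 9, 13)] + [(v, "neg") for v in (-10, -4, 1)]
        summary = roc(scores, positive_class="pos")
        assert summary.auc == 1.0
        assert summary.sensitivity == 1.0
        assert summary.specificity == 1.0
        assert summary.lr_neg == 0.0

    def test_brute_force_pair_count(self):
        pos, neg = [9, 2, 13], [-4, -10, 3]
        scores = [(v, "pos") for v in pos] + [(v, "neg") for v in neg]
        assert roc(scores, "pos").auc == pytest.approx(8 / 9)

    def test_tie_reduces_auc_by_half_pair(self):
        pos, neg = [5.0, 9.0, 13.0], [1.0, 2.0, 5.0]  # one cross-class tie at 5
        assert roc(
            [(v, "pos") for v in pos] + [(v, "neg") for v in neg], "pos"
        ).auc == pytest.approx(1.0 - 0.5 / 9)

    def test_auc_equals_u_over_n1n2(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pos = np.round(rng.normal(1, 1, 8), 1)
            neg = np.round(rng.normal(0, 1, 11), 1)
            scores = [(v, "pos") for v in pos] + [(v, "neg") for v in neg]
            auc = roc(scores, "pos").auc
            u = mann_whitney(pos, neg).u_statistic
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_operating_point_consistent_with_counts(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(1, 1, 15)
        neg = rng.normal(0, 1, 15)
        s = roc([(v, "pos") for v in pos] + [(v, "neg") for v in neg], "pos")
        t = s.threshold_at_operating_point
        assert s.sensitivity == pytest.approx(np.mean(pos >= t))
        assert s.specificity == pytest.approx(np.mean(neg < t))

    def test_ci_brackets_auc(self):
        scores = [(v, "pos") for v in (1, 3, 2, 5)] + [(v, "neg") for v in (0, 2, 1, 4)]
        s = roc(scores, "pos")
        lo, hi = s.auc_ci95
        assert lo <= s.auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([(1, "pos"), (2, "pos")], "pos")


# ---------------------------------------------------------------------------
# Hedges' g
# ---------------------------------------------------------------------------

class TestHedgesG:
    def test_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(5, 30)))
            y = rng.normal(0.5, 1.5, int(rng.integers(5, 30)))
            df = len(x) + len(y) - 2
            sp = math.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df)
            d = (x.mean() - y.mean()) / sp
            expected = d * (1 - 3 / (4 * df - 1))
            assert hedges_g(x, y).hedges_g == pytest.approx(expected, abs=1e-12)

    def test_correction_shrinks_magnitude(self):
        x, y = [10.0, 12.0, 8.0], [7.0, 9.0, 6.0]
        eff = hedges_g(x, y)
        assert abs(eff.hedges_g) <= abs(eff.cohens_d)
        assert 0 < eff.correction_j <= 1

    def test_null_effect(self):
        assert hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).hedges_g == 0.0

    def test_antisymmetry(self):
        x, y = [1.0, 4.0, 2.0, 5.0], [3.0, 6.0, 4.0]
        assert hedges_g(x, y).hedges_g == pytest.approx(-hedges_g(y, x).hedges_g)

    def test_j_tends_to_one(self):
        n = 500_001  # df = 1e6
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n + 1)
        assert hedges_g(x, y).correction_j == pytest.approx(1.0, abs=1e-6)

    def test_constant_groups_with_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# stepwise logistic regression
# ---------------------------------------------------------------------------

def _sim_logit(rng, n, beta, noise_cols=3, x_sd=10.0):
    x = rng.normal(0, x_sd, n)
    p = 1 / (1 + np.exp(-(beta * x)))
    y = (rng.uniform(size=n) < p).astype(float)
    data = {"true_pred": x}
    for k in range(noise_cols):
        data[f"noise{k}"] = rng.normal(0, x_sd, n)
    return pd.DataFrame(data), y


class TestStepwiseLogistic:
    def test_null_selection_with_independent_candidate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        y = np.repeat([0.0, 1.0], 100)
        fit = stepwise_logistic(pd.DataFrame({"x": x}), y)
        assert fit.selected_terms == []
        assert fit.intercept is not None

    def test_intercept_only_recovers_log_odds(self):
        y = np.array([1.0] * 30 + [0.0] * 10)
        fit = stepwise_logistic(pd.DataFrame(index=range(40)), y)
        assert fit.intercept.b == pytest.approx(math.log(3), abs=1e-6)

    def test_true_predictor_selected_with_wald_identities(self):
        rng = np.random.default_rng(8)
        X, y = _sim_logit(rng, 400, beta=-0.09)
        fit = stepwise_logistic(X, y)
        assert fit.selected_terms == ["true_pred"]
        stats = fit.terms["true_pred"]
        assert stats.wald == pytest.approx((stats.b / stats.se) ** 2)
        assert stats.exp_b == pytest.approx(math.exp(stats.b))
        lo, hi = stats.exp_b_ci95
        assert lo < stats.exp_b < hi

    def test_printed_identity_check(self):
        # the Wald and odds-ratio identities at the reported precision
        b, se = -0.091, 0.048
        assert (b / se) ** 2 == pytest.approx(3.594, abs=0.001)
        assert math.exp(b) == pytest.approx(0.913, abs=0.001)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.full(20, -5.0), np.full(20, 5.0)])
        y = (x > 0).astype(float)
        fit = stepwise_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation
        assert "x" not in fit.selected_terms

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="complete-case"):
            stepwise_logistic(pd.DataFrame({"x": [1.0] * 5}), np.array([0, 1, 0, 1, 0.0]))


# ---------------------------------------------------------------------------
# group comparisons over the grid
# ---------------------------------------------------------------------------

class TestCompareGroupsOverTime:
    def test_per_row_n_is_complete_case_count(self, default_cohort, default_outcomes):
        table = compare_groups_over_time(default_cohort, default_outcomes, "map_mmHg")
        for row in table.itertuples():
            n_obs = sum(
                1
                for p in default_cohort
                if (o := p.observation(row.time_h)) is not None and o.map_mmHg is not None
            )
            assert row.n_no_aki + row.n_aki == n_obs

    def test_n_never_increases_under_dropout(self, default_cohort, default_outcomes):
        table = compare_groups_over_time(default_cohort, default_outcomes, "EFFECTIVE_RPP")
        for col in ("n_no_aki", "n_aki"):
            ns = table[col].tolist()
            assert ns[0] >= ns[3] >= ns[4]  # 0 h >= 24 h >= 48 h

    def test_pmean_restricted_to_ventilated_under_exclude(
        self, default_cohort, default_outcomes
    ):
        n_vent = sum(p.ventilated for p in default_cohort)
        table = compare_groups_over_time(
            default_cohort, default_outcomes, "EFFECTIVE_RPP", pmean_policy="exclude"
        )
        assert (table.n_no_aki + table.n_aki).max() <= n_vent

    def test_unknown_parameter_rejected(self, default_cohort, default_outcomes):
        with pytest.raises(ValueError):
            compare_groups_over_time(default_cohort, default_outcomes, "sbp")
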