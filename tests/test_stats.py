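"""Contingency diagnostics, IRLS logistic regression and the nonparametric
tests, each checked against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from olfact import (
    ContingencyTable,
    Combo,
    Disease,
    chi_square_test,
    diagnostics,
    fit_logistic_irls,
    make_table,
    mann_whitney_u,
    univariable_screen,
)
from olfact.exceptions import (
    RankDeficientError,
    SeparationError,
    UndefinedDiagnosticError,
    ValidationError,
)
from olfact.stats import add_intercept, combo_indicators, disease_indicator

cells = st.integers(min_value=1, max_value=60)


def _table_to_data(a, b, c, d):
    """Expand 2x2 counts into (exposure, disease) rows."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return x, y


class TestMakeTable:
    def test_headline_pvod_table(self, paper_cohort):
        t = make_table(paper_cohort, Disease.PVOD, Combo.PN)
        assert (t.a, t.b, t.c, t.d) == (48, 17, 70, 172)

    def test_ptod_table(self, paper_cohort):
        t = make_table(paper_cohort, Disease.PTOD, Combo.NN)
        assert (t.a, t.b, t.c, t.d) == (13, 26, 15, 253)

    def test_cells_partition_cohort(self, paper_cohort):
        t = make_table(paper_cohort, Disease.CRS_POLYP, Combo.NP)
        assert t.n == len(paper_cohort)

    def test_zero_cells_allowed(self, paper_cohort):
        stratum = [r for r in paper_cohort if r.disease is Disease.PVOD]
        t = make_table(stratum, Disease.PVOD, Combo.PP)
        assert t.b == 0 and t.d == 0  # no non-diseased rows in the stratum

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            make_table([], Disease.PVOD, Combo.PP)


class TestDiagnostics:
    @pytest.mark.parametrize(
        "table, or_1dp, sens, spec",
        [
            ((48, 17, 70, 172), 6.9, 0.41, 0.91),
            ((36, 12, 81, 178), 6.6, 0.31, 0.94),
            ((34, 121, 10, 142), 4.0, 0.77, 0.54),
            ((13, 26, 15, 253), 8.4, 0.46, 0.91),
        ],
    )
    def test_headline_triplets_at_printed_rounding(self, table, or_1dp, sens, spec):
        d = diagnostics(ContingencyTable(*table))
        assert round(d.odds_ratio, 1) == or_1dp
        assert round(d.sensitivity, 2) == sens
        assert round(d.specificity, 2) == spec

    @pytest.mark.parametrize("k", [1, 7])
    def test_symmetric_table(self, k):
        d = diagnostics(ContingencyTable(k, k, k, k))
        assert d.odds_ratio == pytest.approx(1.0)
        assert d.sensitivity == pytest.approx(0.5)
        assert d.specificity == pytest.approx(0.5)

    def test_wald_ci_formula(self):
        d = diagnostics(ContingencyTable(48, 17, 70, 172))
        se = math.sqrt(1 / 48 + 1 / 17 + 1 / 70 + 1 / 172)
        assert d.ci95_low == pytest.approx(math.exp(d.log_or - 1.959963984540054 * se))
        assert math.exp(d.log_or) == pytest.approx(d.odds_ratio, abs=1e-12)

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(UndefinedDiagnosticError):
            diagnostics(ContingencyTable(0, 5, 5, 5))
        d = diagnostics(ContingencyTable(0, 5, 5, 5), haldane=True)
        assert d.odds_ratio == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))
        assert d.sensitivity == 0.0  # raw counts, not corrected

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedDiagnosticError):
            diagnostics(ContingencyTable(0, 5, 0, 5))

    @given(cells, cells, cells, cells)
    def test_or_invariant_under_double_swap(self, a, b, c, d):
        """Swapping both rows and columns leaves the OR unchanged; swapping a
        single margin inverts it."""
        base = diagnostics(ContingencyTable(a, b, c, d)).odds_ratio
        double = diagnostics(ContingencyTable(d, c, b, a)).odds_ratio
        rows = diagnostics(ContingencyTable(c, d, a, b)).odds_ratio
        assert double == pytest.approx(base, rel=1e-12)
        assert rows == pytest.approx(1.0 / base, rel=1e-12)


class TestLogisticIrls:
    def test_single_binary_predictor_equals_log_odds_ratio(self):
        a, b, c, d = 48, 17, 70, 172
        x, y = _table_to_data(a, b, c, d)
        fit = fit_logistic_irls(add_intercept(x), y)
        assert fit.converged
        assert fit.coef[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)

    def test_matches_statsmodels_on_two_predictors(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        n = 400
        X = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.4, size=n)])
        eta = -0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        ours = fit_logistic_irls(add_intercept(X), y.astype(float))
        theirs = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.coef, theirs.params, atol=1e-6)
        np.testing.assert_allclose(ours.se, theirs.bse, atol=1e-6)

    def test_constant_outcome_degenerate(self):
        with pytest.raises(SeparationError):
            fit_logistic_irls(add_intercept(np.arange(10.0)), np.zeros(10))

    def test_complete_separation_detected(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        with pytest.raises(SeparationError):
            fit_logistic_irls(add_intercept(x), x.copy())

    def test_collinear_design_rank_error(self):
        x = np.ones(30)
        y = np.tile([0.0, 1.0], 15)
        with pytest.raises((RankDeficientError, SeparationError)):
            fit_logistic_irls(add_intercept(x), y)

    def test_slope_recovery_within_wald_ci(self):
        rng = np.random.default_rng(2000)
        n, beta = 2000, 1.0
        x = rng.binomial(1, 0.5, size=n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + beta * x)))).astype(float)
        fit = fit_logistic_irls(add_intercept(x), y)
        lo = fit.coef[1] - 1.96 * fit.se[1]
        hi = fit.coef[1] + 1.96 * fit.se[1]
        assert lo <= beta <= hi


class TestUnivariableScreen:
    def test_paper_fixture_selection(self, paper_cohort):
        screen = univariable_screen(
            combo_indicators(paper_cohort),
            disease_indicator(paper_cohort, Disease.PVOD),
        )
        assert "PN" in screen.selected  # the positive signature
        assert "NP" in screen.selected  # strong negative predictor
        assert "NN" not in screen.selected

    def test_pn_slope_matches_crude_log_or(self, paper_cohort):
        screen = univariable_screen(
            combo_indicators(paper_cohort),
            disease_indicator(paper_cohort, Disease.PVOD),
        )
        expected = math.log(48 * 172 / (17 * 70))
        assert screen.fits["PN"].coef[1] == pytest.approx(expected, abs=1e-6)

    def test_predictor_identical_to_outcome_recorded_not_fatal(self, paper_cohort):
        y = disease_indicator(paper_cohort, Disease.PVOD)
        predictors = {"self": y.copy(), **combo_indicators(paper_cohort)}
        screen = univariable_screen(predictors, y)
        assert "self" in screen.errors
        assert "PN" in screen.fits  # the rest of the screen still ran

    def test_empty_candidates_rejected(self, paper_cohort):
        with pytest.raises(ValidationError):
            univariable_screen({}, disease_indicator(paper_cohort, Disease.PVOD))


def _chi2_bruteforce(obs):
    """Direct-definition oracle: loops, no vectorization shared with the code."""
    obs = [list(map(float, row)) for row in obs]
    n = sum(sum(r) for r in obs)
    stat = 0.0
    for i, row in enumerate(obs):
        for j in range(len(row)):
            e = sum(obs[i]) * sum(r[j] for r in obs) / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


class TestChiSquare:
    def test_published_domain_table_below_point_001(self):
        assert chi_square_test([[15, 20], [40, 4]]).p_value < 0.001

    def test_identical_rows_give_unit_p(self):
        r = chi_square_test([[10, 5], [10, 5]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_statistic_matches_bruteforce_on_random_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            obs = rng.integers(1, 8, size=(2, 2))
            ours = chi_square_test(obs).statistic
            assert ours == pytest.approx(_chi2_bruteforce(obs), abs=1e-12)

    def test_matches_scipy_including_rxc(self):
        rng = np.random.default_rng(2)
        obs = rng.integers(1, 30, size=(3, 4))
        ours = chi_square_test(obs)
        stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
        assert ours.statistic == pytest.approx(stat, rel=1e-12)
        assert ours.p_value == pytest.approx(p, rel=1e-9)
        assert ours.df == df

    def test_yates_correction_matches_scipy(self):
        obs = [[12, 5], [6, 14]]
        ours = chi_square_test(obs, yates=True)
        stat, p, _, _ = sps.chi2_contingency(obs, correction=True)
        assert ours.statistic == pytest.approx(stat, rel=1e-12)

    @given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 20),
           st.integers(1, 20))
    def test_transposition_invariance(self, a, b, c, d):
        t = [[a, b], [c, d]]
        tt = [[a, c], [b, d]]
        assert chi_square_test(t).statistic == pytest.approx(
            chi_square_test(tt).statistic, rel=1e-12
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_test([[0, 0], [3, 4]])


def _mwu_bruteforce(x, y, alternative):
    """Full label-permutation enumeration of the exact p-value (tie-free)."""
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestMannWhitney:
    def test_identical_samples_no_evidence(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney_u(x, list(x)).p_value == pytest.approx(1.0)

    def test_complete_dominance_one_sided_exact(self):
        x = [10.0, 11.0, 12.0]
        y = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney_u(x, y, alternative="greater")
        assert r.p_value == pytest.approx(1 / math.comb(7, 3), abs=1e-15)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_equals_full_enumeration(self, alternative):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(loc=0.5, size=5)
            ours = mann_whitney_u(x, y, alternative=alternative).p_value
            assert ours == pytest.approx(
                _mwu_bruteforce(x, y, alternative), abs=1e-12
            )

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=8)
        y = rng.normal(size=9)
        ours = mann_whitney_u(x, y).p_value
        theirs = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact").pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_normal_approximation_with_ties_matches_scipy(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(1, 6, size=35).astype(float)
        ours = mann_whitney_u(x, y).p_value
        theirs = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])
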