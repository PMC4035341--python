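"""Candidate building, mixed-model fitting, AICc and selection rules."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from salmosurv.covariates import AlignedDataset
from salmosurv.mixedmodels import (
    ModelFit,
    ModelSpec,
    aicc,
    build_candidates,
    compare_models,
    fit_lmm,
)
from salmosurv.screening import ScreenResult


def make_dataset(frame: pd.DataFrame) -> AlignedDataset:
    pairwise = {c: frame[[c, "survival"]]
                for c in frame.columns if c != "survival"}
    return AlignedDataset(response_name="survival", pairwise=pairwise,
                          frame=frame)


def make_screen_result(name, r=0.6, r2=None, p=0.01, n=27):
    r2 = r * r if r2 is None else r2
    return ScreenResult(covariate=name, n=n, r=r, r2=r2, slope=1.0,
                        intercept=0.0, slope_xy=1.0, intercept_xy=0.0,
                        p_perm=p, significant=True)


def make_fit(label, aicc_value, years, n_terms=1):
    spec = ModelSpec(fixed=tuple(f"v{i}" for i in range(n_terms)),
                     max_vars=3)
    return ModelFit(spec=spec,
                    coefficients={"intercept": 0.0,
                                  **{f"v{i}": 1.0 for i in range(n_terms)}},
                    random_intercept_variance=0.0, residual_variance=1.0,
                    loglik=0.0, k=n_terms + 3, n=len(years),
                    year_set=frozenset(years), aicc=aicc_value,
                    boundary_flag=False)


class TestAicc:
    def test_pencil_and_paper_case(self):
        # -2(-10) + 2*3 + 2*3*4/(22-3-1) = 20 + 6 + 24/18
        assert aicc(-10.0, 3, 22) == pytest.approx(20 + 6 + 24 / 18)
        assert aicc(-10.0, 3, 22) == pytest.approx(27.33333333, abs=1e-6)

    def test_correction_vanishes_for_large_n(self):
        plain_aic = -2 * (-10.0) + 2 * 3
        assert aicc(-10.0, 3, 10 ** 5) - plain_aic < 1e-3

    def test_always_exceeds_aic(self):
        for n in (6, 10, 50, 1000):
            assert aicc(-5.0, 3, n) > -2 * (-5.0) + 2 * 3

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-5.0, 3, 4)


class TestBuildCandidates:
    def corr(self, names, value=0.0):
        m = pd.DataFrame(np.full((len(names), len(names)), value),
                         index=names, columns=names)
        np.fill_diagonal(m.values, 1.0)
        return m

    def test_uncorrelated_pair_gives_three_specs(self):
        universe = [make_screen_result("A"), make_screen_result("B")]
        specs = build_candidates(universe, self.corr(["A", "B"], 0.3))
        labels = {s.label() for s in specs}
        assert labels == {"A", "B", "A + B"}

    def test_collinear_pair_keeps_higher_r2_only(self):
        universe = [make_screen_result("A", r=0.7),
                    make_screen_result("B", r=0.5)]
        specs = build_candidates(universe, self.corr(["A", "B"], 0.9))
        assert {s.label() for s in specs} == {"A"}

    def test_five_uncorrelated_matches_subset_enumeration(self):
        names = list("ABCDE")
        universe = [make_screen_result(n) for n in names]
        specs = build_candidates(universe, self.corr(names, 0.1))
        # brute-force oracle: all subsets of size 1..3
        expected = {frozenset(c) for size in (1, 2, 3)
                    for c in combinations(names, size)}
        got = {frozenset(s.fixed) for s in specs}
        assert got == expected
        assert len(specs) == 25

    def test_empty_universe_empty_list(self):
        assert build_candidates([], self.corr([])) == []

    def test_requested_interaction_added_where_parents_present(self):
        universe = [make_screen_result("A"), make_screen_result("B")]
        specs = build_candidates(universe, self.corr(["A", "B"], 0.2),
                                 interactions=[("A", "B")])
        labels = {s.label() for s in specs}
        assert "A + B + A x B" in labels
        assert "A + B" in labels


class TestFitLmm:
    def test_noise_free_line_recovered(self):
        years = list(range(1980, 2008))
        x = np.linspace(-1, 1, len(years))
        frame = pd.DataFrame({"survival": 2 * x + 1, "x": x}, index=years)
        fit = fit_lmm(ModelSpec(fixed=("x",)), make_dataset(frame))
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coefficients["intercept"] == pytest.approx(1.0, abs=1e-6)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-8)

    def test_zero_variance_covariate_errors(self):
        years = list(range(1980, 2008))
        frame = pd.DataFrame({"survival": np.random.default_rng(0)
                              .normal(size=len(years)),
                              "x": np.ones(len(years))}, index=years)
        with pytest.raises(ValueError, match="zero variance"):
            fit_lmm(ModelSpec(fixed=("x",)), make_dataset(frame))

    def test_singular_design_errors(self):
        years = list(range(1980, 2010))
        x = np.linspace(0, 1, len(years))
        frame = pd.DataFrame({"survival": x + 0.1, "a": x, "b": 2 * x},
                             index=years)
        with pytest.raises(ValueError, match="singular"):
            fit_lmm(ModelSpec(fixed=("a", "b")), make_dataset(frame))

    def test_simulated_slope_within_3se_and_loglik_optimal(self):
        rng = np.random.default_rng(30)
        years = list(range(1980, 2010))
        n = len(years)
        x = rng.normal(size=n)
        true_slope, sigma = 0.5, 0.3
        y = 1.0 + true_slope * x + rng.normal(scale=sigma, size=n)
        frame = pd.DataFrame({"survival": y, "x": x}, index=years)
        fit = fit_lmm(ModelSpec(fixed=("x",)), make_dataset(frame))
        se = sigma / np.sqrt(n * np.var(x))
        assert abs(fit.coefficients["x"] - true_slope) <= 3 * se

        # independent direct likelihood oracle: marginal Gaussian density
        # y ~ N(Xb, (s2_re + s2_e) I) for singleton year groups, evaluated
        # at the generating parameters must not beat the ML fit
        spec_ml = ModelSpec(fixed=("x",), likelihood="ML")
        fit_ml = fit_lmm(spec_ml, make_dataset(frame))

        def direct_loglik(b0, b1, total_var):
            resid = y - b0 - b1 * x
            return float(-0.5 * (n * np.log(2 * np.pi * total_var)
                                 + resid @ resid / total_var))

        at_truth = direct_loglik(1.0, true_slope, sigma ** 2)
        assert fit_ml.loglik >= at_truth - 1e-8

    def test_forced_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(31)
        years = list(range(1980, 2008))
        n = len(years)
        x = rng.normal(size=n)
        y = 0.3 - 0.7 * x + rng.normal(scale=0.5, size=n)
        frame = pd.DataFrame({"survival": y, "x": x}, index=years)
        fit = fit_lmm(ModelSpec(fixed=("x",)), make_dataset(frame),
                      force_zero_random=True)
        beta = np.polyfit(x, y, 1)
        assert fit.coefficients["x"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.coefficients["intercept"] == pytest.approx(beta[1],
                                                              abs=1e-6)
        assert fit.boundary_flag
        assert fit.random_intercept_variance == 0.0

    def test_free_fit_coefficients_equal_ols_for_singleton_groups(self):
        # one observation per year: the mixed model's GLS weights are
        # uniform whatever the variance split, so coefficients are OLS
        rng = np.random.default_rng(32)
        years = list(range(1980, 2008))
        n = len(years)
        x = rng.normal(size=n)
        y = 0.2 + 0.4 * x + rng.normal(scale=0.4, size=n)
        frame = pd.DataFrame({"survival": y, "x": x}, index=years)
        fit = fit_lmm(ModelSpec(fixed=("x",)), make_dataset(frame))
        beta = np.polyfit(x, y, 1)
        assert fit.coefficients["x"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.coefficients["intercept"] == pytest.approx(beta[1],
                                                              abs=1e-6)

    def test_reml_llf_matches_closed_form_on_singleton_groups(self):
        # independent REML oracle for the degenerate (ridge) design
        rng = np.random.default_rng(33)
        years = list(range(1980, 2007))
        n = len(years)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=n)
        frame = pd.DataFrame({"survival": y, "x": x}, index=years)
        fit = fit_lmm(ModelSpec(fixed=("x",)), make_dataset(frame))
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float((y - X @ beta) @ (y - X @ beta))
        s2 = rss / (n - 2)
        oracle = -0.5 * ((n - 2) * (np.log(2 * np.pi) + np.log(s2) + 1)
                         + np.linalg.slogdet(X.T @ X)[1])
        assert fit.loglik == pytest.approx(oracle, abs=1e-5)


class TestCompareModels:
    def test_printed_aicc_pair_prefers_single_variable(self):
        years = range(1980, 2002)  # n = 22
        one = make_fit("one", 94.65, years, n_terms=1)
        two = make_fit("two", 116.06, years, n_terms=2)
        outcome = compare_models([one, two])
        (group,) = outcome.groups.values()
        assert group["preferred"] is one
        deltas = dict(zip(group["table"]["model"],
                          group["table"]["delta_aicc"]))
        assert deltas[two.spec.label()] == pytest.approx(21.41)
        assert group["equivalence_class"] == [one]

    def test_different_year_sets_incomparable(self):
        a = make_fit("a", 94.26, range(1980, 2007))   # n = 27
        b = make_fit("b", 100.61, range(1985, 2007))  # n = 22
        outcome = compare_models([a, b])
        assert len(outcome.groups) == 2
        assert len(outcome.incomparable) == 1
        assert "n=27" in outcome.incomparable[0][2]
        assert "n=22" in outcome.incomparable[0][2]
        # each model is trivially preferred within its own partition
        assert {g["preferred"] for g in outcome.groups.values()} == {a, b}

    def test_equal_aicc_prefers_simpler(self):
        years = range(1980, 2007)
        one = make_fit("one", 100.0, years, n_terms=1)
        two = make_fit("two", 100.0, years, n_terms=2)
        outcome = compare_models([two, one])
        (group,) = outcome.groups.values()
        assert group["preferred"] is one

    def test_equivalence_class_simplest_wins_even_if_not_minimum(self):
        years = range(1980, 2007)
        two = make_fit("two", 100.0, years, n_terms=2)
        one = make_fit("one", 101.5, years, n_terms=1)  # within delta 2
        outcome = compare_models([two, one])
        (group,) = outcome.groups.values()
        assert group["preferred"] is one

    def test_no_fits_errors(self):
        with pytest.raises(ValueError):
            compare_models([])


def test_aicc_ordering_shift_invariant_for_equal_k():
    """Adding a constant to the response shifts all equal-k AICc equally."""
    rng = np.random.default_rng(40)
    years = list(range(1980, 2008))
    n = len(years)
    xa, xb = rng.normal(size=n), rng.normal(size=n)
    y = 0.5 * xa + rng.normal(scale=0.5, size=n)
    for shift in (0.0, 5.0):
        frame = pd.DataFrame({"survival": y + shift, "a": xa, "b": xb},
                             index=years)
        data = make_dataset(frame)
        fa = fit_lmm(ModelSpec(fixed=("a",)), data)
        fb = fit_lmm(ModelSpec(fixed=("b",)), data)
        if shift == 0.0:
            base_delta = fa.aicc - fb.aicc
    assert fa.aicc - fb.aicc == pytest.approx(base_delta, abs=1e-4)
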