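"""Candidate linear mixed-effects models and AICc selection.

The modelling stage turns the screened covariate universe into candidate
models under five explicit conditions:

1. only covariates that passed the permutation screen enter models;
2. covariates correlated with each other above |r| = 0.5 never share a
   model — of such a pair only the one with the higher screening R²
   survives;
3. at most three covariates per model (roughly n/10 for these series);
4. each model is fitted on its own maximal complete-case year set, and
   AICc is compared only between models fitted to identical year sets;
5. within a ΔAICc < 2 equivalence class, the simplest model is preferred.

Models are linear mixed-effects fits (random intercept grouped by
calendar year, survival as response) fitted by REML by default, via
statsmodels' MixedLM.  With a single observation per year the random
intercept is confounded with the residual: the two variance components
are identified only through their sum, the fixed-effect estimates reduce
to ordinary least squares, and fits with the random-intercept variance
at (or forced to) zero are flagged.  An alternative grouping collapses
years into cohort classes (e.g. lag-3 blocks for Chinook, matching the
detected survival autocorrelation), which makes the random effect
genuinely identifiable.

REML likelihoods are not strictly comparable across different
fixed-effect structures; the default mirrors common field practice
(REML), and ``likelihood="ML"`` is available for principled AICc
comparison.  Both can be reported side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .covariates import AlignedDataset
from .screening import ScreenResult

__all__ = [
    "ModelSpec",
    "ModelFit",
    "SelectionOutcome",
    "build_candidates",
    "fit_lmm",
    "aicc",
    "compare_models",
]

#: |r| above which two covariates may not share a model
COLLINEARITY_LIMIT = 0.5
#: random-intercept variance below this fraction of residual variance
#: is treated as a boundary (degenerate) estimate
BOUNDARY_FRAC = 1e-6
EQUIVALENCE_DELTA = 2.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: fixed covariate terms plus optional interactions."""

    fixed: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    likelihood: str = "REML"
    group_by: str = "year"      # "year" or "cohort:<L>" for lag-L classes
    max_vars: int = 3

    def __post_init__(self) -> None:
        if not 1 <= len(self.fixed) <= self.max_vars:
            raise ValueError(
                f"{len(self.fixed)} fixed terms outside 1..{self.max_vars}")
        if self.likelihood not in ("REML", "ML"):
            raise ValueError(f"likelihood must be REML or ML")
        for a, b in self.interactions:
            if a not in self.fixed or b not in self.fixed:
                raise ValueError(f"interaction ({a}, {b}) references a "
                                 "covariate not in the fixed terms")

    @property
    def terms(self) -> list[str]:
        return list(self.fixed) + [f"{a} x {b}" for a, b in self.interactions]

    def label(self) -> str:
        return " + ".join(self.terms)


@dataclass(frozen=True, eq=False)  # identity semantics: fits are unique objects
class ModelFit:
    """A fitted candidate with everything selection needs."""

    spec: ModelSpec
    coefficients: dict[str, float]       # "intercept" + one per term
    random_intercept_variance: float
    residual_variance: float
    loglik: float
    k: int
    n: int
    year_set: frozenset[int]
    aicc: float
    boundary_flag: bool
    slope_pvalues: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_terms(self) -> int:
        return len(self.spec.terms)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def build_candidates(universe: list[ScreenResult],
                     pairwise_corr: pd.DataFrame,
                     max_vars: int = 3,
                     interactions: list[tuple[str, str]] | None = None,
                     likelihood: str = "REML") -> list[ModelSpec]:
    """Enumerate candidate models from the significant screen results.

    Collinearity rule: whenever two universe members correlate above
    |r| = 0.5, the one with the lower screening R² is removed outright, so
    no candidate ever contains a collinear pair and the stronger member
    keeps the weaker one's potential partners.  All non-empty subsets of
    the survivors up to ``max_vars`` become specs; explicitly requested
    two-way interactions are added to the subsets containing both parents.
    """
    sig = [s for s in universe if s.significant]
    if not sig:
        return []
    r2 = {s.covariate: s.r2 for s in sig}

    dropped: set[str] = set()
    for a, b in combinations(sorted(r2), 2):
        if a in pairwise_corr.index and b in pairwise_corr.columns:
            if abs(pairwise_corr.loc[a, b]) > COLLINEARITY_LIMIT:
                dropped.add(a if r2[a] < r2[b] else b)
    names = [s.covariate for s in sig if s.covariate not in dropped]

    wanted = [(a, b) for a, b in (interactions or [])]
    specs = []
    for size in range(1, min(max_vars, len(names)) + 1):
        for subset in combinations(names, size):
            specs.append(ModelSpec(fixed=subset, likelihood=likelihood,
                                   max_vars=max_vars))
            inter = tuple((a, b) for a, b in wanted
                          if a in subset and b in subset)
            if inter:
                specs.append(ModelSpec(fixed=subset, interactions=inter,
                                       likelihood=likelihood,
                                       max_vars=max_vars))
    return specs


def _design(spec: ModelSpec, data: AlignedDataset
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    cols = list(spec.fixed)
    missing = [c for c in cols if c not in data.frame.columns]
    if missing:
        raise KeyError(f"covariates {missing} not in aligned dataset")
    df = data.frame[["survival", *cols]].dropna()
    y = df["survival"].to_numpy()
    X = [np.ones(len(df))]
    names = ["intercept"]
    for c in cols:
        X.append(df[c].to_numpy())
        names.append(c)
    for a, b in spec.interactions:
        X.append(df[a].to_numpy() * df[b].to_numpy())
        names.append(f"{a} x {b}")
    return np.column_stack(X), y, df.index.to_numpy(), names


def _groups(spec: ModelSpec, years: np.ndarray) -> np.ndarray:
    if spec.group_by == "year":
        return years
    if spec.group_by.startswith("cohort:"):
        width = int(spec.group_by.split(":", 1)[1])
        return years // width
    raise ValueError(f"unknown grouping {spec.group_by!r}")


def _ols_reml_loglik(X: np.ndarray, y: np.ndarray, reml: bool) -> float:
    """Gaussian log-likelihood of the zero-random-variance model.

    REML form matches statsmodels' MixedLM convention (verified against
    its llf on ridge-degenerate designs):
    -0.5 [ (n-p)(ln 2π + ln σ̂² + 1) + ln|X'X| ].
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if reml:
        s2 = rss / (n - p)
        _, logdet = np.linalg.slogdet(X.T @ X)
        return -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(s2) + 1)
                       + logdet)
    s2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi) + np.log(s2) + 1)


def fit_lmm(spec: ModelSpec, data: AlignedDataset,
            force_zero_random: bool = False) -> ModelFit:
    """Fit one candidate mixed model on its complete-case year set.

    Random intercept grouped per ``spec.group_by``; REML or ML per the
    spec.  ``force_zero_random=True`` pins the random-intercept variance
    at zero, in which case the fit is exactly generalized least squares
    with identity weights (= OLS) and the flag is raised; this is the
    reference point for the degeneracy contract.

    Raises on singular designs, zero-variance covariates, and
    non-convergence.
    """
    X, y, years, names = _design(spec, data)
    n, p = X.shape
    k = len(spec.terms) + 3  # intercept + slopes/interactions + 2 variances
    if n < k + 2:
        raise ValueError(f"n={n} too small for k={k} parameters")
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} has zero variance on "
                             "the model year set")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"singular design for model {spec.label()!r}")
    reml = spec.likelihood == "REML"

    if force_zero_random:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        resid_var = float(resid @ resid) / (n - p)
        llf = _ols_reml_loglik(X, y, reml)
        se = np.sqrt(np.diag(resid_var * np.linalg.inv(X.T @ X)))
        from scipy import stats as _st
        pvals = {nm: float(2 * _st.t.sf(abs(b / s), n - p))
                 for nm, b, s in zip(names[1:], beta[1:], se[1:])}
        return ModelFit(
            spec=spec,
            coefficients=dict(zip(names, map(float, beta))),
            random_intercept_variance=0.0,
            residual_variance=resid_var,
            loglik=float(llf), k=k, n=n,
            year_set=frozenset(int(t) for t in years),
            aicc=aicc(float(llf), k, n),
            boundary_flag=True,
            slope_pvalues=pvals)

    model = MixedLM(y, X, groups=_groups(spec, years))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method="lbfgs", maxiter=500)
    if not result.converged:
        raise RuntimeError(
            f"mixed model {spec.label()!r} failed to converge "
            f"(n={n}, groups={len(set(_groups(spec, years)))})")
    var_re = float(np.asarray(result.cov_re).ravel()[0])
    resid_var = float(result.scale)
    pvals = {nm: float(pv) for nm, pv in
             zip(names[1:], np.asarray(result.pvalues)[1:p])}
    return ModelFit(
        spec=spec,
        coefficients=dict(zip(names, map(float, np.asarray(result.fe_params)))),
        random_intercept_variance=var_re,
        residual_variance=resid_var,
        loglik=float(result.llf), k=k, n=n,
        year_set=frozenset(int(t) for t in years),
        aicc=aicc(float(result.llf), k, n),
        boundary_flag=var_re <= BOUNDARY_FRAC * max(resid_var, 1e-300),
        slope_pvalues=pvals)


@dataclass(frozen=True)
class SelectionOutcome:
    """AICc comparison restricted to identically sampled models.

    ``groups`` maps each distinct year set to its ΔAICc table (a DataFrame
    sorted by AICc with ``delta_aicc`` and ``in_equivalence_class``
    columns), its preferred fit, and the fits themselves.  Models fitted
    to different year sets are never ranked against each other; every
    such cross pair is listed in ``incomparable``.
    """

    groups: dict[frozenset[int], dict]
    incomparable: list[tuple[str, str, str]]

    @property
    def preferred(self) -> list[ModelFit]:
        return [g["preferred"] for g in self.groups.values()]


def compare_models(fits: list[ModelFit]) -> SelectionOutcome:
    """Partition fits by year set, apply ΔAICc < 2 equivalence, pick winners.

    Within each partition the equivalence class is every fit within
    ΔAICc < 2 of the minimum; the preferred fit is the simplest member
    (fewest terms, ties broken by lower AICc).  Pairs of fits from
    different partitions are reported incomparable with the differing n.
    """
    if not fits:
        raise ValueError("no fits to compare")
    by_years: dict[frozenset[int], list[ModelFit]] = {}
    for f in fits:
        by_years.setdefault(f.year_set, []).append(f)

    groups: dict[frozenset[int], dict] = {}
    for ys, members in by_years.items():
        assert all(f.year_set == ys for f in members)
        best = min(f.aicc for f in members)
        rows = []
        equiv = []
        for f in sorted(members, key=lambda f: f.aicc):
            delta = f.aicc - best
            in_class = delta < EQUIVALENCE_DELTA
            if in_class:
                equiv.append(f)
            rows.append({"model": f.spec.label(), "k": f.k, "n": f.n,
                         "aicc": f.aicc, "delta_aicc": delta,
                         "in_equivalence_class": in_class})
        preferred = min(equiv, key=lambda f: (f.n_terms, f.aicc))
        groups[ys] = {"fits": members,
                      "table": pd.DataFrame(rows),
                      "equivalence_class": equiv,
                      "preferred": preferred}

    incomparable = []
    keys = list(groups)
    for ka, kb in combinations(keys, 2):
        for fa in groups[ka]["fits"]:
            for fb in groups[kb]["fits"]:
                incomparable.append((
                    fa.spec.label(), fb.spec.label(),
                    f"year sets differ (n={fa.n} vs n={fb.n}); "
                    "AICc not comparable"))
    return SelectionOutcome(groups=groups, incomparable=incomparable)


def model_table(outcome: SelectionOutcome, taxon: str = "") -> pd.DataFrame:
    """Flat CSV-ready table of every fit with selection annotations."""
    rows = []
    for ys, g in outcome.groups.items():
        for f in g["fits"]:
            slopes = {k: v for k, v in f.coefficients.items()
                      if k != "intercept"}
            rows.append({
                "taxon": taxon,
                "variables": f.spec.label(),
                "aicc": f.aicc,
                "p": min(f.slope_pvalues.values()) if f.slope_pvalues
                     else np.nan,
                "n": f.n,
                "intercept": f.coefficients["intercept"],
                "slopes": "; ".join(f"{k}={v:.6g}" for k, v in slopes.items()),
                "boundary_flag": f.boundary_flag,
                "likelihood_mode": f.spec.likelihood,
                "preferred": f is g["preferred"],
                "in_equivalence_class": f in g["equivalence_class"],
            })
    return pd.DataFrame(rows).sort_values(["n", "aicc"],
                                          ascending=[False, True])
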