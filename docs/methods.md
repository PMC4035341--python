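# Methods

## Response: cohort reconstruction and the survival index

All inference is on brood-year cohorts. Spawner counts S_t (fish or
fish/km, from snorkel or carcass surveys) observe calendar-year returns;
recruitment of brood year t is reassembled as

    R_t = sum_{n=k}^{K} p_n(t+n) * S_{t+n}

over the mature return ages (k, K) — (3, 5) for Chinook salmon, (4, 7)
for steelhead. The age proportion p_n is indexed by **return** year
(t+n), under which each return year's spawners partition exactly across
the contributing brood years; the alternative brood-year indexing is a
documented convention switch, not a default. The survival index is
ln(R_t/S_t) (apparent per-spawner production, the linearized-Ricker
response).

Handling of imperfect data, all chosen to avoid fabricating signal:

* Age tables with a within-year proportion sum in [0.9, 1.1] are
  renormalized to 1 (agency tables often omit trace ages); outside that
  band the year counts as unobserved.
* Unobserved composition years receive the arithmetic per-age mean of
  the observed years, renormalized; imputed years are recorded.
* Brood years whose return window extends past the spawner series are
  right-truncated; interior spawner gaps drop the brood year with a
  logged warning — never zero-filled.
* Rows with S_t <= 0 or R_t <= 0 keep their place but carry no survival
  value and are flagged out of all regressions.
* Steelhead iteroparity is not modelled: a returning adult counts once
  per return year. Taxa without their own age data can borrow another
  taxon's composition table year by year (`borrow_ages_from`); a pooled
  average can be supplied as a table if preferred.

## Covariate preparation

Each covariate is declared (YAML) with a transform, optional season and
lag list:

* transforms: identity, ln (requires x > 0), ln(ln x) (x > 1, for
  heavy-tailed hatchery-return counts); out-of-domain years are excluded
  and logged, never clamped;
* seasons: within-calendar-year month subsets with mean or sum (e.g.
  May–June mean for ocean-entry climate indices; July–September summed
  base flow for stream-rearing taxa, September–October for fall-run);
  a year missing any requested month is omitted;
* lags: the value at calendar year t+k is attached to brood year t;
  k = 0 is the unlagged variable, harvest rates use k = 3 and 4 (ages at
  capture), hatchery releases and snow depth k = 1.

Alignment with the response is deliberately two-faced: screening uses
each covariate's own complete-case overlap with survival (so correlation
n varies by covariate — series differ in span), while multi-covariate
models use the intersection of all their columns, recorded in the fit.
AICc comparisons are restricted to identical year sets for this reason.

## Permutation screen

Pearson correlation between survival and each prepared covariate, with
significance from reshuffling the response: two-sided on |r|, default
99,999 permutations, add-one correction p = (hits+1)/(n_perm+1)
(avoids p = 0 and is the standard valid Monte-Carlo form). Pearson
rather than rank correlation because variables are transformed toward
normality first. Plain shuffles do not preserve serial autocorrelation
under the null; a circular block-permutation mode exists but is off by
default. An exhaustive n ≤ 8 enumerator with the same ≥ convention
serves as the oracle in tests. Ranking is by ascending p, ties by
descending |r|; at most `top_k` (default 5) significant covariates are
flagged as the modelling universe. No multiple-testing correction is
applied across covariates — the screen is a candidate filter, and the
output says so. Because published screening tables appear in both
regression orientations, both slopes (survival-on-covariate and
covariate-on-survival) are emitted.

## Mixed-effects models and selection

Candidates: all subsets (size ≤ 3) of the universe after removing, from
any pair correlated above |r| = 0.5, the member with the lower screening
R². Two-way interactions are only generated when explicitly requested.
Each candidate is a linear mixed model: fixed intercept and slopes,
random intercept grouped by calendar year, Gaussian residuals, REML by
default (statsmodels MixedLM, L-BFGS, max 500 iterations).

Two statistical caveats are surfaced rather than hidden:

* With one observation per year the random intercept is confounded with
  the residual — only the variance sum is identified, fixed effects
  reduce to OLS, and the variance split is arbitrary along a ridge. The
  `boundary_flag` marks fits whose random variance is at (or forced to)
  zero; `force_zero_random=True` gives the exact OLS reference fit with
  a REML/ML likelihood evaluated in the same convention (verified
  against MixedLM's own likelihood on ridge designs). An alternative
  grouping (`group_by="cohort:L"`) collapses years into lag-L classes
  (e.g. 3 for Chinook, 1 for steelhead, matching detected survival
  autocorrelation), making the random effect identifiable.
* REML likelihoods across different fixed-effect structures are not
  strictly comparable; the default follows common field practice, and
  `likelihood="ML"` is available for principled AICc comparison.

Selection: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k counting the
intercept, each slope/interaction, and both variance components. Fits
are partitioned by identical year set; ΔAICc < 2 within a partition
defines an equivalence class containing the minimum; the preferred fit
is the simplest in the class (fewest terms, ties by lower AICc). Every
cross-partition pair is reported incomparable — no winner is ever
declared across different n.

## Density dependence

ln(R/S) = α + βS by OLS over unflagged rows; β < 0 with two-sided
t-test p < 0.05 is classified compensatory, else none-detected. Constant
survival returns β = 0, p = 1 exactly (the degenerate regression is not
attempted). A permutation p for the slope can be obtained by reusing the
screening machinery on (S, survival). The closed-loop validator
`simulate_then_recover` simulates, refits and reports bias and 95% CI
coverage per replicate.

## Synthetic-data generator

The generator inverts the analysis: covariates are drawn (stationary
AR(1) for climate-index-like persistence, i.i.d. lognormal for
flow/abundance/hatchery counts, constants for degenerate cases), then

    R_t = S_t exp(alpha + beta*S_t + sum_j gamma_j z_{j,t} + eps_t),
    S_t = sum_n q_n R_{t-n},   eps_t ~ N(0, sigma^2)

with a fixed maturation schedule q_n. Recruitment noise is lognormal
(Normal on the log scale), the standard Ricker stochasticity and the
scale on which the survival index lives. Effects gamma act on the
covariate's model-based z-score (AR(1): stationary mean/sd; lognormal:
log-scale mu/sigma), so gamma is in log-survival units per covariate SD
whatever the covariate's natural units. The emitted age composition is
the *realized* one, p_n(t) = q_n R_{t-n} / S_t, which makes
reconstruction an exact inverse of the generator — the round-trip
identity is tested at 1e-12 relative tolerance. The first K cohorts are
seeded at `init_spawners`; `burn_in` years (default 20) are discarded;
the run aborts if the kept population leaves [1, 1e9].

Default scenario (the study conditions for all calibration tests): a
33-year window starting 1980, ages 3–5 with schedule (0.15, 0.65, 0.20),
alpha = 1.2, beta = −6e−4 (equilibrium 2000 fish, a fall-Chinook-like
escapement), process sigma = 0.4, six covariates named after their real
counterparts of which only flow carries an effect (gamma = 0.5).
Climate indices are written as monthly files (value in May and June) so
the seasonal-aggregation path is exercised end to end.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: observation error in spawner counts is
optional and off by default (real snorkel/carcass estimates carry
substantial, possibly autocorrelated error, which attenuates beta);
age-composition sampling noise (realized compositions are exact);
iteroparity; covariates correlated with each other or with the
population; regime shifts or trends in the drivers.

## Numerical choices

* Permutation p-values use a 1e-12 tie tolerance on |r| so exact
  re-orderings of tied data count as "as extreme".
* Monte-Carlo permutations are generated in 20k-row blocks via argsort
  of uniforms — deterministic for a seeded generator regardless of
  block boundaries.
* MixedLM convergence failures raise with diagnostics; they are not
  silently replaced by OLS. Zero-variance covariates and singular
  designs on the model year set raise before fitting.
* The zero-random-variance REML log-likelihood is computed in closed
  form, −½[(n−p)(ln 2π + ln σ̂² + 1) + ln|XᵀX|], matching statsmodels'
  REML constant convention.
* Random streams derive from `numpy.random.SeedSequence` spawns of the
  user seed; every simulation, permutation and fixture is bit-reproducible
  at a fixed seed (reports byte-identical modulo the optional timestamp).

## Problem sizes used in the shipped studies

Calibration and validation studies run at sizes chosen to give stable
Monte-Carlo estimates while keeping the whole suite fast: type-I-error
calibration at 500 replicates (n = 27, 999 permutations each — the
permutation test is exact at any permutation count, so calibration does
not require the screening default of 99,999); driver-recovery power and
null-selection rate at 200 pipeline replicates; Ricker recovery at 100
replicates of 200-year series; Monte-Carlo-vs-exhaustive agreement at
50 inputs with 99,999 permutations each.

## Known limitations

* The year-grouped random intercept is retained as the default for
  fidelity to common practice, but with annual data it is decorative
  (see above); treat its variance component as meaningless and watch
  `boundary_flag`.
* The screen's per-covariate n differences mean the "top 5" ranking can
  compare p-values computed at different power; this mirrors the
  maximum-data convention rather than a common-year restriction.
* OLS on ln(R/S) vs S is consistent when S is predetermined relative to
  the process noise, but small-sample and errors-in-variables biases
  (survey error in S) pull beta negative; the recovery study quantifies
  the former only.
* Lags are calendar shifts; fractional-year timing (ocean entry in
  spring of t+1) is approximated by integer lags plus seasonal windows.
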