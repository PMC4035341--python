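# salmosurv

Analysis pipeline for identifying drivers of survival in Pacific salmonid
(*Oncorhynchus* spp.) populations from annual spawning-ground counts —
the kind of short (20–35 year) escapement series that watershed agencies
collect for Chinook salmon and steelhead, alongside candidate covariates
such as ocean abundance, ocean harvest rate, hatchery releases and
returns, North Pacific climate indices (PDO, NPGO, MEI), summer base
flow, snow depth and watershed-disturbance indices.

## What it computes

**1. Brood-year cohort reconstruction.** Counts observe returns, not
cohorts. For brood year *t* with mature return ages *k..K* (3–5 for
Chinook, 4–7 for steelhead), recruitment is

&nbsp;&nbsp;&nbsp;&nbsp;R&#8209;t = Σₙ₌ₖ..ₖ pₙ(t+n) · S₍t₊ₙ₎

where S is the spawner count and pₙ the age-n proportion of returns in
year t+n (mean-imputed for unobserved years). The response for all
modelling is the **survival index** ln(R_t/S_t), the log of per-spawner
adult production.

**2. Permutation screening.** Each prepared covariate (transformed,
seasonally aggregated, lagged to the brood year) is correlated with
survival; significance comes from a seeded permutation test (default
99,999 reshuffles, two-sided on |r|, add-one correction). The top
(at most five) significant covariates form the model-building universe.

**3. Mixed-model selection.** Candidate linear mixed-effects models
(random intercept by year, REML) are built under explicit rules: only
screened covariates; no pair correlated above |r| = 0.5 in one model
(the higher-R² member survives); at most three covariates. AICc
(= AIC + 2k(k+1)/(n−k−1)) is compared **only between models fitted to
identical year sets**; within ΔAICc < 2 the simplest model wins.

**4. Ricker density dependence.** The linearized Ricker model
ln(R/S) = α + βS is fitted by OLS; a significantly negative β is
compensatory density dependence.

A synthetic-data generator (`salmosurv.simulate`) inverts the whole
chain — age-structured Ricker dynamics with environmental forcing — so
every stage is testable offline, including exact round-trip recovery of
the latent recruitment.

## Worked example

```sh
salmosurv simulate --seed 3 --out example          # synthetic inputs
salmosurv run --config example/analysis.yaml --seed 7 --out example/out
```

The default scenario is a 33-year Chinook-like population (ages 3–5,
maturation schedule 0.15/0.65/0.20, Ricker α = 1.2, β = −6·10⁻⁴,
process σ = 0.4) with six covariates of which only summer flow has a
real effect (γ = 0.5 per SD of ln flow). The run above prints the
screening table

```
         covariate   n         r       p  significant
            flow@t  28  0.653512  0.0004         True
            npgo@t  28  0.263542  0.1741        False
 ocean_abundance@t  28 -0.152349  0.4355        False
             pdo@t  28  0.126676  0.5231        False
     igh_returns@t  28  0.125985  0.5241        False
             mei@t  28 -0.047034  0.8151        False
```

— the screen finds exactly the planted driver (flow, permutation
p = 0.0004) and nothing else. The one-variable flow model is then the
preferred mixed model (AICc = 75.7, n = 28), and the Ricker fit returns

```
 alpha     beta        r2         p   n  classification
 1.453 -0.000631  0.555074  0.000005  28    compensatory
```

i.e. β̂ = −6.3·10⁻⁴ against a generating value of −6·10⁻⁴: the
density-dependence signal is recovered, and classified compensatory
because β < 0 with p < 0.05. All tables are written as CSV under
`example/out/`.

With real agency data the same `run` command applies: point the YAML
config at `year,value` spawner files, `year,age,proportion` age tables
and annual or monthly covariate files, choosing each covariate's
transform, season and lags.

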