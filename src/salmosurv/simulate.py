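"""Synthetic salmonid populations and covariates.

The generator inverts the analysis chain: it draws environmental
covariates, runs an age-structured Ricker population forward,

    R_t = S_t * exp(alpha + beta*S_t + sum_j gamma_j * z_{j,t} + eps_t),
    S_t = sum_{n=k}^{K} q_n * R_{t-n},          eps_t ~ N(0, sigma^2)

with a fixed maturation schedule q_n over return ages, and emits exactly
the tables the pipeline consumes: a spawner count series, the *realized*
per-return-year age composition (so reconstruction recovers the latent
R_t identically), covariate series and a truth record of every
generating parameter.  Covariate effects gamma_j act on the covariate's
standardized scale z (model-based z-score: AR(1) uses its stationary
mean/sd, lognormal its log-scale mu/sigma), so gamma is log-survival
units per covariate SD regardless of the covariate's natural units.

Defaults mimic the kind of data the pipeline targets: a ~33-year annual
window, Chinook-like return ages 3-5 with schedule (0.15, 0.65, 0.20),
lognormal recruitment noise, autocorrelated climate indices and
lognormal flow/abundance/hatchery series named after their real
counterparts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .series import AgeComposition, AnnualSeries, MonthlySeries

__all__ = [
    "AR1", "Lognormal", "Constant", "SimConfig",
    "simulate_covariate", "simulate_population", "generate_fixture",
    "default_config",
]

EXPLOSION_LIMIT = 1e9
EXTINCTION_LIMIT = 1.0


@dataclass(frozen=True)
class AR1:
    """Stationary Gaussian AR(1): x_t = mean + phi*(x_{t-1}-mean) + N(0, sigma^2)."""
    phi: float
    sigma: float
    mean: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.phi) >= 1:
            raise ValueError(f"AR1 phi={self.phi} is non-stationary")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def marginal_sd(self) -> float:
        return self.sigma / np.sqrt(1 - self.phi ** 2) if self.sigma else 0.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = np.empty(n)
        x[0] = self.mean + (rng.normal(0, self.marginal_sd)
                            if self.sigma else 0.0)
        eps = rng.normal(0, self.sigma, size=n - 1) if self.sigma else np.zeros(n - 1)
        for t in range(1, n):
            x[t] = self.mean + self.phi * (x[t - 1] - self.mean) + eps[t - 1]
        return x

    def standardize(self, x: np.ndarray) -> np.ndarray:
        sd = self.marginal_sd
        return (x - self.mean) / sd if sd else np.zeros_like(x)


@dataclass(frozen=True)
class Lognormal:
    """i.i.d. lognormal draws (flow / abundance-like positive series)."""
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return ((np.log(x) - self.mu) / self.sigma if self.sigma
                else np.zeros_like(x))


@dataclass(frozen=True)
class Constant:
    value: float

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.value)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return np.zeros_like(x)


CovariateModel = AR1 | Lognormal | Constant


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic scenario."""

    n_years: int = 33
    start_year: int = 1980
    age_range: tuple[int, int] = (3, 5)
    mean_proportions: dict[int, float] = field(
        default_factory=lambda: {3: 0.15, 4: 0.65, 5: 0.20})
    ricker_alpha: float = 1.2
    ricker_beta: float = -6e-4          # equilibrium alpha/|beta| = 2000 fish
    covariate_effects: dict[str, float] = field(default_factory=dict)
    covariate_models: dict[str, CovariateModel] = field(default_factory=dict)
    process_sigma: float = 0.4
    obs_noise: float = 0.0              # multiplicative lognormal survey error
    init_spawners: float = 1000.0
    burn_in: int = 20
    seed: int = 0
    taxon: str = "synthetic chinook"

    def __post_init__(self) -> None:
        k, K = self.age_range
        if self.n_years < K + 5:
            raise ValueError(f"n_years={self.n_years} < K+5={K + 5}")
        if self.process_sigma < 0 or self.obs_noise < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.init_spawners <= 0:
            raise ValueError("init_spawners must be positive")
        if set(self.mean_proportions) != set(range(k, K + 1)):
            raise ValueError("mean_proportions must cover exactly the age range")
        total = sum(self.mean_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        unknown = set(self.covariate_effects) - set(self.covariate_models)
        if unknown:
            raise ValueError(f"effects for unmodelled covariates {unknown}")


def simulate_covariate(model: CovariateModel, n_years: int,
                       seed: int) -> AnnualSeries:
    """Draw one covariate series on years 0..n_years-1 (relabel as needed)."""
    rng = np.random.default_rng(seed)
    x = model.draw(n_years, rng)
    return AnnualSeries(name="covariate", unit="index",
                        values={i: float(v) for i, v in enumerate(x)})


def simulate_population(config: SimConfig
                        ) -> tuple[AnnualSeries, AgeComposition,
                                   dict[str, AnnualSeries], dict]:
    """Run the age-structured Ricker model forward.

    Returns (spawners, realized age composition, covariates, truth).
    The composition is the *realized* per-year age structure
    p_n(t) = q_n R_{t-n} / S_t, which makes Eq.-style reconstruction an
    exact inverse of the generator.  The first K simulated cohorts are
    seeded at ``init_spawners``; ``burn_in`` further years are simulated
    and discarded before the kept window of ``n_years`` calendar years
    starting at ``start_year``.

    Raises if the population explodes (> 1e9) or goes extinct (< 1)
    inside the kept window.
    """
    k, K = config.age_range
    ages = list(range(k, K + 1))
    q = np.array([config.mean_proportions[a] for a in ages])

    total = K + config.burn_in + config.n_years
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(len(config.covariate_models) + 2)
    rng_proc = np.random.default_rng(child[0])
    rng_obs = np.random.default_rng(child[1])

    cov_raw: dict[str, np.ndarray] = {}
    cov_z: dict[str, np.ndarray] = {}
    for i, (name, model) in enumerate(sorted(config.covariate_models.items())):
        x = model.draw(total, np.random.default_rng(child[i + 2]))
        cov_raw[name] = x
        cov_z[name] = model.standardize(x)

    eps = (rng_proc.normal(0, config.process_sigma, size=total)
           if config.process_sigma else np.zeros(total))

    R = np.empty(total)
    S = np.full(total, np.nan)
    R[:K] = config.init_spawners
    keep_lo = K + config.burn_in
    first_year = config.start_year - keep_lo  # calendar year of index 0

    for t in range(K, total):
        S[t] = float(sum(q[j] * R[t - ages[j]] for j in range(len(ages))))
        drift = config.ricker_alpha + config.ricker_beta * S[t]
        for name, gamma in config.covariate_effects.items():
            drift += gamma * cov_z[name][t]
        R[t] = S[t] * np.exp(drift + eps[t])
        if t >= keep_lo and not EXTINCTION_LIMIT <= S[t] <= EXPLOSION_LIMIT:
            year = first_year + t
            raise RuntimeError(
                f"population left [{EXTINCTION_LIMIT}, {EXPLOSION_LIMIT:g}] "
                f"at year {year} (S={S[t]:.3g}); adjust alpha/beta/noise")

    kept = range(keep_lo, total)
    obs_factor = (np.exp(rng_obs.normal(0, config.obs_noise, size=total))
                  if config.obs_noise else np.ones(total))

    spawners = AnnualSeries(
        name=f"{config.taxon}_spawners", unit="fish",
        values={first_year + t: float(S[t] * obs_factor[t]) for t in kept})

    props = {}
    for t in kept:
        year = first_year + t
        row = {ages[j]: float(q[j] * R[t - ages[j]] / S[t])
               for j in range(len(ages))}
        props[year] = row
    comp = AgeComposition(taxon=config.taxon, age_range=config.age_range,
                          proportions=props)

    covariates = {
        name: AnnualSeries(name=name, unit="index",
                           values={first_year + t: float(cov_raw[name][t])
                                   for t in kept})
        for name in cov_raw
    }

    truth = {
        "ricker_alpha": config.ricker_alpha,
        "ricker_beta": config.ricker_beta,
        "process_sigma": config.process_sigma,
        "obs_noise": config.obs_noise,
        "covariate_effects": dict(config.covariate_effects),
        "mean_proportions": {int(a): float(p)
                             for a, p in config.mean_proportions.items()},
        "seed": config.seed,
        # brood years reconstructable from the kept spawner window:
        # full return window t+k..t+K inside [keep_lo, total-1]
        "latent_recruits": {first_year + t: float(R[t])
                            for t in range(keep_lo - k, total - K)},
        "latent_spawners": {first_year + t: float(S[t]) for t in kept},
    }
    return spawners, comp, covariates, truth


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default scenario: one true driver (summer flow) among decoys.

    Climate indices are AR(1) (decadal-scale persistence), flow and the
    hatchery/abundance series lognormal.  Only ln-flow carries a real
    effect (gamma = 0.5 log-survival units per SD); everything else is a
    decoy for the screen.
    """
    models: dict[str, CovariateModel] = {
        "ocean_abundance": Lognormal(mu=11.5, sigma=0.6),
        "igh_returns": Lognormal(mu=8.0, sigma=0.7),
        "flow": Lognormal(mu=2.5, sigma=0.5),
        "pdo": AR1(phi=0.7, sigma=0.6),
        "npgo": AR1(phi=0.6, sigma=0.7),
        "mei": AR1(phi=0.4, sigma=0.8),
    }
    cfg = dict(
        covariate_models=models,
        covariate_effects={"flow": 0.5},
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


# ---------------------------------------------------------------------------
# fixture writing

_FMT = "%.10g"
#: climate-category covariates are written as monthly files, with the
#: annual value placed in May and June so a May-June mean recovers it
MONTHLY_NAMES = ("pdo", "npgo", "mei")


def _write_csv(path: Path, header: str, rows) -> None:
    lines = [header] + [",".join(_FMT % v if isinstance(v, float) else str(v)
                                 for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def generate_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete, loadable input set for the pipeline.

    Emits ``spawners.csv`` (year,value), ``age_composition.csv``
    (year,age,proportion), one covariate CSV per series (monthly for the
    climate indices, annual otherwise), an ``analysis.yaml`` config and
    ``truth.json``.  Byte-identical across calls at a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spawners, comp, covariates, truth = simulate_population(config)

    files: dict[str, Path] = {}

    p = outdir / "spawners.csv"
    _write_csv(p, "year,value",
               [(y, spawners[y]) for y in spawners.years])
    files["spawners"] = p

    p = outdir / "age_composition.csv"
    _write_csv(p, "year,age,proportion",
               [(y, a, comp.proportions[y][a])
                for y in sorted(comp.proportions) for a in comp.ages])
    files["age_composition"] = p

    cov_entries = []
    for name, series in sorted(covariates.items()):
        p = outdir / f"{name}.csv"
        monthly = name in MONTHLY_NAMES
        if monthly:
            _write_csv(p, "year,month,value",
                       [(y, m, series[y]) for y in series.years
                        for m in (5, 6)])
        else:
            _write_csv(p, "year,value",
                       [(y, series[y]) for y in series.years])
        files[name] = p
        entry = {
            "name": name,
            "file": p.name,
            "category": "climate" if monthly else (
                "habitat" if name == "flow" else "population"),
            "transform": "ln" if isinstance(
                config.covariate_models[name], Lognormal) else "identity",
            "lags": [0],
        }
        if monthly:
            entry["season"] = {"months": [5, 6], "aggregator": "mean"}
        cov_entries.append(entry)

    import yaml
    analysis = {
        "taxa": [{
            "name": config.taxon,
            "age_range": list(config.age_range),
            "spawner_file": "spawners.csv",
            "age_file": "age_composition.csv",
        }],
        "covariates": cov_entries,
        "screen": {"n_perm": 9999, "alpha": 0.05, "top_k": 5},
        "model": {"likelihood": "REML", "max_vars": 3},
    }
    p = outdir / "analysis.yaml"
    p.write_text(yaml.safe_dump(analysis, sort_keys=True))
    files["analysis"] = p

    p = outdir / "truth.json"
    p.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    files["truth"] = p
    return files
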