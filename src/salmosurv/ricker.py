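"""Linearized Ricker density dependence.

The Ricker stock-recruitment relation R = S exp(alpha + beta*S) becomes
linear on the survival scale: ln(R/S) = alpha + beta*S.  The slope beta
is the density-dependence parameter; a significantly negative beta is
compensatory (negative-feedback) density dependence — per-spawner
production falls as spawner abundance rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import StockRecruitTable

__all__ = ["RickerFit", "fit_ricker", "simulate_then_recover"]

ALPHA_LEVEL = 0.05


@dataclass(frozen=True)
class RickerFit:
    taxon: str
    alpha: float          # intercept of ln(R/S) on S
    beta: float           # slope, per-spawner units
    r2: float
    p_value: float        # two-sided t-test on the slope
    n: int
    classification: str   # "compensatory" | "none-detected"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Ricker fit needs n >= 3")
        expect = ("compensatory"
                  if self.beta < 0 and self.p_value < ALPHA_LEVEL
                  else "none-detected")
        if self.classification != expect:
            raise ValueError(
                f"classification {self.classification!r} inconsistent with "
                f"beta={self.beta}, p={self.p_value}")


def fit_ricker(table: StockRecruitTable) -> RickerFit:
    """OLS of survival ln(R_t/S_t) on spawners S_t.

    Flagged rows (non-positive S or R) are excluded.  Classification is
    "compensatory" iff beta < 0 with p < 0.05, else "none-detected".
    """
    ok = table.rows[~table.rows["flagged"]
                    & np.isfinite(table.rows["survival"])]
    if len(ok) < 3:
        raise ValueError(
            f"{table.taxon}: only {len(ok)} usable rows (need >= 3)")
    s = ok["spawners"].to_numpy(dtype=float)
    surv = ok["survival"].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError(f"{table.taxon}: spawner counts have zero variance")
    if np.ptp(surv) == 0:
        # flat survival: slope exactly 0, no evidence of feedback
        return RickerFit(taxon=table.taxon, alpha=float(surv[0]), beta=0.0,
                         r2=0.0, p_value=1.0, n=len(ok),
                         classification="none-detected")
    fit = stats.linregress(s, surv)
    beta, alpha = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    p = float(fit.pvalue)
    classification = ("compensatory" if beta < 0 and p < ALPHA_LEVEL
                      else "none-detected")
    return RickerFit(taxon=table.taxon, alpha=alpha, beta=beta, r2=r2,
                     p_value=p, n=len(ok), classification=classification)


def ricker_table(fits: list[RickerFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "taxon": f.taxon, "alpha": f.alpha, "beta": f.beta, "r2": f.r2,
        "p": f.p_value, "n": f.n, "classification": f.classification,
    } for f in fits])


def simulate_then_recover(true_alpha: float, true_beta: float, sigma: float,
                          n_years: int, seed: int,
                          n_replicates: int = 1) -> pd.DataFrame:
    """Closed-loop validation: simulate a Ricker population, refit beta.

    Each replicate simulates an age-structured population with the given
    Ricker parameters and process noise, reconstructs recruitment from
    the simulated spawners and compositions, fits the linearized model,
    and reports the estimate, bias and whether the 95% CI covers truth.
    Deterministic given ``seed``.
    """
    from .cohort import build_stock_recruit_table
    from .simulate import SimConfig, simulate_population

    if true_beta > 0:
        raise ValueError("true_beta must be <= 0 (density dependence)")
    if n_years < 20:
        raise ValueError("need n_years >= 20")

    # start off equilibrium so the noiseless case still has contrast in S
    equil = -true_alpha / true_beta if true_beta < 0 else 1000.0
    rows = []
    for rep in range(n_replicates):
        cfg = SimConfig(
            n_years=n_years,
            ricker_alpha=true_alpha, ricker_beta=true_beta,
            process_sigma=sigma,
            init_spawners=0.5 * equil,
            burn_in=0,
            seed=seed + rep,
        )
        spawners, comp, _, truth = simulate_population(cfg)
        table = build_stock_recruit_table("sim", spawners, comp)
        fit = fit_ricker(table)
        ok = table.rows[~table.rows["flagged"]]
        s = ok["spawners"].to_numpy()
        surv = ok["survival"].to_numpy()
        lr = stats.linregress(s, surv)
        half = stats.t.ppf(0.975, fit.n - 2) * lr.stderr
        rows.append({
            "replicate": rep, "seed": seed + rep,
            "beta_true": true_beta, "beta_hat": fit.beta,
            "bias": fit.beta - true_beta,
            "ci_low": fit.beta - half, "ci_high": fit.beta + half,
            "covered": fit.beta - half <= true_beta <= fit.beta + half,
            "alpha_hat": fit.alpha, "r2": fit.r2, "n": fit.n,
        })
    return pd.DataFrame(rows)
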