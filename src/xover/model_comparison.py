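"""Maximum-likelihood fits of the sex-specific gamma and gamma-sprinkling
models, the nested likelihood-ratio / AIC comparison, and per-chromosome
reduced-model (nu-only) fits.

Optimization runs on the transformed scale (log nu, logit p) so the
positivity and (0, 1) constraints are implicit; fits are multi-start
Nelder-Mead with an objective tolerance of 1e-8.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .batched import CellLoglik
from .data_model import SEXES, MeiosisDataset
from .likelihood import GammaParams, StahlParams

__all__ = [
    "FitResult",
    "fit_mle",
    "likelihood_ratio_test",
    "LRTResult",
    "fit_per_chromosome_nu",
    "PerChromosomeFit",
]

_GAMMA_STARTS = [math.log(2.0), math.log(8.0), math.log(20.0)]
_STAHL_STARTS = [
    (math.log(nu), special.logit(p))
    for nu, p in itertools.product((5.0, 12.0, 20.0), (0.005, 0.05))
]


@dataclass
class FitResult:
    model: str  # "gamma" | "stahl"
    params: dict[str, GammaParams | StahlParams]
    loglik: float
    n_free: int
    loglik_by_sex: dict[str, float]
    n_starts_converged: int

    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.loglik


def _fit_cell(cell: CellLoglik, model: str, tol: float = 1e-8):
    """Multi-start MLE for one sex; returns (params, max loglik, n_ok)."""
    if model == "gamma":
        def objective(theta):
            return -cell.loglik(math.exp(theta[0]))
        starts = [[s] for s in _GAMMA_STARTS]
    else:
        def objective(theta):
            return -cell.loglik(math.exp(theta[0]), float(special.expit(theta[1])))
        starts = [list(s) for s in _STAHL_STARTS]
    best, n_ok = None, 0
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-7, "maxiter": 2000},
        )
        if res.success:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"maximum-likelihood fit failed to converge from all starts ({model})"
        )
    if model == "gamma":
        params = GammaParams(nu0=math.exp(best.x[0]))
    else:
        params = StahlParams(nu=math.exp(best.x[0]), p=float(special.expit(best.x[1])))
    return params, -best.fun, n_ok


def fit_mle(
    dataset: MeiosisDataset,
    model: str = "stahl",
    position_resolution: float | None = 1e-3,
    tol: float = 1e-8,
) -> FitResult:
    """Sex-specific MLE of the gamma (nu per sex) or gamma-sprinkling
    (nu, p per sex) model; the two sexes factorize and are fitted
    independently."""
    if model not in ("gamma", "stahl"):
        raise ValueError(f"model must be 'gamma' or 'stahl', got {model!r}")
    params: dict[str, GammaParams | StahlParams] = {}
    ll_by_sex: dict[str, float] = {}
    n_ok = 0
    sexes = [s for s in SEXES if any(c.parent_sex == s for c in dataset.chromatids)]
    for sex in sexes:
        chroms = [c for c in dataset.chromatids if c.parent_sex == sex]
        cell = CellLoglik(chroms, mode=model, position_resolution=position_resolution)
        params[sex], ll_by_sex[sex], ok = _fit_cell(cell, model, tol)
        n_ok += ok
    return FitResult(
        model=model,
        params=params,
        loglik=sum(ll_by_sex.values()),
        n_free=len(sexes) * (1 if model == "gamma" else 2),
        loglik_by_sex=ll_by_sex,
        n_starts_converged=n_ok,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    delta_aic: float


def likelihood_ratio_test(fit_null: FitResult, fit_alt: FitResult,
                          tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same data.

    ``statistic = -2 (ll_null - ll_alt)``, chi-square with df equal to the
    difference in free-parameter counts; ``delta_aic = statistic - 2 df``.
    A materially negative statistic means the alternative optimization
    failed and raises.
    """
    df = fit_alt.n_free - fit_null.n_free
    if df <= 0:
        raise ValueError("fit_alt must have more free parameters than fit_null")
    stat = -2.0 * (fit_null.loglik - fit_alt.loglik)
    if stat < -tol:
        raise RuntimeError(
            f"negative LRT statistic ({stat:.3g}): the alternative fit is worse "
            "than the null, indicating optimization failure"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        delta_aic=stat - 2.0 * df,
    )


@dataclass
class PerChromosomeFit:
    table: pd.DataFrame  # sex, chromosome, length_morgan, nu_hat, n_multi, stable
    spearman_rho: float
    spearman_p: float


def fit_per_chromosome_nu(
    dataset: MeiosisDataset,
    min_multi_chromatids: int = 5,
    position_resolution: float | None = 1e-3,
) -> PerChromosomeFit:
    """Reduced-model (gamma, nu only) MLE per (sex, chromosome) cell and
    the Spearman correlation of nu-hat with sex-specific map length.

    Interference information comes from multi-crossover chromatids; cells
    with fewer than ``min_multi_chromatids`` of them are flagged unstable
    (their estimate is reported but rank-correlation consumers may wish to
    exclude them)."""
    rows = []
    for sex in SEXES:
        by_chrom: dict[str, list] = {}
        for c in dataset.chromatids:
            if c.parent_sex == sex:
                by_chrom.setdefault(c.chromosome, []).append(c)
        for chrom, chroms in by_chrom.items():
            cell = CellLoglik(chroms, mode="gamma",
                              position_resolution=position_resolution)
            res = optimize.minimize_scalar(
                lambda t: -cell.loglik(math.exp(t)),
                bounds=(math.log(0.2), math.log(300.0)),
                method="bounded", options={"xatol": 1e-8},
            )
            n_multi = sum(1 for c in chroms if c.n_crossovers >= 2)
            rows.append({
                "sex": sex, "chromosome": chrom,
                "length_morgan": chroms[0].L,
                "nu_hat": math.exp(res.x),
                "n_multi": n_multi,
                "stable": n_multi >= min_multi_chromatids,
            })
    table = pd.DataFrame(rows)
    rho, p = stats.spearmanr(table["nu_hat"], table["length_morgan"])
    return PerChromosomeFit(table=table, spearman_rho=float(rho), spearman_p=float(p))
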