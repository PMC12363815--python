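"""Hierarchical Bayesian model of interference over groups of meioses and
chromosomes, fitted by Metropolis-coupled MCMC.

The group-cell parameters are linked to additive effects on transformed
scales:

    log nu_ij   = beta0  + beta_i  + beta_j
    logit p_ij  = alpha0 + alpha_i + alpha_j

with i indexing meiosis groups (here parental sex) and j chromosome groups
(a single level, per-chromosome, or size bins).  Group effects get
independent Normal(0, sigma^2) priors with a shared scale per link
(sigma_nu for the beta effects, sigma_p for the alpha effects).  The model
as written is translation-invariant, so effects within each factor are
centred (sum-to-zero by reparameterization) and the intercept carries the
global level.  Priors the group-effect prior does not cover: intercepts
get Normal(0, 5^2) on their transformed scales and the scales get
Half-Normal(1), both overridable in the config.

Sampling uses blocked Gaussian random walks — one block per link, each
holding the intercept, the standardized (non-centred) effects and that
link's log-scale — with the block proposal SDs adapted by Robbins-Monro
during burn-in toward an acceptance rate of 0.6 (rejection around 0.4) and
frozen afterwards.  The non-centred effects (effects = sigma * u with
u given a unit-normal prior) avoid the funnel degeneracy between a
hierarchical scale and its few effects that freezes a centred random-walk
sampler.  ``n_chains`` tempered chains (inverse temperatures on a
geometric ladder) run in parallel, with one random adjacent swap proposal
per iteration; only the cold chain is recorded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .batched import DatasetLoglik
from .likelihood import StahlParams, GammaParams

__all__ = [
    "MCMCConfig",
    "HierarchicalState",
    "PosteriorSamples",
    "link_params",
    "log_prior",
    "log_posterior",
    "run_mc3",
    "mc3_sample",
]


@dataclass
class MCMCConfig:
    iterations: int = 25000
    burn_in: int = 5000
    n_chains: int = 3
    ladder: Sequence[float] | None = None  # default geometric 0.7**c
    seed: int = 0
    model: str = "stahl"  # "stahl" or reduced "gamma" (no escape proportion)
    prior_intercept_sd: float = 5.0
    prior_scale_sd: float = 1.0
    sample_scales: bool = True
    sigma_nu: float = 0.5   # initial value, or fixed value when not sampled
    sigma_p: float = 0.5
    target_acceptance: float = 0.6
    position_resolution: float | None = 1e-3
    init: Mapping[str, float] | None = None

    def resolved_ladder(self) -> np.ndarray:
        if self.ladder is not None:
            lad = np.asarray(self.ladder, dtype=float)
        else:
            lad = 0.7 ** np.arange(self.n_chains)
        if lad[0] != 1.0 or np.any(np.diff(lad) >= 0) or np.any(lad <= 0):
            raise ValueError("temperature ladder must start at 1 and decrease, staying > 0")
        return lad


@dataclass
class HierarchicalState:
    """One point in parameter space, on the constrained (centred) scale."""

    meiosis_groups: tuple[str, ...]
    chromosome_groups: tuple[str, ...]
    beta0: float
    beta_i: np.ndarray
    beta_j: np.ndarray
    alpha0: float
    alpha_i: np.ndarray
    alpha_j: np.ndarray
    sigma_nu: float
    sigma_p: float

    def cell(self, i: str | int, j: str | int) -> tuple[int, int]:
        if isinstance(i, str):
            i = self.meiosis_groups.index(i)
        if isinstance(j, str):
            j = self.chromosome_groups.index(j)
        return i, j


def link_params(state: HierarchicalState, i, j) -> StahlParams:
    """Cell parameters via the log / logit links."""
    i, j = state.cell(i, j)
    nu = math.exp(state.beta0 + state.beta_i[i] + state.beta_j[j])
    p = special.expit(state.alpha0 + state.alpha_i[i] + state.alpha_j[j])
    return StahlParams(nu=nu, p=float(p))


def _half_normal_logpdf(x: float, sd: float) -> float:
    return 0.5 * math.log(2.0 / math.pi) - math.log(sd) - 0.5 * (x / sd) ** 2


def _normal_logpdf(x, sd) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * math.log(2.0 * math.pi) - np.log(sd) - 0.5 * (x / sd) ** 2))


def log_prior(state: HierarchicalState, config: MCMCConfig | None = None) -> float:
    """Log prior: Normal(0, sigma^2) on all centred group effects, weak
    normals on the intercepts, half-normals on sampled scales."""
    config = config or MCMCConfig()
    lp = _normal_logpdf(state.beta0, config.prior_intercept_sd)
    lp += _normal_logpdf(state.beta_i, state.sigma_nu)
    lp += _normal_logpdf(state.beta_j, state.sigma_nu)
    if config.model == "stahl":
        lp += _normal_logpdf(state.alpha0, config.prior_intercept_sd)
        lp += _normal_logpdf(state.alpha_i, state.sigma_p)
        lp += _normal_logpdf(state.alpha_j, state.sigma_p)
    if config.sample_scales:
        lp += _half_normal_logpdf(state.sigma_nu, config.prior_scale_sd)
        if config.model == "stahl":
            lp += _half_normal_logpdf(state.sigma_p, config.prior_scale_sd)
    return lp


def log_posterior(state: HierarchicalState, dataset, config: MCMCConfig | None = None,
                  evaluator: DatasetLoglik | None = None) -> float:
    """Log posterior density (up to a constant) of a state given a dataset."""
    config = config or MCMCConfig()
    if evaluator is None:
        evaluator = DatasetLoglik(dataset, mode=config.model,
                                  position_resolution=None)
    params = {}
    for i in state.meiosis_groups:
        for j in state.chromosome_groups:
            sp = link_params(state, i, j)
            params[(i, j)] = sp if config.model == "stahl" else sp.nu
    return evaluator.loglik(params) + log_prior(state, config)


# ---------------------------------------------------------------------------
# sampler internals: a flat parameterization over free (unconstrained) dims

class _ParamSpace:
    """Mapping between the flat sampling vector and HierarchicalState.

    Factors with g levels contribute g - 1 free raw effects; the g-th is
    the negative sum (sum-to-zero).  Effects enter the model non-centred:
    the flat vector stores standardized effects u with a fixed unit-scale
    prior, and the state's effects are sigma * u.  This removes the funnel
    between a hierarchical scale and its (here, very few) effects that
    defeats a centred random-walk sampler.  Scales are sampled as
    log(sigma) inside the block of their own link, since through the
    non-centred effects they touch the likelihood.
    """

    def __init__(self, meiosis_groups, chromosome_groups, config: MCMCConfig):
        self.mg = tuple(meiosis_groups)
        self.cg = tuple(chromosome_groups)
        self.config = config
        self.model = config.model
        m, n = len(self.mg), len(self.cg)
        scal = 1 if config.sample_scales else 0
        idx = 0
        self.i_beta0 = idx; idx += 1
        self.i_beta_i = slice(idx, idx + max(m - 1, 0)); idx += max(m - 1, 0)
        self.i_beta_j = slice(idx, idx + max(n - 1, 0)); idx += max(n - 1, 0)
        self.i_log_sigma_nu = idx if scal else None
        idx += scal
        beta_end = idx
        if self.model == "stahl":
            self.i_alpha0 = idx; idx += 1
            self.i_alpha_i = slice(idx, idx + max(m - 1, 0)); idx += max(m - 1, 0)
            self.i_alpha_j = slice(idx, idx + max(n - 1, 0)); idx += max(n - 1, 0)
            self.i_log_sigma_p = idx if scal else None
            idx += scal
        self.dim = idx
        self.blocks = [np.arange(0, beta_end)]
        if self.model == "stahl":
            self.blocks.append(np.arange(beta_end, self.dim))
        # every block touches the likelihood under the non-centred scheme
        self.block_touches_lik = [True] * len(self.blocks)

    @staticmethod
    def _center(free: np.ndarray, g: int) -> np.ndarray:
        if g <= 1:
            return np.zeros(g)
        return np.append(free, -free.sum())

    def _sigmas(self, theta: np.ndarray) -> tuple[float, float]:
        cfg = self.config
        if not cfg.sample_scales:
            return cfg.sigma_nu, cfg.sigma_p
        sigma_nu = math.exp(theta[self.i_log_sigma_nu])
        sigma_p = math.exp(theta[self.i_log_sigma_p]) if self.model == "stahl" else cfg.sigma_p
        return sigma_nu, sigma_p

    def to_state(self, theta: np.ndarray) -> HierarchicalState:
        m, n = len(self.mg), len(self.cg)
        sigma_nu, sigma_p = self._sigmas(theta)
        return HierarchicalState(
            meiosis_groups=self.mg,
            chromosome_groups=self.cg,
            beta0=float(theta[self.i_beta0]),
            beta_i=sigma_nu * self._center(theta[self.i_beta_i], m),
            beta_j=sigma_nu * self._center(theta[self.i_beta_j], n),
            alpha0=float(theta[self.i_alpha0]) if self.model == "stahl" else 0.0,
            alpha_i=sigma_p * self._center(theta[self.i_alpha_i], m) if self.model == "stahl" else np.zeros(m),
            alpha_j=sigma_p * self._center(theta[self.i_alpha_j], n) if self.model == "stahl" else np.zeros(n),
            sigma_nu=sigma_nu,
            sigma_p=sigma_p,
        )

    def log_prior(self, theta: np.ndarray) -> float:
        """Prior of the flat vector: unit normals on the centred raw
        effects, weak normals on intercepts, half-normals (plus log
        Jacobian) on sampled scales."""
        cfg = self.config
        m, n = len(self.mg), len(self.cg)
        lp = _normal_logpdf(theta[self.i_beta0], cfg.prior_intercept_sd)
        lp += _normal_logpdf(self._center(theta[self.i_beta_i], m), 1.0)
        lp += _normal_logpdf(self._center(theta[self.i_beta_j], n), 1.0)
        if self.model == "stahl":
            lp += _normal_logpdf(theta[self.i_alpha0], cfg.prior_intercept_sd)
            lp += _normal_logpdf(self._center(theta[self.i_alpha_i], m), 1.0)
            lp += _normal_logpdf(self._center(theta[self.i_alpha_j], n), 1.0)
        if cfg.sample_scales:
            ls = theta[self.i_log_sigma_nu]
            lp += _half_normal_logpdf(math.exp(ls), cfg.prior_scale_sd) + ls
            if self.model == "stahl":
                ls = theta[self.i_log_sigma_p]
                lp += _half_normal_logpdf(math.exp(ls), cfg.prior_scale_sd) + ls
        return lp

    def cell_params(self, state: HierarchicalState):
        out = {}
        for i in self.mg:
            for j in self.cg:
                sp = link_params(state, i, j)
                out[(i, j)] = sp if self.model == "stahl" else sp.nu
        return out

    def initial_theta(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        init = dict(self.config.init or {})
        theta[self.i_beta0] = init.get("beta0", math.log(10.0))
        if self.config.sample_scales:
            theta[self.i_log_sigma_nu] = math.log(init.get("sigma_nu", self.config.sigma_nu))
        if self.model == "stahl":
            theta[self.i_alpha0] = init.get("alpha0", special.logit(0.02))
            if self.config.sample_scales:
                theta[self.i_log_sigma_p] = math.log(init.get("sigma_p", self.config.sigma_p))
        return theta

    def column_names(self) -> list[str]:
        names = ["beta0"]
        names += [f"u_beta_sex[{g}]" for g in self.mg[:-1]] if len(self.mg) > 1 else []
        names += [f"u_beta_chr[{g}]" for g in self.cg[:-1]] if len(self.cg) > 1 else []
        if self.config.sample_scales:
            names.append("log_sigma_nu")
        if self.model == "stahl":
            names += ["alpha0"]
            names += [f"u_alpha_sex[{g}]" for g in self.mg[:-1]] if len(self.mg) > 1 else []
            names += [f"u_alpha_chr[{g}]" for g in self.cg[:-1]] if len(self.cg) > 1 else []
            if self.config.sample_scales:
                names.append("log_sigma_p")
        return names


@dataclass
class PosteriorSamples:
    """Post-burn-in cold-chain draws with summary helpers."""

    draws: pd.DataFrame  # free parameters + log-density bookkeeping
    meiosis_groups: tuple[str, ...]
    chromosome_groups: tuple[str, ...]
    config: MCMCConfig
    ladder: np.ndarray
    block_acceptance: dict[str, float]
    proposal_scales: np.ndarray
    swap_acceptance: np.ndarray  # per adjacent pair
    space: _ParamSpace = field(repr=False)

    def __len__(self) -> int:
        return len(self.draws)

    def states(self):
        cols = self.space.column_names()
        for row in self.draws[cols].to_numpy():
            yield self.space.to_state(row)

    def _cell_draws(self, transform) -> dict[tuple[str, str], np.ndarray]:
        cols = self.space.column_names()
        thetas = self.draws[cols].to_numpy()
        out = {(i, j): np.empty(len(thetas)) for i in self.meiosis_groups
               for j in self.chromosome_groups}
        for t, theta in enumerate(thetas):
            state = self.space.to_state(theta)
            for key in out:
                out[key][t] = transform(link_params(state, *key))
        return out

    def effects_frame(self) -> pd.DataFrame:
        """Model-scale draws: intercepts, centred effects and scales."""
        rows = []
        for state in self.states():
            row = {"beta0": state.beta0, "sigma_nu": state.sigma_nu}
            for g, v in zip(state.meiosis_groups, state.beta_i):
                row[f"beta_sex[{g}]"] = v
            for g, v in zip(state.chromosome_groups, state.beta_j):
                row[f"beta_chr[{g}]"] = v
            if self.config.model == "stahl":
                row["alpha0"] = state.alpha0
                row["sigma_p"] = state.sigma_p
                for g, v in zip(state.meiosis_groups, state.alpha_i):
                    row[f"alpha_sex[{g}]"] = v
                for g, v in zip(state.chromosome_groups, state.alpha_j):
                    row[f"alpha_chr[{g}]"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def nu_draws(self) -> dict[tuple[str, str], np.ndarray]:
        return self._cell_draws(lambda sp: sp.nu)

    def p_draws(self) -> dict[tuple[str, str], np.ndarray]:
        if self.config.model != "stahl":
            raise ValueError("the reduced gamma model has no escape proportion")
        return self._cell_draws(lambda sp: sp.p)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        from .summaries import hpdi

        rows = []
        items = [("nu", self.nu_draws())]
        if self.config.model == "stahl":
            items.append(("p", self.p_draws()))
        for name, draws in items:
            for (i, j), x in draws.items():
                iv = hpdi(x, mass)
                rows.append({
                    "parameter": name, "sex": i, "chromosome_group": j,
                    "mean": x.mean(), "median": np.median(x),
                    "q2.5": np.quantile(x, 0.025), "q25": np.quantile(x, 0.25),
                    "q75": np.quantile(x, 0.75), "q97.5": np.quantile(x, 0.975),
                    "hpdi_lower": iv.lower, "hpdi_upper": iv.upper,
                })
        return pd.DataFrame(rows)

    def diagnostics(self) -> pd.DataFrame:
        """Effective sample size and split R-hat per free parameter."""
        import arviz as az

        cols = self.space.column_names()
        rows = []
        for c in cols:
            x = self.draws[c].to_numpy()
            half = (x.size // 2) * 2
            rows.append({
                "parameter": c,
                "ess_bulk": float(az.ess(x[None, :])),
                "rhat": float(az.rhat(x[:half].reshape(2, -1))),
            })
        return pd.DataFrame(rows)

    def save(self, prefix, extra_meta: dict | None = None) -> dict[str, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {"draws": prefix.with_suffix(".draws.tsv"),
                 "meta": prefix.with_suffix(".meta.json")}
        self.draws.to_csv(paths["draws"], sep="\t", index=False)
        meta = {
            **(extra_meta or {}),
            "config": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                       for k, v in asdict(self.config).items()},
            "meiosis_groups": list(self.meiosis_groups),
            "chromosome_groups": list(self.chromosome_groups),
            "ladder": self.ladder.tolist(),
            "block_acceptance": self.block_acceptance,
            "proposal_scales": self.proposal_scales.tolist(),
            "swap_acceptance": self.swap_acceptance.tolist(),
            "n_draws": len(self.draws),
        }
        paths["meta"].write_text(json.dumps(meta, indent=2, default=str))
        return paths


def mc3_sample(log_parts, theta0: np.ndarray, blocks, config: MCMCConfig,
               rng: np.random.Generator, initial_scales=None):
    """Generic Metropolis-coupled sampler over a flat parameter vector.

    ``log_parts(theta, need_lik) -> (log_lik, log_prior)`` supplies the two
    target components; when a block flagged as not touching the likelihood
    is updated, the kernel reuses the current chain's log-likelihood and
    asks only for the prior (``need_lik=False``, first element ignored).
    ``blocks`` is a list of ``(index_array, touches_likelihood)`` pairs.
    Chain ``c`` targets ``ladder[c] * (log_lik + log_prior)``; one random
    adjacent swap is proposed per iteration.  Exposed separately so toy
    targets (e.g. a bivariate normal) can exercise the identical kernel.

    Returns ``(cold_draws, cold_logdensity, stats)``.
    """
    ladder = config.resolved_ladder()
    n_chains = len(ladder)
    dim = theta0.size
    thetas = [theta0.copy() for _ in range(n_chains)]
    lls = np.empty(n_chains)
    lprs = np.empty(n_chains)
    ll0, lpr0 = log_parts(theta0, True)
    if not np.isfinite(ll0 + lpr0):
        raise ValueError(
            "log posterior is not finite at the initial state; "
            "choose a different initialization"
        )
    lls[:] = ll0
    lprs[:] = lpr0
    n_blocks = len(blocks)
    scales = np.asarray(initial_scales if initial_scales is not None
                        else [0.1] * n_blocks, dtype=float)
    scales = np.tile(scales, (n_chains, 1))
    accept = np.zeros((n_chains, n_blocks))
    swap_acc = np.zeros(max(n_chains - 1, 1))
    swap_att = np.zeros(max(n_chains - 1, 1))
    n_keep = config.iterations - config.burn_in
    cold_draws = np.empty((n_keep, dim))
    cold_lp = np.empty(n_keep)

    for it in range(config.iterations):
        adapting = it < config.burn_in
        for c in range(n_chains):
            for b, (idx, touches_lik) in enumerate(blocks):
                prop = thetas[c].copy()
                prop[idx] += scales[c, b] * rng.standard_normal(idx.size)
                if touches_lik:
                    ll_new, lpr_new = log_parts(prop, True)
                else:
                    lpr_new = log_parts(prop, False)[1]
                    ll_new = lls[c]
                log_ratio = ladder[c] * ((ll_new + lpr_new) - (lls[c] + lprs[c]))
                accepted = np.log(rng.random()) < log_ratio
                if accepted:
                    thetas[c] = prop
                    lls[c], lprs[c] = ll_new, lpr_new
                if not adapting:
                    accept[c, b] += accepted
                else:
                    gamma = 2.0 / (20.0 + it) ** 0.6
                    scales[c, b] *= math.exp(gamma * (float(accepted) - config.target_acceptance))
        if n_chains > 1:
            pair = int(rng.integers(0, n_chains - 1))
            swap_att[pair] += 1
            lp_lo = lls[pair] + lprs[pair]
            lp_hi = lls[pair + 1] + lprs[pair + 1]
            log_ratio = (ladder[pair] - ladder[pair + 1]) * (lp_hi - lp_lo)
            if np.log(rng.random()) < log_ratio:
                thetas[pair], thetas[pair + 1] = thetas[pair + 1], thetas[pair]
                lls[[pair, pair + 1]] = lls[[pair + 1, pair]]
                lprs[[pair, pair + 1]] = lprs[[pair + 1, pair]]
                swap_acc[pair] += 1
        if not adapting:
            cold_draws[it - config.burn_in] = thetas[0]
            cold_lp[it - config.burn_in] = lls[0] + lprs[0]

    stats = {
        "block_acceptance": (accept[0] / max(n_keep, 1)).tolist(),
        "proposal_scales": scales[0],
        "swap_acceptance": np.divide(swap_acc, np.maximum(swap_att, 1)),
        "ladder": ladder,
    }
    return cold_draws, cold_lp, stats


def run_mc3(dataset, config: MCMCConfig | None = None) -> PosteriorSamples:
    """Fit the hierarchical model to a grouped dataset by MC3.

    ``dataset=None`` samples the prior alone (likelihood identically zero),
    which is the standard sanity check that the kernel recovers the prior.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)

    if dataset is not None:
        mg = tuple(sorted(set(dataset.meiosis_group_labels())))
        cg = tuple(sorted(set(dataset.chromosome_group_labels())))
        evaluator = DatasetLoglik(dataset, mode=config.model,
                                  position_resolution=config.position_resolution)
    else:
        mg, cg = ("female", "male"), ("all",)
        evaluator = None
    space = _ParamSpace(mg, cg, config)

    def log_parts(theta, need_lik):
        lp_prior = space.log_prior(theta)
        if evaluator is None or not need_lik:
            return 0.0, lp_prior
        state = space.to_state(theta)
        return evaluator.loglik(space.cell_params(state)), lp_prior

    theta0 = space.initial_theta()
    blocks = list(zip(space.blocks, space.block_touches_lik))
    if evaluator is None:
        blocks = [(idx, False) for idx, _ in blocks]
    init_scales = [0.05] * len(blocks)

    draws, lp, stats = mc3_sample(log_parts, theta0, blocks, config, rng,
                                  initial_scales=init_scales)
    cols = space.column_names()
    frame = pd.DataFrame(draws, columns=cols)
    frame["log_posterior"] = lp
    if config.sample_scales:
        frame["sigma_nu"] = np.exp(frame["log_sigma_nu"])
        if config.model == "stahl":
            frame["sigma_p"] = np.exp(frame["log_sigma_p"])
    block_names = ["beta"] + (["alpha"] if config.model == "stahl" else [])
    return PosteriorSamples(
        draws=frame,
        meiosis_groups=mg,
        chromosome_groups=cg,
        config=config,
        ladder=stats["ladder"],
        block_acceptance=dict(zip(block_names, stats["block_acceptance"])),
        proposal_scales=stats["proposal_scales"],
        swap_acceptance=stats["swap_acceptance"],
        space=space,
    )
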