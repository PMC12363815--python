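"""Posterior summaries: HPD intervals, sex/size contrasts, and posterior
predictive checks of the inter-crossover distance distribution."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MeiosisDataset
from .likelihood import StahlParams

__all__ = ["HPDInterval", "hpdi", "contrasts", "posterior_predictive_check",
           "PredictiveCheck"]


@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    mass: float = 0.95


def hpdi(samples, mass: float = 0.95) -> HPDInterval:
    """Highest posterior density interval from draws.

    Shortest contiguous window of ``ceil(mass * N)`` sorted draws; ties go
    to the leftmost window.  Requires at least 100 draws.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"hpdi needs >= 100 draws, got {n}")
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    w = math.ceil(mass * n)
    if w >= n:
        return HPDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin takes the first of ties
    return HPDInterval(float(x[i]), float(x[i + w - 1]), mass)


def _ratio_row(name: str, within: str, num: np.ndarray, den: np.ndarray,
               mass: float) -> dict:
    r = num / den
    iv = hpdi(r, mass)
    return {
        "contrast": name, "within": within,
        "posterior_mean": float(r.mean()), "posterior_median": float(np.median(r)),
        "hpdi_lower": iv.lower, "hpdi_upper": iv.upper, "mass": mass,
    }


def contrasts(samples, mass: float = 0.95) -> pd.DataFrame:
    """Posterior ratio contrasts from hierarchical draws.

    Always reports male/female ratios of nu (and p, if the sprinkling
    model was fitted) within each chromosome group; when the grouping has
    ``short`` and ``long`` size bins, also reports short/long ratios
    within each sex.
    """
    param_draws = {"nu": samples.nu_draws()}
    if samples.config.model == "stahl":
        param_draws["p"] = samples.p_draws()
    rows = []
    for name, draws in param_draws.items():
        for j in samples.chromosome_groups:
            if "male" in samples.meiosis_groups and "female" in samples.meiosis_groups:
                rows.append(_ratio_row(
                    f"{name}_male/{name}_female", j,
                    draws[("male", j)], draws[("female", j)], mass,
                ))
        if {"short", "long"} <= set(samples.chromosome_groups):
            for i in samples.meiosis_groups:
                rows.append(_ratio_row(
                    f"{name}_short/{name}_long", i,
                    draws[(i, "short")], draws[(i, "long")], mass,
                ))
    return pd.DataFrame(rows)


@dataclass
class PredictiveCheck:
    """Observed versus posterior-predictive inter-crossover distances."""

    bin_edges_cM: np.ndarray
    observed_density: np.ndarray
    predictive_density_mean: np.ndarray
    observed_mean_cM: float
    observed_sd_cM: float
    predictive_mean_cM: float
    predictive_sd_cM: float
    per_rep_means_cM: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left_cM": self.bin_edges_cM[:-1],
            "bin_right_cM": self.bin_edges_cM[1:],
            "observed_density": self.observed_density,
            "predictive_density": self.predictive_density_mean,
        })


def _adjacent_gaps_cM(dataset: MeiosisDataset) -> np.ndarray:
    gaps = [np.diff(c.positions) for c in dataset.chromatids if c.n_crossovers >= 2]
    return np.concatenate(gaps) * 100.0 if gaps else np.empty(0)


def posterior_predictive_check(
    samples,
    dataset: MeiosisDataset,
    n_reps: int = 50,
    bin_width_cM: float = 5.0,
    seed: int = 0,
) -> PredictiveCheck:
    """Simulate replicate datasets of the observed design from posterior
    draws and compare inter-crossover distance distributions.

    For each of ``n_reps`` draws (evenly thinned from the chain) a dataset
    with the same meiosis counts, maps and grouping is simulated at that
    draw's cell parameters.  The comparison is descriptive — binned
    densities and moments — not a formal test.
    """
    from .simulate import SimDesign, simulate_dataset

    rng = np.random.default_rng(seed)
    observed = _adjacent_gaps_cM(dataset)
    hi = max(observed.max(initial=0.0), 100.0)
    edges = np.arange(0.0, hi + bin_width_cM, bin_width_cM)
    obs_density = np.histogram(observed, bins=edges, density=True)[0] \
        if observed.size else np.zeros(len(edges) - 1)

    manifest = dataset.manifest()
    n_per_sex = manifest.groupby("sex")["meiosis_id"].nunique().to_dict()
    gmap = dataset.genetic_map()
    nu_draws = samples.nu_draws()
    p_draws = samples.p_draws() if samples.config.model == "stahl" else None

    take = np.linspace(0, len(samples) - 1, n_reps).astype(int)
    densities = np.zeros((n_reps, len(edges) - 1))
    means = np.empty(n_reps)
    all_gaps = []
    for r, t in enumerate(take):
        params = {}
        for key in nu_draws:
            p = float(p_draws[key][t]) if p_draws is not None else 1e-12
            params[key] = StahlParams(nu=float(nu_draws[key][t]), p=max(p, 1e-12))
        design = SimDesign(
            n_meioses_per_sex=n_per_sex, genetic_map=gmap, params=params,
            chromosome_grouping=dataset.chromosome_grouping,
        )
        rep = simulate_dataset(design, rng=rng)
        gaps = _adjacent_gaps_cM(rep)
        if gaps.size:
            densities[r] = np.histogram(gaps, bins=edges, density=True)[0]
            means[r] = gaps.mean()
            all_gaps.append(gaps)
        else:
            means[r] = np.nan
    pooled = np.concatenate(all_gaps) if all_gaps else np.empty(0)
    return PredictiveCheck(
        bin_edges_cM=edges,
        observed_density=obs_density,
        predictive_density_mean=densities.mean(axis=0),
        observed_mean_cM=float(observed.mean()) if observed.size else float("nan"),
        observed_sd_cM=float(observed.std(ddof=1)) if observed.size > 1 else float("nan"),
        predictive_mean_cM=float(pooled.mean()) if pooled.size else float("nan"),
        predictive_sd_cM=float(pooled.std(ddof=1)) if pooled.size > 1 else float("nan"),
        per_rep_means_cM=means,
    )
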