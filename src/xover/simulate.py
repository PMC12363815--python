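"""Forward simulation of crossovers under the gamma-sprinkling model.

Chiasmata are laid down on the four-strand bundle as a stationary gamma
renewal process (shape ``nu``, rate ``2 * nu * (1 - p)``), thinned 1/2 per
chiasma to give the crossovers on one transmitted chromatid, and a
homogeneous Poisson process of rate ``p`` per Morgan is superposed for the
crossovers that escape interference.  Setting ``p = 0`` gives the plain
gamma model; ``nu = 1`` gives a unit-rate Poisson process either way.

Stationarity is achieved by default by starting the renewal process a
burn-in distance before the chromosome and discarding pre-origin events;
drawing the first arrival from the analytic equilibrium (residual-life)
distribution is available as an alternative.

The module doubles as the synthetic-data generator: the default design
emulates the Collaborative Cross study population — 474 scored meioses per
parental sex over 19 autosomes, with sex-specific maps totalling 1355 cM
(female) and 1221 cM (male) and chromosome lengths declining from chr1 to
chr19.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, special

from .data_model import (
    FEMALE,
    MALE,
    SEXES,
    ChromatidCrossovers,
    GeneticMap,
    MeiosisDataset,
    size_bin,
)
from .likelihood import GammaParams, StahlParams

__all__ = [
    "SimDesign",
    "simulate_positions",
    "simulate_chromatid",
    "simulate_dataset",
    "default_cc_map",
    "default_cc_design",
]

# Paper-population design constants: map totals in Morgans and the study's
# scored-meiosis count per parental sex.
CC_TOTAL_MORGANS = {FEMALE: 13.55, MALE: 12.21}
CC_MEIOSES_PER_SEX = 474
CC_N_AUTOSOMES = 19

# Published sex-specific gamma-sprinkling estimates for the house mouse,
# used as the default generating truth for synthetic datasets.
MOUSE_TRUTH = {
    FEMALE: StahlParams(nu=11.2, p=0.0094),
    MALE: StahlParams(nu=18.6, p=0.027),
}


def _as_nu_p(params) -> tuple[float, float]:
    if isinstance(params, GammaParams):
        return params.nu0, 0.0
    if isinstance(params, StahlParams):
        return params.nu, params.p
    nu, p = params
    return float(nu), float(p)


def _equilibrium_first_arrival(nu: float, b: float, rng: np.random.Generator) -> float:
    """Draw the distance to the first chiasma at stationarity by inverting
    the residual-life CDF ``lam_c * [t Q(nu, bt) + (nu/b) P(nu+1, bt)]``."""
    lam_c = b / nu
    u = rng.random()

    def cdf_minus_u(t: float) -> float:
        bt = b * t
        integral = t * special.gammaincc(nu, bt) + (nu / b) * special.gammainc(nu + 1.0, bt)
        return lam_c * integral - u

    hi = 1.0 / lam_c
    while cdf_minus_u(hi) < 0:
        hi *= 2.0
    return optimize.brentq(cdf_minus_u, 0.0, hi, xtol=1e-12)


def simulate_positions(
    L: float,
    nu: float,
    p: float,
    rng: np.random.Generator,
    equilibrium: str = "burnin",
) -> np.ndarray:
    """Sorted crossover positions (Morgans) on one chromatid of length L."""
    if L <= 0:
        raise ValueError(f"chromosome length must be > 0, got {L}")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"escape proportion p must be in [0, 1), got {p}")
    lam_i = 1.0 - p
    b = 2.0 * nu * lam_i  # chiasma renewal rate; mean gap nu/b = 1/(2*lam_i)
    if equilibrium == "burnin":
        # >= 20 mean inter-arrivals of pre-origin process
        start = -20.0 * (0.5 / lam_i)
    elif equilibrium == "analytic":
        start = _equilibrium_first_arrival(nu, b, rng)
    else:
        raise ValueError(f"equilibrium must be 'burnin' or 'analytic', got {equilibrium!r}")

    chiasmata = []
    t = start
    if equilibrium == "analytic" and t <= L:
        chiasmata.append(t)
    batch = max(16, int(2.2 * lam_i * (L - min(start, 0.0))) + 8)
    while t <= L:
        gaps = rng.gamma(nu, scale=1.0 / b, size=batch)
        pts = t + np.cumsum(gaps)
        chiasmata.extend(pts[pts <= L])
        t = pts[-1]
    chiasmata = np.asarray(chiasmata)
    chiasmata = chiasmata[chiasmata >= 0.0]
    kept = chiasmata[rng.random(chiasmata.size) < 0.5]  # no chromatid interference
    n_escape = rng.poisson(p * L)
    escaped = rng.random(n_escape) * L
    return np.sort(np.concatenate([kept, escaped]))


def simulate_chromatid(
    L: float,
    params,
    rng: np.random.Generator,
    meiosis_id: str = "sim",
    parent_sex: str = FEMALE,
    chromosome: str = "1",
    equilibrium: str = "burnin",
) -> ChromatidCrossovers:
    """Simulate one transmitted chromatid under gamma(-sprinkling) params."""
    nu, p = _as_nu_p(params)
    pos = simulate_positions(L, nu, p, rng, equilibrium=equilibrium)
    return ChromatidCrossovers(meiosis_id, parent_sex, chromosome, pos, L)


def default_cc_map(
    totals_morgan: Mapping[str, float] | None = None,
    n_chromosomes: int = CC_N_AUTOSOMES,
) -> GeneticMap:
    """Synthetic sex-specific map: per-chromosome lengths decline linearly
    from chr1 to chr19 and sum to the study totals per sex."""
    totals = dict(totals_morgan or CC_TOTAL_MORGANS)
    weights = np.linspace(1.35, 0.65, n_chromosomes)
    weights /= weights.sum()
    lengths = {}
    for sex, total in totals.items():
        for i, w in enumerate(weights, start=1):
            lengths[(str(i), sex)] = total * w
    return GeneticMap(lengths)


@dataclass
class SimDesign:
    """A synthetic study design: who was scored, on what map, under which
    generating parameters per (sex, chromosome-group) cell."""

    n_meioses_per_sex: Mapping[str, int]
    genetic_map: GeneticMap
    params: Mapping[tuple[str, str], StahlParams]
    chromosome_grouping: str = "none"
    seed: int | None = None
    equilibrium: str = "burnin"

    def cell_params(self, sex: str, chromosome: str) -> StahlParams:
        if self.chromosome_grouping == "none":
            group = "all"
        elif self.chromosome_grouping == "per-chromosome":
            group = chromosome
        else:
            group = size_bin(chromosome)
        return self.params[(sex, group)]


def default_cc_design(
    params: Mapping[str, StahlParams] | None = None,
    n_meioses_per_sex: int = CC_MEIOSES_PER_SEX,
    seed: int | None = None,
) -> SimDesign:
    """CC-like design at the published sex-specific mouse estimates."""
    truth = dict(params or MOUSE_TRUTH)
    return SimDesign(
        n_meioses_per_sex={sex: n_meioses_per_sex for sex in SEXES},
        genetic_map=default_cc_map(),
        params={(sex, "all"): truth[sex] for sex in SEXES},
        chromosome_grouping="none",
        seed=seed,
    )


def simulate_dataset(design: SimDesign, rng: np.random.Generator | None = None) -> MeiosisDataset:
    """Simulate one chromatid per (meiosis, chromosome); deterministic under
    a fixed design seed."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    chromatids = []
    for sex in design.n_meioses_per_sex:
        chroms = design.genetic_map.chromosomes(sex)
        for idx in range(design.n_meioses_per_sex[sex]):
            meiosis_id = f"{sex[0]}{idx + 1:04d}"
            for chrom in chroms:
                L = design.genetic_map.length(chrom, sex)
                cell = design.cell_params(sex, chrom)
                pos = simulate_positions(L, cell.nu, cell.p, rng, design.equilibrium)
                chromatids.append(ChromatidCrossovers(meiosis_id, sex, chrom, pos, L))
    return MeiosisDataset(chromatids, design.chromosome_grouping)
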