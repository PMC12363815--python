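"""Renewal-process likelihoods for crossover interference.

The chiasma process on the four-strand bundle is modelled as a stationary
gamma renewal process with shape ``nu`` (the interference parameter) and
rate ``2 * nu * lam``, where ``lam`` is the resulting *crossover* rate per
Morgan on a transmitted chromatid.  Each chiasma is resolved on a given
chromatid with probability 1/2, independently (no chromatid interference),
so the crossover process on the chromatid is itself a stationary renewal
process with inter-arrival density

    g(x) = sum_{k>=1} 2**(-k) * GammaPDF(x; shape k*nu, rate 2*nu*lam)

and event rate ``lam``.  For the plain gamma model ``lam = 1`` (one
crossover per Morgan, by definition of map distance).  Under the
gamma-sprinkling (Housworth-Stahl) model a proportion ``p`` of crossovers
escape interference: the interfering component runs at rate ``1 - p`` and a
homogeneous Poisson process of rate ``p`` is superposed on it.

``nu = 1`` collapses everything to a Poisson process: the mixture telescopes
to an exponential density and every likelihood below reduces to ``-L``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "GammaParams",
    "StahlParams",
    "interarrival_density",
    "interarrival_survival",
    "interarrival_cdf",
    "survival_integral",
    "no_event_logprob",
    "loglik_gamma",
    "loglik_stahl",
    "total_loglik",
]

# Mixture-series truncation: stop once three consecutive terms contribute
# less than REL_TOL relative to the running sum; the 2**(-k) weights make
# the tail geometric, the cap guards pathological shapes.
REL_TOL = 1e-13
MAX_TERMS = 200

_LOG_HALF = math.log(0.5)


@dataclass(frozen=True)
class GammaParams:
    """Interference strength under the plain gamma model (``nu0 > 0``)."""

    nu0: float

    def __post_init__(self) -> None:
        if not self.nu0 > 0:
            raise ValueError(f"interference shape nu0 must be > 0, got {self.nu0}")


@dataclass(frozen=True)
class StahlParams:
    """Gamma-sprinkling parameters: interference strength ``nu`` and
    escape proportion ``p`` strictly inside (0, 1)."""

    nu: float
    p: float

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"interference shape nu must be > 0, got {self.nu}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"escape proportion p must be in (0, 1), got {self.p}")


def _check_nu(nu: float) -> None:
    if not nu > 0:
        raise ValueError(f"interference shape nu must be > 0, got {nu}")


def mixture_logpdf_logsf(x, nu: float, rate: float):
    """Log-density and log-survival of the thinned-gamma inter-arrival mixture.

    Both series have positive terms and are accumulated with logaddexp so
    that shape/rate combinations which underflow a linear sum still return a
    finite log value where one exists.  Vectorized over ``x``.
    """
    _check_nu(nu)
    x = np.asarray(x, dtype=float)
    bx = rate * x
    log_pdf = np.full_like(x, -np.inf, dtype=float)
    log_sf = np.full_like(x, -np.inf, dtype=float)
    quiet = 0
    for k in range(1, MAX_TERMS + 1):
        a = k * nu
        lw = k * _LOG_HALF
        with np.errstate(divide="ignore", invalid="ignore"):
            term_pdf = (
                lw + a * math.log(rate) + special.xlogy(a - 1.0, x) - bx - special.gammaln(a)
            )
            term_sf = lw + np.log(special.gammaincc(a, bx))
        new_pdf = np.logaddexp(log_pdf, term_pdf)
        new_sf = np.logaddexp(log_sf, term_sf)
        with np.errstate(invalid="ignore"):
            rel = max(
                np.nan_to_num(np.exp(term_pdf - new_pdf), nan=0.0).max(initial=0.0),
                np.nan_to_num(np.exp(term_sf - new_sf), nan=0.0).max(initial=0.0),
            )
        log_pdf, log_sf = new_pdf, new_sf
        quiet = quiet + 1 if rel < REL_TOL else 0
        if quiet >= 3:
            break
    return log_pdf, log_sf


def interarrival_density(x, nu: float, rate_scale: float = 1.0):
    """Density g(x) of the distance between successive crossovers.

    ``rate_scale`` is the crossover rate per Morgan (1 for the plain gamma
    model, ``1 - p`` for the interfering component of the sprinkling model).
    """
    logg, _ = mixture_logpdf_logsf(x, nu, 2.0 * nu * rate_scale)
    out = np.exp(logg)
    return out if out.ndim else float(out)


def interarrival_survival(x, nu: float, rate_scale: float = 1.0):
    """Survival S(x) = P(inter-crossover distance > x)."""
    _, logs = mixture_logpdf_logsf(x, nu, 2.0 * nu * rate_scale)
    out = np.exp(logs)
    return out if out.ndim else float(out)


def survival_integral(L, nu: float, rate: float):
    """``int_0^L S(t) dt`` for the mixture with gamma rate ``rate``.

    Uses the per-term closed form
    ``int_0^L (1 - F(t; a, b)) dt = L * (1 - F(L; a, b)) + (a/b) * F(L; a+1, b)``,
    so the sum has only positive terms.  As ``L -> inf`` this tends to the
    mean inter-arrival ``1 / lam``.  Vectorized over ``L``.
    """
    _check_nu(nu)
    L = np.asarray(L, dtype=float)
    bL = rate * L
    total = np.zeros_like(L, dtype=float)
    quiet = 0
    for k in range(1, MAX_TERMS + 1):
        a = k * nu
        w = 0.5**k
        term = w * (L * special.gammaincc(a, bL) + (a / rate) * special.gammainc(a + 1.0, bL))
        total = total + term
        rel = np.max(term / np.maximum(total, np.finfo(float).tiny), initial=0.0)
        quiet = quiet + 1 if rel < REL_TOL else 0
        if quiet >= 3:
            break
    return total if total.ndim else float(total)


def no_event_logprob(L, nu: float, rate_scale: float = 1.0):
    """Log-probability that a chromatid of length ``L`` Morgans carries no
    crossover from the stationary renewal component of rate ``rate_scale``.

    ``P(k=0) = 1 - lam * int_0^L S(t) dt``; when that difference cancels
    catastrophically (very long L) the equivalent tail form
    ``lam * int_L^inf S`` is used instead.
    """
    lam = rate_scale
    b = 2.0 * nu * lam
    L = np.asarray(L, dtype=float)
    direct = 1.0 - lam * survival_integral(L, nu, b)
    if np.all(direct > 1e-12):
        out = np.log(direct)
        return out if out.ndim else float(out)
    # tail form: lam * sum_k 2^-k int_L^inf (1 - F_k)
    total = np.zeros_like(L, dtype=float)
    quiet = 0
    bL = b * L
    for k in range(1, MAX_TERMS + 1):
        a = k * nu
        w = 0.5**k
        term = w * ((a / b) * special.gammaincc(a + 1.0, bL) - L * special.gammaincc(a, bL))
        term = np.maximum(term, 0.0)
        total = total + term
        rel = np.max(term / np.maximum(total, np.finfo(float).tiny), initial=0.0)
        quiet = quiet + 1 if rel < REL_TOL else 0
        if quiet >= 3:
            break
    with np.errstate(divide="ignore"):
        out = np.log(lam * total)
    return out if out.ndim else float(out)


def interarrival_cdf(x, nu: float, p: float = 0.0):
    """Stationary inter-crossover distance CDF on a chromatid.

    For ``p = 0`` this is the mixture CDF ``G`` of the thinned gamma
    process at unit rate.  For ``p > 0`` it is the exact Palm inter-arrival
    CDF of the superposition of the interfering component (rate ``1 - p``)
    and the escaping Poisson component (rate ``p``): conditioning on the
    component of the event at the origin,

        S_merged(t) = e^{-pt} [ (1-p) S_I(t) + p (1 - (1-p) int_0^t S_I) ].
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p}")
    x = np.asarray(x, dtype=float)
    lam_i = 1.0 - p
    b = 2.0 * nu * lam_i
    _, logs = mixture_logpdf_logsf(x, nu, b)
    s_i = np.exp(logs)
    if p == 0.0:
        out = 1.0 - s_i
        return out if out.ndim else float(out)
    resid = 1.0 - lam_i * survival_integral(x, nu, b)  # residual-life survival
    s_merged = np.exp(-p * x) * (lam_i * s_i + p * resid)
    out = 1.0 - s_merged
    return out if out.ndim else float(out)


def _renewal_logdensity(positions: np.ndarray, L: float, nu: float, lam: float) -> float:
    """Log stationary-renewal likelihood of ordered positions on [0, L].

    k = 0: log(1 - lam * int_0^L S);  k >= 1:
    log[ lam * S(x1) * prod g(x_i - x_{i-1}) * S(L - x_k) ].
    """
    k = len(positions)
    if k == 0:
        return float(no_event_logprob(L, nu, lam))
    b = 2.0 * nu * lam
    x = np.asarray(positions, dtype=float)
    gaps = np.diff(x)
    logg, _ = mixture_logpdf_logsf(gaps, nu, b)
    _, logs = mixture_logpdf_logsf(np.array([x[0], L - x[-1]]), nu, b)
    return math.log(lam) + float(logs.sum() + logg.sum())


def _validate_chromatid(positions, L: float) -> np.ndarray:
    x = np.asarray(positions, dtype=float)
    if x.size and (np.any(np.diff(x) <= 0) or x[0] < 0 or x[-1] > L):
        raise ValueError(
            f"positions must be strictly increasing within [0, L={L}]: {x.tolist()}"
        )
    return x


def loglik_gamma(positions, L: float, nu: float, rate_scale: float = 1.0) -> float:
    """Exact log-likelihood of crossover positions on one chromatid under
    the gamma model with interference shape ``nu``.

    ``positions`` are in Morgans, strictly increasing within ``[0, L]``;
    an empty sequence is the (informative) zero-crossover outcome.
    """
    _check_nu(nu)
    x = _validate_chromatid(positions, L)
    return _renewal_logdensity(x, L, nu, rate_scale)


def loglik_stahl(
    positions, L: float, nu: float, p: float, max_crossovers: int = 10
) -> float:
    """Exact log-likelihood under the gamma-sprinkling (Housworth-Stahl) model.

    Sums over all 2**k assignments of the observed crossovers to the
    interfering component (a gamma renewal process at rate ``1 - p``) versus
    the escaping Poisson component (rate ``p``); the sum is accumulated in
    log space.  Cost is O(2**k), hence the ``max_crossovers`` cap.
    """
    _check_nu(nu)
    if not 0.0 < p < 1.0:
        raise ValueError(f"escape proportion p must be in (0, 1), got {p}")
    x = _validate_chromatid(positions, L)
    k = x.size
    if k > max_crossovers:
        raise ValueError(
            f"{k} crossovers on one chromatid exceeds the subset-sum cap "
            f"({max_crossovers}); review the data or raise max_crossovers"
        )
    lam_i = 1.0 - p
    logp = math.log(p)
    terms = []
    for mask in itertools.product((False, True), repeat=k):
        sub = x[np.fromiter(mask, bool, count=k)] if k else x
        terms.append(_renewal_logdensity(sub, L, nu, lam_i) + (k - len(sub)) * logp)
    return float(special.logsumexp(terms)) - p * L


def total_loglik(dataset, params_by_cell) -> float:
    """Sum of per-chromatid sprinkling log-likelihoods over a dataset.

    ``params_by_cell`` maps each (meiosis-group, chromosome-group) label
    pair to :class:`StahlParams`; chromatids are conditionally independent
    given the parameters.
    """
    total = 0.0
    for chromatid, cell in zip(dataset.chromatids, dataset.cell_labels()):
        try:
            params = params_by_cell[cell]
        except KeyError:
            raise KeyError(f"no parameters supplied for group cell {cell!r}") from None
        total += loglik_stahl(chromatid.positions, chromatid.L, params.nu, params.p)
    return total
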