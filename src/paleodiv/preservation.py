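"""Fossil preservation likelihoods.

A species alive over the age interval [te, ts] leaves fossil occurrences
according to a Poisson process whose intensity may be

* constant over the lifespan (HPP, rate q per lineage-Myr),
* hump-shaped over the lifespan (NHPP): intensity q * Beta(u; a, a) with
  u the relative position within the lifespan, so fossils are least likely
  to form right after origination and right before extinction when
  population size is low (a > 1),
* piecewise-constant in absolute time (TPP): one rate per 1-Myr bin.

All likelihoods condition on the species being sampled at all (>= 1
occurrence), and across-lineage rate heterogeneity is modelled by a
discretized mean-one gamma distribution of per-species rate multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "PreservationModel",
    "hpp_loglik",
    "nhpp_loglik",
    "tpp_loglik",
    "gamma_category_multipliers",
    "gamma_mixture_loglik",
    "default_bin_edges",
]


class PreservationDomainError(ValueError):
    """Occurrence outside the species' lifespan, or degenerate lifespan."""


def _log1mexp(x: np.ndarray | float):
    """log(1 - exp(-x)) for x > 0, stable for both small and large x."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(
            x < 0.693, np.log(-np.expm1(-np.minimum(x, 0.693))), np.log1p(-np.exp(-x))
        )
    return out if out.ndim else float(out)


def _check_span(occ_ages: np.ndarray, ts: float, te: float) -> np.ndarray:
    occ_ages = np.asarray(occ_ages, dtype=float)
    if occ_ages.size < 1:
        raise PreservationDomainError(
            "conditioned preservation likelihood requires >= 1 occurrence"
        )
    if np.any(occ_ages > ts) or np.any(occ_ages < te):
        raise PreservationDomainError(
            f"occurrence age outside lifespan [{te}, {ts}]"
        )
    return occ_ages


def hpp_loglik(occ_ages, ts: float, te: float, q: float) -> float:
    """Homogeneous Poisson preservation, conditioned on >= 1 occurrence.

    k log q - q (ts - te) - log(1 - exp(-q (ts - te)))
    """
    occ_ages = _check_span(occ_ages, ts, te)
    if not q > 0:
        raise ValueError(f"q must be > 0, got {q}")
    span = ts - te
    if span <= 0:
        raise PreservationDomainError("degenerate lifespan (ts == te)")
    k = occ_ages.size
    return float(k * np.log(q) - q * span - _log1mexp(q * span))


def nhpp_loglik(occ_ages, ts: float, te: float, q: float, alpha: float) -> float:
    """Lifespan-varying (non-homogeneous) Poisson preservation.

    Intensity at age t is q * B(u; alpha, alpha) with u = (ts - t)/(ts - te)
    and B the symmetric beta density on [0, 1]; the expected number of
    occurrences over the whole lifespan is q (ts - te) regardless of alpha.
    alpha = 1 reduces exactly to the homogeneous case.
    """
    occ_ages = _check_span(occ_ages, ts, te)
    if not q > 0 or not alpha > 0:
        raise ValueError("q and alpha must be > 0")
    span = ts - te
    if span <= 0:
        raise PreservationDomainError("degenerate lifespan (ts == te)")
    u = (ts - occ_ages) / span
    with np.errstate(divide="ignore"):
        log_intensity = np.log(q) + stats.beta.logpdf(u, alpha, alpha)
    return float(np.sum(log_intensity) - q * span - _log1mexp(q * span))


def default_bin_edges(oldest: float, width: float = 1.0) -> np.ndarray:
    """Time-bin edges anchored at 0 Ma, fixed width, covering up to ``oldest``."""
    n = max(1, int(np.ceil(oldest / width - 1e-12)))
    return np.arange(n + 1, dtype=float) * width


def tpp_loglik(occ_ages, ts: float, te: float, q_bins, bin_edges=None) -> float:
    """Time-variable Poisson preservation with piecewise-constant rates.

    ``q_bins[i]`` applies on ages [edges[i], edges[i+1]); edges default to a
    1-Myr grid anchored at 0 Ma. The bins must cover the whole lifespan.
    """
    occ_ages = _check_span(occ_ages, ts, te)
    q_bins = np.asarray(q_bins, dtype=float)
    if np.any(q_bins <= 0):
        raise ValueError("all bin rates must be > 0")
    if bin_edges is None:
        bin_edges = np.arange(q_bins.size + 1, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.size != q_bins.size + 1:
        raise ValueError("need len(bin_edges) == len(q_bins) + 1")
    if ts - te <= 0:
        raise PreservationDomainError("degenerate lifespan (ts == te)")
    if ts > bin_edges[-1] + 1e-12 or te < bin_edges[0] - 1e-12:
        raise ValueError(
            f"bins [{bin_edges[0]}, {bin_edges[-1]}] do not cover lifespan [{te}, {ts}]"
        )
    idx = np.clip(np.searchsorted(bin_edges, occ_ages, side="right") - 1, 0, q_bins.size - 1)
    log_rate_term = float(np.sum(np.log(q_bins[idx])))
    overlap = np.clip(
        np.minimum(bin_edges[1:], ts) - np.maximum(bin_edges[:-1], te), 0.0, None
    )
    integral = float(np.sum(q_bins * overlap))
    return log_rate_term - integral - _log1mexp(integral)


def gamma_category_multipliers(gamma_shape: float, n_cats: int) -> np.ndarray:
    """Means of the equal-probability categories of a mean-one Gamma(nu, nu).

    The standard discretization of gamma rate heterogeneity: cut the
    distribution at its i/n quantiles and take each category's conditional
    mean; the multipliers average to 1.
    """
    if n_cats < 1:
        raise ValueError("n_cats must be >= 1")
    if not gamma_shape > 0:
        raise ValueError("gamma_shape must be > 0")
    if n_cats == 1:
        return np.array([1.0])
    a = float(gamma_shape)
    probs = np.arange(n_cats + 1) / n_cats
    # Quantile boundaries of Gamma(a, rate=a), expressed on the standard
    # Gamma(a, 1) scale for the partial-expectation identity below.
    bounds = special.gammaincinv(a, probs[1:-1])
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    partial = special.gammainc(a + 1, bounds)  # P(a+1, x): partial expectation / mean
    return n_cats * np.diff(partial)


def gamma_mixture_loglik(per_species_loglik, gamma_shape: float, n_cats: int) -> float:
    """Across-lineage heterogeneity: average each species' likelihood over rate categories.

    ``per_species_loglik(multiplier)`` must return the vector of per-species
    conditioned log-likelihoods when every preservation rate is scaled by
    ``multiplier``. Each species' likelihood is averaged over the category
    multipliers with equal weight; the result is the sum over species of the
    log of that average.
    """
    mults = gamma_category_multipliers(gamma_shape, n_cats)
    lls = np.stack([np.atleast_1d(np.asarray(per_species_loglik(m), dtype=float)) for m in mults])
    return float(np.sum(special.logsumexp(lls, axis=0) - np.log(len(mults))))


@dataclass
class PreservationModel:
    """Configuration of the preservation process.

    kind: "HPP", "NHPP" (lifespan-varying) or "TPP" (time-binned).
    q: mean rate (occurrences per lineage-Myr); for TPP either a scalar used
       to initialize every bin or a vector of per-bin rates.
    alpha: NHPP lifespan-shape parameter (> 0; 1 = uniform).
    gamma_shape: across-lineage heterogeneity nu (> 0; None disables).
    n_gamma_cats: number of discrete heterogeneity categories.
    bin_width: TPP bin width in Myr (bins anchored at 0 Ma).
    """

    kind: str = "NHPP"
    q: float | np.ndarray = 1.0
    alpha: float = 2.0
    gamma_shape: float | None = None
    n_gamma_cats: int = 4
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("HPP", "NHPP", "TPP"):
            raise ValueError(f"unknown preservation kind {self.kind!r}")
        if np.any(np.asarray(self.q) <= 0):
            raise ValueError("preservation rates must be > 0")
        if self.kind == "NHPP" and not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.gamma_shape is not None and not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be > 0")
        if self.n_gamma_cats < 1:
            raise ValueError("n_gamma_cats must be >= 1")

    @property
    def heterogeneous(self) -> bool:
        return self.gamma_shape is not None and self.n_gamma_cats > 1

    def loglik(self, occ_ages, ts: float, te: float, multiplier: float = 1.0,
               q=None, alpha: float | None = None, bin_edges=None) -> float:
        """Single-species conditioned log-likelihood under this model."""
        q = self.q if q is None else q
        alpha = self.alpha if alpha is None else alpha
        if self.kind == "HPP":
            return hpp_loglik(occ_ages, ts, te, float(q) * multiplier)
        if self.kind == "NHPP":
            return nhpp_loglik(occ_ages, ts, te, float(q) * multiplier, alpha)
        q_bins = np.asarray(q, dtype=float) * multiplier
        return tpp_loglik(occ_ages, ts, te, q_bins, bin_edges=bin_edges)
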