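"""Bayesian estimation of species origination/extinction times.

A fixed-dimension Metropolis-Hastings sampler targets the joint posterior of
per-species origination (ts) and extinction (te) times, the preservation
parameters (q, and alpha or per-bin rates, plus the heterogeneity shape nu),
and the constant birth-death rates (lam, mu) that act as the prior on
lifespans. Hard constraints keep every ts at or above the species' oldest
occurrence and every te at or below its youngest occurrence; species flagged
extant have te fixed at 0.

Priors (all configurable): q and each time-bin rate ~ Gamma(1.5, 1.5);
alpha ~ Gamma(2, 1); nu ~ Gamma(2, 2); lam, mu ~ Exponential(1).
Proposals are sliding windows (reflected at the constraints) on times and
log-scale multipliers on rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special, stats

from .bd import BDParams, SpeciesTimes, bd_times_loglik
from .occurrences import ResolvedDataset
from .preservation import (
    PreservationModel,
    default_bin_edges,
    gamma_category_multipliers,
)
from ._rng import rng_from_seed

__all__ = ["McmcConfig", "TimesPosterior", "estimate_times_mcmc", "pool_replicates"]

EXTANT_AGE_CUTOFF = 0.02  # Ma; a youngest occurrence below this marks the species extant


@lru_cache(maxsize=512)
def _betaln_sym(alpha: float) -> float:
    return float(2 * special.gammaln(alpha) - special.gammaln(2 * alpha))


@lru_cache(maxsize=512)
def _cached_multipliers(nu: float, n_cats: int) -> tuple[float, ...]:
    return tuple(gamma_category_multipliers(nu, n_cats))


def _gamma_logpdf(x, shape: float, rate: float):
    x = np.asarray(x, dtype=float)
    out = (shape - 1) * np.log(x) - rate * x + shape * np.log(rate) - special.gammaln(shape)
    return float(np.sum(out))


@dataclass
class McmcConfig:
    """Sampler settings. Defaults give a short desk-scale chain; scale up for real data."""

    n_iterations: int = 200_000
    sampling_freq: int = 100
    burnin_fraction: float = 0.2
    seed: int = 0
    # proposal windows
    window_times: float = 0.4       # Myr, sliding window on ts/te
    window_rate_mult: float = 0.6   # log-scale half-width of rate multipliers
    # prior hyperparameters
    prior_q_shape: float = 1.5
    prior_q_rate: float = 1.5
    prior_alpha_shape: float = 2.0
    prior_alpha_rate: float = 1.0
    prior_nu_shape: float = 2.0
    prior_nu_rate: float = 2.0
    prior_lam_rate: float = 1.0
    prior_mu_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (self.n_iterations >= self.sampling_freq >= 1):
            raise ValueError("need n_iterations >= sampling_freq >= 1")
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("need 0 <= burnin_fraction < 1")


@dataclass
class TimesPosterior:
    """Posterior sample of species times plus the parameter trace."""

    times: SpeciesTimes
    trace: pd.DataFrame = field(repr=False)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.times.ts_samples.shape[0]


class _PreservationEvaluator:
    """Vectorized per-species conditioned preservation log-likelihood.

    Occurrence ages are fixed within a replicate, so per-occurrence bin
    indices (TPP) and species groupings are precomputed once.
    """

    def __init__(self, species_ages: dict[str, np.ndarray], model: PreservationModel,
                 bin_edges: np.ndarray | None = None):
        self.model = model
        self.names = list(species_ages)
        self.n = len(self.names)
        counts = np.array([len(species_ages[s]) for s in self.names])
        if np.any(counts < 1):
            raise ValueError("every species needs >= 1 occurrence")
        self.counts = counts
        self.flat_ages = np.concatenate([np.asarray(species_ages[s], float) for s in self.names])
        self.sp_idx = np.repeat(np.arange(self.n), counts)
        self.fad = np.array([np.max(species_ages[s]) for s in self.names])
        self.lad = np.array([np.min(species_ages[s]) for s in self.names])
        if model.kind == "TPP":
            self.bin_edges = (
                np.asarray(bin_edges, float)
                if bin_edges is not None
                else default_bin_edges(self.fad.max() + 5.0, model.bin_width)
            )
            self.n_bins = self.bin_edges.size - 1
            self.occ_bin = np.clip(
                np.searchsorted(self.bin_edges, self.flat_ages, side="right") - 1,
                0, self.n_bins - 1,
            )
        else:
            self.bin_edges = None
            self.n_bins = 0

    def species_ll(self, ts, te, q, alpha, mults) -> np.ndarray:
        """(n_cats, n_species) matrix of conditioned log-likelihoods.

        Returns -inf columns for invalid geometry instead of raising so the
        sampler can reject the proposal.
        """
        ts = np.asarray(ts, float)
        te = np.asarray(te, float)
        mults = np.atleast_1d(np.asarray(mults, float))
        span = ts - te
        bad = (span <= 0) | (ts < self.fad) | (te > self.lad)
        safe_span = np.where(span > 0, span, 1.0)
        if self.model.kind == "TPP":
            q_bins = np.asarray(q, float)
            if ts.max() > self.bin_edges[-1] + 1e-12:
                return np.full((mults.size, self.n), -np.inf)
            log_rate = np.bincount(
                self.sp_idx, weights=np.log(q_bins[self.occ_bin]), minlength=self.n
            )
            overlap = np.clip(
                np.minimum(self.bin_edges[None, 1:], ts[:, None])
                - np.maximum(self.bin_edges[None, :-1], te[:, None]),
                0.0, None,
            )
            expected = overlap @ q_bins  # per species, multiplier 1
            log_rate_m = log_rate[None, :] + self.counts[None, :] * np.log(mults)[:, None]
            lam_m = expected[None, :] * mults[:, None]
        else:
            u = (ts[self.sp_idx] - self.flat_ages) / safe_span[self.sp_idx]
            if self.model.kind == "NHPP" and alpha != 1.0:
                u = np.clip(u, 0.0, 1.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    # symmetric beta density, written out for speed
                    log_f = (alpha - 1.0) * (np.log(u) + np.log1p(-u)) - _betaln_sym(alpha)
                log_f = np.where(np.isnan(log_f), -np.inf, log_f)
            else:
                log_f = np.zeros_like(u)
            log_int = np.log(q) + log_f
            per_sp = np.bincount(self.sp_idx, weights=log_int, minlength=self.n)
            log_rate_m = per_sp[None, :] + self.counts[None, :] * np.log(mults)[:, None]
            lam_m = (q * span)[None, :] * mults[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(
                lam_m > 1e-300,
                np.where(lam_m < 0.693, np.log(-np.expm1(-np.minimum(lam_m, 0.693))),
                         np.log1p(-np.exp(-lam_m))),
                -np.inf,
            )
        out = log_rate_m - lam_m - cond
        out[:, bad] = -np.inf
        return out


def _mixed_ll(ev: _PreservationEvaluator, ts, te, q, alpha, nu, n_cats) -> float:
    if nu is None or n_cats <= 1:
        mat = ev.species_ll(ts, te, q, alpha, np.array([1.0]))
        return float(np.sum(mat[0]))
    mults = np.array(_cached_multipliers(float(nu), int(n_cats)))
    mat = ev.species_ll(ts, te, q, alpha, mults)
    top = np.max(mat, axis=0)
    finite = np.isfinite(top)
    if not np.all(finite):
        return -np.inf
    mix = top + np.log(np.mean(np.exp(mat - top[None, :]), axis=0))
    return float(np.sum(mix))


def estimate_times_mcmc(
    data: ResolvedDataset | dict[str, np.ndarray],
    model: PreservationModel,
    config: McmcConfig,
    extant: set[str] | None = None,
    fix_times: dict[str, tuple[float, float]] | None = None,
) -> TimesPosterior:
    """Sample the joint posterior of species times and preservation/BD parameters.

    ``data`` is either an age-resolved replicate or a mapping species ->
    occurrence-age array. Species are flagged extant when listed in
    ``extant``, listed in the replicate's extant set, or when their youngest
    occurrence is younger than 0.02 Ma; extant species have te fixed at 0.
    ``fix_times`` pins every species' (ts, te) at the given values and
    samples only the rate parameters (useful for conditional inference and
    cross-checks against grid posteriors).
    """
    if isinstance(data, ResolvedDataset):
        species_ages = data.species_ages()
        extant = set(extant or ()) | set(data.extant)
    else:
        species_ages = {s: np.asarray(a, float) for s, a in data.items()}
        extant = set(extant or ())
    for sp, ages in species_ages.items():
        if len(ages) < 1:
            raise ValueError(f"species {sp!r} has no occurrences")

    ev = _PreservationEvaluator(species_ages, model)
    names = ev.names
    n = ev.n
    rng = rng_from_seed(config.seed)

    is_extant = np.array(
        [sp in extant or ev.lad[i] < EXTANT_AGE_CUTOFF for i, sp in enumerate(names)]
    )

    # initial state
    if fix_times is not None:
        ts = np.array([fix_times[sp][0] for sp in names])
        te = np.array([fix_times[sp][1] for sp in names])
    else:
        ts = ev.fad + 0.3
        te = np.where(is_extant, 0.0, np.maximum(0.0, ev.lad - np.minimum(0.3, ev.lad * 0.5)))
    est_nu = model.heterogeneous
    nu = float(model.gamma_shape) if est_nu else None
    total_occ = ev.counts.sum()
    q0 = max(0.5, total_occ / max(np.sum(ts - te), 1e-6))
    if model.kind == "TPP":
        q = np.full(ev.n_bins, q0)
    else:
        q = q0
    alpha = float(model.alpha) if model.kind == "NHPP" else 1.0
    lam, mu = 0.5, 0.3

    n_extinct = int(np.sum(~is_extant))

    def log_prior(qv, alphav, nuv, lamv, muv) -> float:
        lp = _gamma_logpdf(qv, config.prior_q_shape, config.prior_q_rate)
        if model.kind == "NHPP":
            lp += _gamma_logpdf(alphav, config.prior_alpha_shape, config.prior_alpha_rate)
        if est_nu:
            lp += _gamma_logpdf(nuv, config.prior_nu_shape, config.prior_nu_rate)
        lp += -config.prior_lam_rate * lamv + np.log(config.prior_lam_rate)
        lp += -config.prior_mu_rate * muv + np.log(config.prior_mu_rate)
        return float(lp)

    def bd_ll(tsv, tev) -> float:
        # constant-rate BD prior on lifespans (oldest ts = origin, no lam factor)
        total = float(np.sum(tsv - tev))
        ll = (n - 1) * np.log(lam) - (lam + mu) * total
        if n_extinct:
            ll += n_extinct * np.log(mu) if mu > 0 else -np.inf
        return ll

    pres_ll = _mixed_ll(ev, ts, te, q, alpha, nu, model.n_gamma_cats)
    bd_term = bd_ll(ts, te)
    prior = log_prior(q, alpha, nu, lam, mu)
    if not np.isfinite(pres_ll + bd_term + prior):
        raise RuntimeError(
            "non-finite initial likelihood: "
            f"preservation={pres_ll}, bd={bd_term}, prior={prior}"
        )

    updatable_te = np.flatnonzero(~is_extant & (ev.lad > 0))
    if fix_times is not None:
        updatable_te = np.array([], dtype=int)
        move_kinds = ["q", "lam", "mu"]
        move_probs = [0.7, 0.15, 0.15]
    else:
        move_kinds = ["ts", "q", "lam", "mu"]
        move_probs = [0.42, 0.18, 0.06, 0.06]
    if fix_times is None and updatable_te.size:
        move_kinds.append("te")
        move_probs.append(0.42 * updatable_te.size / n)
    if model.kind == "NHPP":
        move_kinds.append("alpha")
        move_probs.append(0.08)
    if est_nu:
        move_kinds.append("nu")
        move_probs.append(0.08)
    move_probs = np.array(move_probs) / np.sum(move_probs)

    n_rec = config.n_iterations // config.sampling_freq
    ts_rec = np.empty((n_rec, n))
    te_rec = np.empty((n_rec, n))
    rows = []
    accept = {k: 0 for k in move_kinds}
    tries = {k: 0 for k in move_kinds}
    w = config.window_times
    d = config.window_rate_mult
    rec_i = 0

    kind_draws = rng.choice(len(move_kinds), size=config.n_iterations, p=move_probs)
    log_u_acc = np.log(rng.uniform(size=config.n_iterations))
    for it in range(config.n_iterations):
        kind = move_kinds[kind_draws[it]]
        tries[kind] += 1
        log_hastings = 0.0
        new_ts, new_te = ts, te
        new_q, new_alpha, new_nu, new_lam, new_mu = q, alpha, nu, lam, mu
        if kind == "ts":
            i = rng.integers(n)
            new_ts = ts.copy()
            prop = ts[i] + rng.uniform(-w, w)
            if prop < ev.fad[i]:
                prop = 2 * ev.fad[i] - prop  # reflect at the oldest occurrence
            new_ts[i] = prop
        elif kind == "te":
            i = updatable_te[rng.integers(updatable_te.size)]
            new_te = te.copy()
            prop = te[i] + rng.uniform(-w, w)
            lo, hi = 0.0, ev.lad[i]
            for _ in range(100):  # reflect into [0, lad]
                if prop < lo:
                    prop = 2 * lo - prop
                elif prop > hi:
                    prop = 2 * hi - prop
                else:
                    break
            new_te[i] = prop
        elif kind == "q":
            m = np.exp(rng.uniform(-d, d))
            if model.kind == "TPP":
                b = rng.integers(ev.n_bins)
                new_q = q.copy()
                new_q[b] = q[b] * m
            else:
                new_q = q * m
            log_hastings = np.log(m)
        elif kind == "alpha":
            m = np.exp(rng.uniform(-d, d))
            new_alpha = alpha * m
            log_hastings = np.log(m)
        elif kind == "nu":
            m = np.exp(rng.uniform(-d, d))
            new_nu = nu * m
            log_hastings = np.log(m)
        elif kind == "lam":
            m = np.exp(rng.uniform(-d, d))
            new_lam = lam * m
            log_hastings = np.log(m)
        else:  # mu
            m = np.exp(rng.uniform(-d, d))
            new_mu = mu * m
            log_hastings = np.log(m)

        if kind in ("lam", "mu"):
            lam_try, mu_try = new_lam, new_mu
            lam_save, mu_save = lam, mu
            lam, mu = lam_try, mu_try
            new_bd = bd_ll(ts, te)
            lam, mu = lam_save, mu_save
            new_pres = pres_ll
        elif kind in ("ts", "te"):
            new_pres = _mixed_ll(ev, new_ts, new_te, q, alpha, nu, model.n_gamma_cats)
            lam_save, mu_save = lam, mu
            new_bd = bd_ll(new_ts, new_te)
        else:
            new_pres = _mixed_ll(ev, ts, te, new_q, new_alpha, new_nu, model.n_gamma_cats)
            new_bd = bd_term
        new_prior = log_prior(new_q, new_alpha, new_nu, new_lam, new_mu)
        log_ratio = (new_pres + new_bd + new_prior) - (pres_ll + bd_term + prior) + log_hastings
        if np.isfinite(log_ratio) and log_u_acc[it] < log_ratio:
            ts, te = new_ts, new_te
            q, alpha, nu, lam, mu = new_q, new_alpha, new_nu, new_lam, new_mu
            pres_ll, bd_term, prior = new_pres, new_bd, new_prior
            accept[kind] += 1

        if (it + 1) % config.sampling_freq == 0:
            ts_rec[rec_i] = ts
            te_rec[rec_i] = te
            row = {"iteration": it + 1, "loglik": pres_ll + bd_term,
                   "lam": lam, "mu": mu}
            if model.kind == "TPP":
                row.update({f"q_bin_{b}": q[b] for b in range(ev.n_bins)})
            else:
                row["q"] = float(q)
            if model.kind == "NHPP":
                row["alpha"] = alpha
            if est_nu:
                row["nu"] = nu
            rows.append(row)
            rec_i += 1

    burn = int(np.floor(config.burnin_fraction * n_rec))
    ts_keep = ts_rec[burn:]
    te_keep = te_rec[burn:]
    trace = pd.DataFrame(rows[burn:]).reset_index(drop=True)
    times = SpeciesTimes(
        species=tuple(names),
        ts=ts_keep.mean(axis=0),
        te=np.where(is_extant, 0.0, te_keep.mean(axis=0)),
        extant=is_extant,
        ts_samples=ts_keep,
        te_samples=te_keep,
    )
    rates = {k: (accept[k] / tries[k] if tries[k] else np.nan) for k in move_kinds}
    return TimesPosterior(times=times, trace=trace, acceptance=rates)


def pool_replicates(posteriors: list[TimesPosterior]) -> TimesPosterior:
    """Concatenate post-burn-in samples across age-resolution replicates."""
    if not posteriors:
        raise ValueError("need >= 1 posterior")
    ref = posteriors[0].times.species
    for p in posteriors[1:]:
        if p.times.species != ref:
            raise ValueError("replicates have mismatched species sets")
    ts_all = np.concatenate([p.times.ts_samples for p in posteriors])
    te_all = np.concatenate([p.times.te_samples for p in posteriors])
    extant = posteriors[0].times.extant
    times = SpeciesTimes(
        species=ref,
        ts=ts_all.mean(axis=0),
        te=np.where(extant, 0.0, te_all.mean(axis=0)),
        extant=extant,
        ts_samples=ts_all,
        te_samples=te_all,
    )
    trace = pd.concat([p.trace for p in posteriors], ignore_index=True)
    return TimesPosterior(times=times, trace=trace, acceptance={})
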