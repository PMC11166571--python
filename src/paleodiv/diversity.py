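"""Diversity trajectories and the diversity-covariate birth-death model.

The lineage-through-time trajectory D(t) counts species whose lifespan covers
age t (te < t <= ts, with extant species counted at t = 0). The covariate
model lets each group's speciation and extinction rates depend exponentially
on a piecewise-constant predictor, normally the clade's own trajectory:

    lam_g(t) = lam0_g * exp(G_lam_g * D(t))
    mu_g(t)  = mu0_g  * exp(G_mu_g  * D(t))

G > 0 means the rate rises with standing diversity, G < 0 that it falls;
G is in per-species units when D is left on its raw lineage-count scale.
The likelihood sums log-rate terms at each origination (except the clade
origin, the oldest ts) and each extinction, minus the integrated total rate,
evaluated in closed form on the intervals where D and the group lineage
counts are both constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bd import SpeciesTimes
from ._rng import rng_from_seed

__all__ = [
    "DiversityTrajectory",
    "CovariateBDParams",
    "CorrelationSummary",
    "ltt_from_times",
    "covariate_bd_loglik",
    "fit_covariate_model",
    "CovariateBDPosterior",
    "hpd_interval",
    "summarize_correlation",
]


@dataclass
class DiversityTrajectory:
    """Piecewise-constant lineage count through time.

    ``breaks`` are event ages in Ma, strictly descending. ``counts[k]`` is the
    lineage count on the half-open age interval (breaks[k+1], breaks[k]] (the
    last interval extends down to 0). The count is 0 for ages older than
    ``breaks[0]``.
    """

    breaks: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.breaks.size != self.counts.size:
            raise ValueError("breaks and counts must have the same length")
        if self.breaks.size and np.any(np.diff(self.breaks) >= 0):
            raise ValueError("breaks must be strictly descending")

    def at(self, t: float, side: str = "younger") -> float:
        """D(t). ``side='older'`` gives the limit from above (t + eps), i.e.
        the standing diversity just before the event at age t happens; t = 0
        always uses the limit from above so extant species are counted."""
        if self.breaks.size == 0:
            return 0
        t = float(t)
        if side == "older" or t == 0.0:
            t = np.nextafter(t, np.inf)
        if t > self.breaks[0]:
            return 0
        # interval (breaks[k+1], breaks[k]] containing t: largest k with breaks[k] >= t
        k = int(np.searchsorted(-self.breaks, -t, side="right")) - 1
        k = min(max(k, 0), self.breaks.size - 1)
        return float(self.counts[k])

    def integral(self) -> float:
        """Integral of D(t) dt over the trajectory's span (equals total lifespan)."""
        lo = np.append(self.breaks[1:], 0.0)
        return float(np.sum(self.counts * (self.breaks - lo)))

    def shifted(self, c: float) -> "DiversityTrajectory":
        return DiversityTrajectory(self.breaks.copy(), self.counts + c)


def ltt_from_times(times: SpeciesTimes) -> DiversityTrajectory:
    """Build the lineage-through-time trajectory from point origination/extinction times."""
    if len(times) == 0:
        return DiversityTrajectory(np.array([]), np.array([]))
    events: dict[float, int] = {}
    for s, e in zip(times.ts, times.te):
        events[float(s)] = events.get(float(s), 0) + 1
        if e > 0:
            events[float(e)] = events.get(float(e), 0) - 1
    breaks = np.array(sorted(events, reverse=True))
    deltas = np.array([events[b] for b in breaks])
    counts = np.cumsum(deltas)
    return DiversityTrajectory(breaks, counts)


@dataclass
class CovariateBDParams:
    """Per-group baselines and diversity-correlation parameters.

    groups maps a group label to (lambda0, mu0, g_lambda, g_mu); baselines
    are per lineage-Myr, G parameters are per species of standing diversity.
    """

    groups: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for g, (l0, m0, _, _) in self.groups.items():
            if not l0 > 0 or not m0 > 0:
                raise ValueError(f"group {g!r}: baseline rates must be > 0")


def _event_structure(times: SpeciesTimes, groups: dict[str, str],
                     predictor: DiversityTrajectory):
    """Precompute everything the covariate likelihood needs.

    Returns per-group speciation/extinction predictor values at events and,
    on the union grid of predictor breaks and all events, the interval
    widths, predictor values and per-group lineage counts.
    """
    labels = sorted(set(groups.values()))
    for s in times.species:
        if s not in groups:
            raise ValueError(f"species {s!r} has no group assignment")
    for g in labels:
        if not any(groups[s] == g for s in times.species):
            raise ValueError(f"group {g!r} has no species")

    origin_idx = int(np.argmax(times.ts))
    ev_lam = {g: [] for g in labels}
    ev_mu = {g: [] for g in labels}
    for i, sp in enumerate(times.species):
        g = groups[sp]
        if i != origin_idx:
            ev_lam[g].append(predictor.at(times.ts[i], side="older"))
        if not times.extant[i] and times.te[i] > 0:
            ev_mu[g].append(predictor.at(times.te[i], side="older"))

    grid = np.unique(np.concatenate([
        predictor.breaks, times.ts, times.te[times.te > 0], [0.0]
    ]))[::-1]
    hi = grid[:-1]
    lo = grid[1:]
    widths = hi - lo
    mids = (hi + lo) / 2
    d_vals = np.array([predictor.at(m) for m in mids], dtype=float)
    n_by_group = {}
    for g in labels:
        mask = np.array([groups[s] == g for s in times.species])
        n_by_group[g] = np.array([
            int(np.sum((times.te[mask] < m) & (m <= times.ts[mask]))) for m in mids
        ], dtype=float)
    return labels, {g: np.asarray(v, float) for g, v in ev_lam.items()}, \
        {g: np.asarray(v, float) for g, v in ev_mu.items()}, widths, d_vals, n_by_group


def _loglik_from_structure(labels, ev_lam, ev_mu, widths, d_vals, n_by_group,
                           params: CovariateBDParams) -> float:
    ll = 0.0
    for g in labels:
        l0, m0, gl, gm = params.groups[g]
        ll += ev_lam[g].size * np.log(l0) + gl * ev_lam[g].sum()
        ll += ev_mu[g].size * np.log(m0) + gm * ev_mu[g].sum()
        total = np.sum(
            n_by_group[g] * widths * (l0 * np.exp(gl * d_vals) + m0 * np.exp(gm * d_vals))
        )
        ll -= total
    return float(ll)


def covariate_bd_loglik(
    times: SpeciesTimes,
    groups: dict[str, str],
    predictor: DiversityTrajectory,
    params: CovariateBDParams,
) -> float:
    """Log-likelihood of the exponential diversity-covariate birth-death model.

    The predictor is evaluated on the older side of each event (the standing
    diversity the event happened into). The oldest origination is the clade
    origin and contributes no speciation factor.
    """
    structure = _event_structure(times, groups, predictor)
    return _loglik_from_structure(*structure, params)


@dataclass
class CovariateBDPosterior:
    trace: pd.DataFrame = field(repr=False)
    group_labels: tuple[str, ...] = ()
    acceptance: dict = field(default_factory=dict)

    def samples(self, group: str, which: str) -> np.ndarray:
        """Posterior draws of one parameter; which in {lambda0, mu0, g_lambda, g_mu}."""
        return self.trace[f"{which}[{group}]"].to_numpy()


def fit_covariate_model(
    times: SpeciesTimes,
    groups: dict[str, str],
    predictor: DiversityTrajectory,
    config=None,
    seed: int | None = None,
) -> CovariateBDPosterior:
    """Metropolis-Hastings sampler for the covariate model.

    Baselines get log-scale multiplier proposals with Exponential(1) priors;
    G parameters get sliding-window proposals with Normal(0, 5^2) priors.
    """
    from .mcmc import McmcConfig

    config = config or McmcConfig(n_iterations=100_000, sampling_freq=50)
    rng = rng_from_seed(config.seed if seed is None else seed)
    structure = _event_structure(times, groups, predictor)
    labels = structure[0]

    # parameter vector: per group (lam0, mu0, gl, gm)
    state = {g: [0.5, 0.3, 0.0, 0.0] for g in labels}

    def loglik(st) -> float:
        return _loglik_from_structure(
            *structure, CovariateBDParams({g: tuple(v) for g, v in st.items()})
        )

    def log_prior(st) -> float:
        lp = 0.0
        for l0, m0, gl, gm in st.values():
            lp += -l0 - m0  # Exponential(1) baselines
            lp += -(gl * gl + gm * gm) / (2 * 25.0)
        return lp

    ll = loglik(state)
    lp = log_prior(state)
    if not np.isfinite(ll + lp):
        raise RuntimeError(f"non-finite initial likelihood: loglik={ll}, prior={lp}")

    par_list = [(g, j) for g in labels for j in range(4)]
    n_rec = config.n_iterations // config.sampling_freq
    rows = []
    accept = 0
    d = config.window_rate_mult
    w_g = 1.0
    choices = rng.integers(len(par_list), size=config.n_iterations)
    u_prop = rng.uniform(size=config.n_iterations)
    u_acc = np.log(rng.uniform(size=config.n_iterations))
    for it in range(config.n_iterations):
        g, j = par_list[choices[it]]
        new_state = {k: list(v) for k, v in state.items()}
        log_hastings = 0.0
        if j < 2:
            m = np.exp((2 * u_prop[it] - 1) * d)
            new_state[g][j] = state[g][j] * m
            log_hastings = np.log(m)
        else:
            new_state[g][j] = state[g][j] + (2 * u_prop[it] - 1) * w_g
        new_ll = loglik(new_state)
        new_lp = log_prior(new_state)
        if np.isfinite(new_ll) and u_acc[it] < (new_ll + new_lp) - (ll + lp) + log_hastings:
            state, ll, lp = new_state, new_ll, new_lp
            accept += 1
        if (it + 1) % config.sampling_freq == 0:
            row = {"iteration": it + 1, "loglik": ll}
            for gg in labels:
                l0, m0, gl, gm = state[gg]
                row[f"lambda0[{gg}]"] = l0
                row[f"mu0[{gg}]"] = m0
                row[f"g_lambda[{gg}]"] = gl
                row[f"g_mu[{gg}]"] = gm
            rows.append(row)
    burn = int(np.floor(config.burnin_fraction * n_rec))
    trace = pd.DataFrame(rows[burn:]).reset_index(drop=True)
    return CovariateBDPosterior(
        trace=trace,
        group_labels=tuple(labels),
        acceptance={"overall": accept / config.n_iterations},
    )


def pool_covariate_posteriors(posteriors: list[CovariateBDPosterior]) -> CovariateBDPosterior:
    """Concatenate covariate-model posteriors across replicates."""
    if not posteriors:
        raise ValueError("need >= 1 posterior")
    ref = posteriors[0].group_labels
    for p in posteriors[1:]:
        if p.group_labels != ref:
            raise ValueError("replicates have mismatched group sets")
    return CovariateBDPosterior(
        trace=pd.concat([p.trace for p in posteriors], ignore_index=True),
        group_labels=ref,
        acceptance={},
    )


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted samples."""
    samples = np.sort(np.asarray(samples, dtype=float))
    n = samples.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(samples[0]), float(samples[-1])
    widths = samples[k - 1:] - samples[: n - k + 1]
    j = int(np.argmin(widths))
    return float(samples[j]), float(samples[j + k - 1])


@dataclass
class CorrelationSummary:
    """Posterior summary of one diversity-correlation parameter."""

    mean: float
    hpd95: tuple[float, float]
    sign_fraction: float  # percent of the posterior on the mean's side of 0
    direction: str        # "negative" or "positive"

    @property
    def hpd_excludes_zero(self) -> bool:
        lo, hi = self.hpd95
        return lo > 0 or hi < 0


def summarize_correlation(samples, mass: float = 0.95) -> CorrelationSummary:
    """Mean, HPD interval and dominant-sign fraction of a correlation posterior."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        warnings.warn(f"only {samples.size} posterior samples; summary may be unstable")
    frac_pos = 100.0 * np.mean(samples > 0)
    frac_neg = 100.0 * np.mean(samples < 0)
    if frac_neg >= frac_pos:
        direction, frac = "negative", frac_neg
    else:
        direction, frac = "positive", frac_pos
    return CorrelationSummary(
        mean=float(samples.mean()),
        hpd95=hpd_interval(samples, mass),
        sign_fraction=float(frac),
        direction=direction,
    )
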