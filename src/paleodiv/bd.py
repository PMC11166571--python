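"""Species origination/extinction times and the constant-rate birth-death likelihood.

Times are ages in Ma before present (larger = older). A species' lifespan runs
from its origination time ``ts`` back to its extinction time ``te`` with
``ts >= te >= 0``; extant species have ``te = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpeciesTimes", "BDParams", "bd_times_loglik"]


@dataclass
class BDParams:
    """Constant per-lineage speciation (lambda) and extinction (mu) rates, per Myr."""

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


@dataclass
class SpeciesTimes:
    """Per-species origination (ts) and extinction (te) times in Ma.

    Point values are always present; when produced by MCMC, ``ts_samples`` and
    ``te_samples`` hold the posterior draws (rows = samples, columns = species)
    and the point values are the posterior means.
    """

    species: tuple[str, ...]
    ts: np.ndarray
    te: np.ndarray
    extant: np.ndarray
    ts_samples: np.ndarray | None = field(default=None, repr=False)
    te_samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        self.extant = np.asarray(self.extant, dtype=bool)
        n = len(self.species)
        if not (self.ts.shape == self.te.shape == self.extant.shape == (n,)):
            raise ValueError("species, ts, te and extant must have matching lengths")
        if np.any(self.te < 0):
            raise ValueError("extinction times must be >= 0")
        if np.any(self.ts < self.te):
            raise ValueError("origination must not be younger than extinction (ts >= te)")
        if np.any(self.te[self.extant] != 0.0):
            raise ValueError("extant species must have te = 0")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def lifespans(self) -> np.ndarray:
        return self.ts - self.te

    def subset(self, names: list[str]) -> "SpeciesTimes":
        idx = [self.species.index(s) for s in names]
        return SpeciesTimes(
            species=tuple(names),
            ts=self.ts[idx],
            te=self.te[idx],
            extant=self.extant[idx],
            ts_samples=None if self.ts_samples is None else self.ts_samples[:, idx],
            te_samples=None if self.te_samples is None else self.te_samples[:, idx],
        )


def bd_times_loglik(times: SpeciesTimes, params: BDParams) -> float:
    """Log-likelihood of a set of lifespans under a constant-rate birth-death process.

    Every origination except the oldest one (treated as the process origin)
    contributes a speciation factor; every extinct species contributes an
    extinction factor; each lineage is exposed to both rates for its lifespan:

        (S - 1) log lam + E log mu - (lam + mu) * sum_i (ts_i - te_i)

    Returns ``-inf`` (rather than raising) when ``mu = 0`` but extinct species
    are present.
    """
    n = len(times)
    if n == 0:
        return 0.0
    n_extinct = int(np.sum(~times.extant))
    total = float(np.sum(times.lifespans))
    ll = (n - 1) * np.log(params.lam) - (params.lam + params.mu) * total
    if n_extinct > 0:
        if params.mu == 0:
            return -np.inf
        ll += n_extinct * np.log(params.mu)
    return float(ll)
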