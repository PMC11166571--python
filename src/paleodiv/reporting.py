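"""Publication-style tables, run manifests and plain-text outputs.

The correlation table mirrors the conventional presentation of
diversity-correlation posteriors: one row per process x group x preservation
model, with the posterior mean, 95% HPD interval and the percentage of the
posterior on the dominant side of zero. Flag columns encode the usual
emphasis rules: the sign fraction is flagged when strictly greater than 75%,
the HPD when it excludes 0, and the mean when both flags are set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import CorrelationSummary
from .mcmc import TimesPosterior
from .diversity import hpd_interval

__all__ = [
    "SummaryRow",
    "render_table2_style",
    "RunManifest",
    "times_summary_frame",
    "write_times_summary",
]

SIGN_FLAG_THRESHOLD = 75.0  # percent; strict inequality


@dataclass
class SummaryRow:
    """One diversity-correlation posterior with its labelling."""

    process: str   # "speciation" or "extinction"
    group: str     # e.g. "whole clade", "Homo", "non-Homo"
    model: str     # preservation model label
    summary: CorrelationSummary


def render_table2_style(summaries: list[SummaryRow]) -> pd.DataFrame:
    """Tabulate correlation posteriors with emphasis flags.

    flag_sign: > 75% of the posterior on the dominant side of zero (strict).
    flag_hpd: 95% HPD interval excludes zero.
    flag_mean: both of the above.
    """
    if not summaries:
        raise ValueError("need >= 1 summary")
    rows = []
    for sr in summaries:
        s = sr.summary
        flag_sign = s.sign_fraction > SIGN_FLAG_THRESHOLD
        flag_hpd = s.hpd_excludes_zero
        rows.append({
            "process": sr.process,
            "group": sr.group,
            "model": sr.model,
            "mean": s.mean,
            "hpd_lo": s.hpd95[0],
            "hpd_hi": s.hpd95[1],
            "sign_fraction": s.sign_fraction,
            "direction": s.direction,
            "flag_sign": flag_sign,
            "flag_hpd": flag_hpd,
            "flag_mean": flag_sign and flag_hpd,
        })
    order = {"speciation": 0, "extinction": 1}
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["process", "group", "model"],
        key=lambda col: col.map(order) if col.name == "process" else col,
        kind="stable",
    ).reset_index(drop=True)


def format_table(df: pd.DataFrame) -> str:
    """Human-readable rendering of the correlation table (* marks flags)."""
    lines = []
    for process, sub in df.groupby("process", sort=False):
        lines.append(process.capitalize())
        for _, r in sub.iterrows():
            mean = f"{r['mean']:.2f}" + ("*" if r["flag_mean"] else "")
            hpd = f"[{r['hpd_lo']:.2f}, {r['hpd_hi']:.2f}]" + ("*" if r["flag_hpd"] else "")
            sf = f"{r['sign_fraction']:.1f}% {r['direction']}" + ("*" if r["flag_sign"] else "")
            lines.append(f"  {r['group']:<12} {r['model']:<36} {mean:>8}  {hpd:>18}  {sf}")
    return "\n".join(lines)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically (given its seeds)."""

    command: str
    config: dict
    seeds: list
    package_version: str = ""
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    inputs: dict = field(default_factory=dict)

    @classmethod
    def create(cls, command: str, config: dict, seeds, input_paths=()) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config={k: _jsonable(v) for k, v in config.items()},
            seeds=list(np.atleast_1d(seeds).tolist()),
            package_version=__version__,
            inputs={str(p): _digest(Path(p)) for p in input_paths},
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, Path):
        return str(v)
    return v


def times_summary_frame(posterior: TimesPosterior, mass: float = 0.95) -> pd.DataFrame:
    """Per-species posterior summary (mean and HPD of ts and te)."""
    t = posterior.times
    rows = []
    for i, sp in enumerate(t.species):
        ts_lo, ts_hi = hpd_interval(t.ts_samples[:, i], mass)
        te_lo, te_hi = hpd_interval(t.te_samples[:, i], mass)
        rows.append({
            "species": sp,
            "ts_mean": t.ts[i], "ts_hpd_lo": ts_lo, "ts_hpd_hi": ts_hi,
            "te_mean": t.te[i], "te_hpd_lo": te_lo, "te_hpd_hi": te_hi,
            "extant": bool(t.extant[i]),
        })
    return pd.DataFrame(rows).set_index("species")


def write_times_summary(posterior: TimesPosterior, path: str | Path) -> None:
    times_summary_frame(posterior).to_csv(path)
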