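"""Fossil occurrence tables: I/O, hierarchical locality merging, age resolution.

An occurrence is one fossil find assigned to a species, with a locality
recorded hierarchically (site complex > site > subsite, plus geological
formation and stratigraphic unit) and a closed age interval in Ma. Merging to
the ``site_complex`` level collapses all finds of a species at one site
complex into a single occurrence whose interval is the union of the inputs,
mirroring the coarsest operational definition of a fossil locality. Age
uncertainty is propagated by drawing replicate datasets with each occurrence
age resampled uniformly within its interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bd import SpeciesTimes
from ._rng import rng_from_seed, spawn_seeds

__all__ = [
    "LOCALITY_FIELDS",
    "OccurrenceRecord",
    "OccurrenceTable",
    "ResolvedDataset",
    "FadLadTable",
    "read_occurrences",
    "write_occurrences",
    "read_fad_lad",
    "write_fad_lad",
    "merge_to_level",
    "drop_exact_duplicates",
    "resolve_ages",
    "fad_lad_to_times",
]

LOCALITY_FIELDS = ("site_complex", "site", "subsite", "formation", "strat_unit")

_CSV_COLUMNS = ("species", *LOCALITY_FIELDS, "age_min", "age_max", "source_id")


class OccurrenceFormatError(ValueError):
    """Malformed input file (missing mandatory columns, unparseable rows)."""


class OccurrenceValidationError(ValueError):
    """Row content violates an invariant (bad interval, no locality, ...)."""


def _clean(value) -> str | None:
    """Absent locality fields are stored as None, never as empty strings."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    return s or None


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    age_min: float
    age_max: float
    site_complex: str | None = None
    site: str | None = None
    subsite: str | None = None
    formation: str | None = None
    strat_unit: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("site_complex", "site", "subsite", "formation", "strat_unit", "source_id"):
            object.__setattr__(self, name, _clean(getattr(self, name)))
        if not self.species or not str(self.species).strip():
            raise OccurrenceValidationError("species name must be nonempty")
        if not (0 <= self.age_min <= self.age_max):
            raise OccurrenceValidationError(
                f"invalid age interval for {self.species!r}: "
                f"[{self.age_min}, {self.age_max}] (need 0 <= age_min <= age_max)"
            )
        if all(getattr(self, f) is None for f in LOCALITY_FIELDS):
            raise OccurrenceValidationError(
                f"occurrence of {self.species!r} has no locality information"
            )

    @property
    def locality_key(self) -> tuple:
        return tuple(getattr(self, f) for f in LOCALITY_FIELDS)


@dataclass
class OccurrenceTable:
    records: list[OccurrenceRecord]
    level: str = "finest"

    def __post_init__(self) -> None:
        if self.level not in ("finest", "site_complex"):
            raise ValueError(f"unknown level {self.level!r}")
        self.records = list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return tuple(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in _CSV_COLUMNS} for r in self.records],
            columns=list(_CSV_COLUMNS),
        )


def read_occurrences(path: str | Path) -> OccurrenceTable:
    """Read an occurrence CSV (columns: species, locality fields, age_min, age_max)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={f: "string" for f in ("species", *LOCALITY_FIELDS, "source_id")})
    missing = {"species", "age_min", "age_max"} - set(df.columns)
    if missing:
        raise OccurrenceFormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        kwargs = {f: row.get(f) for f in (*LOCALITY_FIELDS, "source_id") if f in df.columns}
        kwargs = {k: (None if pd.isna(v) else v) for k, v in kwargs.items()}
        try:
            records.append(
                OccurrenceRecord(
                    species=str(row["species"]),
                    age_min=float(row["age_min"]),
                    age_max=float(row["age_max"]),
                    **kwargs,
                )
            )
        except OccurrenceValidationError as err:
            raise OccurrenceValidationError(f"{path}, row {i + 2}: {err}") from err
    return OccurrenceTable(records=records, level="finest")


def write_occurrences(table: OccurrenceTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def drop_exact_duplicates(table: OccurrenceTable) -> OccurrenceTable:
    """Drop records identical in species, full locality tuple and age interval."""
    seen: set[tuple] = set()
    kept = []
    for r in table.records:
        key = (r.species, r.locality_key, r.age_min, r.age_max)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return OccurrenceTable(records=kept, level=table.level)


def merge_to_level(table: OccurrenceTable, level: str) -> OccurrenceTable:
    """Collapse occurrences to a locality level.

    At ``site_complex`` level, records sharing (species, site_complex) merge
    into one record whose age interval is the union of the inputs; records
    with no recorded site complex are left as they are. ``finest`` returns the
    input unchanged.
    """
    if level == "finest":
        return OccurrenceTable(records=list(table.records), level="finest")
    if level != "site_complex":
        raise ValueError(f"unknown level {level!r}")
    merged: dict[tuple, OccurrenceRecord] = {}
    out: list[OccurrenceRecord] = []
    for r in table.records:
        if r.site_complex is None:
            out.append(r)
            continue
        key = (r.species, r.site_complex)
        if key not in merged:
            rec = OccurrenceRecord(
                species=r.species,
                age_min=r.age_min,
                age_max=r.age_max,
                site_complex=r.site_complex,
            )
            merged[key] = rec
            out.append(rec)
        else:
            old = merged[key]
            rec = replace(
                old,
                age_min=min(old.age_min, r.age_min),
                age_max=max(old.age_max, r.age_max),
            )
            merged[key] = rec
            out[out.index(old)] = rec
    return OccurrenceTable(records=out, level="site_complex")


@dataclass
class ResolvedDataset:
    """One age-resolved replicate: a point age for every occurrence record."""

    replicate_id: int
    species: tuple[str, ...]
    ages: np.ndarray
    seed: int
    extant: frozenset[str] = field(default_factory=frozenset)

    def species_ages(self) -> dict[str, np.ndarray]:
        """Occurrence ages grouped by species, insertion-ordered."""
        out: dict[str, list[float]] = {}
        for sp, age in zip(self.species, self.ages):
            out.setdefault(sp, []).append(float(age))
        return {sp: np.asarray(v) for sp, v in out.items()}


def resolve_ages(
    table: OccurrenceTable,
    n_replicates: int,
    seed: int,
    extant: set[str] | frozenset[str] | None = None,
) -> list[ResolvedDataset]:
    """Draw replicate datasets with each record's age uniform on [age_min, age_max]."""
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    lo = np.array([r.age_min for r in table.records])
    hi = np.array([r.age_max for r in table.records])
    species = tuple(r.species for r in table.records)
    out = []
    for rep, child_seed in enumerate(spawn_seeds(seed, n_replicates)):
        rng = rng_from_seed(child_seed)
        ages = rng.uniform(lo, hi)
        out.append(
            ResolvedDataset(
                replicate_id=rep,
                species=species,
                ages=ages,
                seed=child_seed,
                extant=frozenset(extant or ()),
            )
        )
    return out


@dataclass
class FadLadTable:
    """First/last appearance data: species -> (FAD Ma, LAD Ma), FAD >= LAD >= 0."""

    data: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sp, (fad, lad) in self.data.items():
            if not (fad >= lad >= 0):
                raise OccurrenceValidationError(
                    f"{sp!r}: need FAD >= LAD >= 0, got FAD={fad}, LAD={lad}"
                )

    def __len__(self) -> int:
        return len(self.data)


def read_fad_lad(path: str | Path) -> FadLadTable:
    df = pd.read_csv(path)
    missing = {"species", "fad", "lad"} - set(df.columns)
    if missing:
        raise OccurrenceFormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    return FadLadTable({str(r.species): (float(r.fad), float(r.lad)) for r in df.itertuples()})


def write_fad_lad(table: FadLadTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"species": sp, "fad": f, "lad": l} for sp, (f, l) in table.data.items()]
    ).to_csv(path, index=False)


def fad_lad_to_times(table: FadLadTable) -> SpeciesTimes:
    """Take FAD/LAD at face value as origination/extinction times (no preservation correction)."""
    species = tuple(table.data)
    ts = np.array([table.data[s][0] for s in species], dtype=float)
    te = np.array([table.data[s][1] for s in species], dtype=float)
    return SpeciesTimes(species=species, ts=ts, te=te, extant=(te == 0.0))
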