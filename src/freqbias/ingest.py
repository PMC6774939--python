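"""Sampling-event tables and frequency tables.

The observed data for a cultural system of this kind is a long-format table of
*sampling events*: one row per adoption of a cultural variant, carrying the
year it happened, an opaque variant identifier, and an opaque agent (artist)
identifier.  Everything downstream works on the year x variant count matrix
built from those events, plus two constants estimated from them: the effective
population size ``N`` (mean number of unique agents active per year) and the
innovation rate ``mu`` (mean fraction of events per year that introduce a
variant never seen before).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("year", "variant", "agent")

__all__ = [
    "EVENT_COLUMNS",
    "FrequencyTable",
    "read_events",
    "validate_events",
    "build_frequency_table",
    "filter_years",
    "estimate_population_size",
    "estimate_innovation_rate",
]


class FrequencyTable:
    """Timepoints x variants count matrix.

    Parameters
    ----------
    years : array-like of int, shape (T,)
        Strictly increasing timepoint labels.
    variants : array-like of str, shape (V,)
        Unique variant identifiers, one per column.
    counts : array-like of int, shape (T, V)
        ``counts[t, v]`` is the number of events of variant ``v`` at
        timepoint ``t``.

    Columns are kept in the order given; :func:`build_frequency_table` sorts
    them lexicographically so that rankings are reproducible.
    """

    __slots__ = ("years", "variants", "counts")

    def __init__(self, years, variants, counts, *, validate: bool = True):
        self.years = np.asarray(years, dtype=np.int64)
        self.variants = np.asarray(variants, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        T, V = self.counts.shape
        if self.years.shape != (T,):
            raise ValueError(f"years has length {self.years.shape[0]}, expected {T}")
        if self.variants.shape != (V,):
            raise ValueError(f"variants has length {self.variants.shape[0]}, expected {V}")
        if len(set(self.variants.tolist())) != V:
            raise ValueError("variant ids must be unique")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    # ------------------------------------------------------------------
    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def first_seen(self) -> np.ndarray:
        """Row index of each variant's first non-zero count."""
        return np.argmax(self.counts > 0, axis=0)

    def n_present(self) -> np.ndarray:
        """Number of variants with non-zero count at each timepoint."""
        return (self.counts > 0).sum(axis=1)

    def row_counts(self, t: int) -> dict[str, int]:
        """Non-zero ``variant -> count`` mapping for row ``t``."""
        row = self.counts[t]
        nz = row > 0
        return dict(zip(self.variants[nz].tolist(), row[nz].tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.variants.tolist())
        df.insert(0, "year", self.years)
        return df

    def equals(self, other: "FrequencyTable") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.variants, other.variants)
            and np.array_equal(self.counts, other.counts)
        )

    # ------------------------------------------------------------------
    def write_csv(self, path: str | Path, *, sidecar: bool = True) -> None:
        """Write the wide CSV (first column ``year``) plus a JSON metadata
        sidecar (``<path>.meta.json``) recording T, V and row totals."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "n_timepoints": int(self.n_timepoints),
                "n_variants": int(self.n_variants),
                "row_totals": self.counts.sum(axis=1).tolist(),
                "total": int(self.counts.sum()),
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=1)
            )

    @classmethod
    def read_csv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path)
        if df.columns[0] != "year":
            raise ValueError(f"{path}: first column must be 'year', got {df.columns[0]!r}")
        years = df["year"].to_numpy()
        variants = np.asarray(df.columns[1:], dtype=object)
        counts = df.iloc[:, 1:].to_numpy(dtype=np.int64)
        return cls(years, variants, counts)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<FrequencyTable {self.n_timepoints} timepoints x "
            f"{self.n_variants} variants, total {self.counts.sum()}>"
        )


# ----------------------------------------------------------------------
# event tables
# ----------------------------------------------------------------------

def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format sampling-event table.

    Requires columns ``year, variant, agent``; years must be integral and no
    field may be missing.  Returns a copy with canonical dtypes.  Duplicate
    rows are allowed (an agent may re-use a variant within a year).
    """
    if events is None or len(events) == 0:
        raise ValueError("event table is empty")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {', '.join(missing)}")
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    for col in EVENT_COLUMNS:
        na = out[col].isna()
        if na.any():
            row = int(np.flatnonzero(na.to_numpy())[0])
            raise ValueError(f"missing {col!r} in event row {row}")
    try:
        years = pd.to_numeric(out["year"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric year in event table: {exc}") from exc
    if not np.all(np.asarray(years) == np.asarray(years).astype(np.int64)):
        bad = int(np.flatnonzero(np.asarray(years) != np.asarray(years).astype(np.int64))[0])
        raise ValueError(f"non-integer year in event row {bad}")
    out["year"] = years.astype(np.int64)
    out["variant"] = out["variant"].astype(str)
    out["agent"] = out["agent"].astype(str)
    return out


def read_events(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a sampling-event table from TSV/CSV (header ``year,variant,agent``).

    The delimiter is taken from the extension (``.tsv`` -> tab) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"variant": str, "agent": str})
    return validate_events(df)


def build_frequency_table(events: pd.DataFrame) -> FrequencyTable:
    """Aggregate sampling events into a year x variant count matrix.

    Timepoints are sorted ascending and variant columns lexicographically.
    The sum of all cells equals the number of event rows.
    """
    events = validate_events(events)
    pivot = pd.crosstab(events["year"], events["variant"])
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    return FrequencyTable(
        pivot.index.to_numpy(),
        pivot.columns.to_numpy(dtype=object),
        pivot.to_numpy(dtype=np.int64),
    )


def filter_years(table: FrequencyTable, min_variants: int) -> FrequencyTable:
    """Drop timepoints with fewer than ``min_variants`` distinct variants.

    "Distinct" means non-zero count in that row.  Row order is preserved;
    columns are untouched (a variant may end up all-zero).
    """
    if min_variants < 1:
        raise ValueError("min_variants must be >= 1")
    keep = table.n_present() >= min_variants
    if not keep.any():
        raise ValueError(
            f"no timepoint has >= {min_variants} variants "
            f"(max is {int(table.n_present().max())})"
        )
    return FrequencyTable(table.years[keep], table.variants, table.counts[keep])


def estimate_population_size(events: pd.DataFrame) -> int:
    """Mean number of unique agents active per timepoint, rounded to the
    nearest integer (halves away from zero).

    This is the effective population size ``N`` handed to the transmission
    model: each simulated timestep redraws the variants of ``N`` agents.
    """
    events = validate_events(events)
    mean = float(events.groupby("year")["agent"].nunique().mean())
    return int(math.floor(mean + 0.5))


def estimate_innovation_rate(table: FrequencyTable) -> float:
    """Mean fraction of events per timepoint that are first appearances.

    For each timepoint after the first, the number of variants whose first
    non-zero count occurs there is divided by that timepoint's total count;
    the mean over those timepoints is returned.  The first timepoint is
    excluded because every variant is trivially "new" there.
    """
    if table.n_timepoints < 2:
        raise ValueError("innovation rate needs at least 2 timepoints")
    first = table.first_seen()
    rates = []
    for t in range(1, table.n_timepoints):
        total = table.counts[t].sum()
        if total == 0:
            raise ValueError(f"timepoint {table.years[t]} has zero total count")
        rates.append((first == t).sum() / total)
    return float(np.mean(rates))
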