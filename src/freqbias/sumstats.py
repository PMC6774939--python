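"""Turn-over and diversity summary statistics.

The statistics that discriminate transmission biases in frequency data are
built on *top lists*: at each timepoint the variants are ranked by descending
count, and the turn-over rate ``z_y(t)`` is the number of variants newly
entering the top-``y`` list between consecutive timepoints.  Across list
sizes the mean turn-over follows a power law::

    z̄_y = A * y**x

whose exponent ``x`` carries the bias signal: simulation studies place the
neutral (random-copying) value at x ~ 0.86, with conformity producing a
convex profile (x > 0.86, slow turn-over in short lists) and novelty a
concave one (x < 0.86).

Rankings need a deterministic tie-break for turn-over to be reproducible:
ties are broken by earlier first appearance in the table, then by column
order (lexicographic variant id for tables built by
:func:`freqbias.ingest.build_frequency_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ingest import FrequencyTable

__all__ = [
    "TurnoverProfile",
    "SummaryVector",
    "top_list",
    "rank_orders",
    "turnover_matrix",
    "turnover_series",
    "mean_turnover",
    "fit_turnover_exponent",
    "turnover_profile",
    "simpson_diversity",
    "diversity_series",
    "summary_vector",
    "summary_names",
    "ks_against_neutral",
]


# ----------------------------------------------------------------------
# ranking and turn-over
# ----------------------------------------------------------------------

def top_list(counts: Mapping[str, int], y: int) -> list[str]:
    """The ``y`` highest-count variants, count descending.

    Ties are broken by ascending variant id (a bare mapping carries no
    first-appearance information).  If fewer than ``y`` variants have
    non-zero count, all of them are returned.
    """
    if y < 1:
        raise ValueError("top-list size y must be >= 1")
    present = [(v, c) for v, c in counts.items() if c > 0]
    present.sort(key=lambda vc: (-vc[1], str(vc[0])))
    return [v for v, _ in present[:y]]


def rank_orders(freq: FrequencyTable) -> list[np.ndarray]:
    """Per-timepoint ranking of the *present* variants as column indices.

    Order: count descending, then first appearance ascending, then column
    index ascending.
    """
    first = freq.first_seen()
    col = np.arange(freq.n_variants)
    orders = []
    for t in range(freq.n_timepoints):
        row = freq.counts[t]
        order = np.lexsort((col, first, -row))
        orders.append(order[: int((row > 0).sum())])
    return orders


def turnover_matrix(freq: FrequencyTable, y_max: int) -> np.ndarray:
    """Turn-over counts ``z_y(t)`` for every transition and list size.

    Returns an ``(T-1, y_max)`` integer matrix; entry ``[t-1, y-1]`` is the
    number of variants in the top-``y`` list at timepoint ``t`` that were not
    in the top-``y`` list at ``t-1``.  Lists truncate to the number of
    variants present.
    """
    if y_max < 1:
        raise ValueError("y_max must be >= 1")
    T, V = freq.shape
    if T < 2:
        raise ValueError("turn-over needs at least 2 timepoints")
    orders = rank_orders(freq)
    ys = np.arange(1, y_max + 1)
    out = np.empty((T - 1, y_max), dtype=np.int64)
    pos_prev = np.empty(V, dtype=np.int64)
    for t in range(1, T):
        prev, cur = orders[t - 1], orders[t]
        pos_prev.fill(V)  # V == "absent" sentinel, beyond any cap
        pos_prev[prev] = np.arange(len(prev))
        L = min(y_max, len(cur))
        r = pos_prev[cur[:L]]
        cap_cur = np.minimum(ys, len(cur))[:, None]
        cap_prev = np.minimum(ys, len(prev))[:, None]
        in_top = np.arange(L)[None, :] < cap_cur
        is_new = r[None, :] >= cap_prev
        out[t - 1] = (in_top & is_new).sum(axis=1)
    return out


def turnover_series(freq: FrequencyTable, y: int) -> np.ndarray:
    """``z_y(t)`` for consecutive timepoints, length ``T-1``."""
    return turnover_matrix(freq, y)[:, y - 1]


def mean_turnover(freq: FrequencyTable, y_max: int) -> np.ndarray:
    """Mean turn-over rate z̄_y per list size, length ``y_max``."""
    return turnover_matrix(freq, y_max).mean(axis=0)


# ----------------------------------------------------------------------
# power-law fit
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TurnoverProfile:
    """A fitted turn-over profile z̄_y = A * y**x."""

    list_sizes: np.ndarray
    mean_turnover: np.ndarray
    coefficient: float  # A
    exponent: float  # x

    def predicted(self) -> np.ndarray:
        return self.coefficient * self.list_sizes**self.exponent


def fit_turnover_exponent(
    zbar: Sequence[float], y_max: int | None = None
) -> tuple[float, float]:
    """Fit ``z̄_y = A * y**x`` by OLS on ``log z̄_y`` vs ``log y``.

    ``zbar[i]`` is the mean turn-over for list size ``i+1``.  Sizes with
    z̄_y = 0 are excluded (their log is undefined); at least two usable
    sizes are required.  Returns ``(A, x)``.
    """
    zbar = np.asarray(zbar, dtype=float)
    if y_max is not None:
        zbar = zbar[:y_max]
    y = np.arange(1, len(zbar) + 1)
    ok = zbar > 0
    if ok.sum() < 2:
        raise ValueError("power-law fit needs >= 2 list sizes with z̄_y > 0")
    slope, intercept = np.polyfit(np.log(y[ok]), np.log(zbar[ok]), 1)
    return float(np.exp(intercept)), float(slope)


def turnover_profile(
    freq: FrequencyTable, y_max: int, *, cap_at_present: bool = True
) -> TurnoverProfile:
    """Mean turn-over per list size with its fitted power law.

    By default the fit is restricted to list sizes no larger than the
    minimum number of variants present in any timepoint (``cap_at_present``):
    beyond that point every "top list" is the whole population, turn-over
    stops growing with y, and the flattened tail would bias the exponent
    downward.  The reported z̄_y still spans 1..y_max.
    """
    zbar = mean_turnover(freq, y_max)
    fit_to = min(y_max, int(freq.n_present().min())) if cap_at_present else y_max
    A, x = fit_turnover_exponent(zbar, fit_to)
    return TurnoverProfile(np.arange(1, y_max + 1), zbar, A, x)


# ----------------------------------------------------------------------
# diversity
# ----------------------------------------------------------------------

def simpson_diversity(
    counts: Mapping[str, int] | Sequence[int] | np.ndarray,
    *,
    unbiased: bool = False,
) -> float:
    """Simpson's index D = sum_i (n_i/n)**2.

    The probability that two tokens drawn *with replacement* are the same
    variant; near 1 means low diversity.  ``unbiased=True`` uses the
    without-replacement form sum n_i(n_i-1) / (n(n-1)).
    """
    if isinstance(counts, Mapping):
        n = np.fromiter(counts.values(), dtype=float)
    else:
        n = np.asarray(counts, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("simpson_diversity needs a positive total count")
    if unbiased:
        if total < 2:
            raise ValueError("unbiased Simpson needs a total count >= 2")
        return float((n * (n - 1)).sum() / (total * (total - 1)))
    p = n / total
    return float((p**2).sum())


def diversity_series(freq: FrequencyTable, *, unbiased: bool = False) -> np.ndarray:
    return np.array(
        [simpson_diversity(freq.counts[t], unbiased=unbiased) for t in range(freq.n_timepoints)]
    )


# ----------------------------------------------------------------------
# the summary vector
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryVector:
    """The flat statistics record handed to the ABC machinery.

    Slot order (fixed): turn-over exponent ``x``; mean turn-over z̄_y for
    y = 1..y_max; per-timepoint Simpson diversity D_t for t = 1..T; mean
    diversity D̄; optionally two linear-discriminant axes.  With y_max = 142
    and T = 32 the base length is 176 (178 with the LDA axes).

    ``x`` is NaN when the power-law fit is degenerate (fewer than two
    non-zero mean turn-over values); such records are rejected from
    reference tables.
    """

    exponent: float
    mean_turnover: np.ndarray
    diversity: np.ndarray
    mean_diversity: float
    lda: np.ndarray | None = None

    def __len__(self) -> int:
        return 2 + len(self.mean_turnover) + len(self.diversity) + (
            len(self.lda) if self.lda is not None else 0
        )

    def to_array(self) -> np.ndarray:
        parts = [
            np.array([self.exponent]),
            np.asarray(self.mean_turnover, dtype=float),
            np.asarray(self.diversity, dtype=float),
            np.array([self.mean_diversity]),
        ]
        if self.lda is not None:
            parts.append(np.asarray(self.lda, dtype=float))
        return np.concatenate(parts)

    def names(self) -> list[str]:
        return summary_names(
            len(self.mean_turnover), len(self.diversity), lda=self.lda is not None
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_array(), index=self.names())

    def with_lda(self, axes: np.ndarray) -> "SummaryVector":
        return SummaryVector(
            self.exponent,
            self.mean_turnover,
            self.diversity,
            self.mean_diversity,
            np.asarray(axes, dtype=float),
        )


def summary_names(y_max: int, n_timepoints: int, *, lda: bool = False) -> list[str]:
    names = (
        ["x"]
        + [f"zbar_{y}" for y in range(1, y_max + 1)]
        + [f"D_{t}" for t in range(1, n_timepoints + 1)]
        + ["Dbar"]
    )
    if lda:
        names += ["LD1", "LD2"]
    return names


def summary_vector(
    freq: FrequencyTable,
    y_max: int,
    *,
    require_full_lists: bool = False,
) -> SummaryVector:
    """Assemble the base summary-statistics vector for a frequency table.

    The exponent slot is fitted over list sizes up to the minimum number of
    variants present in any timepoint (never beyond ``y_max``), where top
    lists are genuinely ranked subsets; see :func:`turnover_profile`.

    ``require_full_lists=True`` errors when any timepoint holds fewer than
    ``y_max`` variants (so every top list is full); by default shorter
    timepoints simply truncate their lists, which is what the simulated
    reference tables need.
    """
    if freq.n_timepoints < 2:
        raise ValueError("summary vector needs at least 2 timepoints")
    if require_full_lists:
        m = int(freq.n_present().min())
        if y_max > m:
            raise ValueError(
                f"y_max={y_max} exceeds the minimum per-timepoint variant count ({m})"
            )
    zbar = mean_turnover(freq, y_max)
    fit_to = min(y_max, int(freq.n_present().min()))
    try:
        _, x = fit_turnover_exponent(zbar, fit_to)
    except ValueError:
        x = float("nan")
    D = diversity_series(freq)
    return SummaryVector(x, zbar, D, float(D.mean()))


# ----------------------------------------------------------------------
# comparison against neutral expectations
# ----------------------------------------------------------------------

def ks_against_neutral(
    observed_z: np.ndarray,
    neutral_z: np.ndarray,
    *,
    method: str = "pooled",
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test of observed vs neutral turn-over.

    ``method='pooled'`` compares all z values (matrices are flattened);
    ``method='per_size_mean'`` first averages each input over time, comparing
    the per-list-size means.  Returns ``(statistic, p_value)``.
    """
    obs = np.asarray(observed_z, dtype=float)
    neu = np.asarray(neutral_z, dtype=float)
    if method == "per_size_mean":
        if obs.ndim == 2:
            obs = obs.mean(axis=0)
        if neu.ndim == 2:
            neu = neu.mean(axis=0)
    elif method == "pooled":
        obs = obs.ravel()
        neu = neu.ravel()
    else:
        raise ValueError(f"unknown method {method!r}")
    if obs.size == 0 or neu.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = sps.ks_2samp(obs, neu)
    return float(res.statistic), float(res.pvalue)
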