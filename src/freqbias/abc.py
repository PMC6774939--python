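"""Rejection approximate Bayesian computation for the bias parameter b.

The estimation recipe: draw ``b`` from a uniform prior, run the transmission
model at the observation-derived constants (N, mu, warm-up, number of
timepoints), summarise each run by the turn-over exponent ``x`` and the mean
Simpson diversity ``D̄``, and accept the fraction ``epsilon`` of draws whose
statistics lie closest (Euclidean distance, after per-statistic
median-absolute-deviation standardisation) to the observed pair.  The
accepted draws approximate the posterior of ``b``; it is summarised by its
median and the 95% highest-posterior-density interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import SimulationParams, run_simulation

__all__ = [
    "UniformPrior",
    "ReferenceTable",
    "Posterior",
    "hpdi",
    "generate_reference",
    "reject",
    "goodness_of_fit",
    "cross_validate",
]

REJECTION_STATS = ("x", "Dbar")


@dataclass(frozen=True)
class UniformPrior:
    """Uniform prior over an interval of b."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate prior: [{self.lower}, {self.upper}]")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=size)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class ReferenceTable:
    """Simulated (b, summary statistics) records.

    ``stats`` is an (n, k) float matrix with columns named by ``stat_names``
    (``("x", "Dbar")`` for parameter inference).
    """

    b: np.ndarray
    stats: np.ndarray
    stat_names: tuple[str, ...] = REJECTION_STATS

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.stats = np.atleast_2d(np.asarray(self.stats, dtype=float))
        if self.stats.shape[0] != self.b.shape[0]:
            raise ValueError("b and stats row counts differ")
        if self.stats.shape[1] != len(self.stat_names):
            raise ValueError("stat_names length does not match stats columns")

    def __len__(self) -> int:
        return len(self.b)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=list(self.stat_names))
        df.insert(0, "b", self.b)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path)
        return cls(
            df["b"].to_numpy(),
            df.drop(columns="b").to_numpy(),
            tuple(c for c in df.columns if c != "b"),
        )


@dataclass(frozen=True)
class Posterior:
    """Accepted-sample posterior of b."""

    accepted: np.ndarray
    epsilon: float
    n_reference: int

    @property
    def median(self) -> float:
        return float(np.median(self.accepted))

    @property
    def hpdi_95(self) -> tuple[float, float]:
        return hpdi(self.accepted, 0.95)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def to_dict(self) -> dict:
        lo, hi = self.hpdi_95
        return {
            "median": self.median,
            "hpdi_95": [lo, hi],
            "epsilon": self.epsilon,
            "n_accepted": self.n_accepted,
            "n_reference": self.n_reference,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def hpdi(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the sample.

    Scans every window of ``ceil(mass * n)`` consecutive order statistics and
    returns the narrowest.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    m = min(n, int(math.ceil(mass * n)))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


# ----------------------------------------------------------------------
# reference-table generation
# ----------------------------------------------------------------------

def generate_reference(
    n_iter: int,
    prior: UniformPrior,
    base_params: SimulationParams,
    *,
    y_max: int = 142,
    seed: int | None = None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_iter`` (b, x, D̄) records with b drawn from the prior.

    Each record runs one simulation at ``base_params`` with its own drawn b
    and an independent child random stream, so the table is reproducible
    from ``seed``.  Records with an unfittable turn-over exponent are
    re-recorded as NaN and dropped (count reported via the table length).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    root = np.random.SeedSequence(seed if seed is not None else base_params.seed)
    draws_rng = np.random.default_rng(root.spawn(1)[0])
    bs = prior.sample(draws_rng, n_iter)
    children = root.spawn(n_iter)
    rows = np.empty((n_iter, 2))
    for i, (b, child) in enumerate(zip(bs, children)):
        params = SimulationParams(
            base_params.n_agents,
            base_params.mu,
            float(b),
            base_params.warmup,
            base_params.timesteps,
        )
        res = run_simulation(params, y_max=y_max, rng=np.random.default_rng(child))
        s = res.summary()
        rows[i] = (s.exponent, s.mean_diversity)
        if progress and (i + 1) % 1000 == 0:  # pragma: no cover
            print(f"  reference: {i + 1}/{n_iter}", flush=True)
    ok = np.isfinite(rows[:, 0])
    return ReferenceTable(bs[ok], rows[ok], REJECTION_STATS)


# ----------------------------------------------------------------------
# rejection
# ----------------------------------------------------------------------

def _mad_scale(stats: np.ndarray) -> np.ndarray:
    scale = sps.median_abs_deviation(stats, axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant stats carry no distance
    return scale


def _distances(
    observed: np.ndarray,
    stats: np.ndarray,
    scale: np.ndarray | None,
) -> np.ndarray:
    diff = stats - observed
    if scale is not None:
        diff = diff / scale
    return np.sqrt((diff**2).sum(axis=1))


def reject(
    observed: Sequence[float],
    ref: ReferenceTable,
    epsilon: float,
    *,
    standardize: bool = True,
) -> Posterior:
    """Rejection step: accept the ``round(epsilon * n)`` closest records.

    Statistics are standardised by their median absolute deviation across the
    reference table before the Euclidean distance is taken
    (``standardize=False`` uses raw statistics).
    """
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must be in (0, 1]")
    if len(ref) == 0:
        raise ValueError("empty reference table")
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (ref.stats.shape[1],):
        raise ValueError(
            f"observed has {observed.shape} statistics, reference has {ref.stats.shape[1]}"
        )
    n_accept = int(round(epsilon * len(ref)))
    if n_accept < 1:
        raise ValueError(
            f"epsilon={epsilon} accepts 0 of {len(ref)} reference records"
        )
    scale = _mad_scale(ref.stats) if standardize else None
    d = _distances(observed, ref.stats, scale)
    idx = np.argsort(d, kind="stable")[:n_accept]
    return Posterior(np.sort(ref.b[idx]), epsilon, len(ref))


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def _median_accepted_distance(
    observed: np.ndarray,
    stats: np.ndarray,
    scale: np.ndarray | None,
    n_accept: int,
) -> float:
    d = _distances(observed, stats, scale)
    return float(np.median(np.partition(d, n_accept - 1)[:n_accept]))


def goodness_of_fit(
    observed: Sequence[float],
    ref: ReferenceTable,
    n: int = 1000,
    epsilon: float = 0.01,
    *,
    standardize: bool = True,
    seed: int | None = None,
) -> float:
    """Posterior-predictive style goodness-of-fit p-value.

    The test statistic is the median distance of the accepted records.  A
    null distribution is built from ``n`` pseudo-observed records drawn from
    the reference table, each evaluated leave-one-out against the remaining
    records; ``p`` is the fraction of null statistics at least as large as
    the observed one.  Small p flags an observation the model cannot reach.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_accept = int(round(epsilon * len(ref)))
    if n_accept < 1:
        raise ValueError("epsilon accepts 0 records")
    scale = _mad_scale(ref.stats) if standardize else None
    obs_stat = _median_accepted_distance(
        np.asarray(observed, dtype=float), ref.stats, scale, n_accept
    )
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(ref), size=n)
    null = np.empty(n)
    mask = np.ones(len(ref), dtype=bool)
    for j, i in enumerate(picks):
        mask[i] = False
        null[j] = _median_accepted_distance(
            ref.stats[i], ref.stats[mask], scale, min(n_accept, len(ref) - 1)
        )
        mask[i] = True
    return float(np.mean(null >= obs_stat))


def cross_validate(
    ref: ReferenceTable,
    tolerances: Sequence[float] = (0.005, 0.01, 0.05),
    n: int = 10,
    *,
    standardize: bool = True,
    seed: int | None = None,
) -> dict[float, np.ndarray]:
    """Leave-one-out cross-validation of the rejection estimator.

    For ``n`` randomly chosen reference records treated as pseudo-observed,
    b is re-estimated (posterior median) from the remaining records at each
    tolerance.  Returns, per tolerance, the squared prediction errors
    normalised by the variance of b across the table, so ~1 means the
    statistics are uninformative and ~0 means near-perfect recovery.
    """
    if len(ref) <= n:
        raise ValueError("reference table must be larger than n")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ref), size=n, replace=False)
    var_b = float(np.var(ref.b))
    out: dict[float, np.ndarray] = {}
    mask = np.ones(len(ref), dtype=bool)
    for tol in tolerances:
        errs = np.empty(n)
        for j, i in enumerate(picks):
            mask[i] = False
            sub = ReferenceTable(ref.b[mask], ref.stats[mask], ref.stat_names)
            post = reject(ref.stats[i], sub, tol, standardize=standardize)
            errs[j] = (post.median - ref.b[i]) ** 2 / var_b
            mask[i] = True
        out[float(tol)] = errs
    return out
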