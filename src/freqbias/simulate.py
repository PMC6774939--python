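"""Agent-based infinite-alleles cultural transmission model.

A population of ``N`` agents each carries one cultural variant.  At every
timestep all agents are replaced simultaneously (non-overlapping
generations): each new agent innovates with probability ``mu`` — adopting a
globally novel variant label, the infinite-alleles convention — and otherwise
copies a variant ``k`` from the previous timestep with probability
proportional to ``n_k ** (1 - b)``, where ``n_k`` is the variant's count.

``b = 0`` is neutral (random copying: adoption exactly proportional to
frequency); ``b < 0`` inflates common variants' weights (conformity bias);
``b > 0`` favours rare variants (novelty bias).

Runs begin from maximal diversity (N distinct singleton variants) and discard
a warm-up period so statistics are measured at quasi-equilibrium, where the
starting condition is immaterial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .ingest import FrequencyTable
from . import sumstats

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "step",
    "run_simulation",
    "estimate_warmup",
]

_LABEL_WIDTH = 9  # zero-padding keeps lexicographic id order == creation order


@dataclass(frozen=True)
class SimulationParams:
    """Configuration of one transmission-model run.

    Parameters
    ----------
    n_agents : int
        Population size N (one variant per agent per timestep).
    mu : float
        Innovation probability per agent per timestep, in [0, 1].
    b : float
        Frequency-bias parameter; negative = conformity, positive = novelty,
        zero = neutral.
    warmup : int
        Timesteps simulated and discarded before recording starts.
    timesteps : int
        Recorded timesteps.
    seed : int or None
        Seed for the run's single random stream.
    """

    n_agents: int
    mu: float
    b: float = 0.0
    warmup: int = 0
    timesteps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")
        if self.timesteps < 1:
            raise ValueError("timesteps must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Recorded output of a run (warm-up excluded).

    ``freq`` rows each sum to N; ``diversity`` is the per-timepoint Simpson
    index; ``turnover[t-1, y-1]`` is the turn-over of the top-``y`` list at
    transition ``t``.
    """

    params: SimulationParams
    freq: FrequencyTable
    diversity: np.ndarray
    turnover: np.ndarray
    y_max: int

    def summary(self, y_max: int | None = None) -> sumstats.SummaryVector:
        """Base summary-statistics vector of the recorded frequencies."""
        if y_max is None or y_max == self.y_max:
            zbar = self.turnover.mean(axis=0) if len(self.turnover) else np.zeros(self.y_max)
            fit_to = min(self.y_max, int(self.freq.n_present().min()))
            try:
                _, x = sumstats.fit_turnover_exponent(zbar, fit_to)
            except ValueError:
                x = float("nan")
            return sumstats.SummaryVector(
                x, zbar, self.diversity, float(self.diversity.mean())
            )
        return sumstats.summary_vector(self.freq, y_max)


# ----------------------------------------------------------------------
# core update
# ----------------------------------------------------------------------

def _step_arrays(
    counts: np.ndarray,
    n_agents: int,
    mu: float,
    b: float,
    n_innovated: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One generation on a dense count vector.

    Returns the multinomial copy counts over the previous variants (the
    ``n_innovated`` novel singletons are appended by the caller).
    """
    n_copy = n_agents - n_innovated
    if n_copy == 0:
        return np.zeros_like(counts), n_innovated
    weights = counts.astype(float) ** (1.0 - b)
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("degenerate copy weights (zero or non-finite sum)")
    return rng.multinomial(n_copy, weights / total), n_innovated


def step(
    counts_prev: Mapping[str, int],
    params: SimulationParams,
    rng: np.random.Generator,
    *,
    novel_labels: "itertools.count | None" = None,
) -> dict[str, int]:
    """Advance one timestep on a ``variant -> count`` mapping.

    ``counts_prev`` must sum to ``params.n_agents``.  Novel variants receive
    labels ``new_0, new_1, ...`` from ``novel_labels`` (a shared
    ``itertools.count`` guarantees infinite-alleles novelty across calls); a
    fresh counter is used when none is given, in which case labels are made
    unique against ``counts_prev`` only.
    """
    labels = np.asarray(list(counts_prev.keys()), dtype=object)
    counts = np.asarray(list(counts_prev.values()), dtype=np.int64)
    if counts.sum() != params.n_agents:
        raise ValueError(
            f"counts_prev sums to {counts.sum()}, expected n_agents={params.n_agents}"
        )
    if np.any(counts < 0):
        raise ValueError("counts_prev has negative counts")
    n_new = int(rng.binomial(params.n_agents, params.mu)) if params.mu > 0 else 0
    copied, _ = _step_arrays(counts, params.n_agents, params.mu, params.b, n_new, rng)
    out: dict[str, int] = {
        str(lab): int(c) for lab, c in zip(labels, copied) if c > 0
    }
    counter = novel_labels if novel_labels is not None else itertools.count()
    for _ in range(n_new):
        lab = f"new_{next(counter)}"
        while lab in counts_prev or lab in out:
            lab = f"new_{next(counter)}"
        out[lab] = 1
    return out


# ----------------------------------------------------------------------
# whole runs
# ----------------------------------------------------------------------

def _run_core(
    params: SimulationParams,
    rng: np.random.Generator,
    record: bool,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Iterate the model; returns recorded (labels, counts) pairs and the
    recorded diversity series.  Labels are a monotone integer counter, so
    creation order == numeric order."""
    N, mu, b = params.n_agents, params.mu, params.b
    labels = np.arange(N, dtype=np.int64)
    counts = np.ones(N, dtype=np.int64)
    next_label = N
    rec_labels: list[np.ndarray] = []
    rec_counts: list[np.ndarray] = []
    diversity = np.empty(params.timesteps)
    for t in range(params.warmup + params.timesteps):
        n_new = int(rng.binomial(N, mu)) if mu > 0 else 0
        copied, _ = _step_arrays(counts, N, mu, b, n_new, rng)
        keep = copied > 0
        if n_new:
            labels = np.concatenate(
                [labels[keep], np.arange(next_label, next_label + n_new)]
            )
            counts = np.concatenate(
                [copied[keep], np.ones(n_new, dtype=np.int64)]
            )
            next_label += n_new
        else:
            labels = labels[keep]
            counts = copied[keep]
        if t >= params.warmup:
            i = t - params.warmup
            p = counts / N
            diversity[i] = float((p**2).sum())
            if record:
                rec_labels.append(labels.copy())
                rec_counts.append(counts.copy())
    return rec_labels, rec_counts, diversity


def _assemble_freq(
    rec_labels: list[np.ndarray],
    rec_counts: list[np.ndarray],
    start_year: int,
) -> FrequencyTable:
    all_labels = np.unique(np.concatenate(rec_labels))
    index = {lab: i for i, lab in enumerate(all_labels.tolist())}
    T, V = len(rec_labels), len(all_labels)
    counts = np.zeros((T, V), dtype=np.int64)
    for t, (labs, cnts) in enumerate(zip(rec_labels, rec_counts)):
        counts[t, [index[l] for l in labs.tolist()]] = cnts
    variants = np.array([f"v{lab:0{_LABEL_WIDTH}d}" for lab in all_labels], dtype=object)
    years = np.arange(start_year, start_year + T)
    return FrequencyTable(years, variants, counts, validate=False)


def run_simulation(
    params: SimulationParams,
    *,
    y_max: int = 142,
    start_year: int = 0,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run the transmission model and summarise the recorded window.

    Initialises N agents with N distinct variants, discards ``params.warmup``
    timesteps, then records ``params.timesteps`` states.  Fully reproducible
    from ``params.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rec_labels, rec_counts, diversity = _run_core(params, rng, record=True)
    freq = _assemble_freq(rec_labels, rec_counts, start_year)
    if params.timesteps >= 2:
        turnover = sumstats.turnover_matrix(freq, y_max)
    else:
        turnover = np.zeros((0, y_max), dtype=np.int64)
    return SimulationResult(params, freq, diversity, turnover, y_max)


# ----------------------------------------------------------------------
# warm-up estimation
# ----------------------------------------------------------------------

def estimate_warmup(
    params_neutral: SimulationParams,
    reps: int = 1000,
    horizon: int = 500,
    *,
    window: int = 50,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> int:
    """Earliest timestep at which mean diversity has reached equilibrium.

    Runs ``reps`` neutral simulations for ``horizon`` steps (no warm-up),
    averages the Simpson-diversity series across runs, and slides a
    ``window``-step OLS fit along it: the first window whose slope is not
    significantly different from zero (t-test, p >= ``alpha``) marks the
    plateau, and its start index is returned.

    Raises if ``params_neutral.b != 0`` or if no plateau is found within the
    horizon.
    """
    if params_neutral.b != 0:
        raise ValueError("warm-up estimation is defined for the neutral model (b = 0)")
    if reps < 1 or horizon < window + 1:
        raise ValueError("need reps >= 1 and horizon > window")
    if rng is None:
        rng = np.random.default_rng(params_neutral.seed)
    p = replace(params_neutral, warmup=0, timesteps=horizon)
    acc = np.zeros(horizon)
    for _ in range(reps):
        _, _, div = _run_core(p, rng, record=False)
        acc += div
    acc /= reps
    xs = np.arange(window)
    for start in range(horizon - window + 1):
        res = sps.linregress(xs, acc[start : start + window])
        if res.pvalue >= alpha:
            return start
    raise RuntimeError(
        f"diversity did not plateau within {horizon} steps "
        f"(window={window}, alpha={alpha})"
    )
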