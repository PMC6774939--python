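"""Random-forest ABC model choice: conformity vs novelty vs neutrality.

Reference data are simulated from three candidate transmission models —
conformity (b drawn from U(-0.2, 0)), novelty (b from U(0, 0.2)) and
neutrality (b fixed at 0) — and summarised by 176 base statistics (turn-over
exponent, per-size mean turn-over, per-timepoint and mean Simpson diversity).
Two linear-discriminant axes fitted on the labelled table are appended
(178 predictors), and a classification forest of bootstrap-trained trees
votes on which model generated the observed statistics.  The forest's
out-of-bag records provide an internal error estimate and, following the
random-forest-ABC recipe, a posterior probability for the selected model:
one minus the predicted OOB misclassification rate at the observed point,
estimated by a regression forest trained on the per-record OOB error
indicator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .abc import UniformPrior
from .simulate import SimulationParams, run_simulation
from .sumstats import SummaryVector, summary_names

logger = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "DEFAULT_PRIORS",
    "ChoiceReference",
    "TrainedForest",
    "RFChoiceResult",
    "build_choice_reference",
    "train_forest",
    "classify",
    "posterior_probability",
    "variable_importance",
]

MODELS = ("conformity", "novelty", "neutrality")
DEFAULT_PRIORS: dict[str, UniformPrior] = {
    "conformity": UniformPrior(-0.2, 0.0),
    "novelty": UniformPrior(0.0, 0.2),
}


@dataclass
class ChoiceReference:
    """Labelled (model, statistics) table with its fitted LDA projection.

    ``stats`` holds the 176 base statistics plus the two LDA axes per row;
    ``labels`` the generating model names.  ``n_dropped`` counts simulated
    records discarded for an unfittable turn-over exponent.
    """

    stats: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    lda: LinearDiscriminantAnalysis
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.stats.shape[0] != self.labels.shape[0]:
            raise ValueError("stats and labels row counts differ")
        if self.stats.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_base(self) -> int:
        return self.stats.shape[1] - 2  # minus the two LDA axes

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=self.feature_names)
        df.insert(0, "model", self.labels)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def project(self, base_stats: np.ndarray) -> np.ndarray:
        """Append the two LDA axes to a vector of base statistics."""
        base_stats = np.asarray(base_stats, dtype=float)
        axes = self.lda.transform(base_stats.reshape(1, -1))[0]
        return np.concatenate([base_stats, axes])


def _simulate_stats(
    n_runs: int,
    b_values: np.ndarray,
    base_params: SimulationParams,
    y_max: int,
    children: list[np.random.SeedSequence],
) -> np.ndarray:
    T = base_params.timesteps
    rows = np.empty((n_runs, 2 + y_max + T))
    for i in range(n_runs):
        params = SimulationParams(
            base_params.n_agents,
            base_params.mu,
            float(b_values[i]),
            base_params.warmup,
            T,
        )
        res = run_simulation(params, y_max=y_max, rng=np.random.default_rng(children[i]))
        rows[i] = res.summary().to_array()
    return rows


def build_choice_reference(
    n_per_model: int,
    base_params: SimulationParams,
    *,
    priors: Mapping[str, UniformPrior] | None = None,
    y_max: int = 142,
    seed: int | None = None,
    shrinkage: bool = False,
    progress: bool = False,
) -> ChoiceReference:
    """Simulate ``n_per_model`` runs per candidate model and fit the LDA axes.

    ``shrinkage=True`` switches the discriminant to the shrinkage-regularised
    eigen solver, needed for tiny tables whose within-class covariance is
    near-singular.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    priors = dict(DEFAULT_PRIORS) if priors is None else dict(priors)
    root = np.random.SeedSequence(seed if seed is not None else base_params.seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    T = base_params.timesteps
    base_cols = summary_names(y_max, T)
    blocks, labels = [], []
    for model in MODELS:
        if model == "neutrality":
            bs = np.zeros(n_per_model)
        else:
            bs = priors[model].sample(draw_rng, n_per_model)
        children = root.spawn(n_per_model)
        if progress:  # pragma: no cover
            print(f"  simulating {n_per_model} runs of the {model} model", flush=True)
        blocks.append(_simulate_stats(n_per_model, bs, base_params, y_max, children))
        labels.append(np.full(n_per_model, model, dtype=object))
    stats = np.vstack(blocks)
    labels = np.concatenate(labels)
    ok = np.isfinite(stats[:, 0])
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d records with unfittable turn-over exponent", n_dropped)
    stats, labels = stats[ok], labels[ok]
    if len(np.unique(labels)) < len(MODELS):
        raise ValueError("a model class lost all its records; increase n_per_model")
    if shrinkage:
        lda = LinearDiscriminantAnalysis(n_components=2, solver="eigen", shrinkage="auto")
    else:
        lda = LinearDiscriminantAnalysis(n_components=2)
    axes = lda.fit_transform(stats, labels.astype(str))
    return ChoiceReference(
        np.hstack([stats, axes]),
        labels,
        base_cols + ["LD1", "LD2"],
        lda,
        n_dropped,
    )


# ----------------------------------------------------------------------
# forest
# ----------------------------------------------------------------------

@dataclass
class TrainedForest:
    """A classification forest with its reference table and OOB bookkeeping."""

    classifier: RandomForestClassifier
    reference: ChoiceReference

    @property
    def n_trees(self) -> int:
        return len(self.classifier.estimators_)

    @property
    def oob_error(self) -> float:
        """Out-of-bag misclassification rate."""
        return float(1.0 - self.classifier.oob_score_)

    def oob_misclassified(self) -> np.ndarray:
        """Per-record indicator: OOB-predicted class != true class."""
        dec = self.classifier.oob_decision_function_
        pred = self.classifier.classes_[np.argmax(dec, axis=1)]
        return (pred != self.reference.labels.astype(str)).astype(float)


def train_forest(
    ref: ChoiceReference,
    n_trees: int = 1000,
    *,
    seed: int | None = None,
    n_jobs: int | None = None,
) -> TrainedForest:
    """Train a bootstrap classification forest on the reference table.

    Each tree sees a bootstrap sample of ``len(ref)`` rows; OOB predictions
    are retained for the error estimate and the posterior-probability step.
    Tree hyper-parameters beyond the count follow the learner's
    classification defaults.
    """
    if len(np.unique(ref.labels)) < 2:
        raise ValueError("reference table must contain at least 2 model classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=None if seed is None else int(seed) % (2**31),
        n_jobs=n_jobs,
    )
    clf.fit(ref.stats, ref.labels.astype(str))
    return TrainedForest(clf, ref)


def _as_feature_row(forest: TrainedForest, observed) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        arr = observed.to_array()
    else:
        arr = np.asarray(observed, dtype=float)
    k = forest.reference.stats.shape[1]
    if arr.shape == (k,):
        return arr
    if arr.shape == (forest.reference.n_base,):
        return forest.reference.project(arr)
    raise ValueError(
        f"observed has {arr.shape[0]} statistics; expected {forest.reference.n_base} "
        f"(base) or {k} (with LDA axes)"
    )


def classify(forest: TrainedForest, observed) -> tuple[dict[str, int], str]:
    """Tally per-tree votes for the observed statistics.

    ``observed`` may be a :class:`SummaryVector` or array of base statistics
    (LDA axes are appended from the training projection) or a full
    LDA-augmented vector.  Returns ``(votes, selected)``; the winner is the
    plurality class, ties broken by class-name order.
    """
    x = _as_feature_row(forest, observed).reshape(1, -1)
    clf = forest.classifier
    tree_pred = np.array(
        [clf.classes_[int(t.predict(x)[0])] for t in clf.estimators_]
    )
    votes = {m: int((tree_pred == m).sum()) for m in MODELS if m in clf.classes_}
    selected = max(sorted(votes), key=lambda m: votes[m])
    return votes, selected


def posterior_probability(
    forest: TrainedForest,
    observed,
    *,
    n_trees: int = 500,
    seed: int | None = None,
) -> float:
    """Posterior probability of the selected model at the observed point.

    A regression forest is fitted to the per-record out-of-bag
    misclassification indicator over the predictors; the posterior
    probability is one minus its prediction at the observed statistics,
    clipped to [0, 1].
    """
    indicator = forest.oob_misclassified()
    reg = RandomForestRegressor(
        n_estimators=n_trees,
        random_state=None if seed is None else int(seed) % (2**31),
    )
    reg.fit(forest.reference.stats, indicator)
    x = _as_feature_row(forest, observed).reshape(1, -1)
    return float(np.clip(1.0 - reg.predict(x)[0], 0.0, 1.0))


def variable_importance(forest: TrainedForest) -> pd.Series:
    """Gini importances (mean impurity decrease) ranked descending."""
    return pd.Series(
        forest.classifier.feature_importances_,
        index=forest.reference.feature_names,
        name="gini_importance",
    ).sort_values(ascending=False)


# ----------------------------------------------------------------------
# result bundle
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RFChoiceResult:
    """Votes, selection and calibration of a model-choice run."""

    votes: dict[str, int]
    selected: str
    posterior_prob: float
    oob_error: float
    importances: pd.Series

    def to_dict(self, top_k: int = 10) -> dict:
        return {
            "votes": self.votes,
            "selected": self.selected,
            "posterior_prob": self.posterior_prob,
            "oob_error": self.oob_error,
            "top_importances": {
                k: float(v) for k, v in self.importances.head(top_k).items()
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def model_choice(
    forest: TrainedForest,
    observed,
    *,
    seed: int | None = None,
) -> RFChoiceResult:
    """Run the classification, calibration and importance steps together."""
    votes, selected = classify(forest, observed)
    prob = posterior_probability(forest, observed, seed=seed)
    return RFChoiceResult(
        votes, selected, prob, forest.oob_error, variable_importance(forest)
    )
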