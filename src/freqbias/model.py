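"""Model/Results interface tying the pipeline together.

:class:`FrequencyBiasModel` is built from observed (or synthetic) data and
holds the frequency table plus the observation-derived constants of the
transmission model.  ``fit()`` runs rejection ABC and returns
:class:`RejectionABCResults` (posterior of the bias parameter b with
uncertainty and diagnostics); ``fit_model_choice()`` runs random-forest ABC
and returns :class:`ModelChoiceResults` (votes, posterior probability,
out-of-bag error, variable importances).  Simulation and plotting hang off
these objects.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import abc as abc_mod
from . import ingest, rf, sumstats
from .simulate import SimulationParams, SimulationResult, run_simulation

__all__ = ["FrequencyBiasModel", "RejectionABCResults", "ModelChoiceResults"]


class FrequencyBiasModel:
    """Frequency-dependent transmission model for a cultural frequency table.

    Parameters
    ----------
    freq : FrequencyTable
        Observed year x variant counts.
    n_agents : int
        Population size N of the transmission model (typically the mean
        number of unique agents per year; see
        :func:`freqbias.ingest.estimate_population_size`).
    mu : float
        Innovation rate (mean fraction of first-appearance events per year).
    warmup : int, default 200
        Warm-up timesteps discarded from every simulation.
    y_max : int, optional
        Largest top-list size used in the turn-over statistics; defaults to
        the minimum number of variants present in any year.

    Examples
    --------
    >>> from freqbias import synth
    >>> ds = synth.generate_dataset(synth.SynthConfig(b_true=-0.05, seed=7))
    >>> model = FrequencyBiasModel.from_events(ds.events)
    >>> res = model.fit(n_iter=2000, seed=1)   # doctest: +SKIP
    >>> print(res.summary())                   # doctest: +SKIP
    """

    def __init__(
        self,
        freq: ingest.FrequencyTable,
        *,
        n_agents: int,
        mu: float,
        warmup: int = 200,
        y_max: int | None = None,
    ) -> None:
        if freq.n_timepoints < 2:
            raise ValueError("model needs a frequency table with >= 2 timepoints")
        self.freq = freq
        self.n_agents = int(n_agents)
        self.mu = float(mu)
        self.warmup = int(warmup)
        self.y_max = int(y_max) if y_max is not None else int(freq.n_present().min())
        self._observed: sumstats.SummaryVector | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        *,
        min_variants: int | None = None,
        warmup: int = 200,
        y_max: int | None = None,
    ) -> "FrequencyBiasModel":
        """Build the model from a long-format sampling-event table.

        Estimates N and mu from the events; ``min_variants`` optionally
        drops sparse years first (frequency-table filtering).
        """
        events = ingest.validate_events(events)
        freq = ingest.build_frequency_table(events)
        if min_variants is not None:
            freq = ingest.filter_years(freq, min_variants)
            events = events[events["year"].isin(freq.years)]
        return cls(
            freq,
            n_agents=ingest.estimate_population_size(events),
            mu=ingest.estimate_innovation_rate(freq),
            warmup=warmup,
            y_max=y_max,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "FrequencyBiasModel":
        """Build the model from an on-disk event table (TSV/CSV)."""
        return cls.from_events(ingest.read_events(path), **kwargs)

    # ------------------------------------------------------------------
    def base_params(self, b: float = 0.0, seed: int | None = None) -> SimulationParams:
        """Simulation parameters matching the observed data's geometry."""
        return SimulationParams(
            self.n_agents, self.mu, b, self.warmup, self.freq.n_timepoints, seed
        )

    def simulate(
        self, b: float = 0.0, *, seed: int | None = None, timesteps: int | None = None
    ) -> SimulationResult:
        """One transmission-model run at this model's constants."""
        params = self.base_params(b, seed)
        if timesteps is not None:
            params = replace(params, timesteps=timesteps)
        return run_simulation(params, y_max=self.y_max)

    @property
    def observed_stats(self) -> sumstats.SummaryVector:
        """Summary statistics of the observed frequency table (cached)."""
        if self._observed is None:
            self._observed = sumstats.summary_vector(self.freq, self.y_max)
        return self._observed

    # ------------------------------------------------------------------
    def fit(
        self,
        *,
        n_iter: int = 100_000,
        epsilon: float = 0.01,
        prior: abc_mod.UniformPrior | tuple[float, float] = (-0.2, 0.2),
        seed: int | None = None,
        reference: abc_mod.ReferenceTable | None = None,
        progress: bool = False,
    ) -> "RejectionABCResults":
        """Estimate b by rejection ABC on (x, D̄).

        A pre-computed ``reference`` table skips simulation (useful for
        refitting at different tolerances).
        """
        if not isinstance(prior, abc_mod.UniformPrior):
            prior = abc_mod.UniformPrior(*prior)
        if reference is None:
            reference = abc_mod.generate_reference(
                n_iter, prior, self.base_params(), y_max=self.y_max,
                seed=seed, progress=progress,
            )
        obs = self.observed_stats
        posterior = abc_mod.reject(
            (obs.exponent, obs.mean_diversity), reference, epsilon
        )
        return RejectionABCResults(self, prior, reference, posterior, seed)

    def fit_model_choice(
        self,
        *,
        n_per_model: int = 50_000,
        n_trees: int = 1000,
        priors: Mapping[str, abc_mod.UniformPrior] | None = None,
        seed: int | None = None,
        reference: rf.ChoiceReference | None = None,
        forest: rf.TrainedForest | None = None,
        shrinkage: bool = False,
        progress: bool = False,
    ) -> "ModelChoiceResults":
        """Choose among conformity / novelty / neutrality by RF-ABC."""
        root = np.random.SeedSequence(seed)
        s_ref, s_forest, s_post = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(3))
        if forest is None:
            if reference is None:
                reference = rf.build_choice_reference(
                    n_per_model, self.base_params(), priors=priors,
                    y_max=self.y_max, seed=s_ref, shrinkage=shrinkage,
                    progress=progress,
                )
            forest = rf.train_forest(reference, n_trees, seed=s_forest)
        choice = rf.model_choice(forest, self.observed_stats, seed=s_post)
        return ModelChoiceResults(self, forest, choice)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<FrequencyBiasModel T={self.freq.n_timepoints} V={self.freq.n_variants} "
            f"N={self.n_agents} mu={self.mu:.4f} y_max={self.y_max}>"
        )


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

class RejectionABCResults:
    """Posterior of the bias parameter b from rejection ABC."""

    def __init__(
        self,
        model: FrequencyBiasModel,
        prior: abc_mod.UniformPrior,
        reference: abc_mod.ReferenceTable,
        posterior: abc_mod.Posterior,
        seed: int | None,
    ) -> None:
        self.model = model
        self.prior = prior
        self.reference = reference
        self.posterior = posterior
        self._seed = seed

    @property
    def bias_median(self) -> float:
        return self.posterior.median

    @property
    def hpdi_95(self) -> tuple[float, float]:
        return self.posterior.hpdi_95

    def goodness_of_fit(self, n: int = 1000, epsilon: float = 0.01, *, seed=None) -> float:
        obs = self.model.observed_stats
        return abc_mod.goodness_of_fit(
            (obs.exponent, obs.mean_diversity), self.reference, n, epsilon,
            seed=self._seed if seed is None else seed,
        )

    def cross_validate(
        self, tolerances: Sequence[float] = (0.005, 0.01, 0.05), n: int = 10, *, seed=None
    ) -> dict[float, np.ndarray]:
        return abc_mod.cross_validate(
            self.reference, tolerances, n,
            seed=self._seed if seed is None else seed,
        )

    def summary(self) -> str:
        obs = self.model.observed_stats
        lo, hi = self.hpdi_95
        interp = (
            "conformity (b < 0)" if hi < 0
            else "novelty (b > 0)" if lo > 0
            else "indistinguishable from neutrality (interval spans 0)"
        )
        lines = [
            "Rejection-ABC estimate of frequency-based bias",
            "=" * 54,
            f"observed turn-over exponent x   {obs.exponent:10.4f}",
            f"observed mean diversity D̄       {obs.mean_diversity:10.4f}",
            f"prior                            U({self.prior.lower:g}, {self.prior.upper:g})",
            f"reference simulations            {self.posterior.n_reference:d}",
            f"tolerance epsilon                {self.posterior.epsilon:g}",
            f"accepted draws                   {self.posterior.n_accepted:d}",
            "-" * 54,
            f"posterior median b               {self.bias_median:10.4f}",
            f"95% HPDI                         [{lo:.4f}, {hi:.4f}]",
            f"interpretation                   {interp}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def plot_posterior(self, ax=None, bins: int = 30):
        """Histogram of the accepted sample with median and HPDI marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.posterior.accepted, bins=bins, color="0.7", edgecolor="0.3")
        lo, hi = self.hpdi_95
        ax.axvspan(lo, hi, color="0.85", zorder=0)
        ax.axvline(self.bias_median, color="k", lw=1.5)
        ax.set_xlabel("frequency-based bias b")
        ax.set_ylabel("accepted draws")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        lo, hi = self.hpdi_95
        return f"<RejectionABCResults median={self.bias_median:.4f} HPDI=[{lo:.4f},{hi:.4f}]>"


class ModelChoiceResults:
    """Random-forest ABC model choice among transmission regimes."""

    def __init__(
        self,
        model: FrequencyBiasModel,
        forest: rf.TrainedForest,
        choice: rf.RFChoiceResult,
    ) -> None:
        self.model = model
        self.forest = forest
        self._choice = choice

    @property
    def votes(self) -> dict[str, int]:
        return self._choice.votes

    @property
    def selected(self) -> str:
        return self._choice.selected

    @property
    def posterior_prob(self) -> float:
        return self._choice.posterior_prob

    @property
    def oob_error(self) -> float:
        return self._choice.oob_error

    @property
    def importances(self) -> pd.Series:
        return self._choice.importances

    def to_dict(self) -> dict:
        return self._choice.to_dict()

    def write_json(self, path: str | Path) -> None:
        self._choice.write_json(path)

    def summary(self, top_k: int = 5) -> str:
        lines = [
            "Random-forest ABC model choice",
            "=" * 54,
            "votes: " + "  ".join(f"{m}={self.votes.get(m, 0)}" for m in rf.MODELS),
            f"selected model                   {self.selected}",
            f"posterior probability            {self.posterior_prob:.3f}",
            f"out-of-bag error                 {self.oob_error:.3f}",
            "-" * 54,
            f"top {top_k} variables (Gini importance):",
        ]
        for name, v in self.importances.head(top_k).items():
            lines.append(f"  {name:<20s} {v:.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_importances(self, ax=None, top_k: int = 10):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        imp = self.importances.head(top_k)[::-1]
        ax.barh(imp.index, imp.to_numpy(), color="0.6")
        ax.set_xlabel("Gini importance")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ModelChoiceResults selected={self.selected!r} "
            f"prob={self.posterior_prob:.3f} oob={self.oob_error:.3f}>"
        )
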