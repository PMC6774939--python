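"""Synthetic sampling-event tables with known ground truth.

Emulates the structure of a scraped sampling-event dataset — one row per
(year, variant, artist) adoption — by running the transmission model at a
chosen bias ``b_true`` and expanding each recorded agent-variant adoption
into an event row.  Artist identifiers are redrawn each year without
replacement from a fixed pool, so the mean number of unique artists per year
equals the simulated population size and the ingest estimators recover the
generating constants.  Heavy-tailed variant popularity arises endogenously
from the transmission dynamics; no extra popularity layer is imposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import FrequencyTable, build_frequency_table
from .simulate import SimulationParams, run_simulation
from .sumstats import summary_vector

__all__ = ["SynthConfig", "SyntheticDataset", "generate_dataset", "generate_event_table", "make_fixtures"]


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration of a synthetic dataset.

    Defaults mirror the sampling-tradition regime the package targets:
    729 active artists per year, innovation rate 0.037, 32 observed years
    starting 1987, 200 warm-up steps.
    """

    b_true: float = 0.0
    mu: float = 0.037
    n_agents: int = 729
    n_years: int = 32
    start_year: int = 1987
    warmup: int = 200
    events_per_agent: int = 1
    agent_pool_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.events_per_agent < 1:
            raise ValueError("events_per_agent must be >= 1")
        if self.agent_pool_factor < 1:
            raise ValueError("agent_pool_factor must be >= 1")

    def params(self) -> SimulationParams:
        return SimulationParams(
            self.n_agents, self.mu, self.b_true, self.warmup, self.n_years, self.seed
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated event table together with its generating truth."""

    config: SynthConfig
    events: pd.DataFrame
    frequency: FrequencyTable  # the simulator's recorded frequencies


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Run the transmission model and expand adoptions into event rows.

    With ``events_per_agent=1`` (default) the frequency table rebuilt from
    the events equals the simulated frequencies exactly; larger values
    replicate each adoption that many times (scaling all counts uniformly).
    """
    root = np.random.SeedSequence(cfg.seed)
    sim_seq, agent_seq = root.spawn(2)
    res = run_simulation(
        cfg.params(),
        y_max=1,
        start_year=cfg.start_year,
        rng=np.random.default_rng(sim_seq),
    )
    freq = res.freq
    agent_rng = np.random.default_rng(agent_seq)
    pool_size = cfg.n_agents * cfg.agent_pool_factor
    width = len(str(pool_size - 1))
    years, variants, agents = [], [], []
    for t in range(freq.n_timepoints):
        row = freq.counts[t]
        nz = row > 0
        row_variants = np.repeat(freq.variants[nz], row[nz])
        ids = agent_rng.choice(pool_size, size=cfg.n_agents, replace=False)
        for _ in range(cfg.events_per_agent):
            years.append(np.full(cfg.n_agents, freq.years[t]))
            variants.append(row_variants)
            agents.append(ids)
    events = pd.DataFrame(
        {
            "year": np.concatenate(years),
            "variant": np.concatenate(variants),
            "agent": [f"a{int(i):0{width}d}" for i in np.concatenate(agents)],
        }
    ).sort_values(["year", "variant", "agent"], kind="stable", ignore_index=True)
    return SyntheticDataset(cfg, events, freq)


def generate_event_table(cfg: SynthConfig) -> pd.DataFrame:
    """Long-format sampling-event table (``year, variant, agent``)."""
    return generate_dataset(cfg).events


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

_FIXTURE_SPECS = {
    "neutral": 0.0,
    "conformity": -0.15,
    "novelty": 0.15,
}


def make_fixtures(
    out_dir: str | Path,
    *,
    seed: int = 2024,
    n_agents: int = 120,
    n_years: int = 24,
    mu: float = 0.05,
    warmup: int = 120,
    y_max: int = 20,
) -> dict:
    """Write small deterministic fixture datasets for regression testing.

    One event table per transmission regime (neutral, strong conformity
    b = -0.15, strong novelty b = +0.15) plus its base summary-statistics
    vector as CSV, and a manifest recording seeds and expected files.
    Regenerating with the same seed reproduces the files byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "y_max": y_max, "datasets": {}}
    for i, (name, b) in enumerate(_FIXTURE_SPECS.items()):
        cfg = SynthConfig(
            b_true=b,
            mu=mu,
            n_agents=n_agents,
            n_years=n_years,
            warmup=warmup,
            seed=seed + i,
        )
        ds = generate_dataset(cfg)
        events_path = out_dir / f"{name}_events.csv"
        ds.events.to_csv(events_path, index=False)
        stats = summary_vector(build_frequency_table(ds.events), y_max)
        stats_path = out_dir / f"{name}_summary.csv"
        stats.to_series().to_frame().T.to_csv(stats_path, index=False)
        manifest["datasets"][name] = {
            "b_true": b,
            "seed": cfg.seed,
            "events": events_path.name,
            "summary": stats_path.name,
            "n_events": int(len(ds.events)),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
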