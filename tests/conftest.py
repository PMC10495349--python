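"""Shared fixtures: small synthetic streams with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from premnet import sim


def small_config(seed: int, **overrides) -> sim.SimConfig:
    """A quick, mid-sized experiment (~1,000 events) for pipeline tests."""
    kwargs = dict(
        seed=seed,
        n_individuals=60,
        n_mate_pairs=8,
        n_sibling_groups=4,
        n_parent_offspring_links=8,
        n_days=30,
        n_feeders=2,
        session_length=3600,
        arrival_rate=1.6,
    )
    kwargs.update(overrides)
    return sim.SimConfig(**kwargs)


def null_overrides() -> dict:
    """Behavioural parameters for a no-learning, no-affiliate-bias stream."""
    return dict(learning_rate=0.0, affiliate_weight=0.0, affiliate_co_arrival=0.0)


@pytest.fixture(scope="session")
def null_result() -> sim.SimResult:
    return sim.simulate_experiment(small_config(101, **null_overrides()))


@pytest.fixture(scope="session")
def learning_result() -> sim.SimResult:
    return sim.simulate_experiment(small_config(202, learning_rate=2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal, well-formed event frame from dict rows."""
    defaults = dict(day=0, feeder=0, start=0, latency=0, duration=10)
    out = []
    for i, row in enumerate(rows, start=1):
        rec = dict(defaults)
        rec.update(row)
        rec["index"] = i
        out.append(rec)
    df = pd.DataFrame(out)
    cols = ["index", "day", "feeder", "source", "target", "start", "latency", "duration"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]
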