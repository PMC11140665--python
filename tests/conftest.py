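"""Shared fixtures: a small, fast study configuration and a cached run.

The tiny profile (20 nodes, 8 sessions, 1,024 frames, B = 100) keeps the
full end-to-end pipeline under a few seconds so it can back many tests;
20 nodes leaves most of the nine networks with at least two members.
"""

from __future__ import annotations

import numpy as np
import pytest

from diurnalconn.config import CoupledEdge, RunConfig, StudyConfig


def tiny_study(seed: int = 0, **overrides) -> StudyConfig:
    params = dict(
        n_nodes=20,
        n_sessions=8,
        n_days=6,
        frames_per_session=1024,
        n_serum_sessions=6,
        seed=seed,
    )
    params.update(overrides)
    return StudyConfig(**params)


def tiny_run(seed: int = 0, **overrides) -> RunConfig:
    study = overrides.pop("study", tiny_study(seed))
    params = dict(study=study, n_permutations=100, seed=seed)
    params.update(overrides)
    return RunConfig(**params)


@pytest.fixture(scope="session")
def tiny_pipeline_run():
    """One cached end-to-end run on the tiny profile (with coupled edges)."""
    from diurnalconn.pipeline import run_pipeline

    cfg = tiny_run(seed=7, study=tiny_study(seed=7, coupled_edges=[CoupledEdge(0, 1, 0.15)]))
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
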