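"""Shared fixtures: a seeded synthetic study and its pipeline result."""

from __future__ import annotations

import pytest

from fosannot.pipeline import run_study
from fosannot.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Full-size synthetic study: 20 inserts, 6 prediction tracks, seed 1."""
    return simulate_study(SimConfig(seed=1, n_inserts=20))


@pytest.fixture(scope="session")
def result(study):
    return run_study(
        study.records,
        study.hits,
        study.tracks,
        study.ests,
        probes=study.probes,
        locus_map={
            g.subject_id: g.best_locus
            for g in study.truth.all_genes()
            if g.best_locus
        },
    )


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SimConfig(seed=7, n_inserts=3))
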