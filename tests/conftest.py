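"""Shared fixtures: toy genomes and simulated runs (session-scoped, since
the full pipeline is the expensive part of the suite)."""

from __future__ import annotations

import numpy as np
import pytest

from ddradkit.pipeline import run_pipeline
from ddradkit.read_processing import RawRead
from ddradkit.simulate import (
    PopulationConfig,
    StarActivityModel,
    make_toy_genome,
    simulate_ddrad_run,
)


def as_raw_reads(run):
    return [RawRead(rid, seq, quals) for rid, seq, quals in run.reads]


@pytest.fixture(scope="session")
def toy():
    return make_toy_genome(seed=42)


@pytest.fixture(scope="session")
def clean_run():
    """Zero sequencing error, no star activity, no chimeras."""
    return simulate_ddrad_run(
        seed=5,
        pop=PopulationConfig(n_individuals=6),
        total_reads=20_000,
        error_rate=0.0,
        star=StarActivityModel(rate_edge=0.0, rate_internal=0.0, chimera_rate=0.0),
    )


@pytest.fixture(scope="session")
def clean_result(clean_run):
    return run_pipeline(as_raw_reads(clean_run), clean_run.barcode_map, clean_run.toy.genome)


@pytest.fixture(scope="session")
def noisy_run():
    """0.1% per-base error with star activity and chimeras at defaults."""
    return simulate_ddrad_run(
        seed=11,
        pop=PopulationConfig(n_individuals=8),
        total_reads=40_000,
        error_rate=0.001,
    )


@pytest.fixture(scope="session")
def noisy_result(noisy_run):
    return run_pipeline(as_raw_reads(noisy_run), noisy_run.barcode_map, noisy_run.toy.genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
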