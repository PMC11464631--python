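"""Shared fixtures: large null simulations and the default pipeline runs.

The expensive simulations (a million-family null consensus run and two full
pipeline executions) are session-scoped so every test file measures the same
realisation instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctmon.consensus import error_rate, pileup_from_family_table
from ctmon.simdata import SimConfig, simulate_families


@pytest.fixture(scope="session")
def null_consensus_sim():
    """Variant-free UMI simulation at the study's raw error rate (1e-3).

    ~1.05 million families mixing 2-, 3- and >=4-copy sizes, grouped and
    consensus-called through the standard path.  Returns (pileup,
    error-rate table, truth).
    """
    cfg = SimConfig(
        n_background_positions=250,
        monitored_variants=[],
        raw_depth_per_position=11_550,  # 4,200 families/position x 2.75 reads
        family_size_distribution={2: 0.55, 3: 0.15, 4: 0.30},
        error_rates=1e-3,
        seed=20_240,
    )
    table, truth = simulate_families(cfg)
    pileup = pileup_from_family_table(table)
    rates = error_rate(pileup, truth.ref_bases)
    return pileup, rates, truth


@pytest.fixture(scope="session")
def noisy_consensus_sim():
    """Null simulation at raw error 0.03, where consensus levels separate.

    At this error rate the expected level-2 rate (~3e-4) and level-4 rate
    (~1e-5) differ by more than 3 binomial standard errors at a million
    consensus calls, making the suppression ordering strictly testable.
    """
    cfg = SimConfig(
        n_background_positions=250,
        monitored_variants=[],
        raw_depth_per_position=12_000,  # 4,000 families/position x 3 reads
        family_size_distribution={2: 0.5, 4: 0.5},
        error_rates=0.03,
        seed=20_241,
    )
    table, truth = simulate_families(cfg)
    pileup = pileup_from_family_table(table)
    return error_rate(pileup, truth.ref_bases)


@pytest.fixture(scope="session")
def default_runs(tmp_path_factory):
    """The default simulated cohort run twice with the same seed."""
    from ctmon.pipeline import RunConfig, run_pipeline

    dirs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp("pipeline") / name
        cfg = RunConfig(out_dir=str(out), seed=11)
        run_pipeline(cfg)
        dirs.append(out)
    return tuple(dirs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
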