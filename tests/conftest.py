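"""Shared fixtures: small synthetic cohorts reused across test modules."""

import pytest

from inflammage import pipeline, synth


@pytest.fixture(scope="session")
def reference12():
    """A 12-parameter DII reference table."""
    return synth.generate_reference(12, seed=5)


@pytest.fixture(scope="session")
def small_sim():
    """A small complete synthetic cohort (n=600, 40 IDPs)."""
    config = synth.SimulationConfig(n_participants=600, seed=11, n_idps=40)
    return synth.simulate(config)


@pytest.fixture(scope="session")
def analysis_table():
    """A mid-sized scored cohort for association/mediation tests (n=3000)."""
    config = synth.SimulationConfig(n_participants=3000, seed=23, n_idps=60)
    sim = synth.simulate(config)
    table, model, info, cascade = pipeline.build_analysis_table(
        sim, grid="lasso", seed=23
    )
    return sim, table
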