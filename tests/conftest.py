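import numpy as np
import pytest

from ribotopo import (
    LibraryConfig,
    align_reads,
    build_operon,
    compute_profile,
    default_operon_spec,
    run_pipeline,
    simulate_scenario,
)

SCENARIOS = ("linear", "circular", "permuted_with_excision", "hidden_break")
GRID_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def default_build():
    """Default operon (seed 1): (reference sequence, truth)."""
    return build_operon(default_operon_spec(rng_seed=1))


@pytest.fixture(scope="session")
def pipeline():
    """Session-wide cache of full pipeline runs keyed by (scenario, seed)."""
    cache = {}

    def get(scenario, seed, **kwargs):
        key = (scenario, seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = run_pipeline(scenario=scenario, seed=seed, **kwargs)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def permuted_run(pipeline):
    return pipeline("permuted_with_excision", 1)


@pytest.fixture(scope="session")
def linear_run(pipeline):
    return pipeline("linear", 1)


@pytest.fixture(scope="session")
def linear_profile():
    """Profile of a linear-LSU simulation on the conventional reference."""
    sim = simulate_scenario(scenario="linear", seed=3)
    alns = align_reads(sim.reads, sim.lsu_reference, reference_id="LSU")
    return sim, alns, compute_profile(alns, sim.lsu_reference, reference_id="LSU")
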