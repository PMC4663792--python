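"""Shared fixtures: end-to-end synthetic runs are expensive enough to build
once per session and reuse across test modules."""

from __future__ import annotations

import pytest

from anchorkit import ld, pipeline
from anchorkit.synthetic import simulate_population

SEED = 1


@pytest.fixture(scope="session")
def clean_result():
    """Full pipeline on the noiseless desk-scale scenario."""
    return pipeline.run_synthetic(SEED, pipeline.CLEAN_SCENARIO)


@pytest.fixture(scope="session")
def clean_bundle():
    return pipeline.simulate_scenario(SEED, pipeline.CLEAN_SCENARIO)


@pytest.fixture(scope="session")
def corrupted_result():
    """Full pipeline on the corrupted scenario (wrong-LG / multi-map /
    discordant markers, chimeras, one sink contig)."""
    return pipeline.run_synthetic(SEED, pipeline.CORRUPTED_SCENARIO)


@pytest.fixture(scope="session")
def corrupted_bundle():
    return pipeline.simulate_scenario(SEED, pipeline.CORRUPTED_SCENARIO)


@pytest.fixture(scope="session")
def small_founder_bins():
    pop = simulate_population(pipeline.CHROM_LENGTHS, n_founders=4, seed=SEED + 4)
    matrix = ld.filter_sites(ld.call_genotypes(pop.matrix))
    return ld.ld_decay(matrix)


@pytest.fixture(scope="session")
def large_founder_bins():
    pop = simulate_population(pipeline.CHROM_LENGTHS, n_founders=32, seed=SEED + 32)
    matrix = ld.filter_sites(ld.call_genotypes(pop.matrix))
    return ld.ld_decay(matrix)
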