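"""Shared simulation fixtures (session-scoped: the preset genome is the
substrate for most recovery tests and takes a few seconds to build)."""

from __future__ import annotations

import pytest

from chromoscape import simulate, tandem


@pytest.fixture(scope="session")
def preset_sim():
    """Preset genome, annotations and truth (seed 1)."""
    cfg = simulate.raspberry_like_config(seed=1)
    return simulate.generate_genome(cfg), cfg


@pytest.fixture(scope="session")
def genome(preset_sim):
    return preset_sim[0][0]


@pytest.fixture(scope="session")
def annotations(preset_sim):
    return preset_sim[0][1]


@pytest.fixture(scope="session")
def truth(preset_sim):
    return preset_sim[0][2]


@pytest.fixture(scope="session")
def sim_config(preset_sim):
    return preset_sim[1]


@pytest.fixture(scope="session")
def gene_sequences(genome, annotations):
    return tandem.extract_gene_sequences(genome, annotations)


@pytest.fixture(scope="session")
def same_chrom_hits(annotations, gene_sequences):
    return tandem.all_vs_all_hits(annotations.genes, gene_sequences, same_chrom_only=True)


@pytest.fixture(scope="session")
def tandem_arrays_called(annotations, same_chrom_hits):
    return tandem.call_tandem_arrays(annotations, same_chrom_hits)


@pytest.fixture(scope="session")
def ortholog_sim(genome, annotations, truth):
    """Diverged relative with two arm-sized inversions and one 12-member
    array contracted to a single copy."""
    return simulate.generate_ortholog_genome(
        genome, annotations, truth,
        substitution_rate=0.1, inversion_count=2,
        lineage_array_spec={"fam02": 1}, seed=51,
    )
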