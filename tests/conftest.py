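import pytest

from chordax import synth


@pytest.fixture(scope="session")
def cohort_spec():
    return synth.default_cohort_spec(seed=11)


@pytest.fixture(scope="session")
def genome_and_genes(cohort_spec):
    return synth.make_genome(cohort_spec)


@pytest.fixture(scope="session")
def genome(genome_and_genes):
    return genome_and_genes[0]


@pytest.fixture(scope="session")
def genes(genome_and_genes):
    return genome_and_genes[1]


@pytest.fixture(scope="session")
def chrom_lengths(genome):
    return {k: len(v) for k, v in genome.items()}
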