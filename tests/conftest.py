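import warnings

import pytest

from phagechar.synthetic_data import GenomeSpec, generate_genome

# the generator legitimately warns when analysis windows clip at genome ends
warnings.filterwarnings("ignore", message=".*window clipped.*")


@pytest.fixture(scope="session")
def default_genome_truth():
    """One default synthetic 936-like genome with its truth, shared per session."""
    return generate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def default_genome(default_genome_truth):
    return default_genome_truth[0]


@pytest.fixture(scope="session")
def default_truth(default_genome_truth):
    genome, truth = default_genome_truth
    return truth.scalars[genome.id]
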