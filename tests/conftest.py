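import numpy as np
import pytest

import seedless as sl


@pytest.fixture()
def small_genome():
    """A 60 kb synthetic reference with an 8 kb deletion allele and truth."""
    spec = sl.GenomeSpec(ref_length=60_000, deletion_interval=(20_000, 28_000),
                         seed=11)
    reference, allele, truth = sl.simulate_genome_pair(spec)
    return reference, allele, truth


@pytest.fixture()
def small_alignments(small_genome):
    reference, allele, truth = small_genome
    return sl.simulate_alignments(allele, reference, depth=18.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
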