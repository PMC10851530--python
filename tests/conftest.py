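import numpy as np
import pytest

from ovarpop import (BreedSpec, generate_allele_library,
                     sample_population_genotypes)
from ovarpop.datasets import (load_sds_frequencies, load_sds_frequency_table,
                              SDS_BREED_SAMPLE_SIZES)


@pytest.fixture(scope="session")
def library46():
    """46-allele 270-bp library, the scale of the real locus."""
    return generate_allele_library(46, 270, min_pairwise_diff=2, seed=7)


@pytest.fixture(scope="session")
def small_library():
    return generate_allele_library(6, 30, min_pairwise_diff=1, seed=3)


@pytest.fixture(scope="session")
def sds_fm():
    """Bundled six-breed frequency matrix (normalised proportions)."""
    return load_sds_frequencies()


@pytest.fixture(scope="session")
def sds_percent():
    """Bundled table as published: breeds x alleles, percent scale."""
    return load_sds_frequency_table().T


@pytest.fixture(scope="session")
def sds_sizes():
    return dict(SDS_BREED_SAMPLE_SIZES)


@pytest.fixture(scope="session")
def hwe_cohort(small_library):
    """A 200-sample Hardy-Weinberg cohort over six alleles."""
    freqs = dict(zip(small_library.names, [0.3, 0.25, 0.2, 0.1, 0.1, 0.05]))
    return sample_population_genotypes(
        small_library, [BreedSpec("HW", 200, freqs)], seed=11
    )
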