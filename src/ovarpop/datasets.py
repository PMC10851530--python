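"""Bundled datasets.

The package ships the published breed-by-allele frequency table of the
Ovar-DRB1 exon-2 locus in six Sudan Desert Sheep breeds (Abrag, Ashgar,
Buze'e, Hamari, Kabashi, Watish), transcribed from percentages printed at
two decimal places, together with the per-breed sample sizes.  Frequency
analyses (heterozygosity, distances, PCA, allele sharing) run directly on
this matrix; genotype-level statistics need per-animal data and are
exercised on synthetic cohorts instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotypes import FrequencyMatrix

#: diploid sample sizes per breed
SDS_BREED_SAMPLE_SIZES: dict[str, int] = {
    "AB": 37, "AS": 44, "B": 23, "H": 72, "K": 45, "W": 38,
}

#: the five breeds of the allele-sharing (Venn) analysis, which
#: excludes the Buze'e crossbreed
SDS_VENN_BREEDS: tuple[str, ...] = ("AB", "AS", "H", "K", "W")


def load_sds_frequency_table() -> pd.DataFrame:
    """Raw allele-by-breed percentage table (46 alleles x 6 breeds)."""
    ref = resources.files("ovarpop.data") / "sds_drb1_allele_frequencies.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)


def load_sds_frequencies() -> FrequencyMatrix:
    """Breed-by-allele FrequencyMatrix with sample sizes attached."""
    tab = load_sds_frequency_table()
    return FrequencyMatrix.from_percent(tab.T, SDS_BREED_SAMPLE_SIZES)
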