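"""Diploid genotype tables and breed-by-allele frequency matrices."""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "breed", "allele1", "allele2")


class GenotypeTable:
    """Per-sample diploid allele calls grouped by breed.

    Wraps a DataFrame with columns ``sample, breed, allele1, allele2``
    (extra columns such as QC fields are preserved).  Samples are unique;
    rows are kept sorted by (breed, sample) for stable output.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"genotype table missing columns {missing}")
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicated sample ids {dups[:5]}")
        if df[list(REQUIRED_COLUMNS)].isna().any().any() or (
            df[["allele1", "allele2"]] == ""
        ).any().any():
            raise ValueError("empty allele or breed entries in genotype table")
        self.df = (
            df.sort_values(["breed", "sample"], kind="stable")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "GenotypeTable":
        return cls(pd.DataFrame(records, columns=list(REQUIRED_COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def breeds(self) -> list[str]:
        return sorted(self.df["breed"].unique())

    def sample_sizes(self) -> dict[str, int]:
        return self.df.groupby("breed").size().to_dict()

    def breed_subset(self, breeds: Iterable[str]) -> "GenotypeTable":
        breeds = list(breeds)
        unknown = set(breeds) - set(self.breeds)
        if unknown:
            raise ValueError(f"unknown breeds {sorted(unknown)}")
        return GenotypeTable(self.df[self.df["breed"].isin(breeds)].copy())

    def gene_copies(self, breed: str) -> np.ndarray:
        """All 2N allele names of one breed as an array."""
        sub = self.df[self.df["breed"] == breed]
        if sub.empty:
            raise ValueError(f"breed {breed!r} not present")
        return np.concatenate([sub["allele1"].values, sub["allele2"].values])

    def allele_names(self) -> list[str]:
        return sorted(set(self.df["allele1"]) | set(self.df["allele2"]))

    def content_hash(self) -> str:
        import hashlib

        payload = self.df[list(REQUIRED_COLUMNS)].to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class FrequencyMatrix:
    """Breed-by-allele relative frequencies with per-breed sample sizes.

    ``df`` holds proportions (rows sum to 1); ``n_samples`` maps breed to
    the number of diploid individuals N, so gene-copy counts are 2N.
    """

    def __init__(
        self, df: pd.DataFrame, n_samples: Mapping[str, int] | None = None
    ) -> None:
        if (df.values < -1e-12).any() or (df.values > 1 + 1e-12).any():
            raise ValueError("frequencies must lie in [0, 1]")
        sums = df.sum(axis=1)
        bad = sums[(sums - 1).abs() > 1e-9]
        if len(bad):
            raise ValueError(f"rows do not sum to 1: {bad.to_dict()}")
        self.df = df
        self.n_samples = dict(n_samples) if n_samples else {}

    @classmethod
    def from_percent(
        cls, df_percent: pd.DataFrame, n_samples: Mapping[str, int] | None = None
    ) -> "FrequencyMatrix":
        """Build from a percent-scale table, renormalising rounding slack.

        Published tables print 2-d.p. percentages whose rows sum to
        99.9-100.1; each row is rescaled to sum exactly to 1.
        """
        df = df_percent / 100.0
        df = df.div(df.sum(axis=1), axis=0)
        return cls(df, n_samples)

    @property
    def breeds(self) -> list[str]:
        return list(self.df.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.df.columns)

    def frequencies(self, breed: str) -> pd.Series:
        return self.df.loc[breed]

    def n_alleles(self, breed: str) -> int:
        """n_a: number of alleles segregating in the breed."""
        return int((self.df.loc[breed] > 0).sum())

    def gene_copies(self, breed: str) -> int:
        if breed not in self.n_samples:
            raise ValueError(f"no sample size recorded for breed {breed!r}")
        return 2 * self.n_samples[breed]

    def breed_subset(self, breeds: Iterable[str]) -> "FrequencyMatrix":
        breeds = list(breeds)
        sub = self.df.loc[breeds]
        keep = sub.columns[(sub > 0).any(axis=0)]
        sub = sub[keep]
        n = {b: self.n_samples[b] for b in breeds if b in self.n_samples}
        return FrequencyMatrix(sub, n)


def allele_frequencies(gt: GenotypeTable) -> FrequencyMatrix:
    """Direct-counting allele frequencies per breed.

    p_i = (copies of allele i among the breed's 2N gene copies) / 2N.
    Breeds with zero samples cannot occur in a GenotypeTable; empty
    requested subsets raise upstream.
    """
    if len(gt) == 0:
        raise ValueError("empty genotype table")
    alleles = gt.allele_names()
    rows = {}
    n_samples = {}
    for breed in gt.breeds:
        copies = gt.gene_copies(breed)
        if copies.size == 0:  # pragma: no cover - guarded by GenotypeTable
            warnings.warn(f"breed {breed!r} has no samples; omitted")
            continue
        counts = pd.Series(copies).value_counts()
        rows[breed] = [counts.get(a, 0) / copies.size for a in alleles]
        n_samples[breed] = copies.size // 2
    df = pd.DataFrame.from_dict(rows, orient="index", columns=alleles)
    return FrequencyMatrix(df, n_samples)
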