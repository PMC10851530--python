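"""Allele sequences and the named-allele database.

An allele here is a full-length haplotype of a fixed-length amplicon
(by default the 270-bp second exon of Ovar-DRB1, which encodes the
hypervariable beta-1 antigen-binding domain).  Alleles carry IPD-MHC
style names such as ``Ovar-DRB1*10:01``; haplotypes discovered in a
cohort but absent from the known set are registered under a study
prefix (``Ovar-DRB1*Sudan1`` style) and flagged as novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlleleSequence:
    """A named amplicon haplotype.

    Parameters
    ----------
    name
        Allele identifier, e.g. ``"Ovar-DRB1*10:01"``.
    seq
        Nucleotide sequence (uppercase A/C/G/T).
    frame_offset
        0-based position of the first in-frame codon within ``seq``.
    """

    name: str
    seq: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not set(self.seq) <= DNA_ALPHABET:
            bad = sorted(set(self.seq) - DNA_ALPHABET)
            raise ValueError(f"allele {self.name!r}: non-ACGT characters {bad}")
        if not 0 <= self.frame_offset < 3:
            raise ValueError("frame_offset must be 0, 1 or 2")
        if (len(self.seq) - self.frame_offset) % 3:
            raise ValueError(
                f"allele {self.name!r}: translated portion "
                f"({len(self.seq)} - {self.frame_offset}) not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def coding(self) -> str:
        """The in-frame portion of the sequence."""
        return self.seq[self.frame_offset:]


class AlleleDatabase:
    """Registry of known (and registered novel) alleles of one locus.

    Names and sequences are both unique; all sequences share one length,
    because assignment is exact full-length sequence identity.
    """

    def __init__(self, alleles: Iterable[AlleleSequence] = ()) -> None:
        self._by_name: dict[str, AlleleSequence] = {}
        self._by_seq: dict[str, str] = {}
        self._provenance: dict[str, str] = {}
        for a in alleles:
            self.add(a, provenance="known")

    def add(self, allele: AlleleSequence, provenance: str = "known") -> None:
        if provenance not in ("known", "novel-registered"):
            raise ValueError(f"unknown provenance {provenance!r}")
        if allele.name in self._by_name:
            raise ValueError(f"duplicate allele name {allele.name!r}")
        if allele.seq in self._by_seq:
            other = self._by_seq[allele.seq]
            raise ValueError(
                f"sequence of {allele.name!r} duplicates allele {other!r}"
            )
        if self._by_name:
            ref_len = len(next(iter(self._by_name.values())).seq)
            if len(allele.seq) != ref_len:
                raise ValueError(
                    f"allele {allele.name!r} length {len(allele.seq)} != "
                    f"database length {ref_len}"
                )
        self._by_name[allele.name] = allele
        self._by_seq[allele.seq] = allele.name
        self._provenance[allele.name] = provenance

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self) -> Iterator[AlleleSequence]:
        return iter(self._by_name.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    @property
    def amplicon_length(self) -> int:
        if not self._by_name:
            raise ValueError("empty database has no amplicon length")
        return len(next(iter(self._by_name.values())).seq)

    def get(self, name: str) -> AlleleSequence:
        return self._by_name[name]

    def lookup_sequence(self, seq: str) -> str | None:
        """Name of the allele with exactly this sequence, or None."""
        return self._by_seq.get(seq)

    def provenance(self, name: str) -> str:
        return self._provenance[name]

    def novel_names(self) -> list[str]:
        return [n for n, p in self._provenance.items() if p == "novel-registered"]

    def subset(self, names: Iterable[str]) -> "AlleleDatabase":
        sub = AlleleDatabase()
        for n in names:
            sub.add(self.get(n), provenance=self._provenance[n])
        return sub

    def copy(self) -> "AlleleDatabase":
        return self.subset(self.names)
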