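"""Synthetic cohorts: allele libraries, diploid genotypes, paired amplicon reads.

The generator mirrors the structure of a targeted MiSeq amplicon run on a
single multi-allelic locus: a library of same-length haplotypes free of
in-frame stop codons, diploid cohorts drawn breed-by-breed from explicit
frequency vectors (with optional inbreeding) or from the Ewens sampling
formula, and overlapping paired-end reads with truncated-normal depth
(default mean 32.61, sd 18.29 — the dispersion of a pooled single-run
amplicon experiment) and independent per-base substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .alleles import AlleleDatabase, AlleleSequence, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))

DEFAULT_AMPLICON_LENGTH = 270
DEFAULT_DEPTH_MEAN = 32.61
DEFAULT_DEPTH_SD = 18.29


@dataclass
class BreedSpec:
    """Sampling specification for one breed.

    freq_model is either a mapping of allele name -> frequency (summing to
    1 within 1e-9) or a positive float, interpreted as the Ewens theta
    parameter.  inbreeding_f in [-1, 1] tilts genotypes away from
    Hardy-Weinberg pairing: with probability f a single gene copy is drawn
    and duplicated (f = 1 gives all homozygotes); negative f mixes in
    forced heterozygote draws instead.
    """

    name: str
    n_individuals: int
    freq_model: Mapping[str, float] | float
    inbreeding_f: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not -1.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [-1, 1]")
        if isinstance(self.freq_model, Mapping):
            total = sum(self.freq_model.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")
        else:
            if self.freq_model <= 0:
                raise ValueError("Ewens theta must be > 0")


@dataclass
class ReadPairSet:
    """Simulated read pairs for one sample, with the generating truth."""

    sample_id: str
    breed: str
    pairs: list[tuple[str, str, str, str]]  # (fwd, fwd_qual, rev, rev_qual)
    truth: tuple[str, str]


def _random_coding_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random sequence of full codons avoiding stop codons."""
    codons = []
    for _ in range(length // 3):
        while True:
            c = "".join(rng.choice(_BASES, size=3))
            if c not in STOP_CODONS:
                break
        codons.append(c)
    return "".join(codons)


def _mutate_keep_frame(
    rng: np.random.Generator, seq: str, n_subs: int
) -> str | None:
    """Apply n_subs distinct substitutions, rejecting in-frame stops."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    mutated = "".join(out)
    for i in range(0, len(mutated), 3):
        if mutated[i : i + 3] in STOP_CODONS:
            return None
    return mutated


def generate_allele_library(
    n_alleles: int,
    length: int = DEFAULT_AMPLICON_LENGTH,
    min_pairwise_diff: int = 1,
    seed: int | None = None,
    name_prefix: str = "Ovar-DRB1*",
    max_retries: int = 2000,
) -> AlleleDatabase:
    """Generate a library of unique same-length alleles.

    Every pair of alleles differs at >= min_pairwise_diff positions and no
    allele contains an in-frame stop codon, so the whole library translates
    cleanly.  Deterministic for a fixed seed.  Allele i is named
    ``<name_prefix><family>:<variant>`` in IPD-MHC style.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    if min_pairwise_diff < 1:
        raise ValueError("min_pairwise_diff must be >= 1")
    if length % 3:
        raise ValueError("length must be divisible by 3")
    rng = np.random.default_rng(seed)
    base = _random_coding_sequence(rng, length)
    seqs = [base]
    arr = [np.frombuffer(base.encode(), dtype=np.uint8)]
    # each new allele: mutate the base at >= min_pairwise_diff random sites,
    # retry until it clears the distance floor against everything accepted
    spread = max(2 * min_pairwise_diff, min_pairwise_diff + 4)
    while len(seqs) < n_alleles:
        for attempt in range(max_retries):
            n_subs = int(rng.integers(min_pairwise_diff, spread + 1))
            if n_subs > length:
                n_subs = length
            cand = _mutate_keep_frame(rng, base, n_subs)
            if cand is None:
                continue
            cand_arr = np.frombuffer(cand.encode(), dtype=np.uint8)
            if all(
                int((cand_arr != other).sum()) >= min_pairwise_diff
                for other in arr
            ):
                seqs.append(cand)
                arr.append(cand_arr)
                break
        else:
            raise RuntimeError(
                f"could not place allele {len(seqs) + 1}/{n_alleles} after "
                f"{max_retries} retries (length={length}, "
                f"min_pairwise_diff={min_pairwise_diff})"
            )
    db = AlleleDatabase()
    for i, seq in enumerate(seqs):
        family, variant = divmod(i, 100)
        name = f"{name_prefix}{family + 1:02d}:{variant + 1:02d}"
        db.add(AlleleSequence(name=name, seq=seq, frame_offset=0))
    return db


def expected_ewens_allele_count(theta: float, n: int) -> float:
    """E[k] under the Ewens sampling formula: sum_{i=0}^{n-1} theta/(theta+i)."""
    i = np.arange(n)
    return float((theta / (theta + i)).sum())


def _ewens_copy_counts(
    rng: np.random.Generator, theta: float, n: int
) -> list[int]:
    """Allele copy counts for n gene copies via the sequential ESF urn."""
    counts: list[int] = []
    for i in range(n):
        if rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            # join an existing allele with probability proportional to count
            total = i
            pick = rng.integers(total)
            acc = 0
            for j, c in enumerate(counts):
                acc += c
                if pick < acc:
                    counts[j] += 1
                    break
    return counts


def _draw_breed_genotypes(
    rng: np.random.Generator, db: AlleleDatabase, spec: BreedSpec
) -> list[tuple[str, str]]:
    if isinstance(spec.freq_model, Mapping):
        names = list(spec.freq_model)
        missing = [a for a in names if a not in db]
        if missing:
            raise ValueError(f"alleles not in database: {missing}")
        p = np.array([spec.freq_model[a] for a in names], dtype=float)
        p = p / p.sum()
        f = spec.inbreeding_f
        genotypes = []
        for _ in range(spec.n_individuals):
            u = rng.random()
            if f >= 0 and u < f:
                a = names[rng.choice(len(names), p=p)]
                genotypes.append((a, a))
            elif f < 0 and u < -f and len(names) > 1:
                # forced heterozygote: redraw the partner until distinct
                a = names[rng.choice(len(names), p=p)]
                while True:
                    b = names[rng.choice(len(names), p=p)]
                    if b != a:
                        break
                genotypes.append((a, b))
            else:
                a = names[rng.choice(len(names), p=p)]
                b = names[rng.choice(len(names), p=p)]
                genotypes.append((a, b))
        return genotypes
    # Ewens model: copy counts for 2N copies, mapped onto library alleles,
    # then random pairing of the copies
    theta = float(spec.freq_model)
    n_copies = 2 * spec.n_individuals
    counts = _ewens_copy_counts(rng, theta, n_copies)
    if len(counts) > len(db):
        raise ValueError(
            f"Ewens draw produced {len(counts)} alleles but the database "
            f"holds only {len(db)}"
        )
    chosen = rng.choice(db.names, size=len(counts), replace=False)
    copies = np.repeat(chosen, counts)
    rng.shuffle(copies)
    it = iter(copies)
    return [(a, b) for a, b in zip(it, it)]


def sample_population_genotypes(
    db: AlleleDatabase, specs: Sequence[BreedSpec], seed: int | None = None
):
    """Draw diploid cohorts breed by breed; returns a GenotypeTable."""
    from .genotypes import GenotypeTable

    rng = np.random.default_rng(seed)
    records = []
    for spec in specs:
        genotypes = _draw_breed_genotypes(rng, db, spec)
        for i, (a, b) in enumerate(genotypes, start=1):
            records.append((f"{spec.name}_{i:04d}", spec.name, a, b))
    return GenotypeTable.from_records(records)


def _apply_errors(
    rng: np.random.Generator, read: np.ndarray, error_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (read with substitutions, error position indices)."""
    if error_rate <= 0:
        return read, np.empty(0, dtype=int)
    hits = np.nonzero(rng.random(read.size) < error_rate)[0]
    if hits.size == 0:
        return read, hits
    read = read.copy()
    for pos in hits:
        alternatives = _BASES[_BASES != chr(read[pos])]
        read[pos] = ord(rng.choice(alternatives))
    return read, hits


def simulate_amplicon_reads(
    gt,
    db: AlleleDatabase,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    depth_sd: float = DEFAULT_DEPTH_SD,
    read_len: int | None = None,
    error_rate: float = 0.002,
    seed: int | None = None,
    base_quality: int = 30,
    error_quality: int | None = 15,
) -> list[ReadPairSet]:
    """Simulate overlapping paired-end reads for every sample in ``gt``.

    Per-sample pair counts follow a normal(depth_mean, depth_sd) truncated
    at zero and rounded; each pair derives from one of the sample's two
    alleles with probability 1/2; the forward read is the amplicon prefix
    and the reverse read the reverse complement of the suffix, with
    independent per-base substitution errors.

    ``read_len`` defaults to the amplicon length: a 600-cycle paired run
    on a short amplicon yields reads that each span the whole insert after
    adapter trimming.  Quality strings are a constant Phred score except
    that substituted positions are written at ``error_quality`` (as a real
    base caller tends to do); pass ``error_quality=None`` for strictly
    constant qualities (merge logic works either way, it simply loses the
    ability to arbitrate overlap conflicts).
    """
    amplicon_len = db.amplicon_length
    if read_len is None:
        read_len = amplicon_len
    if read_len > amplicon_len:
        raise ValueError("read_len exceeds amplicon length")
    if 2 * read_len <= amplicon_len:
        raise ValueError(
            "2*read_len must exceed the amplicon length so pairs overlap"
        )
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = np.random.default_rng(seed)
    base_q = chr(base_quality + 33)
    err_q = chr(error_quality + 33) if error_quality is not None else base_q

    def qual_string(hits: np.ndarray) -> str:
        if hits.size == 0 or err_q == base_q:
            return base_q * read_len
        q = [base_q] * read_len
        for pos in hits:
            q[pos] = err_q
        return "".join(q)

    if depth_sd > 0:
        depth_dist = stats.truncnorm(
            -depth_mean / depth_sd, np.inf, loc=depth_mean, scale=depth_sd
        )
    else:
        depth_dist = None
    out: list[ReadPairSet] = []
    for row in gt.df.itertuples(index=False):
        if depth_dist is not None:
            depth = int(round(depth_dist.rvs(random_state=rng)))
        else:
            depth = int(round(depth_mean))
        alleles = (db.get(row.allele1).seq, db.get(row.allele2).seq)
        pairs = []
        which = rng.integers(2, size=depth)
        for w in which:
            src = np.frombuffer(alleles[w].encode(), dtype=np.uint8)
            fwd, fhits = _apply_errors(rng, src[:read_len], error_rate)
            rev_template, rhits = _apply_errors(
                rng, src[-read_len:], error_rate)
            rev = reverse_complement(rev_template.tobytes().decode())
            rhits = read_len - 1 - rhits  # positions in sequenced orientation
            pairs.append(
                (fwd.tobytes().decode(), qual_string(fhits),
                 rev, qual_string(rhits))
            )
        out.append(
            ReadPairSet(
                sample_id=row.sample,
                breed=row.breed,
                pairs=pairs,
                truth=(row.allele1, row.allele2),
            )
        )
    return out
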