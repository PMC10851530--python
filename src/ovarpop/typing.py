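"""Direct amplicon haplotyping from overlapping paired reads.

Because a single amplicon spans the whole 270-bp exon, a merged read pair
observes a complete haplotype: merging, tallying identical merged
sequences, and requiring the two top sequences to carry balanced read
counts yields the diploid genotype directly, with no mapping or phasing
step.  Haplotypes absent from the known-allele database become novel
candidates and, with enough support, registered novel alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleDatabase, AlleleSequence, reverse_complement
from .genotypes import GenotypeTable
from .simulate import ReadPairSet


@dataclass
class MergedRead:
    seq: str
    n_conflicts: int = 0


@dataclass
class HaplotypeCall:
    """Reconstructed haplotypes for one sample.

    status is one of {homozygous, heterozygous, failed}; haplotypes are
    (sequence, read_count) pairs sorted by descending count, empty when
    the call failed.
    """

    sample_id: str
    haplotypes: list[tuple[str, int]]
    status: str
    total_depth: int
    n_conflicts: int = 0

    def __post_init__(self) -> None:
        if self.status == "heterozygous" and len(self.haplotypes) != 2:
            raise ValueError("heterozygous call requires exactly 2 haplotypes")
        if self.status == "failed" and self.haplotypes:
            raise ValueError("failed call must not report haplotypes")


@dataclass
class TypingParams:
    """Thresholds for the merge/call/register stages."""

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    min_depth: int = 10
    balance_threshold: float = 0.25
    noise_frac: float = 0.10
    collapse_max_dist: int = 2
    collapse_min_fold: int = 5
    min_support_reads: int = 5
    min_support_samples: int = 1
    novel_prefix: str = "Ovar-DRB1*Sudan"


def merge_read_pair(
    fwd: str,
    rev: str,
    fwd_qual: str | None = None,
    rev_qual: str | None = None,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge a read pair by overlap; None when no admissible overlap exists.

    ``rev`` is the reverse read as sequenced (reverse strand); it is
    reverse-complemented before alignment.  The overlap offset maximising
    the number of matching bases is chosen among offsets with overlap >=
    min_overlap and mismatch fraction <= max_mismatch_frac.  Conflicting
    overlap bases go to the higher-quality base, ties to the forward read.
    """
    if not fwd or not rev:
        raise ValueError("empty read")
    rc = reverse_complement(rev)
    rc_qual = rev_qual[::-1] if rev_qual is not None else None
    f = np.frombuffer(fwd.encode(), dtype=np.uint8)
    r = np.frombuffer(rc.encode(), dtype=np.uint8)
    best = None  # (matches, -offset) -> offset, mismatch positions
    # offset = start of the reverse-complement read on the forward read
    for offset in range(0, len(f) - min_overlap + 1):
        ov = min(len(f) - offset, len(r))
        if ov < min_overlap:
            break
        matches = int((f[offset : offset + ov] == r[:ov]).sum())
        if (ov - matches) / ov > max_mismatch_frac:
            continue
        if best is None or matches > best[0]:
            best = (matches, offset, ov)
    if best is None:
        return None
    _, offset, ov = best
    merged = list(fwd[: offset + ov])
    n_conflicts = 0
    for i in range(ov):
        fb, rb = fwd[offset + i], rc[i]
        if fb != rb:
            n_conflicts += 1
            fq = fwd_qual[offset + i] if fwd_qual else "!"
            rq = rc_qual[i] if rc_qual else "!"
            merged[offset + i] = rb if rq > fq else fb
    merged.extend(rc[ov:])
    return MergedRead(seq="".join(merged), n_conflicts=n_conflicts)


def tally_haplotypes(merged: Iterable[MergedRead]) -> list[tuple[str, int]]:
    """Group identical merged sequences; sort by count desc, then sequence."""
    counts: dict[str, int] = {}
    length = None
    for m in merged:
        if length is None:
            length = len(m.seq)
        elif len(m.seq) != length:
            raise ValueError("merged reads differ in length")
        counts[m.seq] = counts.get(m.seq, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def collapse_errors(
    tally: Sequence[tuple[str, int]],
    max_dist: int = 2,
    min_fold: int = 5,
) -> list[tuple[str, int]]:
    """Absorb rare near-duplicate sequences into their abundant parents.

    Sequencing errors scatter a haplotype's reads over satellite sequences
    a few substitutions away; a sequence is folded into the most abundant
    sequence within ``max_dist`` substitutions that carries at least
    ``min_fold`` times its count.  Balanced true haplotypes can never
    absorb one another, so heterozygotes survive.  Processing runs from
    rarest to most abundant; output ordering matches tally_haplotypes.
    """
    if max_dist < 0 or min_fold < 2:
        raise ValueError("max_dist must be >= 0 and min_fold >= 2")
    ranked = sorted(tally, key=lambda kv: (-kv[1], kv[0]))
    counts = dict(ranked)
    arrs = {
        s: np.frombuffer(s.encode(), dtype=np.uint8) for s, _ in ranked
    }
    for seq, _ in reversed(ranked):  # rarest first
        best = None
        for parent, _ in ranked:
            if parent == seq or parent not in counts or seq not in counts:
                continue
            if counts[parent] < min_fold * counts[seq]:
                continue
            d = int((arrs[seq] != arrs[parent]).sum())
            if d <= max_dist and (best is None or counts[parent] > counts[best]):
                best = parent
        if best is not None:
            counts[best] += counts.pop(seq)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def call_genotype(
    tally: Sequence[tuple[str, int]],
    sample_id: str = "",
    min_depth: int = 10,
    balance_threshold: float = 0.25,
    noise_frac: float = 0.10,
    n_conflicts: int = 0,
) -> HaplotypeCall:
    """Call homo-/heterozygous from a ranked haplotype tally.

    Sequences below noise_frac of the top count are treated as error or
    chimera noise.  A heterozygote requires the surviving runner-up to hold
    at least balance_threshold of the top count ("balanced numbers of
    reads"); more than two surviving sequences is ambiguous -> failed.
    """
    if not 0 < balance_threshold <= 1:
        raise ValueError("balance_threshold must lie in (0, 1]")
    if not 0 <= noise_frac < 1:
        raise ValueError("noise_frac must lie in [0, 1)")
    total = sum(c for _, c in tally)
    if total < min_depth:
        return HaplotypeCall(sample_id, [], "failed", total, n_conflicts)
    top = tally[0][1]
    surviving = [(s, c) for s, c in tally if c >= noise_frac * top]
    if len(surviving) > 2:
        return HaplotypeCall(sample_id, [], "failed", total, n_conflicts)
    if len(surviving) == 2 and surviving[1][1] >= balance_threshold * top:
        return HaplotypeCall(
            sample_id, surviving, "heterozygous", total, n_conflicts
        )
    return HaplotypeCall(
        sample_id, [surviving[0]], "homozygous", total, n_conflicts
    )


@dataclass
class NovelCandidate:
    seq: str
    sample_id: str
    read_count: int


def assign_alleles(
    call: HaplotypeCall, db: AlleleDatabase
) -> tuple[list[str], list[NovelCandidate]]:
    """Name each haplotype by exact full-length database match.

    Returns (allele names, novel candidates).  A homozygous call yields the
    same name twice.  Haplotypes matching no database entry are emitted as
    novel candidates with their read support; no fuzzy matching.
    """
    if call.status == "failed":
        raise ValueError("cannot assign a failed call")
    names: list[str] = []
    novel: list[NovelCandidate] = []
    for seq, count in call.haplotypes:
        if len(seq) != db.amplicon_length:
            raise ValueError(
                f"haplotype length {len(seq)} != database length "
                f"{db.amplicon_length} (sample {call.sample_id})"
            )
        hit = db.lookup_sequence(seq)
        if hit is None:
            novel.append(NovelCandidate(seq, call.sample_id, count))
            names.append(seq)  # placeholder: replaced after registration
        else:
            names.append(hit)
    if call.status == "homozygous":
        names = names * 2
        novel = novel  # single candidate entry; support already totalled
    return names, novel


def register_novel_alleles(
    candidates: Iterable[NovelCandidate],
    db: AlleleDatabase,
    min_support_reads: int = 5,
    min_support_samples: int = 1,
    prefix: str = "Ovar-DRB1*Sudan",
    frame_offset: int = 0,
) -> tuple[AlleleDatabase, pd.DataFrame]:
    """Pool identical candidate sequences and register the supported ones.

    A sequence is accepted when it reaches min_support_reads reads in at
    least min_support_samples samples.  Accepted alleles are named
    ``<prefix><k>`` in order of (descending total support, sequence), so
    reruns name identically.  Returns the extended database (the input is
    not mutated) and a per-candidate report.
    """
    pooled: dict[str, dict[str, int]] = {}
    for c in candidates:
        pooled.setdefault(c.seq, {})
        pooled[c.seq][c.sample_id] = pooled[c.seq].get(c.sample_id, 0) + c.read_count
    rows = []
    accepted = []
    for seq, by_sample in pooled.items():
        supporting = {s: r for s, r in by_sample.items() if r >= min_support_reads}
        total = sum(by_sample.values())
        ok = len(supporting) >= min_support_samples
        rows.append(
            {
                "seq": seq,
                "n_samples": len(by_sample),
                "n_supporting_samples": len(supporting),
                "total_reads": total,
                "accepted": ok,
            }
        )
        if ok:
            accepted.append((total, seq))
    accepted.sort(key=lambda t: (-t[0], t[1]))
    extended = db.copy()
    name_of: dict[str, str] = {}
    for k, (_, seq) in enumerate(accepted, start=1):
        name = f"{prefix}{k}"
        if name in extended:
            raise ValueError(f"novel name {name!r} collides with database")
        extended.add(
            AlleleSequence(name=name, seq=seq, frame_offset=frame_offset),
            provenance="novel-registered",
        )
        name_of[seq] = name
    report = pd.DataFrame(
        rows, columns=["seq", "n_samples", "n_supporting_samples",
                       "total_reads", "accepted"]
    )
    if len(report):
        report.insert(0, "name", report["seq"].map(name_of).fillna(""))
        report = report.sort_values(
            ["accepted", "total_reads", "seq"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return extended, report


def type_cohort(
    readsets: Sequence[ReadPairSet],
    db: AlleleDatabase,
    params: TypingParams | None = None,
) -> tuple[GenotypeTable, pd.DataFrame, AlleleDatabase, pd.DataFrame]:
    """Run merge -> tally -> call -> assign -> register over a cohort.

    Returns (genotype table of non-failed samples, per-sample QC table,
    extended allele database, novel-allele report).  Haplotypes that end
    up registered are named; candidates that fail registration leave their
    sample's genotype failed (status 'failed_novel_support').
    """
    if not readsets:
        raise ValueError("empty cohort")
    params = params or TypingParams()
    calls: list[HaplotypeCall] = []
    qc_rows = []
    for rs in readsets:
        merged = []
        n_failed_merge = 0
        for fwd, fq, rev, rq in rs.pairs:
            m = merge_read_pair(
                fwd, rev, fq, rq,
                min_overlap=params.min_overlap,
                max_mismatch_frac=params.max_mismatch_frac,
            )
            if m is None or len(m.seq) != db.amplicon_length:
                n_failed_merge += 1
                continue
            merged.append(m)
        conflicts = sum(m.n_conflicts for m in merged)
        tally = collapse_errors(
            tally_haplotypes(merged),
            max_dist=params.collapse_max_dist,
            min_fold=params.collapse_min_fold,
        )
        call = call_genotype(
            tally,
            sample_id=rs.sample_id,
            min_depth=params.min_depth,
            balance_threshold=params.balance_threshold,
            noise_frac=params.noise_frac,
            n_conflicts=conflicts,
        )
        calls.append(call)
        qc_rows.append(
            {
                "sample": rs.sample_id,
                "breed": rs.breed,
                "n_pairs": len(rs.pairs),
                "n_merged": len(merged),
                "n_failed_merge": n_failed_merge,
                "n_overlap_conflicts": conflicts,
                "depth": call.total_depth,
                "status": call.status,
            }
        )
    breed_of = {rs.sample_id: rs.breed for rs in readsets}
    # first pass: collect candidates across the cohort
    all_candidates: list[NovelCandidate] = []
    assigned: dict[str, list[str]] = {}
    for call in calls:
        if call.status == "failed":
            continue
        names, novel = assign_alleles(call, db)
        assigned[call.sample_id] = names
        all_candidates.extend(novel)
    extended, novel_report = register_novel_alleles(
        all_candidates,
        db,
        min_support_reads=params.min_support_reads,
        min_support_samples=params.min_support_samples,
        prefix=params.novel_prefix,
    )
    # second pass: replace candidate placeholders with registered names
    records = []
    status_of = {row["sample"]: row["status"] for row in qc_rows}
    for sample_id, names in assigned.items():
        resolved = []
        ok = True
        for n in names:
            if n in extended:
                resolved.append(n)
            else:
                registered = extended.lookup_sequence(n)
                if registered is None:
                    ok = False
                    break
                resolved.append(registered)
        if ok:
            records.append(
                (sample_id, breed_of[sample_id], resolved[0], resolved[1])
            )
        else:
            status_of[sample_id] = "failed_novel_support"
    for row in qc_rows:
        row["status"] = status_of[row["sample"]]
    qc = pd.DataFrame(qc_rows)
    if not records:
        gt = GenotypeTable(
            pd.DataFrame(columns=["sample", "breed", "allele1", "allele2"])
        )
    else:
        gt = GenotypeTable.from_records(records)
    return gt, qc, extended, novel_report
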