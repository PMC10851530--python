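"""Sequence-level diversity of the allele set carried by each breed.

Provides nucleotide diversity (pi) and the mean number of pairwise
differences (NPD) weighted by allele frequency, synonymous/nonsynonymous
substitution rates under the modified Nei-Gojobori codon model with
Jukes-Cantor correction (over the whole exon or restricted to the
antigen-binding-site codons), translation of the beta-1 domain, pocket
amino-acid motif frequencies, and distance-based allele trees.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from skbio import TreeNode

from .alleles import AlleleDatabase, AlleleSequence
from .distances import (DistanceMatrix, bipartitions, neighbor_joining,
                        sequence_distance_matrix)
from .genotypes import FrequencyMatrix, GenotypeTable, allele_frequencies

_CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# pairwise differences and nucleotide diversity


def pairwise_diff(a: str, b: str) -> int:
    """Hamming distance between two aligned equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((x != y).sum())


@dataclass
class BreedAlleleSet:
    """Alleles carried by one breed with frequencies and copy counts.

    n is the number of gene copies (2N) behind the frequencies; it drives
    the small-sample correction of NPD.
    """

    breed: str
    alleles: list[tuple[AlleleSequence, float, int]]
    n: int

    def __post_init__(self) -> None:
        total = sum(f for _, f, _ in self.alleles)
        if abs(total - 1) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        lengths = {len(a.seq) for a, _, _ in self.alleles}
        if len(lengths) > 1:
            raise ValueError("alleles differ in length")


def breed_allele_set(
    gt: GenotypeTable, db: AlleleDatabase, breed: str
) -> BreedAlleleSet:
    """Collect one breed's alleles (with frequencies) from a genotype table."""
    copies = gt.gene_copies(breed)
    counts = pd.Series(copies).value_counts().sort_index()
    n = copies.size
    alleles = [
        (db.get(name), c / n, int(c)) for name, c in counts.items()
    ]
    return BreedAlleleSet(breed=breed, alleles=alleles, n=n)


def nucleotide_diversity(
    bs: BreedAlleleSet, weighted: bool = True
) -> tuple[float, float]:
    """(pi, NPD) for a breed's allele set.

    Weighted (default): NPD = n/(n-1) * sum_i sum_j p_i p_j d_ij over all
    ordered allele pairs — the frequency-weighted mean number of pairwise
    differences among gene copies with the small-sample correction; pi is
    NPD per site.  weighted=False averages d_ij over distinct allele pairs
    without frequency weighting.
    """
    k = len(bs.alleles)
    if k < 2:
        return 0.0, 0.0
    if bs.n < 2:
        raise ValueError("need >= 2 gene copies")
    length = len(bs.alleles[0][0].seq)
    total = 0.0
    npairs = 0
    for i in range(k):
        for j in range(i + 1, k):
            d = pairwise_diff(bs.alleles[i][0].seq, bs.alleles[j][0].seq)
            if weighted:
                total += 2 * bs.alleles[i][1] * bs.alleles[j][1] * d
            else:
                total += d
                npairs += 1
    if weighted:
        npd = bs.n / (bs.n - 1) * total
    else:
        npd = total / npairs
    return npd / length, npd


# ---------------------------------------------------------------------------
# modified Nei-Gojobori with Jukes-Cantor correction


def _syn_sites_codon(codon: str, r: float) -> float:
    """Weighted synonymous site count of one codon.

    At each position the three possible changes carry weight r (transition)
    or 1 (transversion); the position contributes the synonymous share of
    that weight.  Changes creating stop codons count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn_w = 0.0
        tot_w = 0.0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            w = r if (codon[pos], base) in _TRANSITIONS else 1.0
            tot_w += w
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and _CODON_TABLE[alt] == aa:
                syn_w += w
        s += syn_w / tot_w
    return s


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over substitution pathways.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are excluded (if every pathway is blocked
    the full set is used, which cannot occur with the standard code for
    sense-codon pairs at distance <= 3 but is kept as a safeguard).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if through_stop:
            blocked.append((sd, nd))
        else:
            valid.append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    if not valid:
        sd, nd = 0.0, float(len(diff))  # safeguard: count all as nonsyn
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC-corrected distance d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return float(-0.75 * np.log(1 - 4 * p / 3))


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def nei_gojobori_modified(
    a: str, b: str, r: float = 2.0,
    codon_indices: Sequence[int] | None = None,
) -> tuple[float, float, float, float]:
    """(pS, pN, dS, dN) between two in-frame codon sequences.

    Synonymous/nonsynonymous site counts are weighted by the
    transition/transversion ratio ``r`` (r = 1 recovers the unweighted
    model); differences are averaged over all minimal substitution
    pathways; proportions are Jukes-Cantor corrected.  ``codon_indices``
    restricts the computation to a codon subset (0-based), e.g. the
    antigen-binding-site positions.  dS or dN is NaN when the JC formula
    is undefined (p >= 3/4).
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length must be divisible by 3")
    if r <= 0:
        raise ValueError("transition/transversion ratio must be > 0")
    ca, cb = _codons(a), _codons(b)
    if codon_indices is not None:
        ca = [ca[i] for i in codon_indices]
        cb = [cb[i] for i in codon_indices]
    for seq_codons, label in ((ca, "first"), (cb, "second")):
        for i, c in enumerate(seq_codons):
            if c in STOP_CODONS:
                raise ValueError(f"in-frame stop codon in {label} sequence "
                                 f"at codon {i}")
    s_sites = 0.5 * (
        sum(_syn_sites_codon(c, r) for c in ca)
        + sum(_syn_sites_codon(c, r) for c in cb)
    )
    n_sites = 3 * len(ca) - s_sites
    sd = nd = 0.0
    for x, y in zip(ca, cb):
        ds_, dn_ = _pathway_counts(x, y)
        sd += ds_
        nd += dn_
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return ps, pn, jukes_cantor(ps), jukes_cantor(pn)


def mean_dn_ds(
    bs: BreedAlleleSet,
    codon_subset: str = "all",
    r: float = 2.0,
    pockets: "Mapping[str, PocketDefinition] | None" = None,
    mature_start: int = 6,
) -> dict[str, float]:
    """Average dS/dN over all unordered pairs of distinct alleles.

    codon_subset 'all' uses the whole exon; 'ABS' restricts to the union
    of the pocket codons (see :data:`DEFAULT_POCKETS`).  Pairs where the
    JC correction is undefined are dropped with a warning; if all pairs
    are undefined the averages are NaN.  Reports both the difference
    dS - dN (the published layout) and the ratio dN/dS.
    """
    distinct = [a for a, _, _ in bs.alleles]
    if len(distinct) < 2:
        raise ValueError("need >= 2 distinct alleles")
    indices = None
    if codon_subset == "ABS":
        pockets = pockets or DEFAULT_POCKETS
        n_codons = len(distinct[0].coding) // 3
        indices = abs_codon_indices(pockets, mature_start, n_codons)
    elif codon_subset != "all":
        raise ValueError("codon_subset must be 'all' or 'ABS'")
    ds_vals, dn_vals = [], []
    n_undefined = 0
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            _, _, ds_, dn_ = nei_gojobori_modified(
                distinct[i].coding, distinct[j].coding, r=r,
                codon_indices=indices,
            )
            if np.isnan(ds_) or np.isnan(dn_):
                n_undefined += 1
                continue
            ds_vals.append(ds_)
            dn_vals.append(dn_)
    if n_undefined:
        warnings.warn(
            f"{n_undefined} allele pairs had JC-undefined distances "
            f"and were dropped"
        )
    if not ds_vals:
        return {"breed": bs.breed, "d_s": float("nan"), "d_n": float("nan"),
                "d_s_minus_d_n": float("nan"), "dn_ds_ratio": float("nan"),
                "n_pairs": 0}
    ds_m = float(np.mean(ds_vals))
    dn_m = float(np.mean(dn_vals))
    return {
        "breed": bs.breed,
        "d_s": ds_m,
        "d_n": dn_m,
        "d_s_minus_d_n": ds_m - dn_m,
        "dn_ds_ratio": dn_m / ds_m if ds_m > 0 else float("nan"),
        "n_pairs": len(ds_vals),
    }


def diversity_table(
    gt: GenotypeTable,
    db: AlleleDatabase,
    r: float = 2.0,
    pockets: "Mapping[str, PocketDefinition] | None" = None,
    mature_start: int = 6,
) -> pd.DataFrame:
    """Per-breed pi, NPD and dS/dN for the full exon and the ABS codons."""
    n_codons = len(next(iter(db)).coding) // 3
    try:
        abs_codon_indices(pockets or DEFAULT_POCKETS, mature_start, n_codons)
        abs_ok = True
    except ValueError:
        warnings.warn(
            "pocket positions fall outside the translated region; "
            "ABS columns omitted"
        )
        abs_ok = False
    rows = []
    for breed in gt.breeds:
        bs = breed_allele_set(gt, db, breed)
        pi, npd = nucleotide_diversity(bs)
        row = {"breed": breed, "pi": pi, "NPD": npd}
        if len(bs.alleles) >= 2:
            total = mean_dn_ds(bs, "all", r, pockets, mature_start)
            row.update(
                {
                    "d_s_total": total["d_s"],
                    "d_n_total": total["d_n"],
                    "d_s_minus_d_n_total": total["d_s_minus_d_n"],
                }
            )
            if abs_ok:
                abs_ = mean_dn_ds(bs, "ABS", r, pockets, mature_start)
                row.update(
                    {
                        "d_s_ABS": abs_["d_s"],
                        "d_n_ABS": abs_["d_n"],
                        "d_s_minus_d_n_ABS": abs_["d_s_minus_d_n"],
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# translation and pocket motifs


def translate_beta1(a: AlleleSequence) -> str:
    """Standard-code translation of the in-frame portion of an allele."""
    coding = a.coding
    out = []
    for i in range(0, len(coding), 3):
        codon = coding[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(
                f"stop codon {codon} at codon {i // 3} of allele {a.name!r}"
            )
        out.append(_CODON_TABLE[codon])
    return "".join(out)


@dataclass(frozen=True)
class PocketDefinition:
    """Codon positions (1-based, mature beta-chain numbering) of one pocket."""

    pocket: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based and must be >= 1")


# Peptide-binding pocket residues of the DR beta-1 domain (mature-chain
# numbering), following the standard DRB pocket assignments; the exon-2
# amplicon's first complete codon corresponds to mature residue
# ``mature_start`` (default 6).
DEFAULT_POCKETS: dict[str, PocketDefinition] = {
    "P1": PocketDefinition("P1", (85, 86, 89, 90)),
    "P4": PocketDefinition("P4", (13, 26, 70, 71, 74, 78)),
    "P6": PocketDefinition("P6", (11, 30)),
    "P7": PocketDefinition("P7", (28, 47, 61, 67, 71)),
    "P9": PocketDefinition("P9", (9, 37, 57, 61)),
}


def abs_codon_indices(
    pockets: Mapping[str, PocketDefinition], mature_start: int, n_codons: int
) -> list[int]:
    """0-based amplicon codon indices of the ABS (union of all pockets)."""
    out = set()
    for pd_ in pockets.values():
        for pos in pd_.positions:
            idx = pos - mature_start
            if not 0 <= idx < n_codons:
                raise ValueError(
                    f"pocket {pd_.pocket} position {pos} falls outside the "
                    f"translated amplicon (mature_start={mature_start}, "
                    f"{n_codons} codons)"
                )
            out.add(idx)
    return sorted(out)


def pocket_motif_frequencies(
    gt: GenotypeTable,
    db: AlleleDatabase,
    pockets: Mapping[str, PocketDefinition] | None = None,
    mature_start: int = 6,
) -> dict[str, FrequencyMatrix]:
    """Per-pocket breed-by-motif frequency matrices.

    Each allele contributes its pocket amino-acid motif weighted by its
    allele frequency; identical motifs pool.  Motif frequencies per breed
    and pocket sum to 1.
    """
    pockets = pockets or DEFAULT_POCKETS
    fm = allele_frequencies(gt)
    proteins = {}
    for name in fm.alleles:
        if name not in db:
            raise ValueError(f"allele {name!r} missing from database")
        proteins[name] = translate_beta1(db.get(name))
    out = {}
    for pid, pdef in pockets.items():
        n_codons = min(len(p) for p in proteins.values())
        idx = [
            pos - mature_start
            for pos in pdef.positions
        ]
        for pos, i in zip(pdef.positions, idx):
            if not 0 <= i < n_codons:
                raise ValueError(
                    f"pocket {pid} position {pos} outside translated region"
                )
        motif_of = {
            name: "".join(prot[i] for i in idx)
            for name, prot in proteins.items()
        }
        rows = {}
        for breed in fm.breeds:
            freqs: dict[str, float] = {}
            for name, p in fm.frequencies(breed).items():
                if p > 0:
                    motif = motif_of[name]
                    freqs[motif] = freqs.get(motif, 0.0) + float(p)
            rows[breed] = freqs
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
        df = df[sorted(df.columns)]
        df = df.div(df.sum(axis=1), axis=0)  # absorb float round-off
        out[pid] = FrequencyMatrix(df, fm.n_samples)
    return out


# ---------------------------------------------------------------------------
# allele trees


def allele_nj_tree(
    db: AlleleDatabase | Sequence[AlleleSequence],
    metric: str = "p",
    outgroup: str | None = None,
    columns: Sequence[int] | None = None,
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> tuple[TreeNode, dict[frozenset, float] | None]:
    """Neighbor-joining tree of allele sequences.

    ``columns`` restricts the alignment to the given 0-based nucleotide
    positions (e.g. ABS codons); ``bootstrap_reps`` > 0 adds column-
    resampling bootstrap support (percent, annotated on internal nodes).
    With an ``outgroup`` the tree is rooted on that allele's edge.
    """
    alleles = list(db)
    if len(alleles) < 3:
        raise ValueError("need >= 3 sequences")
    names = [a.name for a in alleles]
    seqs = [a.seq for a in alleles]
    if columns is not None:
        seqs = ["".join(s[i] for i in columns) for s in seqs]
    if outgroup is not None and outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among the sequences")
    tree = neighbor_joining(sequence_distance_matrix(names, seqs, metric))
    support = None
    if bootstrap_reps:
        rng = np.random.default_rng(seed)
        target = bipartitions(tree)
        hits = {bp: 0 for bp in target}
        length = len(seqs[0])
        mats = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
        aln = np.vstack(mats)
        for _ in range(bootstrap_reps):
            cols = rng.integers(length, size=length)
            boot = aln[:, cols]
            boot_seqs = [row.tobytes().decode() for row in boot]
            try:
                bt = neighbor_joining(
                    sequence_distance_matrix(names, boot_seqs, metric)
                )
            except ValueError:  # JC undefined on a resample
                continue
            found = bipartitions(bt)
            for bp in target:
                if bp in found:
                    hits[bp] += 1
        support = {bp: 100.0 * h / bootstrap_reps for bp, h in hits.items()}
        tips = frozenset(names)
        ref = min(tips)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = tips - side
            if side in support:
                node.name = f"{support[side]:.0f}"
    if outgroup is not None:
        og = tree.find(outgroup)
        tree = tree.root_at(og.parent)
    return tree, support
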