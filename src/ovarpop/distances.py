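"""Between-breed genetic distances and distance-based trees.

Nei's standard distance Ds and the arc-type DA distance are computed from
breed allele-frequency vectors; UPGMA and neighbor-joining build the
dendrograms, and bootstrap resampling of individuals within breeds gives
node support.  Trees are :class:`skbio.TreeNode` objects, so Newick
output and re-rooting come from scikit-bio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotypes import FrequencyMatrix, GenotypeTable, allele_frequencies


# ---------------------------------------------------------------------------
# distance measures


def nei_standard_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Nei's standard genetic distance Ds = -ln(Jxy / sqrt(Jx*Jy)).

    +inf (with a warning) when the two vectors share no alleles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    jx = float((x ** 2).sum())
    jy = float((y ** 2).sum())
    jxy = float((x * y).sum())
    if jxy == 0:
        warnings.warn("no shared alleles: Ds is infinite")
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_da_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Nei's DA = 1 - sum_i sqrt(x_i * y_i) (single-locus form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(1.0 - np.sqrt(x * y).sum())


_METRICS: dict[str, Callable] = {
    "Ds": nei_standard_distance,
    "DA": nei_da_distance,
}


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a metric tag."""

    df: pd.DataFrame
    tag: str

    def __post_init__(self) -> None:
        m = self.df.values
        if not np.array_equal(np.diag(m), np.zeros(len(m))):
            raise ValueError("diagonal must be exactly zero")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite], atol=1e-12):
            raise ValueError("matrix must be symmetric")

    @property
    def labels(self) -> list[str]:
        return list(self.df.index)

    def has_infinite(self) -> bool:
        return bool(np.isinf(self.df.values).any())


def breed_distance_matrix(fm: FrequencyMatrix, metric: str = "DA"
                          ) -> DistanceMatrix:
    """All-pairs breed distance matrix under Ds or DA."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; use 'Ds' or 'DA'")
    fn = _METRICS[metric]
    breeds = fm.breeds
    mat = pd.DataFrame(0.0, index=breeds, columns=breeds)
    for i, a in enumerate(breeds):
        for b in breeds[i + 1:]:
            d = fn(fm.df.loc[a].values, fm.df.loc[b].values)
            mat.loc[a, b] = mat.loc[b, a] = d
    return DistanceMatrix(mat, metric)


def sequence_distance_matrix(names: Sequence[str], seqs: Sequence[str],
                             metric: str = "p") -> DistanceMatrix:
    """p-distance or Jukes-Cantor distance matrix between aligned sequences."""
    n = len(seqs)
    length = len(seqs[0])
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    mat = pd.DataFrame(0.0, index=list(names), columns=list(names))
    for i in range(n):
        for j in range(i + 1, n):
            p = float((arrs[i] != arrs[j]).sum()) / length
            if metric == "p":
                d = p
            elif metric == "JC":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} >= 3/4: JC undefined for pair "
                        f"({names[i]}, {names[j]})"
                    )
                d = -0.75 * np.log(1 - 4 * p / 3)
            else:
                raise ValueError(f"unknown metric {metric!r}; use 'p' or 'JC'")
            mat.iloc[i, j] = mat.iloc[j, i] = d
    return DistanceMatrix(mat, metric)


# ---------------------------------------------------------------------------
# tree building


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage clustering; ultrametric rooted tree.

    Node heights are half the between-cluster distance; ties are broken by
    joining the pair whose (lexicographically smallest) representative
    labels sort first, so the merge order is deterministic.
    """
    if d.has_infinite():
        raise ValueError(
            f"infinite {d.tag} entries: use the DA distance for tree building"
        )
    labels = d.labels
    dist = {
        frozenset((a, b)): float(d.df.loc[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }

    def get(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    nodes = {lab: TreeNode(name=lab) for lab in labels}
    sizes = {lab: 1 for lab in labels}
    heights = {lab: 0.0 for lab in labels}
    active = sorted(labels)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                key = (get(a, b), a, b)
                if best is None or key < best:
                    best = key
        dm, a, b = best
        height = dm / 2
        child_a, child_b = nodes[a], nodes[b]
        child_a.length = height - heights[a]
        child_b.length = height - heights[b]
        parent = TreeNode(children=[child_a, child_b])
        rep = min(a, b)  # representative: smallest leaf label
        for other in active:
            if other in (a, b):
                continue
            dnew = (sizes[a] * get(a, other) + sizes[b] * get(b, other)) / (
                sizes[a] + sizes[b]
            )
            dist[frozenset((rep, other))] = dnew
        nodes[rep] = parent
        sizes[rep] = sizes[a] + sizes[b]
        heights[rep] = height
        active = sorted(set(active) - {a, b} | {rep})
    root = nodes[active[0]]
    root.length = None
    return root


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted tree (trifurcating root).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch; ties in the Q criterion break lexicographically by
    representative labels.
    """
    if d.has_infinite():
        raise ValueError(
            f"infinite {d.tag} entries: use the DA distance for tree building"
        )
    labels = sorted(d.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    dist = {
        frozenset((a, b)): float(d.df.loc[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }
    nodes = {lab: TreeNode(name=lab) for lab in labels}
    active = list(labels)

    def get(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        totals = {a: sum(get(a, o) for o in active if o != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * get(a, b) - totals[a] - totals[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = get(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (m - 2))
        lb = dab - la
        # clamp negatives, transferring the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        node_a, node_b = nodes[a], nodes[b]
        node_a.length = la
        node_b.length = lb
        parent = TreeNode(children=[node_a, node_b])
        rep = min(a, b)
        for other in active:
            if other in (a, b):
                continue
            dnew = 0.5 * (get(a, other) + get(b, other) - dab)
            dist[frozenset((rep, other))] = max(dnew, 0.0)
        nodes[rep] = parent
        active = sorted(set(active) - {a, b} | {rep})
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lab].length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


# ---------------------------------------------------------------------------
# bipartitions and bootstrap support


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical bipartitions induced by the internal edges of a tree.

    Each internal edge splits the taxa into two sides; the canonical form
    is the side not containing the alphabetically first taxon, so rooted
    and unrooted versions of the same grouping compare equal.  Trivial
    splits (single taxon or all taxa) are dropped.
    """
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if 1 < len(side) < len(tips) - 1:
            out.add(side)
    return out


def bootstrap_support(
    gt: GenotypeTable,
    distance: str = "DA",
    method: str = "nj",
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Tree with bootstrap support from resampling individuals within breeds.

    Each replicate resamples every breed's individuals with replacement,
    recomputes allele frequencies, the distance matrix and the tree;
    support for each original bipartition is the percentage of replicates
    containing it.  Internal nodes of the returned tree carry the support
    in their name.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    build = {"upgma": upgma, "nj": neighbor_joining}[method]
    fm = allele_frequencies(gt)
    tree = build(breed_distance_matrix(fm, distance))
    target = bipartitions(tree)
    sizes = gt.sample_sizes()
    for breed, n in sizes.items():
        if n == 1:
            warnings.warn(f"breed {breed!r} has a single sample; "
                          "its resampling is degenerate")
    rng = np.random.default_rng(seed)
    hits = {bp: 0 for bp in target}
    groups = {b: gt.df[gt.df["breed"] == b] for b in gt.breeds}
    for _ in range(n_reps):
        frames = []
        for breed, sub in groups.items():
            idx = rng.integers(len(sub), size=len(sub))
            boot = sub.iloc[idx].copy()
            boot["sample"] = [f"{breed}_{i}" for i in range(len(boot))]
            frames.append(boot)
        boot_gt = GenotypeTable(pd.concat(frames, ignore_index=True))
        boot_tree = build(breed_distance_matrix(
            allele_frequencies(boot_gt), distance))
        found = bipartitions(boot_tree)
        for bp in target:
            if bp in found:
                hits[bp] += 1
    support = {bp: 100.0 * h / n_reps for bp, h in hits.items()}
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if side in support:
            node.name = f"{support[side]:.0f}"
    return tree, support


# ---------------------------------------------------------------------------
# allele sharing and common-allele profiles


def allele_sharing_summary(
    fm: FrequencyMatrix, breed_subset: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Venn-style membership of alleles across breeds.

    Returns (cell table, counts per membership cardinality).  The cell
    table lists, per allele present in the subset, the breeds carrying it;
    the counts Series maps "present in exactly m breeds" to allele counts,
    so counts.sum() equals the number of alleles segregating in the subset.
    """
    breeds = list(breed_subset) if breed_subset else fm.breeds
    if not breeds:
        raise ValueError("empty breed subset")
    present = fm.df.loc[breeds] > 0
    memb = present.sum(axis=0)
    cells = pd.DataFrame(
        {
            "allele": fm.alleles,
            "breeds": [
                ",".join(b for b in breeds if present.loc[b, a])
                for a in fm.alleles
            ],
            "n_breeds": memb.values,
        }
    )
    cells = cells[cells["n_breeds"] > 0].reset_index(drop=True)
    counts = cells["n_breeds"].value_counts().sort_index()
    counts.index.name = "n_breeds"
    return cells, counts


def common_allele_profile(
    fm: FrequencyMatrix, threshold: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Common alleles (frequency > threshold) per breed and ranked curves.

    Returns (per-breed summary, ranked cumulative-frequency table).  The
    summary holds the number of common alleles and their summed frequency;
    the ranked table gives, per breed, allele frequencies sorted in
    decreasing order with the running cumulative frequency (the data behind
    a cumulative gene-frequency plot).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    summary_rows = []
    curve_rows = []
    for breed in fm.breeds:
        p = fm.frequencies(breed)
        p = p[p > 0].sort_values(ascending=False)
        common = p[p > threshold]
        summary_rows.append(
            {
                "breed": breed,
                "n_common": len(common),
                "cumulative_common": float(common.sum()),
            }
        )
        cum = p.cumsum()
        for rank, (allele, freq) in enumerate(p.items(), start=1):
            curve_rows.append(
                {
                    "breed": breed,
                    "rank": rank,
                    "allele": allele,
                    "frequency": float(freq),
                    "cumulative": float(cum.loc[allele]),
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(curve_rows)
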