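"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, closed forms, scans)
and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import factorial, log

import numpy as np

# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test, 2 alleles, by complete enumeration


def hwe_exact_2allele(n1: int, n2: int, obs_het: int) -> float:
    """Exact conditional p-value for a 2-allele genotype table.

    Tables with allele counts (n1, n2) are indexed by the heterozygote
    count n12 (same parity as n1); Pr(table) is proportional to
    N! / (n11! n12! n22!) * 2^n12.  The p-value sums the probabilities of
    all tables no more probable than the observed one.
    """
    assert (n1 + n2) % 2 == 0
    tables = []
    for n12 in range(n1 % 2, min(n1, n2) + 1, 2):
        n11 = (n1 - n12) // 2
        n22 = (n2 - n12) // 2
        n = n11 + n12 + n22
        pr = (
            factorial(n)
            / (factorial(n11) * factorial(n12) * factorial(n22))
            * 2 ** n12
        )
        tables.append((n12, pr))
    total = sum(pr for _, pr in tables)
    obs_pr = dict(tables)[obs_het]
    return sum(pr for _, pr in tables if pr <= obs_pr * (1 + 1e-12)) / total


# ---------------------------------------------------------------------------
# unsigned Stirling numbers of the first kind (ESF normaliser)


@lru_cache(maxsize=None)
def stirling_unsigned(n: int, k: int) -> int:
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0:
        return 0
    return stirling_unsigned(n - 1, k - 1) + (n - 1) * stirling_unsigned(
        n - 1, k
    )


def esf_config_probability(partition: tuple[int, ...]) -> float:
    """Pr(configuration | n, k) under the Ewens sampling formula."""
    n = sum(partition)
    k = len(partition)
    mult = {}
    for part in partition:
        mult[part] = mult.get(part, 0) + 1
    w = factorial(n)
    for j, a_j in mult.items():
        w /= j ** a_j * factorial(a_j)
    return w / stirling_unsigned(n, k)


# ---------------------------------------------------------------------------
# Nei-Gojobori by explicit enumeration

_CODE = {}


def _codon_table():
    global _CODE
    if not _CODE:
        from Bio.Seq import Seq

        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    c = b1 + b2 + b3
                    _CODE[c] = str(Seq(c).translate())
    return _CODE


def ng_sites_oracle(seq: str, r: float) -> float:
    """Weighted synonymous site count by scanning every possible change."""
    code = _codon_table()
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        for pos in range(3):
            syn_w = tot_w = 0.0
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                w = r if (codon[pos], alt) in transitions else 1.0
                tot_w += w
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if code[mutant] != "*" and code[mutant] == code[codon]:
                    syn_w += w
            s += syn_w / tot_w
    return s


def ng_diffs_oracle(a: str, b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over substitution orderings."""
    code = _codon_table()
    sd = nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        diff = [j for j in range(3) if ca[j] != cb[j]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur = ca
            steps = []
            ok = True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if code[nxt] == "*":
                    ok = False
                    break
                steps.append(1 if code[cur] == code[nxt] else 0)
                cur = nxt
            if ok:
                paths.append(steps)
        assert paths, "all pathways blocked by stops in oracle input"
        sd += np.mean([sum(p) for p in paths])
        nd += np.mean([len(p) - sum(p) for p in paths])
    return sd, nd


# ---------------------------------------------------------------------------
# random additive trees and their metrics


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree with positive branch lengths.

    Returns (labels, distance matrix, set of canonical non-trivial
    bipartitions).  Built by sequential leaf insertion into random edges;
    distances are path lengths through the tree.
    """
    import networkx as nx

    labels = [f"L{i}" for i in range(n_leaves)]
    g = nx.Graph()
    g.add_edge(labels[0], labels[1],
               weight=float(rng.uniform(0.05, 1.0)))
    internal = 0
    for leaf in labels[2:]:
        edges = list(g.edges(data=True))
        u, v, data = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
        mid = f"I{internal}"
        internal += 1
        w = data["weight"]
        split = float(rng.uniform(0.2, 0.8)) * w
        g.add_edge(u, mid, weight=split)
        g.add_edge(mid, v, weight=w - split)
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.05, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    d = np.array([[dist[a][b] for b in labels] for a in labels])
    # bipartitions: removing each internal edge splits the leaves
    bips = set()
    ref = min(labels)
    for u, v in g.edges():
        if u in labels or v in labels:
            continue
        h = g.copy()
        h.remove_edge(u, v)
        import networkx as nx2

        comp = nx2.node_connected_component(h, u)
        side = frozenset(x for x in comp if x in labels)
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < n_leaves - 1:
            bips.add(side)
    return labels, d, bips
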