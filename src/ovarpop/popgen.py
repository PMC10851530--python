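"""Allele-level diversity and structure statistics.

Covers direct-counting frequencies (see :mod:`ovarpop.genotypes`),
observed and Nei-unbiased expected heterozygosity, the Weir-Cockerham
variance-component estimators f (within-breed, F_IS) and theta (among-
breed, F_ST) with permutation p-values, a Monte-Carlo exact test of
Hardy-Weinberg proportions conditional on allele counts, and the
Ewens-Watterson-Slatkin exact test of selective neutrality conditional
on sample size and allele number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import FrequencyMatrix, GenotypeTable, allele_frequencies

__all__ = [
    "allele_frequencies",
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "fis",
    "hwe_exact_test",
    "ewens_watterson_slatkin",
    "fst_weir_cockerham",
    "diversity_report",
    "FstReport",
]


# ---------------------------------------------------------------------------
# heterozygosity


def observed_heterozygosity(gt: GenotypeTable, breed: str) -> float:
    """h_O: fraction of the breed's samples with two distinct alleles."""
    sub = gt.df[gt.df["breed"] == breed]
    if sub.empty:
        raise ValueError(f"breed {breed!r} not present")
    return float((sub["allele1"] != sub["allele2"]).mean())


def unbiased_expected_heterozygosity(
    freqs: Sequence[float], n_samples: int
) -> float:
    """Nei's unbiased h_E = (2N/(2N-1)) * (1 - sum p_i^2)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    two_n = 2 * n_samples
    return float(two_n / (two_n - 1) * (1.0 - (p ** 2).sum()))


def heterozygosity_from_frequencies(fm: FrequencyMatrix) -> pd.DataFrame:
    """Per-breed N, n_a and unbiased h_E straight from a frequency matrix.

    This is the subset of the diversity report computable without
    genotype-level data (published frequency tables carry no h_O, F_IS or
    exact-test information).
    """
    rows = []
    for breed in fm.breeds:
        p = fm.frequencies(breed)
        p = p[p > 0]
        n = fm.n_samples[breed]
        rows.append(
            {
                "breed": breed,
                "N": n,
                "n_a": fm.n_alleles(breed),
                "h_E": unbiased_expected_heterozygosity(p.values, n),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components

def _encode_breed(gt: GenotypeTable, breed: str):
    sub = gt.df[gt.df["breed"] == breed]
    if sub.empty:
        raise ValueError(f"breed {breed!r} not present")
    alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
    code = {a: i for i, a in enumerate(alleles)}
    c1 = sub["allele1"].map(code).to_numpy()
    c2 = sub["allele2"].map(code).to_numpy()
    return c1, c2, len(alleles)


def fis(gt: GenotypeTable, breed: str) -> float:
    """Weir-Cockerham within-population f for one breed.

    Per allele, with n individuals, allele frequency p and observed
    frequency h of heterozygotes carrying the allele:

        b = n/(n-1) * [ p(1-p) - (2n-1)/(4n) * h ]
        c = h/2
        f = 1 - sum(c) / sum(b + c)

    Monomorphic breeds have no defined f and return NaN.
    """
    c1, c2, k = _encode_breed(gt, breed)
    n = c1.size
    if n < 2 or k < 2:
        return float("nan")
    het = c1 != c2
    b_sum = c_sum = 0.0
    for i in range(k):
        p = ((c1 == i).sum() + (c2 == i).sum()) / (2 * n)
        h = (het & ((c1 == i) | (c2 == i))).sum() / n
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        b_sum += b
        c_sum += h / 2
    denom = b_sum + c_sum
    if denom == 0:
        return float("nan")
    return float(1.0 - c_sum / denom)


def _wc_theta(pop: np.ndarray, c1: np.ndarray, c2: np.ndarray,
              n_pops: int, n_alleles: int) -> float:
    """Weir-Cockerham theta from population labels and genotype codes."""
    r = n_pops
    n_i = np.bincount(pop, minlength=r).astype(float)  # individuals per pop
    if (n_i < 2).any():
        raise ValueError("every population needs >= 2 individuals")
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    het = c1 != c2
    # per-pop allele counts over gene copies
    counts = (
        np.bincount(pop * n_alleles + c1, minlength=r * n_alleles)
        + np.bincount(pop * n_alleles + c2, minlength=r * n_alleles)
    ).reshape(r, n_alleles).astype(float)
    p_ia = counts / (2 * n_i)[:, None]
    # per-pop frequency of heterozygotes carrying each allele
    hcounts = (
        np.bincount(pop[het] * n_alleles + c1[het], minlength=r * n_alleles)
        + np.bincount(pop[het] * n_alleles + c2[het], minlength=r * n_alleles)
    ).reshape(r, n_alleles).astype(float)
    h_ia = hcounts / n_i[:, None]
    w = n_i / (r * nbar)
    pbar = w @ p_ia
    s2 = ((n_i[:, None] * (p_ia - pbar) ** 2).sum(axis=0)
          / ((r - 1) * nbar))
    hbar = w @ h_ia
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


@dataclass
class FstReport:
    """Global and pairwise Weir-Cockerham theta with permutation p-values."""

    theta_global: float
    p_global: float
    pairwise: pd.DataFrame  # symmetric theta matrix, zero diagonal
    pairwise_p: pd.DataFrame


def _encode_cohort(gt: GenotypeTable, breeds: Sequence[str]):
    sub = gt.df[gt.df["breed"].isin(breeds)]
    alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
    code = {a: i for i, a in enumerate(alleles)}
    bcode = {b: i for i, b in enumerate(breeds)}
    pop = sub["breed"].map(bcode).to_numpy()
    c1 = sub["allele1"].map(code).to_numpy()
    c2 = sub["allele2"].map(code).to_numpy()
    return pop, c1, c2, len(alleles)


def _perm_pvalue(pop, c1, c2, n_pops, n_alleles, observed,
                 n_perms, rng) -> float:
    """P(theta_perm >= theta_obs) under random reassignment of individuals."""
    if math.isnan(observed):
        return float("nan")
    hits = 0
    labels = pop.copy()
    for _ in range(n_perms):
        rng.shuffle(labels)
        t = _wc_theta(labels, c1, c2, n_pops, n_alleles)
        if t >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perms + 1)


def fst_weir_cockerham(
    gt: GenotypeTable,
    breeds: Sequence[str] | None = None,
    n_perms: int = 10_000,
    seed: int | None = None,
) -> FstReport:
    """Global and pairwise theta over the requested breeds.

    Negative estimates are reported as computed (no truncation at zero).
    p-values come from permuting individuals among breeds; breeds with a
    single sample are excluded with a warning.
    """
    import warnings

    if breeds is None:
        breeds = gt.breeds
    sizes = gt.sample_sizes()
    usable = [b for b in breeds if sizes.get(b, 0) >= 2]
    dropped = sorted(set(breeds) - set(usable))
    if dropped:
        warnings.warn(f"breeds excluded (single sample or absent): {dropped}")
    if len(usable) < 2:
        raise ValueError("need >= 2 breeds with >= 2 samples each")
    rng = np.random.default_rng(seed)
    pop, c1, c2, k = _encode_cohort(gt, usable)
    theta = _wc_theta(pop, c1, c2, len(usable), k)
    p_global = _perm_pvalue(pop, c1, c2, len(usable), k, theta, n_perms, rng)
    nb = len(usable)
    mat = pd.DataFrame(0.0, index=usable, columns=usable)
    pmat = pd.DataFrame(np.nan, index=usable, columns=usable)
    for i in range(nb):
        for j in range(i + 1, nb):
            pair = [usable[i], usable[j]]
            ppop, pc1, pc2, pk = _encode_cohort(gt, pair)
            th = _wc_theta(ppop, pc1, pc2, 2, pk)
            pv = _perm_pvalue(ppop, pc1, pc2, 2, pk, th, n_perms, rng)
            mat.iloc[i, j] = mat.iloc[j, i] = th
            pmat.iloc[i, j] = pmat.iloc[j, i] = pv
    return FstReport(theta, p_global, mat, pmat)


# ---------------------------------------------------------------------------
# exact test of Hardy-Weinberg proportions


def _table_stat(c1: np.ndarray, c2: np.ndarray, k: int) -> float:
    """log-probability statistic of a genotype table, constants dropped.

    The conditional probability of a table given allele counts is
    N! / prod(n_ij!) * 2^h * prod(n_i!) / (2N)!; terms fixed by the allele
    counts cancel when ranking tables, leaving h*log2 - sum log n_ij!.
    """
    lo = np.minimum(c1, c2)
    hi = np.maximum(c1, c2)
    codes = lo * k + hi
    counts = np.bincount(codes, minlength=k * k)
    h = int((c1 != c2).sum())
    return float(h * math.log(2) - gammaln(counts + 1).sum())


def hwe_exact_test(
    gt: GenotypeTable,
    breed: str,
    n_reps: int = 100_000,
    seed: int | None = None,
    _batch: int = 20_000,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions for one breed.

    Tables are generated by randomly re-pairing the breed's observed 2N
    gene copies; the p-value is the fraction of tables (observed included)
    whose conditional probability given the allele counts is <= that of
    the observed table.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000")
    c1, c2, k = _encode_breed(gt, breed)
    if k < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    t_obs = _table_stat(c1, c2, k)
    copies = np.concatenate([c1, c2]).astype(np.int64)
    n = c1.size
    hits = 0
    done = 0
    log2 = math.log(2)
    while done < n_reps:
        m = min(_batch, n_reps - done)
        block = rng.permuted(np.tile(copies, (m, 1)), axis=1)
        a = block[:, 0::2]
        b = block[:, 1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = lo * k + hi + (np.arange(m) * k * k)[:, None]
        counts = np.bincount(codes.ravel(), minlength=m * k * k)
        counts = counts.reshape(m, k * k)
        h = (a != b).sum(axis=1)
        t = h * log2 - gammaln(counts + 1).sum(axis=1)
        hits += int((t <= t_obs + 1e-9).sum())
        done += m
    return (hits + 1) / (n_reps + 1)


# ---------------------------------------------------------------------------
# Ewens-Watterson-Slatkin exact test of neutrality


def _partitions_into_k(n: int, k: int, max_part: int | None = None
                       ) -> Iterator[tuple[int, ...]]:
    """Partitions of n into exactly k positive parts, nonincreasing."""
    if max_part is None:
        max_part = n
    if k == 1:
        if n <= max_part:
            yield (n,)
        return
    for first in range(min(n - k + 1, max_part), 0, -1):
        if first * k < n:
            break
        for rest in _partitions_into_k(n - first, k - 1, first):
            yield (first,) + rest


def _log_esf_weight(partition: Sequence[int]) -> float:
    """log of n! / prod_j (j^{a_j} a_j!) for a partition of n.

    These weights, normalised over all partitions of n into k parts, give
    the Ewens sampling formula conditional on (n, k); the normaliser is
    the unsigned Stirling number |s(n, k)| and theta cancels.
    """
    n = int(sum(partition))
    a = np.bincount(np.asarray(partition, dtype=int))
    j = np.nonzero(a)[0]
    return float(
        gammaln(n + 1) - (a[j] * np.log(j)).sum() - gammaln(a[j] + 1).sum()
    )


def watterson_f(allele_counts: Sequence[int]) -> float:
    """Watterson's homozygosity F = sum p_i^2 of a count configuration."""
    c = np.asarray(allele_counts, dtype=float)
    p = c / c.sum()
    return float((p ** 2).sum())


def _solve_theta_for_k(n: int, k: int) -> float:
    """theta with E[number of alleles] = k under the ESF, by bisection."""
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        ek = sum(mid / (mid + i) for i in range(n))
        if ek < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _sample_esf_partition(rng: np.random.Generator, theta: float, n: int
                          ) -> tuple[int, ...]:
    counts: list[int] = []
    for i in range(n):
        if rng.random() * (theta + i) < theta:
            counts.append(1)
        else:
            pick = rng.integers(i)
            acc = 0
            for j, c in enumerate(counts):
                acc += c
                if pick < acc:
                    counts[j] += 1
                    break
    return tuple(sorted(counts, reverse=True))


def ewens_watterson_slatkin(
    allele_counts: Sequence[int],
    mode: str = "auto",
    n_reps: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Slatkin's exact test of the Ewens configuration; returns (F_obs, p).

    F_obs is Watterson's homozygosity sum p_i^2.  Conditional on the
    sample size n and allele number k, each count configuration has an
    Ewens-sampling-formula probability proportional to
    n! / prod_j (j^{a_j} a_j!); the exact p-value sums the probabilities
    of configurations no more probable than the observed one.

    mode 'enumerate' iterates all partitions of n into k parts (used
    automatically for n <= 40); 'montecarlo' samples configurations from
    the conditional distribution by running the Ewens urn at a theta tuned
    so E[k] matches, rejecting other allele numbers.
    """
    counts = sorted((int(c) for c in allele_counts), reverse=True)
    if any(c <= 0 for c in counts):
        raise ValueError("allele counts must be positive")
    k = len(counts)
    n = sum(counts)
    f_obs = watterson_f(counts)
    if k == 1:
        import warnings

        warnings.warn("monomorphic configuration: neutrality test undefined")
        return f_obs, 1.0
    if mode == "auto":
        mode = "enumerate" if n <= 40 else "montecarlo"
    obs = tuple(counts)
    log_w_obs = _log_esf_weight(obs)
    if mode == "enumerate":
        log_ws = np.array(
            [_log_esf_weight(p) for p in _partitions_into_k(n, k)]
        )
        total = np.exp(log_ws - log_ws.max())
        le = log_ws <= log_w_obs + 1e-9
        p = float(total[le].sum() / total.sum())
        return f_obs, p
    if mode != "montecarlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    theta = _solve_theta_for_k(n, k)
    hits = accepted = 0
    target = n_reps
    max_draws = 200 * n_reps  # rejection guard
    draws = 0
    while accepted < target and draws < max_draws:
        draws += 1
        part = _sample_esf_partition(rng, theta, n)
        if len(part) != k:
            continue
        accepted += 1
        if _log_esf_weight(part) <= log_w_obs + 1e-9:
            hits += 1
    if accepted == 0:
        raise RuntimeError("conditional sampler accepted no configurations")
    return f_obs, (hits + 1) / (accepted + 1)


# ---------------------------------------------------------------------------
# per-breed summary (the published diversity-table layout)


def diversity_report(
    gt: GenotypeTable,
    n_reps_hwe: int = 100_000,
    n_reps_slatkin: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One row per breed: N, n_a, h_O, h_E, F_IS, HWE p, F_obs, Slatkin p."""
    fm = allele_frequencies(gt)
    rng = np.random.default_rng(seed)
    rows = []
    for breed in gt.breeds:
        p = fm.frequencies(breed)
        p = p[p > 0]
        n = fm.n_samples[breed]
        counts = np.rint(p.values * 2 * n).astype(int)
        f_obs, p_slatkin = ewens_watterson_slatkin(
            counts, seed=int(rng.integers(2**31)), n_reps=n_reps_slatkin
        )
        rows.append(
            {
                "breed": breed,
                "N": n,
                "n_a": fm.n_alleles(breed),
                "h_O": observed_heterozygosity(gt, breed),
                "h_E": unbiased_expected_heterozygosity(p.values, n),
                "F_IS": fis(gt, breed),
                "p_HWE": hwe_exact_test(
                    gt, breed, n_reps=n_reps_hwe,
                    seed=int(rng.integers(2**31)),
                ),
                "F_watterson": f_obs,
                "p_slatkin": p_slatkin,
            }
        )
    return pd.DataFrame(rows)
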