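# Methods

This note documents the models, estimators and numerical choices behind
`ovarpop`, and what the synthetic-data tests do and do not establish
about real data.

## The locus and the data model

The target is a single ~270-bp amplicon spanning the second exon of a
hypervariable MHC class II gene (the ovine *DRB1* β1 domain). Because
one amplicon covers the whole exon, a merged read pair observes a
complete haplotype, so diploid genotypes can be read directly from the
two dominant merged sequences — no mapping, variant calling or
statistical phasing is involved. All analyses treat the locus as a
single multi-allelic marker; alleles are full-length exon haplotypes
with IPD-MHC-style names.

## Synthetic-data generator

The generator emulates a pooled single-run paired-end amplicon
experiment:

- **Allele library.** A random base sequence composed of non-stop
  codons is mutated to produce `n_alleles` unique sequences, every pair
  differing at ≥ `min_pairwise_diff` sites and none containing an
  in-frame stop. This preserves the two properties the downstream code
  relies on: exact-match assignment is unambiguous, and every allele
  translates.
- **Cohorts.** Per breed, 2N gene copies are drawn either from an
  explicit frequency vector or from the Ewens sampling formula
  (sequential urn). The inbreeding parameter f mixes in a proportion f
  of "one draw duplicated" genotypes, which yields genotype frequencies
  f·p + (1−f)·p² for homozygotes — the standard single-parameter
  departure from Hardy–Weinberg; f = 0 gives HWE draws and f = 1 all
  homozygotes.
- **Reads.** Per-sample pair counts follow a normal truncated at zero,
  with defaults mean 32.61 and sd 18.29 — the depth statistics of the
  run the package models. A truncated normal rather than a Poisson is
  used deliberately: pooled amplicon runs are strongly overdispersed,
  and the truncated normal reproduces the reported mean±sd directly.
  Each pair comes from one of the two alleles with probability 1/2.
  `read_len` defaults to the amplicon length: a 600-cycle (2×300)
  paired run on a ~270-bp insert yields reads that each span the whole
  insert after trimming, which is exactly what makes whole-haplotype
  phasing possible. Substitution errors are independent per base
  (no indels — the exon is typed as a fixed-length unit and indel
  alleles are not modelled); erroneous positions are written at a lower
  Phred score (Q15 against a Q30 baseline) as a base caller would, and
  `error_quality=None` switches to strictly flat qualities.

What the simulator does **not** model: PCR chimeras, primer artefacts,
quality decay along the read, indels, copy-number variation, and
cross-sample contamination. Green typing tests therefore demonstrate
correctness of the algorithmic chain under the stated error model, not
robustness to every artefact of real libraries (chimera filtering is
the main omission; the ambiguity rule fails samples with a third
abundant haplotype rather than rescuing them).

## Typing

1. **Merging.** For each pair the reverse read is reverse-complemented
   and slid along the forward read; the offset maximising matching
   bases, subject to overlap ≥ `min_overlap` (20) and mismatch fraction
   ≤ `max_mismatch_frac` (0.1), wins. Overlap conflicts go to the
   higher-quality base; ties keep the forward base. Merges whose length
   differs from the database amplicon length are dropped.
2. **Error collapse.** Identical merged sequences are tallied, then
   rare sequences are folded into an abundant neighbour: a sequence is
   absorbed by the most abundant sequence within `collapse_max_dist`
   (2) substitutions carrying ≥ `collapse_min_fold` (5)× its count,
   processed rarest-first. Balanced true haplotypes can never absorb
   each other; satellite error sequences (typically 1–2 substitutions
   off, count 1–2) are reclaimed by their source haplotype. Without
   this step, raw tallies at realistic error rates leave singleton
   error sequences above the noise cut for heterozygotes and trigger
   spurious ambiguity failures.
3. **Calling.** Samples with fewer than `min_depth` (10) merged reads
   fail. Sequences below `noise_frac` (0.10) of the top count are
   discarded as residual noise. A heterozygote is called when the
   runner-up holds ≥ `balance_threshold` (0.25) of the top count — the
   quantitative form of "both alleles with balanced read numbers"; the
   source material gives no number, so 0.25 is an explicit, configurable
   stand-in. More than two surviving sequences → failed (ambiguous).
4. **Assignment and novelty.** Assignment is exact full-length sequence
   identity against the database — allele identity at this locus is
   sequence-exact, so near-misses are novel candidates by definition,
   not fuzzy matches. Candidates pooled across the cohort register as
   novel alleles when they reach `min_support_reads` (5) in
   ≥ `min_support_samples` (1) samples, named `<prefix>k` in order of
   descending total support (ties broken by sequence) so reruns name
   identically.

Measured on the simulator at defaults: 100/100 correct genotypes at
depth 30 / error 0.002, 99/100 at depth 20 / error 0.005.

## Allele-level statistics

- **h_E** uses Nei's unbiased estimator (2N/(2N−1))(1 − Σp²); **h_O**
  is the heterozygote fraction.
- **F_IS** is the Weir–Cockerham within-population f from per-allele
  variance components (b, c as in the r = 1 reduction of the 1984
  estimator); monomorphic breeds return NaN rather than an exception.
  The companion HWE p-value is computed separately (below) and reported
  side by side, because "an exact test for F_IS" conflates an estimator
  with a test.
- **Exact HWE test.** The statistic is the conditional probability of
  the genotype table given the allele counts,
  Pr = N!/(∏ n_ij!)·2^h·(∏ n_i!)/(2N)!. Tables are sampled by random
  re-pairing of the observed gene copies (vectorised over replicates);
  p = (1 + #{Pr_rep ≤ Pr_obs})/(1 + n_reps), observed table included on
  both sides. Default 10⁵ replicates. Probability ties are compared
  with a 1e-9 relative tolerance in log space.
- **Ewens–Watterson–Slatkin test.** F_obs = Σp². Conditional on
  (n = 2N, k), configuration probabilities are θ-free ESF weights
  normalised by the unsigned Stirling number |s(n,k)|; the exact p sums
  weights of configurations no more probable than observed. All
  partitions of n into k parts are enumerated for n ≤ 40 (the partition
  count is still small there); above that, configurations are sampled
  from the conditional distribution by running the Ewens urn at θ
  solved so E[k] matches (bisection) and rejecting draws with the wrong
  k. The switch point trades exactness against partition-count growth.
- **F_ST.** Weir–Cockerham variance components a, b, c per allele,
  θ = Σa/Σ(a+b+c), global and pairwise (r = 2); negative estimates are
  reported as computed. p-values permute individuals among breeds
  (default 10⁴ permutations).

Calibration measured by the test suite: the exact HWE test rejects
3–5% of true-HWE cohorts at α = 0.05 (slightly conservative, as
discrete exact tests are); θ̂ recovers a Balding–Nichols island model
with F = 0.05 to within ±0.01. The island simulation uses 20 demes of
2000 diploids and 46 alleles with Dirichlet(p·(1−F)/F) deme
frequencies — many demes and alleles are needed because the estimator's
replicate-to-replicate spread is dominated by the evolutionary variance
of the realised deme frequencies, not by sampling noise; with 6 demes
and 20 alleles the spread is ±0.013 and no estimator could pass a
±0.01 recovery band.

## Distances, trees, ordination

- D_s = −ln(J_xy/√(J_x J_y)) (+∞ with a warning when no alleles are
  shared) and D_A = 1 − Σ√(x_i y_i) in the single-locus form.
- UPGMA heights are half the between-cluster distance; tie-breaks join
  the pair whose representative labels sort first, making merge order
  deterministic. Infinite D_s entries abort tree building with an
  instruction to use D_A (the distance the published trees use).
- NJ follows Saitou–Nei Q-minimisation with lexicographic tie-breaks;
  negative branch lengths are clamped to zero with the deficit moved to
  the sister branch (Kuhner–Felsenstein), and the tree is returned
  unrooted (trifurcating root).
- Bootstrap support resamples **individuals within breeds** (the data
  are single-locus, so locus resampling is unavailable); support is the
  percentage of replicates containing each original bipartition.
  Allele trees bootstrap alignment columns instead.
- PCA decomposes the covariance matrix of raw frequencies by default
  (the convention of the desktop package the study used); a correlation
  variant is a flag. Components are sign-fixed so the largest-magnitude
  loading is positive. The constant-matrix edge case returns an empty
  result with a warning.

## Sequence-level diversity

- NPD = (n/(n−1))·ΣᵢΣⱼ pᵢpⱼdᵢⱼ over allele pairs (frequency-weighted,
  small-sample corrected — the convention of the population-genetics
  package the study used for these quantities); π = NPD/L. An
  unweighted distinct-allele average is available by flag because the
  exact option used for the published table is not recorded.
- Modified Nei–Gojobori: synonymous site counts weight transitions R
  (default 2.0, configurable; the source does not print its value) and
  transversions 1; differences average syn/nonsyn steps over all
  orderings of the differing codon positions, excluding pathways
  through stop codons; proportions are Jukes–Cantor corrected,
  d = −(3/4)ln(1 − 4p/3), undefined (NaN, flagged) at p ≥ 3/4. Changes
  *to* stop codons count as nonsynonymous in site counting. Breed
  averages are unweighted over distinct allele pairs (frequency
  weighting by flag); both d_s − d_n and d_n/d_s are reported, labelled
  unambiguously. Variances/z-tests of d_n − d_s are not computed.
- The ABS restriction uses a shipped pocket table (P1: 85, 86, 89, 90;
  P4: 13, 26, 70, 71, 74, 78; P6: 11, 30; P7: 28, 47, 61, 67, 71;
  P9: 9, 37, 57, 61 in mature β-chain numbering, following the standard
  DRB pocket assignments), mapped onto the amplicon by `mature_start`
  (default 6: the first complete codon of the exon encodes mature
  residue 6). Both the table and the offset are configurable; analyses
  degrade gracefully (ABS columns omitted with a warning) when pockets
  fall outside a shorter amplicon.

## Bundled dataset

`ovarpop.datasets` carries the published six-breed × 46-allele
frequency table (percent, two decimals) and the breed sample sizes
(N = 37, 44, 23, 72, 45, 38). Loading renormalises each row of the
proportion-scale matrix to sum to one; the raw percent table is also
available and is what the ordination reproduction uses, since the
published PCA ran on the printed values. Allele-sharing summaries
reproduce the published Venn counts on the five-breed subset that
excludes the Buze'e crossbreed (12 breed-unique alleles, 10 present in
all five); over all six breeds the counts are 11 and 8.

## Problem sizes used by the tests

Simulation-backed tests run at sizes chosen to make their tolerance
bands meaningful at interactive cost: typing recovery uses 100 samples
at depth 30; parameter-recovery tests use 5000-individual cohorts;
the island model uses 20 × 2000 diploids; HWE calibration uses 1000
cohorts of 50 with 2000 Monte-Carlo replicates per test (the p-value
noise this adds at the rejection boundary is small relative to the
±0.02 band); Slatkin Monte-Carlo agreement uses 10⁵ conditional draws.

## Known limitations

- Single locus only: no multi-locus containers, linkage statistics or
  locus-bootstrap.
- No chimera simulation or chimera-aware rescue; ambiguous samples
  fail.
- Exact-match assignment means a database with truncated or
  differently-trimmed alleles will misclassify everything as novel;
  inputs must share one trimming convention.
- The Slatkin Monte-Carlo sampler rejection-samples on k; for extreme
  configurations (k near 1 or near n) acceptance degrades and the
  sampler guards with a bounded draw budget.
- dN/dS standard errors are not computed.
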