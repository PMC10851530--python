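"""Haplotyping: merging, tallying, calling, assignment, novel registration."""

import numpy as np
import pytest

from ovarpop import (BreedSpec, TypingParams, call_genotype,
                     generate_allele_library, merge_read_pair,
                     register_novel_alleles, sample_population_genotypes,
                     simulate_amplicon_reads, tally_haplotypes, type_cohort)
from ovarpop.alleles import AlleleDatabase, AlleleSequence, reverse_complement
from ovarpop.typing import (HaplotypeCall, MergedRead, NovelCandidate,
                            assign_alleles, collapse_errors)


def _q(ch, n):
    return ch * n


class TestMergeReadPair:
    def test_error_free_pair_reconstructs_amplicon(self, library46):
        amplicon = library46.get(library46.names[0]).seq
        fwd = amplicon[:200]
        rev = reverse_complement(amplicon[-200:])
        m = merge_read_pair(fwd, rev, _q("I", 200), _q("I", 200))
        assert m is not None
        assert m.seq == amplicon
        assert m.n_conflicts == 0

    @staticmethod
    def _random_amplicon(length=80, seed=13):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=length))

    def test_conflict_resolved_by_quality(self):
        amplicon = self._random_amplicon()
        fwd = amplicon[:60]
        true_suffix = amplicon[-60:]
        # corrupt one overlap base on the reverse read
        pos = 30  # within the overlap in suffix coordinates
        corrupted = (true_suffix[:pos]
                     + ("A" if true_suffix[pos] != "A" else "C")
                     + true_suffix[pos + 1:])
        rev = reverse_complement(corrupted)
        # forward Q40 ('I') vs reverse Q10 ('+') -> forward base wins
        m = merge_read_pair(fwd, rev, _q("I", 60), _q("+", 60))
        assert m.seq == amplicon
        assert m.n_conflicts == 1
        # reversed qualities -> the corrupted reverse base wins
        m2 = merge_read_pair(fwd, rev, _q("+", 60), _q("I", 60))
        assert m2.seq != amplicon
        assert m2.n_conflicts == 1

    def test_equal_quality_tie_keeps_forward(self):
        amplicon = self._random_amplicon()
        fwd = amplicon[:60]
        suffix = amplicon[-60:]
        # corrupt a reverse base inside the overlap; the tie rule keeps
        # the forward base, so the merge restores the amplicon
        pos = 25
        corrupted = (suffix[:pos]
                     + ("T" if suffix[pos] != "T" else "G")
                     + suffix[pos + 1:])
        rev = reverse_complement(corrupted)
        m = merge_read_pair(fwd, rev, _q("I", 60), _q("I", 60))
        assert m.seq == amplicon

    def test_chimeric_pair_rejected(self):
        db = generate_allele_library(2, 270, min_pairwise_diff=60, seed=2)
        a, b = [al.seq for al in db]
        fwd = a[:200]
        rev = reverse_complement(b[-200:])
        m = merge_read_pair(fwd, rev, max_mismatch_frac=0.1)
        # either no admissible overlap, or a misassembled non-amplicon length
        assert m is None or len(m.seq) != 270

    def test_empty_read_raises(self):
        with pytest.raises(ValueError):
            merge_read_pair("", "ACGT")


class TestTallyAndCall:
    def test_tally_groups_and_sorts(self):
        merged = [MergedRead("AAA"), MergedRead("AAA"), MergedRead("CCC")]
        assert tally_haplotypes(merged) == [("AAA", 2), ("CCC", 1)]

    def test_tally_tie_breaks_lexicographically(self):
        merged = [MergedRead("TTT"), MergedRead("AAA")]
        assert tally_haplotypes(merged) == [("AAA", 1), ("TTT", 1)]

    def test_tally_empty(self):
        assert tally_haplotypes([]) == []

    def test_tally_length_mismatch(self):
        with pytest.raises(ValueError):
            tally_haplotypes([MergedRead("AA"), MergedRead("AAA")])

    def test_balanced_pair_called_heterozygous(self):
        call = call_genotype([("A" * 9, 15), ("C" * 9, 14)], min_depth=10,
                             balance_threshold=0.25, noise_frac=0.1)
        assert call.status == "heterozygous"
        assert [c for _, c in call.haplotypes] == [15, 14]

    def test_minor_noise_sequence_discarded(self):
        call = call_genotype([("A" * 9, 29), ("C" * 9, 1)], min_depth=10,
                             balance_threshold=0.25, noise_frac=0.1)
        assert call.status == "homozygous"
        assert call.haplotypes == [("A" * 9, 29)]

    def test_low_depth_fails(self):
        call = call_genotype([("A" * 9, 4)], min_depth=5)
        assert call.status == "failed"
        assert call.haplotypes == []

    def test_three_surviving_sequences_ambiguous(self):
        call = call_genotype([("A" * 9, 10), ("C" * 9, 9), ("G" * 9, 8)],
                             min_depth=10, noise_frac=0.1)
        assert call.status == "failed"

    def test_collapse_absorbs_satellites_keeps_balanced(self):
        top = "A" * 30
        sat = "A" * 15 + "C" + "A" * 14  # 1 substitution, rare
        other = "G" * 30
        tally = [(top, 14), (other, 13), (sat, 2)]
        out = collapse_errors(tally, max_dist=2, min_fold=5)
        assert dict(out)[top] == 16
        assert dict(out)[other] == 13
        # balanced haplotypes never absorb each other
        assert len(out) == 2


class TestAssignment:
    def _db(self):
        db = AlleleDatabase()
        db.add(AlleleSequence("Ovar-DRB1*10:01", "ACGGCT" * 5))
        db.add(AlleleSequence("Ovar-DRB1*04:02", "ACGGCA" * 5))
        return db

    def test_exact_match_assigns_name(self):
        db = self._db()
        call = HaplotypeCall("s", [("ACGGCT" * 5, 20)], "homozygous", 20)
        names, novel = assign_alleles(call, db)
        assert names == ["Ovar-DRB1*10:01"] * 2
        assert novel == []

    def test_single_substitution_is_novel_not_fuzzy(self):
        db = self._db()
        seq = "T" + ("ACGGCT" * 5)[1:]
        call = HaplotypeCall("s", [(seq, 20)], "homozygous", 20)
        names, novel = assign_alleles(call, db)
        assert len(novel) == 1 and novel[0].seq == seq

    def test_mixed_known_and_novel_heterozygote(self):
        db = self._db()
        known = "ACGGCT" * 5
        seq = "T" + known[1:]
        call = HaplotypeCall("s", [(known, 12), (seq, 11)],
                             "heterozygous", 23)
        names, novel = assign_alleles(call, db)
        assert "Ovar-DRB1*10:01" in names
        assert len(novel) == 1

    def test_failed_call_rejected(self):
        with pytest.raises(ValueError):
            assign_alleles(HaplotypeCall("s", [], "failed", 0), self._db())

    def test_length_mismatch_rejected(self):
        call = HaplotypeCall("s", [("ACGT", 20)], "homozygous", 20)
        with pytest.raises(ValueError):
            assign_alleles(call, self._db())


class TestNovelRegistration:
    def test_supported_candidate_registered_deterministically(self):
        db = AlleleDatabase([AlleleSequence("K*01", "AAACCC")])
        cand = [NovelCandidate("AAACCG", f"s{i}", 12) for i in range(4)]
        ext, report = register_novel_alleles(cand, db, 5, 1, prefix="K*New")
        assert ext.novel_names() == ["K*New1"]
        assert report["accepted"].sum() == 1

    def test_unsupported_candidate_rejected(self):
        db = AlleleDatabase([AlleleSequence("K*01", "AAACCC")])
        ext, report = register_novel_alleles(
            [NovelCandidate("AAACCG", "s1", 2)], db, 5, 1, prefix="K*New")
        assert ext.novel_names() == []
        assert not report["accepted"].any()

    def test_ordering_by_support_then_sequence(self):
        db = AlleleDatabase([AlleleSequence("K*01", "AAACCC")])
        cand = [
            NovelCandidate("TTTCCC", "s1", 8),
            NovelCandidate("GGGCCC", "s2", 20),
        ]
        ext, _ = register_novel_alleles(cand, db, 5, 1, prefix="K*New")
        assert ext.get("K*New1").seq == "GGGCCC"
        assert ext.get("K*New2").seq == "TTTCCC"

    def test_name_collision_raises(self):
        db = AlleleDatabase([AlleleSequence("K*New1", "AAACCC")])
        with pytest.raises(ValueError):
            register_novel_alleles(
                [NovelCandidate("AAACCG", "s1", 9)], db, 5, 1,
                prefix="K*New")


@pytest.fixture(scope="module")
def cohort(library46):
    known = library46.subset(library46.names[:42])
    freqs = {n: 1 / 46 for n in library46.names}
    truth = sample_population_genotypes(
        library46, [BreedSpec("C", 60, freqs)], seed=21)
    reads = simulate_amplicon_reads(
        truth, library46, depth_mean=30, depth_sd=0,
        error_rate=0.002, seed=22)
    return library46, known, truth, reads


class TestTypeCohort:
    def test_recovery_and_novel_discovery(self, cohort):
        full, known, truth, reads = cohort
        gt, qc, ext, novel = type_cohort(reads, known)
        assert len(gt) == len(truth)
        # every injected database-absent allele that was actually sampled
        sampled = set(truth.df["allele1"]) | set(truth.df["allele2"])
        injected = sampled - set(known.names)
        assert len(ext.novel_names()) == len(injected)
        # genotype concordance at sequence level
        seq_of = {a.name: a.seq for a in full}
        ext_seq = {a.name: a.seq for a in ext}
        t = {r.sample: frozenset((seq_of[r.allele1], seq_of[r.allele2]))
             for r in truth.df.itertuples()}
        ok = sum(
            frozenset((ext_seq[r.allele1], ext_seq[r.allele2]))
            == t[r.sample]
            for r in gt.df.itertuples()
        )
        assert ok / len(gt) >= 0.99

    def test_every_output_allele_in_extended_database(self, cohort):
        _, known, _, reads = cohort
        gt, _, ext, _ = type_cohort(reads, known)
        for col in ("allele1", "allele2"):
            assert all(name in ext for name in gt.df[col])

    def test_min_depth_monotonicity(self, cohort):
        _, known, _, reads = cohort
        prev_failed = -1
        for min_depth in (5, 15, 25, 31):
            params = TypingParams(min_depth=min_depth)
            _, qc, _, _ = type_cohort(reads, known, params)
            failed = int(qc["status"].str.startswith("failed").sum())
            assert failed >= prev_failed
            prev_failed = failed

    def test_impossible_depth_fails_everything(self, cohort):
        _, known, _, reads = cohort
        params = TypingParams(min_depth=10_000)
        gt, qc, _, _ = type_cohort(reads, known, params)
        assert len(gt) == 0
        assert (qc["status"] == "failed").all()

    def test_rerun_identical(self, cohort):
        _, known, _, reads = cohort
        a = type_cohort(reads, known)
        b = type_cohort(reads, known)
        assert a[0].df.equals(b[0].df)
        assert a[1].equals(b[1])

    def test_empty_cohort_raises(self, library46):
        with pytest.raises(ValueError):
            type_cohort([], library46)


def test_frequency_recovery_end_to_end(library46):
    """Cohort allele frequencies from typing match the simulated truth."""
    freqs = {n: 1 / 46 for n in library46.names}
    truth = sample_population_genotypes(
        library46, [BreedSpec("C", 80, freqs)], seed=31)
    reads = simulate_amplicon_reads(
        truth, library46, depth_mean=30, depth_sd=5,
        error_rate=0.002, seed=32)
    gt, _, ext, _ = type_cohort(reads, library46)
    from ovarpop import allele_frequencies

    est = allele_frequencies(gt)
    tru = allele_frequencies(truth)
    two_n = 2 * len(truth)
    for allele in tru.df.columns:
        p = tru.df.loc["C", allele]
        se = max(np.sqrt(p * (1 - p) / two_n), 1 / two_n)
        q = est.df.loc["C", allele] if allele in est.df.columns else 0.0
        assert abs(q - p) <= 3 * se
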