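"""Diversity statistics, exact tests and F-statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (esf_config_probability, hwe_exact_2allele,
                      stirling_unsigned)
from ovarpop import (BreedSpec, GenotypeTable, ewens_watterson_slatkin, fis,
                     fst_weir_cockerham, hwe_exact_test,
                     observed_heterozygosity, sample_population_genotypes,
                     unbiased_expected_heterozygosity)
from ovarpop.popgen import (_partitions_into_k, diversity_report,
                            heterozygosity_from_frequencies, watterson_f)


class TestHeterozygosity:
    def test_observed_extremes_and_half(self):
        gt = GenotypeTable.from_records(
            [("a", "X", "A", "B"), ("b", "X", "A", "A")])
        assert observed_heterozygosity(gt, "X") == 0.5
        gt2 = GenotypeTable.from_records([("a", "X", "A", "A")])
        assert observed_heterozygosity(gt2, "X") == 0.0

    def test_unbiased_expected_closed_form(self):
        assert unbiased_expected_heterozygosity([1.0], 5) == 0.0
        he = unbiased_expected_heterozygosity([0.5, 0.5], 10)
        assert he == pytest.approx(20 / 19 * 0.5)

    def test_published_breed_values_to_2dp(self, sds_fm):
        """The transcribed frequency table reproduces the printed h_E."""
        expected = {"AB": 0.94, "B": 0.95}
        for breed, val in expected.items():
            p = sds_fm.frequencies(breed)
            p = p[p > 0]
            he = unbiased_expected_heterozygosity(
                p.values, sds_fm.n_samples[breed])
            assert round(he, 2) == val

    def test_relabelling_invariance(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        a = unbiased_expected_heterozygosity(p, 20)
        b = unbiased_expected_heterozygosity(p[::-1], 20)
        assert a == pytest.approx(b)

    @given(st.lists(st.integers(1, 40), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_bounds_property(self, counts):
        """h_E stays in [0, 1] for any real count configuration."""
        counts = np.array(counts)
        if counts.sum() % 2:
            counts[0] += 1
        n = counts.sum() // 2
        p = counts / counts.sum()
        he = unbiased_expected_heterozygosity(p, n)
        assert 0.0 <= he <= 1.0 + 1e-12

    def test_frequency_only_report(self, sds_fm):
        rep = heterozygosity_from_frequencies(sds_fm)
        by_breed = rep.set_index("breed")
        assert by_breed.loc["H", "n_a"] == 33
        assert by_breed.loc["B", "n_a"] == 17
        assert round(by_breed.loc["AB", "h_E"], 2) == 0.94


class TestFis:
    def test_all_heterozygous_negative(self):
        gt = GenotypeTable.from_records(
            [(f"s{i}", "X", "A", "B") for i in range(10)])
        assert fis(gt, "X") < 0

    def test_hwe_cohort_near_zero(self, hwe_cohort):
        f = fis(hwe_cohort, "HW")
        assert abs(f) < 0.1

    def test_inbreeding_parameter_recovery(self, small_library):
        freqs = dict(zip(small_library.names,
                         [0.3, 0.25, 0.2, 0.1, 0.1, 0.05]))
        gt = sample_population_genotypes(
            small_library,
            [BreedSpec("P", 5000, freqs, inbreeding_f=0.5)], seed=9)
        assert fis(gt, "P") == pytest.approx(0.5, abs=0.05)

    def test_monomorphic_is_missing(self):
        gt = GenotypeTable.from_records(
            [("a", "X", "A", "A"), ("b", "X", "A", "A")])
        assert np.isnan(fis(gt, "X"))


class TestHweExactTest:
    def test_two_homozygotes_enumeration_value(self):
        # allele counts (2, 2): Pr(AA+BB) = 1/3, Pr(two AB) = 2/3
        gt = GenotypeTable.from_records(
            [("a", "X", "A", "A"), ("b", "X", "B", "B")])
        p = hwe_exact_test(gt, "X", n_reps=50_000, seed=1)
        assert p == pytest.approx(1 / 3, abs=0.02)

    def test_modal_table_p_is_one(self):
        # two heterozygotes is the modal table for counts (2, 2)
        gt = GenotypeTable.from_records(
            [("a", "X", "A", "B"), ("b", "X", "A", "B")])
        p = hwe_exact_test(gt, "X", n_reps=50_000, seed=1)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_matches_enumeration_on_all_small_tables(self):
        """Monte-Carlo p equals the exact enumeration for 2N <= 12."""
        for two_n in range(4, 13, 2):
            for n1 in range(2, two_n - 1):
                n2 = two_n - n1
                if n2 < 2 or n1 < n2:
                    continue
                for n12 in range(n1 % 2, min(n1, n2) + 1, 2):
                    exact = hwe_exact_2allele(n1, n2, n12)
                    n11 = (n1 - n12) // 2
                    n22 = (n2 - n12) // 2
                    recs = (
                        [(f"h{i}", "X", "A", "B") for i in range(n12)]
                        + [(f"a{i}", "X", "A", "A") for i in range(n11)]
                        + [(f"b{i}", "X", "B", "B") for i in range(n22)]
                    )
                    gt = GenotypeTable.from_records(recs)
                    p = hwe_exact_test(gt, "X", n_reps=20_000,
                                       seed=n1 * 100 + n12)
                    assert p == pytest.approx(exact, abs=0.02), (
                        n1, n2, n12)

    def test_monomorphic_returns_one(self):
        gt = GenotypeTable.from_records([("a", "X", "A", "A")] )
        assert hwe_exact_test(gt, "X", n_reps=1000, seed=1) == 1.0

    def test_reproducible(self, hwe_cohort):
        p1 = hwe_exact_test(hwe_cohort, "HW", n_reps=5000, seed=5)
        p2 = hwe_exact_test(hwe_cohort, "HW", n_reps=5000, seed=5)
        assert p1 == p2


class TestEwensWattersonSlatkin:
    def test_hand_enumeration_n4_k2(self):
        # partitions of 4 into 2: (3,1) w=8, (2,2) w=3; |s(4,2)| = 11
        f, p = ewens_watterson_slatkin([2, 2], mode="enumerate")
        assert f == pytest.approx(0.5)
        assert p == pytest.approx(3 / 11)
        _, p31 = ewens_watterson_slatkin([3, 1], mode="enumerate")
        assert p31 == pytest.approx(1.0)

    def test_least_probable_partition_p_equals_own_probability(self):
        # for n=10, k=2 the rarest configuration is the most even one
        parts = list(_partitions_into_k(10, 2))
        probs = {p: esf_config_probability(p) for p in parts}
        rarest = min(probs, key=probs.get)
        _, p = ewens_watterson_slatkin(rarest, mode="enumerate")
        assert p == pytest.approx(probs[rarest])

    def test_partition_weights_sum_to_stirling(self):
        for n, k in [(6, 2), (8, 3), (10, 4), (12, 5)]:
            total = sum(
                esf_config_probability(p) for p in _partitions_into_k(n, k)
            )
            assert total == pytest.approx(1.0)
            # and the raw weights reproduce the Stirling normaliser
            from math import factorial

            w = 0
            for part in _partitions_into_k(n, k):
                mult = {}
                for x in part:
                    mult[x] = mult.get(x, 0) + 1
                term = factorial(n)
                for j, a in mult.items():
                    term //= j ** a * factorial(a)
                w += term
            assert w == stirling_unsigned(n, k)

    def test_montecarlo_agrees_with_enumeration(self):
        cfg = (8, 5, 4, 2, 1)
        _, pe = ewens_watterson_slatkin(cfg, mode="enumerate")
        _, pm = ewens_watterson_slatkin(cfg, mode="montecarlo",
                                        n_reps=20_000, seed=5)
        assert pm == pytest.approx(pe, abs=0.02)

    def test_pvalues_super_uniform_under_null(self):
        """Conditional-ESF draws give p-values stochastically >= uniform."""
        from ovarpop.popgen import _sample_esf_partition, _solve_theta_for_k

        rng = np.random.default_rng(17)
        n, k = 12, 3
        theta = _solve_theta_for_k(n, k)
        ps = []
        while len(ps) < 300:
            part = _sample_esf_partition(rng, theta, n)
            if len(part) != k:
                continue
            _, p = ewens_watterson_slatkin(part, mode="enumerate")
            ps.append(p)
        ps = np.sort(ps)
        # ECDF(t) <= t + allowance for the test's discreteness + noise
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.searchsorted(ps, grid, side="right") / len(ps)
        assert (ecdf <= grid + 0.10).all()

    def test_monomorphic_warns(self):
        with pytest.warns(UserWarning):
            f, p = ewens_watterson_slatkin([10])
        assert p == 1.0


class TestFst:
    def test_fixed_differences_theta_one(self):
        gt = GenotypeTable.from_records(
            [(f"a{i}", "P1", "A", "A") for i in range(5)]
            + [(f"b{i}", "P2", "B", "B") for i in range(5)])
        rep = fst_weir_cockerham(gt, n_perms=100, seed=1)
        assert rep.theta_global == pytest.approx(1.0)

    def test_duplicated_breed_theta_near_zero(self, hwe_cohort):
        df = hwe_cohort.df.copy()
        half = len(df) // 2
        df.loc[df.index[:half], "breed"] = "HW2"
        df["sample"] = [f"s{i}" for i in range(len(df))]
        gt = GenotypeTable(df)
        rep = fst_weir_cockerham(gt, n_perms=200, seed=2)
        assert abs(rep.theta_global) < 0.02
        assert rep.p_global > 0.05

    def test_pairwise_matrix_symmetric_zero_diagonal(self, small_library):
        freqs1 = dict(zip(small_library.names,
                          [0.5, 0.2, 0.1, 0.1, 0.05, 0.05]))
        freqs2 = dict(zip(small_library.names,
                          [0.1, 0.1, 0.3, 0.3, 0.1, 0.1]))
        gt = sample_population_genotypes(
            small_library,
            [BreedSpec("P1", 40, freqs1), BreedSpec("P2", 40, freqs2),
             BreedSpec("P3", 40, freqs1)],
            seed=3)
        rep = fst_weir_cockerham(gt, n_perms=100, seed=4)
        m = rep.pairwise
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert (m.values <= 1.0 + 1e-12).all()

    def test_invariance_under_relabelling(self, small_library):
        freqs1 = dict(zip(small_library.names,
                          [0.5, 0.2, 0.1, 0.1, 0.05, 0.05]))
        freqs2 = dict(zip(small_library.names,
                          [0.1, 0.1, 0.3, 0.3, 0.1, 0.1]))
        gt = sample_population_genotypes(
            small_library,
            [BreedSpec("P1", 30, freqs1), BreedSpec("P2", 30, freqs2)],
            seed=5)
        theta = fst_weir_cockerham(gt, n_perms=100, seed=6).theta_global
        relabel = {n: f"Z{i}" for i, n in enumerate(small_library.names)}
        df = gt.df.copy()
        df["allele1"] = df["allele1"].map(relabel)
        df["allele2"] = df["allele2"].map(relabel)
        theta2 = fst_weir_cockerham(
            GenotypeTable(df), n_perms=100, seed=6).theta_global
        assert theta == pytest.approx(theta2)

    def test_single_sample_breed_excluded(self):
        gt = GenotypeTable.from_records(
            [(f"a{i}", "P1", "A", "B") for i in range(4)]
            + [(f"b{i}", "P2", "A", "A") for i in range(4)]
            + [("c0", "P3", "B", "B")])
        with pytest.warns(UserWarning):
            rep = fst_weir_cockerham(gt, n_perms=100, seed=1)
        assert list(rep.pairwise.index) == ["P1", "P2"]


def test_diversity_report_columns_and_ranges(hwe_cohort):
    rep = diversity_report(hwe_cohort, n_reps_hwe=2000,
                           n_reps_slatkin=2000, seed=3)
    row = rep.iloc[0]
    assert row["N"] == 200
    assert 0 <= row["h_O"] <= 1
    assert 0 <= row["h_E"] <= 1
    assert 0 <= row["p_HWE"] <= 1
    assert 0 <= row["p_slatkin"] <= 1
    # F_obs recomputed independently from the frequency matrix
    from ovarpop import allele_frequencies

    p = allele_frequencies(hwe_cohort).frequencies("HW")
    assert row["F_watterson"] == pytest.approx(float((p ** 2).sum()))
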