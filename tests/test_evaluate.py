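import math

import numpy as np
import pytest

from iglocus.evaluate import (accessibility_partition, assembly_concordance,
                              assembly_identity_vs_truth, compare_callsets,
                              derive_truth_from_haplotype_alignment,
                              hwe_chi2_test, hwe_exact_test,
                              imputation_comparison, mendelian_check,
                              switch_error_count, truth_phase_map)

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestCompareCallsets:
    def _set(self, n, gt="0/1"):
        return [(i * 10, "A", "C", gt) for i in range(n)]

    def test_identical_sets(self):
        rep = compare_callsets(self._set(100), self._set(100))
        assert (rep.true_positives, rep.false_positives,
                rep.false_negatives) == (100, 0, 0)
        assert rep.recall == 1.0 and rep.precision == 1.0

    def test_genotype_discordance_is_not_tp(self):
        q = [(50, "A", "C", "1/1")]
        t = [(50, "A", "C", "0/1")]
        rep = compare_callsets(q, t)
        assert rep.true_positives == 0
        assert rep.genotype_discordant == 1
        assert rep.false_positives == 1 and rep.false_negatives == 1

    def test_disjoint_sets(self):
        q = [(i, "A", "C", "0/1") for i in range(10)]
        t = [(1000 + i, "A", "C", "0/1") for i in range(10)]
        rep = compare_callsets(q, t)
        assert (rep.false_positives, rep.false_negatives) == (10, 10)

    def test_phased_and_unphased_genotypes_agree(self):
        rep = compare_callsets([(5, "A", "C", "1|0")],
                               [(5, "A", "C", "0/1")])
        assert rep.true_positives == 1

    def test_haploid_call_matches_het_truth(self):
        rep = compare_callsets([(5, "A", "C", "1")],
                               [(5, "A", "C", "0|1")])
        assert rep.true_positives == 1

    def test_unmappable_bucket_not_fp(self):
        q = [(5, "A", "C", "0/1"), (500, "A", "C", "0/1")]
        t = [(5, "A", "C", "0/1")]
        rep = compare_callsets(q, t,
                               liftover=lambda p: None if p > 100 else p)
        assert rep.false_positives == 0
        assert rep.unmappable == 1
        assert rep.true_positives == 1

    def test_conservation_tp_plus_fn_is_truth_size(self):
        rng = np.random.default_rng(91)
        truth = [(int(p), "A", "C", "0/1")
                 for p in rng.choice(10_000, 200, replace=False)]
        query = truth[:150] + [(20_000 + i, "A", "C", "0/1")
                               for i in range(30)]
        rep = compare_callsets(query, truth)
        assert rep.true_positives + rep.false_negatives == len(truth)


class TestDeriveTruthFromHaplotypeAlignment:
    def test_identical_sequences_empty(self):
        rng = np.random.default_rng(92)
        s = rand_seq(rng, 3_000)
        assert derive_truth_from_haplotype_alignment(s, s) == []

    def test_planted_substitutions_recovered(self):
        rng = np.random.default_rng(93)
        a = rand_seq(rng, 3_000)
        b = list(a)
        planted = {}
        for p in (500, 1500, 2500):
            b[p] = "A" if a[p] != "A" else "T"
            planted[p] = b[p]
        # positions are on the first sequence; second/first bases reported
        snvs = derive_truth_from_haplotype_alignment("".join(b), a)
        assert {(p, rb) for p, rb, ab in snvs} == set(planted.items())
        assert {(p, ab) for p, rb, ab in snvs} == \
            {(p, a[p]) for p in planted}

    def test_agrees_with_simulator_truth(self, small_ref):
        from iglocus.synthetic import DiploidConfig, simulate_diploid
        for seed in range(5):
            cfg = DiploidConfig(n_snv=15, het_fraction=1.0, n_indel=0,
                                sv_spec=(), n_known_nonref_alleles=0,
                                n_novel_alleles=0)
            truth = simulate_diploid(small_ref, cfg, seed=300 + seed)
            snvs = derive_truth_from_haplotype_alignment(
                truth.hap2, truth.hap1)
            got = {(p, rb) for p, rb, ab in snvs}
            assert got == {(v.start,
                            v.alt_allele if v.on_hap2 else v.ref_allele)
                           for v in truth.variants if v.is_het()}


class TestMendelianCheck:
    def test_consistent_trio_site(self):
        assert mendelian_check({5: "0/1"}, {5: "0/0"}, {5: "1/1"}) == []

    def test_violating_site(self):
        assert mendelian_check({5: "1/1"}, {5: "0/0"}, {5: "0/1"}) == [5]

    def test_transmitted_haplotype_trio_has_zero_violations(self):
        rng = np.random.default_rng(94)
        n = 300
        mother = {i: f"{rng.integers(2)}/{rng.integers(2)}"
                  for i in range(n)}
        father = {i: f"{rng.integers(2)}/{rng.integers(2)}"
                  for i in range(n)}
        child = {}
        for i in range(n):
            m = rng.choice(mother[i].split("/"))
            f = rng.choice(father[i].split("/"))
            child[i] = f"{m}/{f}"
        assert mendelian_check(child, mother, father) == []

    def test_planted_violations_all_detected(self):
        mother = {i: "0/0" for i in range(50)}
        father = {i: "0/0" for i in range(50)}
        child = {i: "0/0" for i in range(50)}
        for i in (3, 17, 42):
            child[i] = "0/1"
        assert mendelian_check(child, mother, father) == [3, 17, 42]


class TestSwitchErrors:
    def test_perfect_phasing_zero(self):
        inferred = [(i * 10, 1 if i % 2 else 2) for i in range(20)]
        truth = {p: h for p, h in inferred}
        assert switch_error_count(inferred, truth) == 0

    def test_global_flip_zero(self):
        inferred = [(i * 10, 1) for i in range(20)]
        truth = {p: 2 for p, _ in inferred}
        assert switch_error_count(inferred, truth) == 0

    def test_single_internal_flip_is_one_switch(self):
        inferred = [(i * 10, 1) for i in range(20)]
        truth = {p: (1 if p < 100 else 2) for p, _ in inferred}
        assert switch_error_count(inferred, truth) == 1

    def test_random_phasing_mean_matches_closed_form(self):
        rng = np.random.default_rng(95)
        n = 40
        trials = 1_000
        counts = []
        truth = {i: 1 for i in range(n)}
        for _ in range(trials):
            inferred = [(i, int(rng.integers(1, 3))) for i in range(n)]
            counts.append(switch_error_count(inferred, truth))
        mean = np.mean(counts)
        expect = (n - 1) / 2
        se = np.std(counts) / math.sqrt(trials)
        assert abs(mean - expect) <= 3 * se


class TestAssemblyConcordance:
    def test_identical_sequences(self):
        rng = np.random.default_rng(96)
        s = rand_seq(rng, 10_000)
        rep = assembly_concordance(s, s)
        assert rep["accuracy"] == 1.0
        assert rep["substitutions"] == 0 and rep["indels"] == []

    def test_homopolymer_insertion_classified(self):
        rng = np.random.default_rng(97)
        truth = rand_seq(rng, 500) + "AAAAA" + rand_seq(rng, 500)
        pos = truth.index("AAAAA")
        asm = truth[:pos + 2] + "AA" + truth[pos + 2:]
        rep = assembly_concordance(asm, truth)
        assert rep["indels"] == [(pos, 0, 2)] or \
            len(rep["indels"]) == 1
        assert rep["homopolymer_fraction"] == 1.0

    def test_three_planted_edits_counted(self):
        rng = np.random.default_rng(98)
        truth = rand_seq(rng, 1_000)
        # one substitution, one 2 bp deletion, one 3 bp insertion
        asm = list(truth)
        asm[100] = "A" if truth[100] != "A" else "C"
        asm = "".join(asm)
        asm = asm[:400] + asm[402:]
        asm = asm[:700] + "GGG" + asm[700:]
        rep = assembly_concordance(asm, truth)
        assert rep["substitutions"] == 1
        assert sorted((r, a) for _, r, a in rep["indels"]) == \
            [(0, 3), (2, 0)]

    def test_agrees_with_edit_composition_identity(self, small_result,
                                                   small_truth):
        ident = assembly_identity_vs_truth(small_result.contigs,
                                           small_truth)
        assert ident == 1.0


class TestHweExact:
    @staticmethod
    def oracle(n_aa, n_ab, n_bb):
        """Full enumeration from log-factorials (independent route)."""
        import math as m
        n = n_aa + n_ab + n_bb
        rare = 2 * min(n_aa, n_bb) + n_ab
        if rare == 0 or rare == 2 * n:
            return 1.0

        def log_prob(h):
            nr = (rare - h) // 2
            nc = n - nr - h
            return (m.lgamma(n + 1) - m.lgamma(nr + 1) - m.lgamma(nc + 1)
                    - m.lgamma(h + 1) + h * m.log(2)
                    + m.lgamma(rare + 1) + m.lgamma(2 * n - rare + 1)
                    - m.lgamma(2 * n + 1))
        hs = [h for h in range(rare % 2, rare + 1, 2)
              if (rare - h) // 2 >= 0 and n - (rare - h) // 2 - h >= 0]
        probs = {h: m.exp(log_prob(h)) for h in hs}
        total = sum(probs.values())
        p_obs = probs[n_ab] / total
        return min(1.0, sum(v for v in probs.values()
                            if v / total <= p_obs * (1 + 1e-12)) / total)

    def test_perfect_proportions_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(120):
            n = int(rng.integers(1, 51))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            got = hwe_exact_test(n_aa, n_ab, n_bb)
            want = self.oracle(n_aa, n_ab, n_bb)
            assert got == pytest.approx(want, abs=1e-9), (n_aa, n_ab, n_bb)

    def test_monomorphic_site_p_one(self):
        assert hwe_exact_test(30, 0, 0) == 1.0

    def test_chi2_agreement_large_balanced_samples(self):
        # genotype counts at the Hardy-Weinberg expectation (n = 1000),
        # plus het-deficit perturbations; the discrete and asymptotic
        # tests agree closely in this regime
        n = 1_000
        for p10 in range(2, 9):
            p = p10 / 10
            n_aa = round(n * p * p)
            n_ab = round(n * 2 * p * (1 - p))
            n_bb = n - n_aa - n_ab
            for d in (0, 2, 4):
                # move d alleles from hets into homs (het deficit)
                counts = (n_aa + d - d // 2, n_ab - d, n_bb + d // 2)
                exact = hwe_exact_test(*counts)
                chi2 = hwe_chi2_test(*counts)
                assert abs(exact - chi2) < 0.02, (p, d)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestAccessibilityPartition:
    def test_all_inside_one_interval(self):
        inside, outside = accessibility_partition(range(10, 20),
                                                  [(0, 100)])
        assert (inside, outside) == (10, 0)

    def test_empty_mask(self):
        inside, outside = accessibility_partition([1, 2, 3], [])
        assert (inside, outside) == (0, 3)

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(101)
        cuts = np.sort(rng.choice(100_000, 40, replace=False))
        mask = [(int(cuts[i]), int(cuts[i + 1]))
                for i in range(0, 40, 4)]
        pos = rng.integers(0, 100_000, 10_000)
        inside, outside = accessibility_partition(pos.tolist(), mask)
        brute = sum(1 for p in pos
                    if any(s <= p < e for s, e in mask))
        assert inside == brute
        assert inside + outside == len(pos)


class TestImputationComparison:
    def test_snr_arithmetic(self):
        q = set(range(100))
        imputed = {0.9: set(range(10, 130))}
        out = imputation_comparison(q, imputed)
        assert out[0.9]["overlap"] == 90
        assert out[0.9]["imputed_only"] == 30
        assert out[0.9]["snr"] == pytest.approx(3.0)

    def test_zero_imputed_only_is_infinite(self):
        out = imputation_comparison({1, 2, 3}, {0.5: {1, 2}})
        assert out[0.5]["snr"] == math.inf

    def test_identical_sets(self):
        out = imputation_comparison({1, 2}, {0.1: {1, 2}})
        assert out[0.1]["query_only"] == 0
        assert out[0.1]["imputed_only"] == 0


def test_phase_switch_errors_zero_on_noiseless_run(small_result,
                                                   small_truth):
    truth = truth_phase_map(small_truth)
    for b in small_result.blocks:
        if len(b.phased_snvs) >= 2:
            inferred = [(s.position, s.phase) for s in b.phased_snvs]
            assert switch_error_count(inferred, truth) == 0
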