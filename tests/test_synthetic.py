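import numpy as np
import pytest

from iglocus.synthetic import (AlleleDatabase, DiploidConfig, ReadConfig,
                               SVSpec, apply_variants, collapse_subreads,
                               default_allele_database, homopolymer_mask,
                               make_locus, read_fastq, read_truth,
                               simulate_diploid, simulate_multiplex,
                               simulate_reads, write_fastq, write_truth)


@pytest.fixture(scope="module")
def tiny_ref():
    return make_locus(seed=21, length=60_000, n_v=4, n_d=2, n_j=2,
                      insertion_lengths=(3_000,))


class TestSimulateDiploid:
    def test_zero_variants_reproduces_reference(self, tiny_ref):
        cfg = DiploidConfig(n_snv=0, n_indel=0, sv_spec=(),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        truth = simulate_diploid(tiny_ref, cfg, seed=1)
        assert truth.hap1 == tiny_ref.sequence
        assert truth.hap2 == tiny_ref.sequence

    def test_single_het_snv_differs_at_one_position(self, tiny_ref):
        cfg = DiploidConfig(n_snv=1, het_fraction=1.0, n_indel=0,
                            sv_spec=(), n_known_nonref_alleles=0,
                            n_novel_alleles=0)
        truth = simulate_diploid(tiny_ref, cfg, seed=2)
        diffs = [i for i, (a, b) in enumerate(zip(truth.hap1, truth.hap2))
                 if a != b]
        assert len(diffs) == 1
        assert len(truth.hap1) == len(truth.hap2)

    def test_large_deletion_shortens_one_haplotype(self):
        # a sparser locus so a 25 kb deletion fits between genes
        ref = make_locus(seed=22, length=200_000, n_v=3, n_d=2, n_j=2,
                         insertion_lengths=())
        cfg = DiploidConfig(n_snv=0, n_indel=0,
                            sv_spec=(SVSpec("deletion", length=25_000,
                                            genotype="0|1"),),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        truth = simulate_diploid(ref, cfg, seed=3)
        assert len(truth.hap1) == len(ref.sequence)
        assert len(truth.hap2) == len(ref.sequence) - 25_000

    def test_reconstruction_from_variant_list(self, tiny_ref):
        # independent re-application of the phased edit list
        for seed in range(8):
            cfg = DiploidConfig(n_snv=20, n_indel=4,
                                sv_spec=(SVSpec("embedded_absence",
                                                sv_id="SV1",
                                                genotype="0|1"),),
                                n_known_nonref_alleles=1, n_novel_alleles=1,
                                vdj_deletion=bool(seed % 2))
            truth = simulate_diploid(tiny_ref, cfg, seed=seed)
            for h, expected in ((1, truth.hap1), (2, truth.hap2)):
                parts, prev = [], 0
                for v in truth.hap_edits(h):
                    parts.append(tiny_ref.sequence[prev:v.start])
                    parts.append(v.alt_allele)
                    prev = v.end
                parts.append(tiny_ref.sequence[prev:])
                assert "".join(parts) == expected

    def test_infeasible_configuration_raises(self, tiny_ref):
        cfg = DiploidConfig(n_snv=100_000, n_indel=0, sv_spec=(),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        with pytest.raises(ValueError):
            simulate_diploid(tiny_ref, cfg, seed=4)


class TestSimulateReads:
    @pytest.fixture(scope="class")
    def truth(self, tiny_ref):
        cfg = DiploidConfig(n_snv=10, n_indel=2, sv_spec=(),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        return simulate_diploid(tiny_ref, cfg, seed=5)

    def test_error_free_reads_are_exact_substrings(self, truth):
        reads, stats = simulate_reads(truth, ReadConfig(coverage=5), seed=6)
        assert stats["n_mismatch"] == 0 and stats["n_indel"] == 0
        for r in reads:
            hap = truth.hap(r.truth_haplotype)
            s, e = r.truth_interval
            assert r.sequence == hap[s:e]

    def test_read_count_poisson(self, truth):
        # expected count per haplotype = coverage * L / mean_length
        cfg = ReadConfig(coverage=10, length_mean=3_000, length_sd=1)
        counts = [len(simulate_reads(truth, cfg, seed=s)[0])
                  for s in range(50)]
        expect = 2 * round(10 * len(truth.hap1) / 3_000)
        assert abs(np.mean(counts) - expect) < 0.05 * expect

    def test_homopolymer_bias_floor(self, truth):
        bias = 0.6
        cfg = ReadConfig(coverage=30, mismatch_rate=0.0, indel_rate=0.01,
                         homopolymer_bias=bias)
        _, stats = simulate_reads(truth, cfg, seed=7)
        assert stats["n_indel"] >= 10_000
        assert stats["n_indel_hp"] / stats["n_indel"] >= bias

    def test_coverage_matches_request_outside_dropout(self, truth):
        cfg = ReadConfig(coverage=15, dropout=((20_000, 25_000, 0.2),))
        depth = np.zeros(len(truth.hap1))
        n_seeds = 6
        for s in range(n_seeds):
            reads, _ = simulate_reads(truth, cfg, seed=100 + s)
            for r in reads:
                if r.truth_haplotype == 1:
                    a, b = r.truth_interval
                    depth[a:b] += 1
        depth /= n_seeds
        inside = depth[30_000:50_000].mean()
        se = depth[30_000:50_000].std() / np.sqrt(20_000 / 6_000)
        assert abs(inside - 15) <= 3 * max(se, 0.5)
        assert depth[21_000:24_000].mean() < 0.5 * inside

    def test_quality_string_encodes_error_model(self, truth):
        reads, _ = simulate_reads(
            truth, ReadConfig(coverage=2, mismatch_rate=0.006,
                              indel_rate=0.004), seed=8)
        q = ord(reads[0].quality[0]) - 33
        assert q == 20    # phred of total error rate 0.01

    def test_subread_mode_emits_copies(self, truth):
        cfg = ReadConfig(coverage=2, subread_mode=True,
                         singleton_fraction=0.3)
        reads, _ = simulate_reads(truth, cfg, seed=9)
        assert any(r.n_passes == 1 for r in reads)
        r = next(r for r in reads if r.n_passes >= 3)
        assert len(r.subreads) == r.n_passes
        collapsed = collapse_subreads(r.subreads)
        hap = truth.hap(r.truth_haplotype)
        frag = hap[r.truth_interval[0]:r.truth_interval[1]]
        import edlib
        d = edlib.align(collapsed, frag, mode="NW")["editDistance"]
        assert d / len(frag) < 0.02


class TestSimulateMultiplex:
    def _readsets(self, truth):
        sets = []
        for s in range(4):
            reads, _ = simulate_reads(truth, ReadConfig(coverage=3),
                                      seed=200 + s)
            sets.append(reads)
        return sets

    def test_fixed_yield_partition(self, tiny_ref):
        cfg = DiploidConfig(n_snv=4, n_indel=0, sv_spec=(),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        truth = simulate_diploid(tiny_ref, cfg, seed=10)
        sets = self._readsets(truth)
        total = sum(len(s) for s in sets)
        out = simulate_multiplex(sets, [2, 4, 8], seed=1)
        for plex, readsets in out.items():
            assert len(readsets) == plex
            for rs in readsets:
                assert len(rs) == total // plex

    def test_determinism(self, tiny_ref):
        cfg = DiploidConfig(n_snv=4, n_indel=0, sv_spec=(),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        truth = simulate_diploid(tiny_ref, cfg, seed=10)
        sets = self._readsets(truth)
        a = simulate_multiplex(sets, [4], seed=7)
        b = simulate_multiplex(sets, [4], seed=7)
        ids_a = [[r.read_id for r in rs] for rs in a[4]]
        ids_b = [[r.read_id for r in rs] for rs in b[4]]
        assert ids_a == ids_b


class TestIO:
    def test_fastq_round_trip(self, tiny_ref, tmp_path):
        cfg = DiploidConfig(n_snv=5, n_indel=1, sv_spec=(),
                            n_known_nonref_alleles=0, n_novel_alleles=0)
        truth = simulate_diploid(tiny_ref, cfg, seed=11)
        reads, _ = simulate_reads(truth, ReadConfig(coverage=2), seed=12)
        path = tmp_path / "reads.fastq"
        write_fastq(reads, str(path))
        back = read_fastq(str(path))
        assert len(back) == len(reads)
        for a, b in zip(reads, back):
            assert (a.read_id, a.sequence, a.n_passes, a.truth_haplotype,
                    a.truth_interval) == \
                (b.read_id, b.sequence, b.n_passes, b.truth_haplotype,
                 b.truth_interval)

    def test_truth_round_trip(self, tiny_ref, tmp_path):
        cfg = DiploidConfig(
            n_snv=12, n_indel=3,
            sv_spec=(SVSpec("embedded_absence", sv_id="SV1",
                            genotype="1|1"),),
            n_known_nonref_alleles=1, n_novel_alleles=1, vdj_deletion=True)
        truth = simulate_diploid(tiny_ref, cfg, seed=13)
        write_truth(truth, str(tmp_path))
        back = read_truth(str(tmp_path), tiny_ref)
        assert back.hap1 == truth.hap1 and back.hap2 == truth.hap2
        assert back.sv_genotypes == truth.sv_genotypes
        assert back.vdj_deletion == truth.vdj_deletion
        assert back.allele_assignments == truth.allele_assignments
        assert [(v.type, v.start, v.end, v.genotype) for v in back.variants] \
            == [(v.type, v.start, v.end, v.genotype)
                for v in truth.variants]


def test_allele_database_rejects_ambiguity(tmp_path):
    p = tmp_path / "db.fasta"
    p.write_text(">g1*01\nACGTN\n")
    with pytest.raises(ValueError):
        AlleleDatabase.from_fasta(str(p))


def test_homopolymer_mask():
    mask = homopolymer_mask("ACGGGTAAAAC")
    assert mask.tolist() == [False, False, True, True, True, False,
                             True, True, True, True, False]
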