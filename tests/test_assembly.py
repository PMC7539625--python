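import numpy as np
import pytest

from iglocus.align import seq_to_codes
from iglocus.assembly import (Contig, assemble_block, filter_contigs,
                              find_het_signatures, merge_overlapping_contigs,
                              recruit_and_retry)
from iglocus.mapping import ReadAlignment

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def make_aln(name, ref_start, seq, cigar=None):
    return ReadAlignment(name, ref_start, "+",
                         cigar or [("M", len(seq))], seq_to_codes(seq))


def tile_reads(ref, start, end, read_len, step, prefix="r", mutate=None,
               rng=None):
    out = []
    i = 0
    pos = start
    while pos < end:
        s, e = pos, min(pos + read_len, end)
        seq = ref[s:e]
        if mutate is not None:
            seq = mutate(seq, rng)
        out.append(make_aln(f"{prefix}{i}", s, seq))
        pos += step
        i += 1
    return out


def contig_from_ref(ref, s, e, contig_id="c", hap=0, qv=60.0):
    cols = np.arange(s, e, dtype=np.int64)
    return Contig(contig_id, "B", hap, cols, seq_to_codes(ref[s:e]),
                  np.full(e - s, qv, dtype=np.float32))


class TestAssembleBlock:
    def test_error_free_tiling_yields_single_exact_contig(self):
        rng = np.random.default_rng(41)
        ref = rand_seq(rng, 50_000)
        reads = tile_reads(ref, 0, 50_000, 6_000, 4_000)
        contigs = assemble_block(reads, start=0, end=50_000, edge_trim=0)
        assert len(contigs) == 1
        assert contigs[0].sequence == ref

    def test_coverage_gap_splits_contig(self):
        rng = np.random.default_rng(42)
        ref = rand_seq(rng, 50_000)
        reads = tile_reads(ref, 0, 20_000, 6_000, 4_000) + \
            tile_reads(ref, 25_000, 50_000, 6_000, 4_000, prefix="s")
        contigs = assemble_block(reads, start=0, end=50_000, edge_trim=0)
        assert len(contigs) == 2
        assert contigs[0].ref_end <= 25_000 <= contigs[1].ref_start

    def test_noisy_consensus_identity(self):
        rng = np.random.default_rng(43)
        ref = rand_seq(rng, 20_000)

        def mutate(seq, rng):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            k = rng.binomial(len(arr), 0.01)
            pos = rng.choice(len(arr), size=k, replace=False)
            arr[pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[
                rng.integers(0, 4, k)]
            return arr.tobytes().decode()

        reads = tile_reads(ref, 0, 20_000, 4_000, 100, mutate=mutate,
                           rng=rng)
        contigs = assemble_block(reads, start=0, end=20_000, edge_trim=0)
        assert len(contigs) == 1
        seq = contigs[0].sequence
        matches = sum(a == b for a, b in zip(seq, ref))
        assert matches / len(ref) >= 0.999

    def test_empty_bin(self):
        assert assemble_block([]) == []

    def test_majority_deletion_removed_from_consensus(self):
        rng = np.random.default_rng(44)
        ref = rand_seq(rng, 3_000)
        hap = ref[:1_000] + ref[1_100:]
        reads = []
        for i in range(10):
            reads.append(make_aln(
                f"d{i}", 0, hap,
                [("M", 1_000), ("D", 100), ("M", 1_900)]))
        contigs = assemble_block(reads, start=0, end=3_000, edge_trim=0)
        assert len(contigs) == 1
        assert contigs[0].sequence == hap
        assert contigs[0].deletion_runs() == [(1_000, 1_100)]


class TestFilterContigs:
    def _c(self, qv):
        return contig_from_ref("A" * 100, 0, 100, f"q{qv}", qv=qv)

    def test_boundary_is_strict_less_than(self):
        kept = filter_contigs([self._c(19.0), self._c(20.0), self._c(35.0)])
        assert [c.mean_qv for c in kept] == [20.0, 35.0]

    def test_empty_input(self):
        assert filter_contigs([]) == []

    def test_idempotent_and_order_preserving(self):
        cs = [self._c(30.0), self._c(25.0), self._c(50.0)]
        once = filter_contigs(cs)
        assert filter_contigs(once) == once
        assert [c.contig_id for c in once] == ["q30.0", "q25.0", "q50.0"]


class TestMergeOverlappingContigs:
    def test_exact_terminal_overlap_merges(self):
        rng = np.random.default_rng(45)
        ref = rand_seq(rng, 12_000)
        a = contig_from_ref(ref, 0, 8_000, "a")
        b = contig_from_ref(ref, 3_000, 12_000, "b")
        merged, reports = merge_overlapping_contigs([a, b])
        assert len(merged) == 1
        assert len(merged[0]) == 8_000 + 9_000 - 5_000
        assert merged[0].sequence == ref

    def test_short_overlap_not_merged(self):
        rng = np.random.default_rng(46)
        ref = rand_seq(rng, 10_000)
        a = contig_from_ref(ref, 0, 5_200, "a")
        b = contig_from_ref(ref, 4_800, 10_000, "b")
        merged, _ = merge_overlapping_contigs([a, b],
                                              min_overlap_bp=1_000)
        assert len(merged) == 2

    def test_discordant_overlap_reported_not_merged(self):
        rng = np.random.default_rng(47)
        ref = rand_seq(rng, 10_000)
        other = rand_seq(rng, 10_000)
        a = contig_from_ref(ref, 0, 6_000, "a")
        b = contig_from_ref(other, 4_000, 10_000, "b")
        merged, reports = merge_overlapping_contigs([a, b])
        assert len(merged) == 2
        assert reports and reports[0]["merged"] is False

    def test_three_chained_contigs_merge_to_one(self):
        rng = np.random.default_rng(48)
        ref = rand_seq(rng, 20_000)
        cs = [contig_from_ref(ref, 0, 8_000, "a"),
              contig_from_ref(ref, 6_000, 14_000, "b"),
              contig_from_ref(ref, 12_000, 20_000, "c")]
        merged, _ = merge_overlapping_contigs(cs)
        assert len(merged) == 1
        assert merged[0].sequence == ref


class TestRecruitAndRetry:
    def test_gap_recovered_from_pool(self):
        rng = np.random.default_rng(49)
        ref = rand_seq(rng, 12_000)
        contigs = [contig_from_ref(ref, 0, 5_000, "a"),
                   contig_from_ref(ref, 8_000, 12_000, "b")]
        pool = tile_reads(ref, 4_000, 9_000, 2_000, 1_000)
        new, uncovered = recruit_and_retry(contigs, pool, 12_000,
                                           edge_trim=0)
        assert uncovered == []
        assert any(c.ref_start <= 5_000 and c.ref_end >= 8_000 for c in new)

    def test_empty_pool_leaves_gap(self):
        rng = np.random.default_rng(50)
        ref = rand_seq(rng, 12_000)
        contigs = [contig_from_ref(ref, 0, 5_000, "a"),
                   contig_from_ref(ref, 8_000, 12_000, "b")]
        new, uncovered = recruit_and_retry(contigs, [], 12_000)
        assert new == []
        assert uncovered == [(5_000, 8_000)]

    def test_full_coverage_no_retry(self):
        rng = np.random.default_rng(51)
        ref = rand_seq(rng, 6_000)
        contigs = [contig_from_ref(ref, 0, 6_000, "a")]
        new, uncovered = recruit_and_retry(contigs, [], 6_000)
        assert new == [] and uncovered == []


class TestHetSignatures:
    def _cohort(self, ref, carriers, non_carriers, del_pos, del_len):
        alns = []
        hap = ref[:del_pos] + ref[del_pos + del_len:]
        for i in range(carriers):
            alns.append(make_aln(
                f"c{i}", 0, hap,
                [("M", del_pos), ("D", del_len),
                 ("M", len(ref) - del_pos - del_len)]))
        for i in range(non_carriers):
            alns.append(make_aln(f"n{i}", 0, ref))
        cov = np.zeros(len(ref), dtype=np.int32)
        for a in alns:
            cov[a.ref_start:a.ref_end] += 1
        return alns, cov

    def test_half_support_is_signature(self):
        rng = np.random.default_rng(52)
        ref = rand_seq(rng, 4_000)
        alns, cov = self._cohort(ref, 10, 10, 2_000, 80)
        sigs = find_het_signatures(alns, cov)
        assert len(sigs) == 1
        s = sigs[0]
        assert s.kind == "D" and s.pos == 2_000 and s.length == 80
        assert len(s.carriers) == 10

    def test_full_support_not_a_signature(self):
        rng = np.random.default_rng(53)
        ref = rand_seq(rng, 4_000)
        alns, cov = self._cohort(ref, 20, 0, 2_000, 80)
        assert find_het_signatures(alns, cov) == []

    def test_rare_events_ignored(self):
        rng = np.random.default_rng(54)
        ref = rand_seq(rng, 4_000)
        alns, cov = self._cohort(ref, 2, 28, 2_000, 80)
        assert find_het_signatures(alns, cov) == []
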