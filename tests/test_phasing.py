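import numpy as np
import pytest

from iglocus.align import seq_to_codes
from iglocus.mapping import ReadAlignment
from iglocus.phasing import (HET_CLASS, HOM_CLASS, HaplotypeBlock,
                             assign_reads, define_blocks,
                             detect_het_candidates, filter_reads,
                             pileup_counts)


def make_aln(name, ref_start, seq):
    return ReadAlignment(name, ref_start, "+", [("M", len(seq))],
                         seq_to_codes(seq))


class _Read:
    def __init__(self, n_passes):
        self.n_passes = n_passes


class TestFilterReads:
    def test_single_pass_dropped_two_kept(self):
        reads = [_Read(1), _Read(2), _Read(5)]
        kept = filter_reads(reads)
        assert [r.n_passes for r in kept] == [2, 5]

    def test_empty_input(self):
        assert filter_reads([]) == []

    def test_order_preserving(self):
        reads = [_Read(7), _Read(1), _Read(3), _Read(2)]
        assert [r.n_passes for r in filter_reads(reads)] == [7, 3, 2]


class TestDetectHetCandidates:
    def _alns(self, ref, variants, depth=40):
        """depth reads covering the whole ref; half carry the variants."""
        alns = []
        for i in range(depth):
            seq = list(ref)
            if i % 2 == 0:
                for pos, alt in variants:
                    seq[pos] = alt
            alns.append(make_aln(f"r{i}", 0, "".join(seq)))
        return alns

    def test_balanced_site_is_candidate(self):
        ref = "ACGT" * 25
        alns = self._alns(ref, [(38, "C")])   # ref[38] == "G"
        cands = detect_het_candidates(alns, ref)
        assert cands == [(38, "G", "C")]

    def test_all_reference_no_candidate(self):
        ref = "ACGT" * 25
        alns = self._alns(ref, [])
        assert detect_het_candidates(alns, ref) == []

    def test_low_fraction_rejected(self):
        ref = "ACGT" * 25
        alns = [make_aln(f"r{i}", 0, ref) for i in range(38)]
        mut = list(ref)
        mut[50] = "A" if ref[50] != "A" else "C"
        alns += [make_aln(f"m{i}", 0, "".join(mut)) for i in range(2)]
        assert detect_het_candidates(alns, ref,
                                     min_alt_fraction=0.25) == []

    def test_depth_threshold(self):
        ref = "ACGT" * 25
        alns = self._alns(ref, [(20, "A" if ref[20] != "A" else "C")],
                          depth=8)
        assert detect_het_candidates(alns, ref, min_depth=10) == []


class TestAssignReads:
    def _fixture(self, rng, n_sites=6, depth=30, noise=0.0):
        L = 3000
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
        sites = np.linspace(200, L - 200, n_sites).astype(int)
        hap_alt = rng.integers(0, 2, n_sites)    # which hap carries alt
        alts = []
        for p in sites:
            alts.append("A" if ref[p] != "A" else "G")
        cands = [(int(p), ref[p], a) for p, a in zip(sites, alts)]
        alns, truth = [], {}
        for i in range(depth):
            h = i % 2
            seq = list(ref)
            for j, p in enumerate(sites):
                if hap_alt[j] == h:
                    seq[p] = alts[j]
            name = f"r{i}"
            truth[name] = h + 1
            alns.append(make_aln(name, 0, "".join(seq)))
        return alns, cands, truth

    def test_perfect_match_assigned(self):
        rng = np.random.default_rng(31)
        alns, cands, truth = self._fixture(rng)
        phased, part = assign_reads(alns, cands)
        # label symmetry: orientation is arbitrary but must be consistent
        maps = {}
        for name, h in part.items():
            assert h in (1, 2)
            maps.setdefault(truth[name], set()).add(h)
        assert maps[1] != maps[2]
        assert all(len(v) == 1 for v in maps.values())

    def test_tie_read_unassigned(self):
        ref = "A" * 100 + "C" + "A" * 100 + "G" + "A" * 100
        cands = [(100, "C", "T"), (201, "G", "T")]
        h1 = list(ref)
        h2 = list(ref)
        h1[100] = "T"
        h2[201] = "T"
        alns = [make_aln(f"a{i}", 0, "".join(h1)) for i in range(4)]
        alns += [make_aln(f"b{i}", 0, "".join(h2)) for i in range(4)]
        # a read matching hap1 at one site and hap2 at the other
        mixed = list(ref)
        mixed[100] = "T"
        mixed[201] = "T"
        alns.append(make_aln("tie", 0, "".join(mixed)))
        phased, part = assign_reads(alns, cands)
        assert part["tie"] == 0

    def test_noiseless_partition_matches_truth(self):
        rng = np.random.default_rng(32)
        alns, cands, truth = self._fixture(rng, n_sites=30, depth=40)
        _, part = assign_reads(alns, cands)
        orient = {}
        errors = 0
        for name, h in part.items():
            if h == 0:
                errors += 1
                continue
            key = (truth[name], h)
            orient[key] = orient.get(key, 0) + 1
        # all reads of one truth hap must share one label
        assert len(orient) == 2
        assert errors == 0

    def test_zero_candidates(self):
        alns = [make_aln("r", 0, "ACGT")]
        phased, part = assign_reads(alns, [])
        assert phased == [] and part == {"r": 0}


class TestDefineBlocks:
    def _phase(self, alns, cands):
        return assign_reads(alns, cands)

    def test_spanning_read_joins_sites(self):
        ref = "A" * 500
        cands = [(100, "A", "C"), (300, "A", "G")]
        alns = []
        for i in range(12):
            seq = list(ref)
            if i % 2:
                seq[100] = "C"
                seq[300] = "G"
            alns.append(make_aln(f"r{i}", 0, "".join(seq)))
        phased, part = self._phase(alns, cands)
        blocks = define_blocks(phased, alns, part, 500)
        het = [b for b in blocks if b.cls == HET_CLASS]
        assert len(het) == 1
        assert len(het[0].phased_snvs) == 2

    def test_unconnected_clusters_split_with_hom_gap(self):
        L = 9000
        ref = "A" * L
        cands = [(100, "A", "C"), (8800, "A", "G")]
        alns = []
        for i in range(20):
            start = 0 if i < 10 else 8000
            seq = list(ref[start:start + 1000])
            if i % 2:
                if start == 0:
                    seq[100] = "C"
                else:
                    seq[800] = "G"
            alns.append(make_aln(f"r{i}", start, "".join(seq)))
        # middle coverage with no het sites
        for i in range(10):
            alns.append(make_aln(f"m{i}", 1000 + i * 700, "A" * 1000))
        phased, part = self._phase(alns, cands)
        blocks = define_blocks(phased, alns, part, L)
        classes = [b.cls for b in blocks]
        assert classes.count(HET_CLASS) == 2
        assert HOM_CLASS in classes

    def test_zero_het_sites_single_hom_block(self):
        alns = [make_aln(f"r{i}", i * 500, "A" * 1000) for i in range(10)]
        blocks = define_blocks([], alns, {a.name: 0 for a in alns}, 5200)
        assert [b.cls for b in blocks] == [HOM_CLASS]
        assert (blocks[0].start, blocks[0].end) == (0, 5200)

    def test_block_tiling_covers_read_span(self, small_result):
        blocks = sorted(small_result.blocks, key=lambda b: b.start)
        for a, b in zip(blocks, blocks[1:]):
            assert a.end == b.start
        cov = small_result.coverage > 0
        covered = (int(np.flatnonzero(cov)[0]),
                   int(np.flatnonzero(cov)[-1]) + 1)
        assert blocks[0].start == covered[0]
        assert blocks[-1].end == covered[1]

    def test_het_block_invariants(self, small_result):
        for b in small_result.blocks:
            if b.cls == HET_CLASS:
                assert len(b.phased_snvs) >= 1
                for s in b.phased_snvs:
                    assert b.start <= s.position < b.end
            else:
                assert b.phased_snvs == []


def test_pileup_counts_shape_and_totals():
    ref = "ACGT" * 10
    alns = [make_aln("a", 0, ref), make_aln("b", 8, ref[8:24])]
    counts, delcov = pileup_counts(alns, 40)
    assert counts.shape == (40, 4)
    assert counts.sum() == 40 + 16
    assert delcov.sum() == 0


class TestTrioRelabeling:
    def _block(self, phases):
        b = HaplotypeBlock("B1", 0, 1000, HET_CLASS)
        from iglocus.phasing import PhasedSNV
        for i, ph in enumerate(phases):
            b.phased_snvs.append(PhasedSNV(i * 100, "A", "C", "0/1", ph,
                                           "B1"))
        return b

    def test_consistent_maternal_votes(self):
        from iglocus.phasing import relabel_blocks_by_trio
        b = self._block([1, 1, 2])
        mother = {0: "0/1", 100: "1/1", 200: "0/0"}
        father = {0: "0/0", 100: "0/0", 200: "0/1"}
        out = relabel_blocks_by_trio([b], mother, father)
        assert out == {"B1": {1: "maternal", 2: "paternal"}}

    def test_uninformative_block_stays_local(self):
        from iglocus.phasing import relabel_blocks_by_trio
        b = self._block([1, 2])
        both = {0: "0/1", 100: "0/1"}
        assert relabel_blocks_by_trio([b], both, both) == {}

    def test_conflicting_votes_resolved_by_majority(self):
        from iglocus.phasing import relabel_blocks_by_trio
        b = self._block([1, 1, 1])
        mother = {0: "0/1", 100: "0/1", 200: "0/0"}
        father = {0: "0/0", 100: "0/0", 200: "0/1"}
        out = relabel_blocks_by_trio([b], mother, father)
        assert out["B1"][1] == "maternal"
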