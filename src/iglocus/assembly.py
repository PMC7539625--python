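"""Haplotype-resolved assembly of aligned reads into contigs.

Assembly is reference-guided: reads already carry alignments to the
custom reference, so layout is their reference placement and consensus is
per-column majority over each (block, haplotype) bin, racon-style.  Reads
whose spans fail to overlap by at least ``min_overlap`` break the layout
chain, so coverage gaps yield multiple contigs per bin.

Heterozygous indel/SV alleles that fall in homozygous_or_hemizygous
blocks (no het SNV within read range) cannot be represented by a single
consensus: reads sharing such an indel signature at intermediate support
are split into carrier/non-carrier clusters and each cluster is assembled
separately as a locally phased pair (``phase_confident=False``).  The
same mechanism sets aside a minority cluster produced by a somatic
deletion on one haplotype.

Per-base consensus quality is the phred-scaled column agreement, capped
at 60; a contig's QV is the mean over its columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import seq_to_codes
from .phasing import HET_CLASS, HOM_CLASS

__all__ = [
    "Contig", "AssemblyBin", "Signature", "assemble_block",
    "find_het_signatures", "build_bins", "recruit_and_retry",
    "filter_contigs", "merge_overlapping_contigs",
]

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
MAX_QV = 60.0


def _codes_to_str(codes) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


@dataclass
class Contig:
    """An assembled consensus anchored to the reference.

    ``col_ref`` holds the reference position of every aligned consensus
    base (strictly increasing; gaps are deletions relative to the
    reference), ``insertions`` the extra sequence between columns as
    ``(ref_pos, seq, qv)``.
    """

    contig_id: str
    block_id: str
    haplotype: int                  # 1/2, or 0 for unphased bins
    col_ref: np.ndarray
    col_code: np.ndarray
    col_qv: np.ndarray
    insertions: list = field(default_factory=list)
    phase_confident: bool = True

    @property
    def ref_start(self) -> int:
        return int(self.col_ref[0])

    @property
    def ref_end(self) -> int:
        return int(self.col_ref[-1]) + 1

    @property
    def mean_qv(self) -> float:
        qvs = [self.col_qv]
        for _, seq, qv in self.insertions:
            qvs.append(np.full(len(seq), qv))
        return float(np.mean(np.concatenate(qvs)))

    @property
    def sequence(self) -> str:
        parts, prev = [], 0
        ins = sorted(self.insertions)
        for p, seq, _ in ins:
            cut = int(np.searchsorted(self.col_ref, p))
            parts.append(_codes_to_str(self.col_code[prev:cut]))
            parts.append(seq)
            prev = cut
        parts.append(_codes_to_str(self.col_code[prev:]))
        return "".join(parts)

    def __len__(self):
        return len(self.col_code) + sum(len(s) for _, s, _ in self.insertions)

    def covers(self, start: int, end: int) -> bool:
        return self.ref_start <= start and end <= self.ref_end

    def project(self, start: int, end: int) -> str:
        """Consensus sequence projected from reference window [start, end)."""
        lo = int(np.searchsorted(self.col_ref, start))
        hi = int(np.searchsorted(self.col_ref, end))
        parts, prev = [], lo
        for p, seq, _ in sorted(self.insertions):
            if start < p < end:
                cut = int(np.searchsorted(self.col_ref, p))
                parts.append(_codes_to_str(self.col_code[prev:cut]))
                parts.append(seq)
                prev = cut
        parts.append(_codes_to_str(self.col_code[prev:hi]))
        return "".join(parts)

    def base_allele(self, pos: int):
        """Consensus base at a reference position, or None if deleted /
        out of range."""
        i = int(np.searchsorted(self.col_ref, pos))
        if i < len(self.col_ref) and self.col_ref[i] == pos:
            return "ACGT"[self.col_code[i]]
        return None

    def deletion_runs(self):
        """(start, end) reference intervals deleted in the consensus."""
        gaps = np.flatnonzero(np.diff(self.col_ref) > 1)
        return [(int(self.col_ref[i]) + 1, int(self.col_ref[i + 1]))
                for i in gaps]


@dataclass
class AssemblyBin:
    bin_id: str
    block_id: str
    start: int
    end: int
    haplotype: int
    reads: list
    phase_confident: bool = True


@dataclass
class Signature:
    kind: str           # I or D
    pos: int
    length: int
    span: tuple         # (start, end) on the reference
    carriers: set
    support: int
    depth: int


def assemble_block(reads, start=None, end=None, block_id="B0", haplotype=0,
                   min_overlap: int = 100, min_identity: float = 0.8,
                   ref_codes=None, phase_confident=True,
                   contig_prefix="ctg", min_insert_frac: float = 0.5,
                   edge_trim: int = 5, tail_trim_depth: int = 1):
    """Assemble one bin of aligned reads into consensus contigs.

    Reads are laid out by reference position; a chain breaks where the
    next read overlaps the chain by fewer than ``min_overlap`` bases.
    Reads whose aligned identity to the current reference falls below
    ``min_identity`` are dropped before layout.  Each chain yields one
    contig via column-majority consensus.
    """
    if not reads:
        return []
    if ref_codes is not None and min_identity > 0:
        reads = [r for r in reads if _read_identity(r, ref_codes) >= min_identity]
        if not reads:
            return []
    reads = sorted(reads, key=lambda a: (a.ref_start, a.name))
    lo = min(a.ref_start for a in reads) if start is None else start
    hi = max(a.ref_end for a in reads) if end is None else end

    chains, cur, cur_end = [], [], None
    for a in reads:
        s, e = max(a.ref_start, lo), min(a.ref_end, hi)
        if e - s <= 0:
            continue
        # a read clipped shorter than min_overlap cannot overlap by more
        # than its own clipped span
        required = min(min_overlap, e - s)
        if cur and cur_end - s < required:
            chains.append(cur)
            cur = []
        cur.append(a)
        cur_end = max(cur_end or e, e)
    if cur:
        chains.append(cur)

    contigs = []
    serial = 0
    for chain in chains:
        cs = max(lo, min(a.ref_start for a in chain))
        ce = min(hi, max(a.ref_end for a in chain))
        for ctg in _consensus(chain, cs, ce, block_id, haplotype,
                              phase_confident, min_insert_frac, edge_trim,
                              tail_trim_depth, ref_codes):
            serial += 1
            ctg.contig_id = f"{contig_prefix}.{serial}"
            contigs.append(ctg)
    return contigs


def _read_identity(a, ref_codes):
    rpos, qpos = a.matched_columns()
    if len(rpos) == 0:
        return 0.0
    return float(np.mean(a.seq_codes[qpos] == ref_codes[rpos]))


MIN_DEL_VOTES = 3


def _consensus(reads, start, end, block_id, haplotype,
               phase_confident, min_insert_frac, edge_trim=5,
               tail_trim_depth=1, ref_codes=None):
    """Column-majority consensus over one layout chain.

    Returns a LIST of contigs: a column is deleted only with at least
    ``MIN_DEL_VOTES`` deletion-majority votes; a column with neither base
    support nor such deletion support is uncovered and splits the chain
    (a stray bridging read must not fabricate a deletion).
    """
    w = end - start
    if w <= 0:
        return []
    base = np.zeros((w, 4), dtype=np.int32)
    dels = np.zeros(w, dtype=np.int32)
    ins_events = {}
    for a in reads:
        rpos, codes, dspans, ins = a.column_votes(start, end, edge_trim)
        ok = codes < 4
        np.add.at(base, (rpos[ok] - start, codes[ok].astype(np.int64)), 1)
        for s, e in dspans:
            dels[s - start:e - start] += 1
        for p, seq in ins:
            ins_events.setdefault(p, []).append(seq)

    bdepth = base.sum(axis=1)
    cov = bdepth + dels
    # trim thin tails: a bin's phased coverage tapers at its edges, where
    # one or two reads would dominate the consensus; the retry stage
    # re-assembles trimmed spans from the full read pool instead
    if tail_trim_depth > 1:
        good = np.flatnonzero(cov >= tail_trim_depth)
        if len(good) == 0:
            return []
        cov[:good[0]] = 0
        base[:good[0]] = 0
        dels[:good[0]] = 0
        if good[-1] + 1 < w:
            cov[good[-1] + 1:] = 0
            base[good[-1] + 1:] = 0
            dels[good[-1] + 1:] = 0
        bdepth = base.sum(axis=1)

    deleted = (dels > bdepth) & \
        (dels >= min(MIN_DEL_VOTES, max(1, int(cov.max()))))
    covered = (bdepth > 0) | deleted
    # a long thin stretch (e.g. the hemizygous interior of a large
    # deletion seen only by a few phased reads) is left to the
    # recruitment pass, which assembles it from the full read pool
    if tail_trim_depth > 1:
        low = cov < tail_trim_depth
        for ls, le in _bool_runs(low & ~deleted):
            if le - ls >= 2_000:
                covered[ls:le] = False
    if not covered.any():
        return []

    # insertion consensus, assigned to runs afterwards
    merged = []
    for p, seqs in sorted(ins_events.items()):
        if merged and p - merged[-1][0] <= 3:
            merged[-1][1].extend(seqs)
        else:
            merged.append([p, list(seqs)])
    final_ins = []
    for p, seqs in merged:
        col = min(max(p - start, 0), w - 1)
        depth_here = cov[col]
        if depth_here and len(seqs) * 2 > depth_here:
            seq = _insertion_consensus(seqs)
            if ref_codes is not None:
                p, seq = _normalize_insertion(p, seq, ref_codes)
            ag = len(seqs) / depth_here
            iqv = min(MAX_QV, -10 * math.log10(max(1 - ag, 1e-6)))
            final_ins.append((p, seq, iqv))

    out = []
    for rs, re_ in _bool_runs(covered):
        keep = np.zeros(w, dtype=bool)
        keep[rs:re_] = ~deleted[rs:re_] & (bdepth[rs:re_] > 0)
        kidx = np.flatnonzero(keep)
        if len(kidx) < 30:
            continue
        codes = base[kidx].argmax(axis=1).astype(np.int8)
        best = base[kidx].max(axis=1)
        agree = best / cov[kidx]
        qv = np.minimum(MAX_QV, -10 * np.log10(np.maximum(1 - agree, 1e-6)))
        lo_ref, hi_ref = start + rs, start + re_
        ins_here = [(p, s, q) for p, s, q in final_ins
                    if lo_ref < p < hi_ref]
        out.append(Contig("", block_id, haplotype,
                          (kidx + start).astype(np.int64), codes,
                          qv.astype(np.float32), ins_here, phase_confident))
    return out


def _normalize_insertion(p, seq, ref_codes):
    codes = "ACGT"
    while p > 0 and seq and seq[-1] in codes and \
            ref_codes[p - 1] == codes.index(seq[-1]):
        seq = codes[ref_codes[p - 1]] + seq[:-1]
        p -= 1
    return p, seq


def _insertion_consensus(seqs):
    from collections import Counter
    counts = Counter(seqs)
    top, n = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    if n * 2 > len(seqs) or len(top) <= 10:
        return top
    return polish_sequence(top, seqs)


def polish_sequence(draft: str, seqs) -> str:
    """Column-majority polish of a draft against supporting sequences."""
    from .align import edlib_ops
    votes = [dict() for _ in range(len(draft))]
    for s in seqs:
        ops, _, _ = edlib_ops(s, draft, mode="NW")
        qi = ri = 0
        for op, l in ops:
            if op in ("=", "X", "M"):
                for t in range(l):
                    b = s[qi + t]
                    votes[ri + t][b] = votes[ri + t].get(b, 0) + 1
                qi += l
                ri += l
            elif op == "I":
                qi += l
            else:
                for t in range(l):
                    votes[ri + t]["-"] = votes[ri + t].get("-", 0) + 1
                ri += l
    out = []
    for v in votes:
        if not v:
            continue
        b = max(sorted(v), key=lambda k: v[k])
        if b != "-":
            out.append(b)
    return "".join(out)


# ---------------------------------------------------------------------------
# het indel signatures and bin construction


def find_het_signatures(alignments, coverage, min_len: int = 2,
                        lo: float = 0.2, hi: float = 0.85,
                        min_support: int = 3, pos_tol: int = 20,
                        len_tol: float = 0.25):
    """Indel signatures shared by an intermediate fraction of reads.

    Events of the same kind within ``pos_tol`` bp whose lengths agree
    within ``len_tol`` are clustered; a cluster whose carrier fraction of
    the spanning depth falls in [lo, hi] is returned as a het signature.
    """
    events = []
    for a in alignments:
        for p, kind, l, _ in a.indel_events(min_len=min_len):
            events.append((kind, p, l, a.name))
    events.sort()
    sigs = []
    i = 0
    while i < len(events):
        kind, p0, l0, _ = events[i]
        cluster = [events[i]]
        j = i + 1
        while j < len(events):
            k, p, l, _ = events[j]
            ref_l = cluster[-1][2]
            if k != kind or p - cluster[-1][1] > pos_tol or \
                    abs(l - ref_l) > max(2, len_tol * max(l, ref_l)):
                break
            cluster.append(events[j])
            j += 1
        i = j
        carriers = {e[3] for e in cluster}
        if len(carriers) < min_support:
            continue
        pos = int(np.median([e[1] for e in cluster]))
        length = int(np.median([e[2] for e in cluster]))
        depth = int(coverage[min(pos, len(coverage) - 1)])
        if depth == 0:
            continue
        frac = len(carriers) / depth
        if lo <= frac <= hi:
            span = (pos, pos + (length if kind == "D" else 1))
            sigs.append(Signature(kind, pos, length, span, carriers,
                                  len(cluster), depth))
    return sigs


def build_bins(blocks, alignments, partition, signatures,
               avoid_intervals=()):
    """Assembly bins from haplotype blocks and het indel signatures.

    Het blocks yield one bin per haplotype (reads whose het sites phased
    the block).  Hom blocks yield a single unphased bin, except where a
    het signature overlaps: the carrier span is carved out and assembled
    as a locally phased carrier / non-carrier pair.
    """
    by_name = {a.name: a for a in alignments}
    read_block = _read_to_block(blocks, alignments)
    bins = []
    for b in blocks:
        overl = [a for a in alignments
                 if a.ref_start < b.end and b.start < a.ref_end]
        if b.cls == HET_CLASS:
            for h in (1, 2):
                picked = [a for a in overl
                          if partition.get(a.name, 0) == h
                          and read_block.get(a.name) == b.block_id]
                bins.append(AssemblyBin(f"{b.block_id}.h{h}", b.block_id,
                                        b.start, b.end, h, picked))
            continue
        sigs = [s for s in signatures
                if s.span[0] < b.end and b.start < s.span[1]]
        if not sigs:
            bins.append(AssemblyBin(f"{b.block_id}.h0", b.block_id,
                                    b.start, b.end, 0, overl))
            continue
        carves = []
        for s in sigs:
            carrier_alns = [by_name[n] for n in s.carriers if n in by_name]
            cs = max(b.start, min(a.ref_start for a in carrier_alns))
            ce = min(b.end, max(a.ref_end for a in carrier_alns))
            carves.append([cs, ce, set(s.carriers)])
        carves.sort(key=lambda c: c[0])
        mergedc = [carves[0]]
        for cs, ce, car in carves[1:]:
            if cs <= mergedc[-1][1]:
                mergedc[-1][1] = max(mergedc[-1][1], ce)
                mergedc[-1][2] |= car
            else:
                mergedc.append([cs, ce, car])
        for c in mergedc:
            c[0] = _avoid_point(c[0], avoid_intervals, up=False)
            c[1] = _avoid_point(c[1], avoid_intervals, up=True)
            c[0], c[1] = max(b.start, c[0]), min(b.end, c[1])
        cursor = b.start
        piece = 0
        for cs, ce, carriers in mergedc:
            if cs > cursor:
                piece += 1
                sub = [a for a in overl
                       if a.ref_start < cs and cursor < a.ref_end]
                bins.append(AssemblyBin(f"{b.block_id}.p{piece}.h0",
                                        b.block_id, cursor, cs, 0, sub))
            piece += 1
            inside = [a for a in overl
                      if a.ref_start < ce and cs < a.ref_end]
            car = [a for a in inside if a.name in carriers]
            non = [a for a in inside if a.name not in carriers]
            bins.append(AssemblyBin(f"{b.block_id}.p{piece}.h1",
                                    b.block_id, cs, ce, 1, non,
                                    phase_confident=False))
            bins.append(AssemblyBin(f"{b.block_id}.p{piece}.h2",
                                    b.block_id, cs, ce, 2, car,
                                    phase_confident=False))
            cursor = ce
        if cursor < b.end:
            piece += 1
            sub = [a for a in overl
                   if a.ref_start < b.end and cursor < a.ref_end]
            bins.append(AssemblyBin(f"{b.block_id}.p{piece}.h0",
                                    b.block_id, cursor, b.end, 0, sub))
    return bins


def _read_to_block(blocks, alignments):
    """Map each read to the het block whose SNVs it covers."""
    site_pos, site_block = [], []
    for b in blocks:
        for s in b.phased_snvs:
            site_pos.append(s.position)
            site_block.append(b.block_id)
    order = np.argsort(site_pos)
    site_pos = np.array(site_pos)[order] if site_pos else np.zeros(0, np.int64)
    site_block = [site_block[i] for i in order]
    out = {}
    for a in alignments:
        lo = np.searchsorted(site_pos, a.ref_start)
        hi = np.searchsorted(site_pos, a.ref_end)
        if hi > lo:
            out[a.name] = site_block[int(lo)]
    return out


def _avoid_point(p, avoids, up: bool):
    for s, e in avoids:
        if s <= p < e:
            return e if up else s
    return p


# ---------------------------------------------------------------------------
# retry, filtering, merging


def recruit_and_retry(contigs, pool, ref_len: int, min_gap: int = 50,
                      forbidden=(), **assemble_kwargs):
    """Assemble reads from ``pool`` over regions no contig sequence covers.

    ``pool`` is the unfiltered alignment set (including single-pass
    molecules, the stand-in for raw subreads).  Coverage is judged by
    consensus columns, so the interior of a long one-haplotype deletion —
    spanned by a carrier contig only as a gap — is retried too; when a
    single-haplotype contig's deletion spans the gap, the new contig gets
    the complementary haplotype label (the region is hemizygous).
    Returns ``(new_contigs, still_uncovered_intervals)``.
    """
    cov = np.zeros(ref_len, dtype=bool)
    for c in contigs:
        cov[c.col_ref] = True
    new = []
    uncovered = []
    runs = _bool_runs(~cov)
    for i, (s, e) in enumerate(runs):
        if e - s < min_gap:
            continue
        hap, block_id, pc = 0, f"R{i + 1}", True
        for c in contigs:
            if c.haplotype == 0 or not (c.ref_start <= s and e <= c.ref_end):
                continue
            gap_cov = sum(max(0, min(de, e) - max(ds, s))
                          for ds, de in c.deletion_runs())
            if gap_cov >= 0.9 * (e - s):
                hap = 3 - c.haplotype
                block_id = c.block_id
                pc = c.phase_confident
                break
        sub = [a for a in pool if a.ref_start < e and s < a.ref_end
               and not _spans_as_deletion(a, s, e)]
        got = assemble_block(sub, start=s, end=e, block_id=block_id,
                             haplotype=hap, phase_confident=pc,
                             contig_prefix=f"retry{i + 1}",
                             **assemble_kwargs)
        if got:
            new.extend(got)
        else:
            uncovered.append((s, e))

    # second pass: holes on ONE haplotype only (phased-bin tails whose
    # columns are masked by the other haplotype in the union coverage).
    # Only variant-free spans are refilled — with all reads, labelled for
    # the haplotype that lacked coverage.
    all_c = list(contigs) + new
    for h in (1, 2):
        cov_h = np.zeros(ref_len, dtype=bool)
        for c in all_c:
            if c.haplotype in (0, h):
                cov_h[c.col_ref] = True
        for i, (s, e) in enumerate(_bool_runs(~cov_h & cov)):
            if e - s < min_gap:
                continue
            if any(fs < e and s < fe for fs, fe in forbidden):
                continue
            own_deletion = any(
                c.haplotype == h and c.ref_start <= s and e <= c.ref_end
                and sum(max(0, min(de, e) - max(ds, s))
                        for ds, de in c.deletion_runs()) >= 0.9 * (e - s)
                for c in all_c)
            if own_deletion:
                continue    # the hole is a real absence on this haplotype
            sub = [a for a in pool if a.ref_start < e and s < a.ref_end
                   and not _spans_as_deletion(a, s, e)]
            got = assemble_block(sub, start=s, end=e, block_id=f"Rh{h}",
                                 haplotype=h, phase_confident=True,
                                 contig_prefix=f"retryh{h}x{i + 1}",
                                 **assemble_kwargs)
            new.extend(got)
            all_c.extend(got)
    return new, uncovered


def _spans_as_deletion(a, s, e, frac: float = 0.5):
    """True when the read crosses [s, e) mostly as a deletion (it carries
    the absence allele and must not vote in a presence-side retry)."""
    span = 0
    for p, kind, l, _ in a.indel_events(min_len=50):
        if kind == "D":
            span += max(0, min(p + l, e) - max(p, s))
    return span >= frac * (e - s)


def _bool_runs(mask):
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask.size and mask[0]:
        starts = [0] + starts
    if mask.size and mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def filter_contigs(contigs, qv_min: float = 20.0):
    """Drop contigs whose mean consensus QV is below ``qv_min`` (strict:
    a contig at exactly the threshold is retained)."""
    return [c for c in contigs if c.mean_qv >= qv_min]


def merge_overlapping_contigs(contigs, min_overlap_bp: int = 1000,
                              max_mismatch_rate: float = 0.002,
                              max_gap_bases: int = 20):
    """Merge contigs of one haplotype whose terminal overlaps agree.

    All pairs of same-haplotype (or unphased) contigs overlapping in
    reference coordinates by at least ``min_overlap_bp`` are aligned over
    the shared window; pairs within the mismatch/gap budget are merged,
    taking the higher-QV contig's copy of the overlap.  Repeats to a
    fixed point.  Returns ``(merged_contigs, reports)`` where reports
    describe rejected or inconsistent overlaps.
    """
    contigs = list(contigs)
    reports = []
    changed = True
    while changed:
        changed = False
        contigs.sort(key=lambda c: (c.ref_start, c.contig_id))
        for i in range(len(contigs) - 1):
            a = contigs[i]
            for j in range(i + 1, len(contigs)):
                b = contigs[j]
                if b.ref_start >= a.ref_end:
                    break
                if a.haplotype != b.haplotype and 0 not in (a.haplotype,
                                                            b.haplotype):
                    continue
                ov_s, ov_e = b.ref_start, min(a.ref_end, b.ref_end)
                if ov_e - ov_s < min_overlap_bp:
                    continue
                sa = a.project(ov_s, ov_e)
                sb = b.project(ov_s, ov_e)
                from .align import edlib_ops
                ops, _, _ = edlib_ops(sa, sb, mode="NW")
                mism = sum(l for op, l in ops if op == "X")
                gaps = sum(l for op, l in ops if op in ("I", "D"))
                ov_len = ov_e - ov_s
                if mism / max(ov_len, 1) <= max_mismatch_rate and \
                        gaps <= max_gap_bases:
                    contigs[i] = _merge_pair(a, b, ov_s, ov_e)
                    del contigs[j]
                    changed = True
                    break
                reports.append({
                    "left": a.contig_id, "right": b.contig_id,
                    "overlap": ov_len, "mismatches": mism, "gap_bases": gaps,
                    "merged": False})
            if changed:
                break
    return contigs, reports


def _merge_pair(a, b, ov_s, ov_e):
    qa = float(np.mean(a.col_qv)) if len(a.col_qv) else 0.0
    qb = float(np.mean(b.col_qv)) if len(b.col_qv) else 0.0
    # higher-QV contig supplies the overlap columns
    if qa >= qb:
        cut_b = int(np.searchsorted(b.col_ref, a.ref_end))
        col_ref = np.concatenate([a.col_ref, b.col_ref[cut_b:]])
        col_code = np.concatenate([a.col_code, b.col_code[cut_b:]])
        col_qv = np.concatenate([a.col_qv, b.col_qv[cut_b:]])
        ins = list(a.insertions) + [x for x in b.insertions
                                    if x[0] >= a.ref_end]
    else:
        cut_a = int(np.searchsorted(a.col_ref, b.ref_start))
        col_ref = np.concatenate([a.col_ref[:cut_a], b.col_ref])
        col_code = np.concatenate([a.col_code[:cut_a], b.col_code])
        col_qv = np.concatenate([a.col_qv[:cut_a], b.col_qv])
        ins = [x for x in a.insertions if x[0] < b.ref_start] + \
            list(b.insertions)
    return Contig(f"{a.contig_id}+{b.contig_id}", a.block_id,
                  a.haplotype if a.haplotype else b.haplotype,
                  col_ref, col_code, col_qv, sorted(ins),
                  a.phase_confident and b.phase_confident)
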