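"""Read-to-reference mapping via minimap2, with split-alignment stitching.

Reads are placed on the custom locus reference with minimap2 (map-hifi
preset, single thread).  Long deletions relative to the reference — an
absent embedded SV allele, a multi-kb germline deletion, a V(D)J-like
somatic loss — are reported by minimap2 as primary + supplementary
alignment pairs; :func:`stitch_alignments` re-joins colinear pairs into a
single gapped alignment so downstream pileup and consensus code sees one
read with one deletion.

The in-memory representation (:class:`ReadAlignment`) keeps the aligned
query sequence as a numpy code array plus the cigar, and serves vectorized
per-column votes to the pileup and consensus builders.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pysam

from .align import seq_to_codes
from .reference import LocusReference

__all__ = ["ReadAlignment", "map_reads", "stitch_alignments", "write_tagged_sam"]

MAX_STITCH_GAP = 200_000


@dataclass
class ReadAlignment:
    """One (possibly stitched) read alignment on the custom reference.

    ``cigar`` ops: M (aligned, match or mismatch), I (insertion to the
    reference), D (deletion from the reference), S (soft clip).  The
    sequence is stored in aligned orientation.
    """

    name: str
    ref_start: int
    strand: str
    cigar: list
    seq_codes: np.ndarray
    n_passes: int = 2
    truth_hap: int = 0
    barcode: str = None

    def __post_init__(self):
        self.ref_end = self.ref_start + sum(
            l for op, l in self.cigar if op in ("M", "D"))

    @property
    def ref_span(self):
        return self.ref_start, self.ref_end

    def matched_columns(self):
        """(ref positions, query positions) of all M columns."""
        rpos, qpos = [], []
        r, q = self.ref_start, 0
        for op, l in self.cigar:
            if op == "M":
                rpos.append(np.arange(r, r + l, dtype=np.int64))
                qpos.append(np.arange(q, q + l, dtype=np.int64))
                r += l
                q += l
            elif op == "D":
                r += l
            elif op in ("I", "S"):
                q += l
        if not rpos:
            return (np.zeros(0, np.int64), np.zeros(0, np.int64))
        return np.concatenate(rpos), np.concatenate(qpos)

    def indel_events(self, min_len: int = 1):
        """[(ref_pos, kind, length, inserted_seq)] for I/D ops >= min_len."""
        out = []
        r, q = self.ref_start, 0
        for op, l in self.cigar:
            if op == "M":
                r += l
                q += l
            elif op == "D":
                if l >= min_len:
                    out.append((r, "D", l, ""))
                r += l
            elif op == "I":
                if l >= min_len:
                    seq = self.seq_codes[q:q + l]
                    out.append((r, "I", l, _codes_to_str(seq)))
                q += l
            elif op == "S":
                q += l
        return out

    def column_votes(self, start: int, end: int, edge_trim: int = 0):
        """Votes restricted to reference window [start, end).

        Returns ``(match_ref_pos, match_codes, del_spans, insertions)``
        where del_spans are (s, e) reference intervals and insertions are
        (ref_pos, seq).  ``edge_trim`` suppresses the first and last few
        aligned columns of the read, where terminal micro-matches across
        unrecognized breakpoints would otherwise cast spurious votes.
        """
        if edge_trim:
            start = max(start, self.ref_start + edge_trim)
            end = min(end, self.ref_end - edge_trim)
            if end <= start:
                return (np.zeros(0, np.int64), np.zeros(0, np.int8), [], [])
        rpos, qpos = self.matched_columns()
        sel = (rpos >= start) & (rpos < end)
        dels, ins = [], []
        for p, kind, l, seq in self.indel_events():
            if kind == "D":
                s, e = max(p, start), min(p + l, end)
                if s < e:
                    dels.append((s, e))
            elif start < p < end or (p == start == 0):
                ins.append((p, seq))
        return rpos[sel], self.seq_codes[qpos[sel]], dels, ins

    def base_at(self, positions: np.ndarray) -> np.ndarray:
        """Base codes at the given reference positions (4 = not aligned)."""
        rpos, qpos = self.matched_columns()
        out = np.full(len(positions), 4, dtype=np.int8)
        idx = np.searchsorted(rpos, positions)
        ok = (idx < len(rpos))
        ok[ok] &= rpos[idx[ok]] == positions[ok]
        out[ok] = self.seq_codes[qpos[idx[ok]]]
        return out


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes.astype(np.uint8)].tobytes().decode()


def map_reads(reads, ref: LocusReference, preset: str = "map-hifi",
              keep_sam: str = None):
    """Map simulated/loaded reads to the custom reference.

    ``reads`` is a list of objects with ``read_id``, ``sequence``,
    ``n_passes``, ``truth_haplotype`` and optional ``barcode``.  Returns a
    list of :class:`ReadAlignment` sorted by reference start, with split
    alignments stitched.  Unmapped reads are dropped.
    """
    meta = {r.read_id: r for r in reads}
    with tempfile.TemporaryDirectory() as tmp:
        ref_fa = os.path.join(tmp, "ref.fa")
        with open(ref_fa, "w") as f:
            f.write(f">{ref.seq_id}\n{ref.sequence}\n")
        reads_fa = os.path.join(tmp, "reads.fa")
        with open(reads_fa, "w") as f:
            for r in reads:
                f.write(f">{r.read_id}\n{r.sequence}\n")
        sam = keep_sam or os.path.join(tmp, "out.sam")
        with open(sam, "w") as out:
            subprocess.run(
                ["minimap2", "-a", "-x", preset, "-t", "1",
                 "--secondary=no", ref_fa, reads_fa],
                stdout=out, stderr=subprocess.DEVNULL, check=True)
        parts = _parse_sam(sam)
    alns = stitch_alignments(parts)
    ref_codes = seq_to_codes(ref.sequence)
    for a in alns:
        left_align_indels(a, ref_codes)
        m = meta.get(a.name)
        if m is not None:
            a.n_passes = m.n_passes
            a.truth_hap = m.truth_haplotype
            a.barcode = getattr(m, "barcode", None)
    alns.sort(key=lambda a: (a.ref_start, a.name))
    return alns


def _parse_sam(path: str):
    """Raw alignment segments grouped by read name."""
    parts = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            # full-read query offsets (account for hard clips)
            cig = rec.cigartuples
            lead = 0
            if cig and cig[0][0] in (4, 5):
                lead = cig[0][1]
            tail = 0
            if cig and cig[-1][0] in (4, 5) and len(cig) > 1:
                tail = cig[-1][1]
            qlen_aln = sum(l for op, l in cig if op in (0, 1, 7, 8))
            ops = []
            for op, l in cig:
                if op in (0, 7, 8):
                    ops.append(("M", l))
                elif op == 1:
                    ops.append(("I", l))
                elif op in (2, 3):
                    ops.append(("D", l))
            seq = rec.query_sequence or ""
            parts.setdefault(rec.query_name, []).append({
                "name": rec.query_name,
                "strand": "-" if rec.is_reverse else "+",
                "ref_start": rec.reference_start,
                "ref_end": rec.reference_end,
                "q_start": lead,
                "q_end": lead + qlen_aln,
                "ops": ops,
                "seq": seq if not rec.is_supplementary else None,
                "full_len": lead + qlen_aln + tail,
                "is_supp": rec.is_supplementary,
            })
    return parts


def stitch_alignments(parts: dict):
    """Join colinear primary + supplementary segments of each read.

    Segments on the same strand whose query and reference orders agree are
    merged with an I op for the skipped query bases and a D op for the
    skipped reference bases.  Non-colinear extra segments are discarded
    (the primary segment alone is kept).
    """
    out = []
    for name, segs in parts.items():
        primary = next((s for s in segs if not s["is_supp"]), None)
        if primary is None:
            continue
        full_seq = primary["seq"]
        segs = sorted(segs, key=lambda s: s["q_start"])
        chain = [segs[0]]
        ok = True
        for s in segs[1:]:
            prev = chain[-1]
            if s["strand"] != primary["strand"]:
                ok = False
                break
            qover = prev["q_end"] - s["q_start"]
            rover = prev["ref_end"] - s["ref_start"]
            if qover > 50 or rover > 50:
                ok = False
                break
            if qover > 0 or rover > 0:
                s = _trim_leading(s, prev["q_end"], prev["ref_end"])
                if s is None:
                    ok = False
                    break
            if s["ref_start"] - prev["ref_end"] > MAX_STITCH_GAP:
                ok = False
                break
            chain.append(s)
        if not ok or len(chain) == 1:
            chain = [primary]
        ops = []
        if chain[0]["q_start"]:
            ops.append(("S", chain[0]["q_start"]))
        ops.extend(chain[0]["ops"])
        for prev, s in zip(chain, chain[1:]):
            qgap = s["q_start"] - prev["q_end"]
            rgap = s["ref_start"] - prev["ref_end"]
            if qgap:
                ops.append(("I", qgap))
            if rgap:
                ops.append(("D", rgap))
            ops.extend(s["ops"])
        tail = primary["full_len"] - chain[-1]["q_end"]
        if tail:
            ops.append(("S", tail))
        ops = _merge_adjacent(ops)
        out.append(ReadAlignment(
            name=name,
            ref_start=chain[0]["ref_start"],
            strand=primary["strand"],
            cigar=ops,
            seq_codes=seq_to_codes(full_seq)))
    return out


def _trim_leading(seg, q_min, r_min):
    """Trim a supplementary segment's head so it starts at or after the
    previous segment's end in both query and reference coordinates."""
    ops = [list(o) for o in seg["ops"]]
    q, r = seg["q_start"], seg["ref_start"]
    i = 0
    while i < len(ops) and (q < q_min or r < r_min):
        op, l = ops[i]
        if op == "M":
            k = min(l, max(q_min - q, r_min - r))
            q += k
            r += k
            ops[i][1] -= k
        elif op == "I":
            k = min(l, q_min - q) if q < q_min else 0
            q += k
            ops[i][1] -= k
        else:  # D
            k = min(l, r_min - r) if r < r_min else 0
            r += k
            ops[i][1] -= k
        if ops[i][1] == 0:
            i += 1
        elif q >= q_min and r >= r_min:
            break
        else:
            return None     # stuck: op cannot absorb the deficit
    ops = [tuple(o) for o in ops[i:] if o[1] > 0]
    # alignments must not start with a gap op
    while ops and ops[0][0] in ("D", "I"):
        op, l = ops.pop(0)
        if op == "D":
            r += l
        else:
            q += l
    if not ops:
        return None
    new = dict(seg)
    new["ops"] = ops
    new["q_start"] = q
    new["ref_start"] = r
    return new


def left_align_indels(aln: ReadAlignment, ref_codes: np.ndarray):
    """Shift every I/D op leftward through repeated reference context.

    Different reads spanning the same breakpoint-ambiguous indel can
    place it at different (equivalent) positions; normalizing against the
    reference before voting makes consensus breakpoints consistent.  The
    shift rule uses reference context only (``ref[p-1] == ref[p+l-1]``
    for deletions, ``ref[p-1] == last inserted base`` for insertions), so
    all reads normalize identically.
    """
    cig = aln.cigar
    changed = False
    r = aln.ref_start
    q = 0
    new = []
    for idx, (op, l) in enumerate(cig):
        if op == "M":
            new.append([op, l])
            r += l
            q += l
        elif op == "S":
            new.append([op, l])
            q += l
        elif op == "D":
            shift = 0
            while (new and new[-1][0] == "M" and new[-1][1] > shift
                   and r - shift - 1 >= 0
                   and ref_codes[r - shift - 1] == ref_codes[r + l - shift - 1]):
                shift += 1
            if shift:
                changed = True
                new[-1][1] -= shift
                if new[-1][1] == 0:
                    new.pop()
                new.append(["D", l])
                new.append(["M", shift])
            else:
                new.append([op, l])
            r += l
        else:  # I
            shift = 0
            while (new and new[-1][0] == "M" and new[-1][1] > shift
                   and r - shift - 1 >= 0
                   and ref_codes[r - shift - 1]
                   == aln.seq_codes[q + l - shift - 1]):
                shift += 1
            if shift:
                changed = True
                new[-1][1] -= shift
                if new[-1][1] == 0:
                    new.pop()
                new.append(["I", l])
                new.append(["M", shift])
            else:
                new.append([op, l])
            q += l
    if changed:
        merged = []
        for op, l in new:
            if l <= 0:
                continue
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + l)
            else:
                merged.append((op, l))
        aln.cigar = merged
    return aln


def _merge_adjacent(ops):
    merged = []
    for op, l in ops:
        if l <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + l)
        else:
            merged.append((op, l))
    return merged


def write_tagged_sam(alignments, ref: LocusReference, partition: dict,
                     path: str):
    """Write alignments as SAM with the haplotype in the HP tag
    (0 = unassigned)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.seq_id, "LN": len(ref.sequence)}],
        "RG": [{"ID": f"hap{h}", "SM": "sample"} for h in (0, 1, 2)],
    })
    opmap = {"M": 0, "I": 1, "D": 2, "S": 4}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = a.name
            rec.query_sequence = _codes_to_str(a.seq_codes)
            rec.flag = 16 if a.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = a.ref_start
            rec.mapping_quality = 60
            rec.cigartuples = [(opmap[op], l) for op, l in a.cigar]
            hp = partition.get(a.name, 0)
            rec.set_tag("HP", int(hp))
            rec.set_tag("RG", f"hap{hp}")
            rec.set_tag("np", int(a.n_passes))
            out.write(rec)
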