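"""Pairwise sequence alignment primitives.

Three layers, used by assembly, variant detection and evaluation:

* :func:`affine_align` — exact global alignment with affine gap costs
  (Gotoh), suitable for sequences up to a few kb.  A gap of length ``k``
  costs ``gap_open + k * gap_extend``.
* :func:`edlib_ops` — unit-cost global/infix alignment via edlib, used
  where only the edit path matters (consensus polishing, overlap checks).
* :func:`anchor_align` — global alignment of long, mostly-colinear
  sequences: unique-k-mer anchors are chained colinearly and the gaps
  between anchors are filled with :func:`affine_align` (small gaps) or
  edlib (large gaps).  Handles multi-kb indels between anchors directly.

Alignments are op lists ``[(op, length), ...]`` with ops ``=`` (match),
``X`` (mismatch), ``I`` (present in query only) and ``D`` (present in
reference only).  Query is the first argument, reference the second.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

__all__ = [
    "affine_align", "edlib_ops", "anchor_align", "ops_to_events",
    "left_normalize", "merge_nearby_events", "identity_from_ops",
]

_CIG_RE = re.compile(r"(\d+)([=XIDM])")

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def affine_align(query: str, ref: str, match: int = 1, mismatch: int = -2,
                 gap_open: int = -4, gap_extend: int = -1):
    """Optimal global affine-gap alignment (Gotoh).

    Returns ``(score, ops)``.  Ties are broken toward the diagonal and then
    toward gaps in the reference, which places gaps leftmost after the
    event normalization used downstream.  Intended for sequences up to a
    few kb (quadratic memory).
    """
    n, m = len(query), len(ref)
    if n == 0 and m == 0:
        return 0, []
    if n == 0:
        return gap_open + gap_extend * m, [("D", m)]
    if m == 0:
        return gap_open + gap_extend * n, [("I", n)]
    if n * m > 64_000_000:
        raise ValueError("sequences too long for quadratic alignment")

    qa = seq_to_codes(query)
    ra = seq_to_codes(ref)
    NEG = -(10 ** 9)
    # rows over query (i), columns over ref (j)
    M = np.full(m + 1, NEG, dtype=np.int64)
    Ix = np.full(m + 1, NEG, dtype=np.int64)  # gap in ref (consumes query)
    Iy = np.full(m + 1, NEG, dtype=np.int64)  # gap in query (consumes ref)
    M[0] = 0
    Iy[1:] = gap_open + gap_extend * np.arange(1, m + 1)
    # pointer codes: bit-packed per matrix
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag-M,1 diag-Ix,2 diag-Iy
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 open-from-M,1 extend
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    # boundary gap runs extend themselves back to the origin
    ptrY[0, 2:] = 1
    ptrX[2:, 0] = 1

    for i in range(1, n + 1):
        subst = np.where(ra == qa[i - 1], match, mismatch)
        prevM, prevIx, prevIy = M.copy(), Ix.copy(), Iy.copy()
        # Ix: vertical gap (consumes query base i)
        openx = prevM + gap_open + gap_extend
        extx = prevIx + gap_extend
        Ix = np.maximum(openx, extx)
        ptrX[i] = (extx > openx).astype(np.int8)
        # M: diagonal
        diag_candidates = np.stack([prevM[:-1], prevIx[:-1], prevIy[:-1]])
        best = diag_candidates.argmax(axis=0)
        Mnew = np.full(m + 1, NEG, dtype=np.int64)
        Mnew[1:] = diag_candidates.max(axis=0) + subst
        ptrM[i, 1:] = best.astype(np.int8)
        M = Mnew
        # Iy: horizontal gap (consumes ref base j) — sequential scan
        Iy = _horizontal_pass(M, gap_open, gap_extend, ptrY[i])

    # traceback
    i, j = n, m
    end_scores = (M[m], Ix[m], Iy[m])
    state = int(np.argmax(end_scores))
    score = int(end_scores[state])
    ops = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("=" if qa[i - 1] == ra[j - 1] else "X")
            state = int(ptrM[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("I")
            state = 1 if ptrX[i, j] else 0
            i -= 1
        else:
            ops.append("D")
            state = 2 if ptrY[i, j] else 0
            j -= 1
    ops.reverse()
    return score, _rle(ops)


def _horizontal_pass(M, gap_open, gap_extend, ptr_row):
    m = len(M) - 1
    Iy = np.full(m + 1, -(10 ** 9), dtype=np.int64)
    cur = -(10 ** 18)
    for j in range(1, m + 1):
        opn = M[j - 1] + gap_open + gap_extend
        ext = cur + gap_extend
        if ext > opn:
            cur = ext
            ptr_row[j] = 1
        else:
            cur = opn
            ptr_row[j] = 0
        Iy[j] = cur
    return Iy


def _rle(ops):
    out = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1][1] += 1
        else:
            out.append([op, 1])
    return [(o, l) for o, l in out]


def edlib_ops(query: str, ref: str, mode: str = "NW"):
    """Unit-cost alignment path from edlib as an op list."""
    if not query and not ref:
        return [], 0, len(ref)
    if not query:
        return [("D", len(ref))], 0, len(ref)
    if not ref:
        return [("I", len(query))], 0, 0
    res = edlib.align(query, ref, mode=mode, task="path")
    ops = []
    for num, op in _CIG_RE.findall(res["cigar"]):
        ops.append((op, int(num)))
    start = res["locations"][0][0] if mode != "NW" else 0
    end = res["locations"][0][1] + 1 if mode != "NW" else len(ref)
    return ops, start, end


def _unique_kmer_positions(codes: np.ndarray, k: int):
    """Hash positions of k-mers occurring exactly once."""
    if len(codes) < k:
        return {}
    # 2-bit packed hash; exact for k <= 31
    c = codes.astype(np.int64)
    bad = c >= 4
    if bad.any():
        c = np.where(bad, 0, c)
        win_bad = np.convolve(bad.astype(np.int8), np.ones(k, dtype=np.int8),
                              "valid") > 0
    else:
        win_bad = None
    h = np.zeros(len(c) - k + 1, dtype=np.int64)
    for i in range(k):
        h = h * 4 + c[i:len(c) - k + 1 + i]
    order = np.argsort(h, kind="stable")
    hs = h[order]
    uniq_mask = np.ones(len(hs), dtype=bool)
    dup = hs[1:] == hs[:-1]
    uniq_mask[1:] &= ~dup
    uniq_mask[:-1] &= ~dup
    out = {}
    for idx in order[uniq_mask]:
        if win_bad is None or not win_bad[idx]:
            out[int(h[idx])] = int(idx)
    return out


def anchor_align(query: str, ref: str, k: int = 32, small_gap: int = 400):
    """Global alignment of long colinear sequences via unique-k-mer anchors.

    Gaps between consecutive anchors are filled with :func:`affine_align`
    when both sides are at most ``small_gap`` long, otherwise with edlib
    (or emitted as pure indels when one side is empty).  Returns an op
    list covering both sequences end to end.
    """
    if len(query) < 2 * k or len(ref) < 2 * k:
        return _fill(query, ref, small_gap)
    qk = _unique_kmer_positions(seq_to_codes(query), k)
    rk = _unique_kmer_positions(seq_to_codes(ref), k)
    shared = [(rk[h], q) for h, q in qk.items() if h in rk]
    shared.sort()
    # longest chain increasing in query position (patience-style LIS)
    if shared:
        qpos = [q for _, q in shared]
        chain_idx = _lis(qpos)
        chain = [shared[i] for i in chain_idx]
        # enforce non-overlap of anchors on both sequences
        filt = []
        last_r = last_q = -k
        for r, q in chain:
            if r >= last_r + k and q >= last_q + k:
                filt.append((r, q))
                last_r, last_q = r, q
        chain = filt
    else:
        chain = []
    if not chain:
        return _fill(query, ref, small_gap)

    ops = []
    pq = pr = 0
    for r, q in chain:
        ops.extend(_fill(query[pq:q], ref[pr:r], small_gap))
        ops.append(("=", k))
        pq, pr = q + k, r + k
    ops.extend(_fill(query[pq:], ref[pr:], small_gap))
    return _merge_runs(ops)


def _lis(seq):
    """Indices of a longest strictly-increasing subsequence."""
    import bisect
    tails, tails_idx, prev = [], [], [-1] * len(seq)
    for i, x in enumerate(seq):
        j = bisect.bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tails_idx.append(i)
        else:
            tails[j] = x
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def _fill(q: str, r: str, small_gap: int):
    if not q and not r:
        return []
    if not q:
        return [("D", len(r))]
    if not r:
        return [("I", len(q))]
    if len(q) <= small_gap and len(r) <= small_gap:
        return affine_align(q, r)[1]
    ops, _, _ = edlib_ops(q, r, mode="NW")
    return ops


def _merge_runs(ops):
    out = []
    for op, l in ops:
        if l == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + l)
        else:
            out.append((op, l))
    return out


# ---------------------------------------------------------------------------
# event extraction


def ops_to_events(ops, query: str, ref: str, ref_offset: int = 0):
    """Turn an op list into substitution and indel events.

    Returns ``(snvs, indels)`` where snvs are ``(ref_pos, ref_base,
    alt_base)`` and indels are ``(ref_pos, ref_allele, alt_allele)`` with
    one side empty for pure insertions/deletions.  ``ref_pos`` is the
    position of the first affected reference base (for insertions, the
    base before which the insertion occurs).
    """
    snvs, indels = [], []
    qi = ri = 0
    for op, l in ops:
        if op in ("=", "M"):
            qi += l
            ri += l
        elif op == "X":
            for t in range(l):
                snvs.append((ref_offset + ri + t, ref[ri + t], query[qi + t]))
            qi += l
            ri += l
        elif op == "I":
            indels.append((ref_offset + ri, "", query[qi:qi + l]))
            qi += l
        elif op == "D":
            indels.append((ref_offset + ri, ref[ri:ri + l], ""))
            ri += l
        else:
            raise ValueError(f"unknown op {op!r}")
    return snvs, indels


def left_normalize(pos: int, ref_allele: str, alt_allele: str, refseq: str):
    """Shift a pure insertion/deletion left through repeated context.

    Standard VCF-style normalization: while the base before the event
    equals the last base of the varying sequence, rotate the event one
    base left.  Substitutions and complex events are returned unchanged.
    """
    if ref_allele and alt_allele:
        return pos, ref_allele, alt_allele
    var = ref_allele or alt_allele
    if not var:
        return pos, ref_allele, alt_allele
    while pos > 0 and refseq[pos - 1] == var[-1]:
        var = refseq[pos - 1] + var[:-1]
        pos -= 1
    if ref_allele:
        return pos, var, ""
    return pos, "", var


def merge_nearby_events(indels, refseq: str, query_lookup=None,
                        min_separation: int = 10):
    """Merge indel events separated by fewer than ``min_separation``
    matched reference columns into one replacement event.

    ``indels`` are ``(ref_pos, ref_allele, alt_allele)`` sorted by
    position.  Merged events get ref allele = reference span between the
    outermost breakpoints and alt allele = concatenation of the intervening
    reference sequence and the inserted sequences in order.
    """
    if not indels:
        return []
    out = [list(indels[0])]
    for pos, ra, aa in indels[1:]:
        ppos, pra, paa = out[-1]
        prev_ref_end = ppos + len(pra)
        if pos - prev_ref_end < min_separation:
            between = refseq[prev_ref_end:pos]
            out[-1] = [ppos, pra + between + ra, paa + between + aa]
        else:
            out.append([pos, ra, aa])
    return [tuple(e) for e in out]


def classify_event(ref_allele: str, alt_allele: str):
    """Size-classify an indel/SV event.

    Event length is ``|len(ref) - len(alt)|`` for pure events and
    ``max(len(ref), len(alt))`` for balanced replacements.  Returns
    ``(type, size_class)`` with type in {"indel", "SV"} and size_class in
    {1, "2-49", ">=50"}; 1 bp events keep type "indel" with size_class 1.
    """
    if len(ref_allele) != len(alt_allele):
        length = abs(len(ref_allele) - len(alt_allele))
    else:
        length = max(len(ref_allele), len(alt_allele))
    if length >= 50:
        return "SV", ">=50"
    if length >= 2:
        return "indel", "2-49"
    return "indel", 1


def identity_from_ops(ops):
    """Fraction of alignment columns that are matches."""
    total = sum(l for _, l in ops)
    if total == 0:
        return 1.0
    return sum(l for op, l in ops if op == "=") / total
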