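"""Call-set comparison and validation machinery.

Implements the arithmetic behind every benchmark the pipeline reports:
SNV/indel call-set concordance with genotype-discordance accounting,
truth derivation from haplotype alignment, Mendelian trio checks, phase
switch errors, assembly concordance with homopolymer-indel
classification, an exact Hardy-Weinberg equilibrium test, accessibility
partitioning, imputation signal-to-noise, and the multiplex downsampling
sweep.

Genotypes are compared as unordered allele multisets, so phased and
unphased representations of the same genotype agree.  A query variant
that matches a truth position but disagrees in genotype is *discordant*
and counts as both a false positive and a false negative, never as a
true positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ComparisonReport", "compare_callsets",
    "derive_truth_from_haplotype_alignment", "mendelian_check",
    "switch_error_count", "assembly_concordance", "hwe_exact_test",
    "hwe_chi2_test", "accessibility_partition", "imputation_comparison",
    "multiplex_sweep",
]


@dataclass
class ComparisonReport:
    true_positives: int = 0
    false_positives: int = 0
    false_negatives: int = 0
    genotype_discordant: int = 0
    unmappable: int = 0
    stratifications: dict = field(default_factory=dict)

    @property
    def recall(self):
        t = self.true_positives + self.false_negatives
        return self.true_positives / t if t else float("nan")

    @property
    def precision(self):
        t = self.true_positives + self.false_positives
        return self.true_positives / t if t else float("nan")


def _norm(rec):
    """(pos, ref, alt, allele-multiset) from a VariantCall, TruthVariant
    or plain (pos, ref, alt, genotype) tuple."""
    if isinstance(rec, tuple):
        pos, ra, aa, gt = rec
    else:
        pos = rec.start
        ra = rec.ref_allele
        aa = rec.alt_allele
        gt = rec.genotype
    alleles = tuple(sorted(gt.replace("|", "/").split("/")))
    return int(pos), ra, aa, alleles


def compare_callsets(query, truth, liftover=None, stratify=None):
    """Concordance of a query call set against a truth set.

    A query record is a true positive iff position and alleles match a
    truth record AND the genotype allele multisets agree; a haploid
    genotype matching either allele of a het truth genotype also agrees.
    Matched-position records with different genotypes are discordant and
    count toward both FP and FN.  When ``liftover`` is given (a callable
    returning None for unmappable positions) unmappable query records go
    to a separate bucket, not to FP.
    """
    rep = ComparisonReport()
    tmap = {}
    for t in truth:
        pos, ra, aa, alleles = _norm(t)
        tmap[(pos, ra, aa)] = alleles
    seen = set()
    for q in query:
        pos, ra, aa, alleles = _norm(q)
        if liftover is not None and liftover(pos) is None:
            rep.unmappable += 1
            continue
        key = (pos, ra, aa)
        if key in tmap:
            seen.add(key)
            if _gt_agree(alleles, tmap[key]):
                rep.true_positives += 1
                if stratify is not None:
                    s = stratify(q)
                    rep.stratifications[s] = rep.stratifications.get(s, 0) + 1
            else:
                rep.genotype_discordant += 1
                rep.false_positives += 1
                rep.false_negatives += 1
        else:
            rep.false_positives += 1
    for key in tmap:
        if key not in seen:
            rep.false_negatives += 1
    return rep


def _gt_agree(a, b):
    if a == b:
        return True
    # haploid call against diploid truth (hemizygous region): one allele
    if len(a) == 1 and a[0] in b:
        return True
    if len(b) == 1 and b[0] in a:
        return True
    return False


def derive_truth_from_haplotype_alignment(hap_a: str, hap_b: str,
                                          offset: int = 0):
    """Truth SNVs as the mismatch columns of a haplotype alignment.

    Aligns the two sequences end to end and emits ``(pos, base_a,
    base_b)`` for every substitution column, with ``pos`` on ``hap_a``
    coordinates plus ``offset``.
    """
    from .align import anchor_align, ops_to_events
    ops = anchor_align(hap_b, hap_a)
    snvs, _ = ops_to_events(ops, hap_b, hap_a, ref_offset=offset)
    return [(p, rb, ab) for p, rb, ab in snvs]


def mendelian_check(child: dict, mother: dict, father: dict):
    """Sites where no parental transmission explains the child genotype.

    Arguments map position -> genotype string; only positions present in
    all three maps are testable.  Returns the violating positions.
    """
    violations = []
    for pos in sorted(set(child) & set(mother) & set(father)):
        c = child[pos].replace("|", "/").split("/")
        m = mother[pos].replace("|", "/").split("/")
        f = father[pos].replace("|", "/").split("/")
        if len(c) == 1:
            ok = c[0] in m or c[0] in f
        else:
            ok = any(sorted((a, b)) == sorted(c) for a in m for b in f)
        if not ok:
            violations.append(pos)
    return violations


def switch_error_count(inferred, truth_phase: dict):
    """Phase switch errors of one block against truth.

    ``inferred`` is a sequence of (position, haplotype carrying the alt)
    pairs — e.g. ``(s.position, s.phase)`` from PhasedSNVs; ``truth_phase``
    maps position -> haplotype carrying the alt in truth.  The count is
    the number of adjacent evaluated-site pairs whose relative phase
    flips, minimized over the two orientations of the block labels (a
    global relabeling is not an error).
    """
    agree = []
    for pos, hap in sorted(inferred):
        if pos in truth_phase:
            agree.append(1 if hap == truth_phase[pos] else 0)
    if len(agree) < 2:
        return 0
    # inverting the block labels inverts every agreement indicator, which
    # leaves the flip count unchanged — the orientation minimum is implicit
    return sum(1 for a, b in zip(agree, agree[1:]) if a != b)


def assembly_concordance(assembly: str, truth: str):
    """Base-level concordance of an assembly against an orthogonal
    sequence.

    Returns accuracy (matches / alignment columns), substitution count,
    indel events with lengths, and the fraction of 1–2 bp indels in or
    adjacent to a homopolymer run (>= 3 equal bases).
    """
    from .align import anchor_align, ops_to_events
    ops = anchor_align(assembly, truth)
    total = sum(l for _, l in ops)
    matches = sum(l for op, l in ops if op == "=")
    subs = sum(l for op, l in ops if op == "X")
    snvs, indels = ops_to_events(ops, assembly, truth)
    small = [e for e in indels if len(e[1] or e[2]) <= 2]
    in_hp = 0
    for pos, ra, aa in small:
        if _near_homopolymer(truth, pos, len(ra)):
            in_hp += 1
    return {
        "accuracy": matches / total if total else 1.0,
        "substitutions": subs,
        "indels": [(p, len(r), len(a)) for p, r, a in indels],
        "homopolymer_fraction": in_hp / len(small) if small else float("nan"),
    }


def _near_homopolymer(seq: str, pos: int, del_len: int, min_run: int = 3):
    lo = max(0, pos - min_run)
    hi = min(len(seq), pos + max(del_len, 1) + min_run)
    window = seq[lo:hi]
    run, prev = 1, ""
    for ch in window:
        if ch == prev:
            run += 1
            if run >= min_run:
                return True
        else:
            run, prev = 1, ch
    return False


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test.

    The p-value is the sum of probabilities, over all heterozygote counts
    compatible with the observed allele counts, of tables as or more
    extreme (probability <= that of the observed table).  A monomorphic
    site returns 1 by convention.
    """
    for n in (n_hom_ref, n_het, n_hom_alt):
        if n < 0:
            raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty sample")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0
    # probabilities over het counts with the same parity as `rare`
    probs = {}
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    h = mid
    while h >= 2:
        nr = (rare - h) // 2
        nc = (2 * n - rare - h) // 2
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (nr + 1) * (nc + 1))
        h -= 2
    h = mid
    while h <= rare - 2 and (2 * n - rare - h) >= 2:
        nr = (rare - h) // 2
        nc = (2 * n - rare - h) // 2
        probs[h + 2] = probs[h] * 4.0 * nr * nc / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12))
    return min(1.0, p / total)


def hwe_chi2_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square HWE test (1 df), available as the asymptotic option."""
    from scipy import stats
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty sample")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# partitions and ratios


def accessibility_partition(positions, mask_intervals):
    """Counts of positions inside / outside sorted mask intervals."""
    if not mask_intervals:
        return 0, len(list(positions))
    starts = np.array([s for s, _ in mask_intervals])
    ends = np.array([e for _, e in mask_intervals])
    pos = np.asarray(list(positions), dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(pos), dtype=bool)
    inside[ok] = pos[ok] < ends[idx[ok]]
    return int(inside.sum()), int((~inside).sum())


def imputation_comparison(query, imputed_by_threshold: dict):
    """Overlap accounting against imputed call sets at hard-call
    thresholds; snr = overlap / imputed-only (inf when imputed-only is 0).
    """
    q = set(query)
    out = {}
    for thr, imputed in imputed_by_threshold.items():
        s = set(imputed)
        overlap = len(q & s)
        imp_only = len(s - q)
        out[thr] = {
            "overlap": overlap,
            "imputed_only": imp_only,
            "query_only": len(q - s),
            "snr": overlap / imp_only if imp_only else math.inf,
        }
    return out


def assembly_identity_vs_truth(contigs, truth):
    """Weighted identity of consensus contigs against the truth
    haplotypes.

    Both a contig and a truth haplotype are exact edit sets on the custom
    reference, so their alignment can be composed through the reference:
    the error bases of a contig against a haplotype are the symmetric
    difference of the two (left-normalized) edit sets over the contig
    span.  Each contig scores against its better-matching haplotype
    (block hap labels are arbitrary); the return value is the
    length-weighted mean identity.  Exact for sparse, non-overlapping
    edits — the regime of a high-accuracy consensus.
    """
    from .align import left_normalize, seq_to_codes
    ref_seq = truth.ref.sequence
    refcodes = seq_to_codes(ref_seq)
    truth_edits = {}
    truth_big_dels = {}
    for h in (1, 2):
        ed = {}
        big = []
        for v in truth.hap_edits(h):
            p, ra, aa = left_normalize(v.start, v.ref_allele, v.alt_allele,
                                       ref_seq)
            if not aa and len(ra) >= 50:
                big.append((p, p + len(ra)))
            else:
                ed[(p, ra, aa)] = max(len(ra), len(aa))
        truth_edits[h] = ed
        truth_big_dels[h] = big
    total_len = 0
    total_err = 0
    for c in contigs:
        ed = {}
        big_c = []
        mism = np.flatnonzero(c.col_code != refcodes[c.col_ref])
        for i in mism:
            p = int(c.col_ref[i])
            ed[(p, ref_seq[p], "ACGT"[c.col_code[i]])] = 1
        for s, e in c.deletion_runs():
            p, ra, aa = left_normalize(s, ref_seq[s:e], "", ref_seq)
            if len(ra) >= 50:
                big_c.append((p, p + len(ra)))
            else:
                ed[(p, ra, aa)] = len(ra)
        for p, seq, _ in c.insertions:
            p2, ra, aa = left_normalize(p, "", seq, ref_seq)
            ed[(p2, ra, aa)] = len(aa)
        span = (c.ref_start, c.ref_end)
        best_err = None
        for h in (1, 2):
            th = {k: w for k, w in truth_edits[h].items()
                  if span[0] <= k[0] < span[1]}
            err = sum(w for k, w in ed.items() if k not in th)
            err += sum(w for k, w in th.items() if k not in ed)
            # large deletions are compared as interval sets clipped to the
            # contig span (a contig may begin or end inside one)
            err += _interval_symmetric_difference(
                big_c, truth_big_dels[h], span)
            if best_err is None or err < best_err:
                best_err = err
        total_len += len(c)
        total_err += best_err
    if total_len == 0:
        return float("nan")
    return 1.0 - total_err / total_len


def _interval_symmetric_difference(a, b, span):
    """Total length of the symmetric difference of two interval sets,
    clipped to ``span``."""
    s0, e0 = span
    if e0 <= s0:
        return 0
    marks = np.zeros(e0 - s0, dtype=np.int8)
    for s, e in a:
        s, e = max(s, s0), min(e, e0)
        if s < e:
            marks[s - s0:e - s0] |= 1
    for s, e in b:
        s, e = max(s, s0), min(e, e0)
        if s < e:
            marks[s - s0:e - s0] |= 2
    return int(np.sum((marks == 1) | (marks == 2)))


def truth_phase_map(truth):
    """position -> haplotype carrying the alt, for truth het SNVs."""
    out = {}
    for v in truth.variants:
        if v.type == "SNV" and v.is_het():
            out[v.start] = 1 if v.on_hap1 else 2
    return out


def multiplex_sweep(plex_readsets: dict, ref, db, truth, run_one,
                    sample_index: int = 0):
    """Run the pipeline per plex level and score against both the
    simulator truth and the highest-coverage run.

    ``run_one(reads)`` must execute the pipeline and return its result
    object.  Returns a per-plex table (list of dicts, ordered by plex).
    """
    rows = []
    results = {}
    truth_snvs = [v for v in truth.variants if v.type == "SNV"]
    for plex in sorted(plex_readsets):
        reads = plex_readsets[plex][sample_index]
        res = run_one(reads)
        results[plex] = res
        cov = sum(len(r.sequence) for r in reads) / len(ref.sequence)
        rep = compare_callsets(res.snv_calls, truth_snvs)
        rows.append({
            "plex": plex, "coverage": cov, "n_reads": len(reads),
            "n_snvs": len(res.snv_calls),
            "recall": rep.recall, "precision": rep.precision,
            "tp": rep.true_positives, "fp": rep.false_positives,
            "fp_rate": rep.false_positives / len(ref.sequence),
        })
    # score against the lowest-plex (highest coverage) run as reference
    ref_plex = min(results)
    ref_calls = [(v.start, v.ref_allele, v.alt_allele, v.genotype)
                 for v in results[ref_plex].snv_calls]
    for row in rows:
        rep = compare_callsets(results[row["plex"]].snv_calls, ref_calls)
        row["recall_vs_reference"] = rep.recall
        row["precision_vs_reference"] = rep.precision
    return rows
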