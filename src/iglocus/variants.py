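"""Variant detection from haplotype-resolved contigs.

SNVs are mismatch columns of the contig/reference alignment, genotyped
from the per-haplotype consensus alleles; every call carries the
annotations of the detect stage: source contig, overlapping embedded-SV
region, read-pileup support, gene feature class, V/D/J region class and
haplotype block.  Indels and SVs come from the projected alignments of
both haplotype consensuses against the reference and are sequence
resolved: the full alternate sequence is part of the call.  Events are
left-aligned; adjacent events separated by fewer than 10 matched columns
are merged before size classification (2–49 bp indels, >=50 bp SVs; 1 bp
events keep type "indel" with size class 1).

A putative V(D)J-like somatic deletion — a single-haplotype deletion of
at least 10 kb whose right edge abuts the J-proximal end of the locus —
is flagged, and calls within it are marked artifact-suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import classify_event, left_normalize, merge_nearby_events, \
    seq_to_codes
from .phasing import HET_CLASS

__all__ = ["VariantCall", "call_snvs", "call_indels_svs",
           "detect_vdj_artifact", "write_snv_vcf", "write_indel_sv_bed"]


@dataclass
class VariantCall:
    type: str                   # SNV | indel | SV
    start: int
    end: int                    # reference span (end == start for pure ins)
    ref_allele: str
    alt_allele: str
    genotype: str               # "0|1" phased, "0/1" unphased, "1" haploid
    size_class: object = None
    contig_id: str = ""
    sv_id: str = None
    ccs_support: bool = False
    feature_class: str = "intergenic"
    region_class: str = None
    gene_name: str = None
    block_id: str = ""
    phase_confident: bool = True
    vdj_suspect: bool = False
    qual: float = 0.0

    @property
    def alleles(self):
        """Unordered allele multiset of the genotype (for comparisons)."""
        return tuple(sorted(self.genotype.replace("|", "/").split("/")))

    def key(self):
        return (self.start, self.ref_allele, self.alt_allele)


class _HapIndex:
    """Locate the contig covering a position for each haplotype.

    Unphased (hap 0) contigs cover both haplotypes; locally phased pairs
    (phase_confident=False) act as haplotypes 1/2 of their own block.
    """

    def __init__(self, contigs):
        self.by_hap = {1: [], 2: []}
        for c in contigs:
            haps = (1, 2) if c.haplotype == 0 else (c.haplotype,)
            for h in haps:
                self.by_hap[h].append(c)
        for h in (1, 2):
            self.by_hap[h].sort(key=lambda c: c.ref_start)
            # prefer higher-QV contig where spans collide
        self.starts = {h: np.array([c.ref_start for c in self.by_hap[h]])
                       for h in (1, 2)}

    def covering(self, hap: int, pos: int):
        lst = self.by_hap[hap]
        i = int(np.searchsorted(self.starts[hap], pos, side="right")) - 1
        best = None
        while i >= 0:
            c = lst[i]
            if c.ref_start <= pos < c.ref_end:
                if best is None or _ctg_qv(c) > _ctg_qv(best):
                    best = c
            if pos - c.ref_start > 2_000_000:
                break
            i -= 1
        return best


def _ctg_qv(c):
    return float(np.mean(c.col_qv)) if len(c.col_qv) else 0.0


def _annotate(call: VariantCall, ref, blocks):
    gene, feat, region, sv_id = ref.annotate_position(
        min(call.start, len(ref.sequence) - 1))
    call.gene_name, call.feature_class = gene, feat
    call.region_class, call.sv_id = region, sv_id
    for b in blocks:
        if b.start <= call.start < b.end:
            call.block_id = b.block_id
            break
    return call


def call_snvs(contigs, ref, blocks, pileup=None, support_reads: int = 2,
              support_fraction: float = 0.1, min_alt_reads: int = 2):
    """SNVs from mismatch columns of the haplotype consensuses.

    ``pileup`` is the (L, 4) read base-count matrix; it drives the
    ``ccs_support`` annotation (alt seen in >= support_reads reads and >=
    support_fraction of the pileup) and, when ``min_alt_reads`` > 0, a
    read-backed floor that suppresses assembly-only calls.
    """
    refcodes = seq_to_codes(ref.sequence)
    hidx = _HapIndex(contigs)
    sites = {}
    for c in contigs:
        mism = np.flatnonzero(c.col_code != refcodes[c.col_ref])
        for i in mism:
            pos = int(c.col_ref[i])
            sites.setdefault(pos, [])
    out = []
    for pos in sorted(sites):
        alleles, covers, src = {}, {}, {}
        for h in (1, 2):
            c = hidx.covering(h, pos)
            if c is None:
                alleles[h] = None
                continue
            covers[h] = c
            alleles[h] = c.base_allele(pos)
            src[h] = c
        ref_base = ref.sequence[pos]
        alts = sorted({a for a in alleles.values()
                       if a is not None and a != ref_base})
        if not alts:
            continue
        alt = alts[0]          # biallelic model: first alt wins, rest flagged
        codes = {None: None, ref_base: "0", alt: "1"}
        g1 = codes.get(alleles.get(1), "1")
        g2 = codes.get(alleles.get(2), "1")
        ctgs = [covers.get(h) for h in (1, 2) if covers.get(h)]
        phase_conf = all(c.phase_confident for c in ctgs)
        same_block = len({c.block_id for c in ctgs}) == 1
        if g1 is None and g2 is None:
            continue
        if g1 is None or g2 is None:
            gt = g2 if g1 is None else g1
            if gt == "0":
                continue
        elif phase_conf and same_block:
            gt = f"{g1}|{g2}"
        else:
            gt = "/".join(sorted((g1, g2)))
        if "1" not in gt:
            continue
        supp_n = 0
        frac = 0.0
        if pileup is not None:
            col = pileup[pos]
            depth = int(col.sum())
            supp_n = int(col[seq_to_codes(alt)[0]])
            frac = supp_n / depth if depth else 0.0
        if pileup is not None and min_alt_reads and supp_n < min_alt_reads:
            continue
        call = VariantCall(
            "SNV", pos, pos + 1, ref_base, alt, gt,
            contig_id=",".join(sorted({c.contig_id for c in ctgs})),
            ccs_support=(supp_n >= support_reads and frac >= support_fraction),
            phase_confident=phase_conf,
            qual=float(np.mean([_ctg_qv(c) for c in ctgs])) if ctgs else 0.0)
        out.append(_annotate(call, ref, blocks))
    return out


def call_indels_svs(contigs, ref, blocks, alignments=None,
                    min_separation: int = 10, min_read_support: int = 0):
    """Sequence-resolved indels and SVs from the haplotype consensuses.

    Each contig's deletion runs and insertion records are merged
    (< ``min_separation`` matched columns apart), left-normalized and then
    matched across haplotypes to produce genotypes.  ``alignments``
    (optional) provides read-level corroboration for the ccs_support
    annotation.
    """
    per_hap_events = {}
    hidx = _HapIndex(contigs)
    for c in contigs:
        events = [(s, ref.sequence[s:e], "") for s, e in c.deletion_runs()]
        events += [(p, "", seq) for p, seq, _ in c.insertions]
        events.sort()
        events = merge_nearby_events(events, ref.sequence,
                                     min_separation=min_separation)
        for pos, ra, aa in events:
            pos, ra, aa = left_normalize(pos, ra, aa, ref.sequence)
            haps = (1, 2) if c.haplotype == 0 else (c.haplotype,)
            for h in haps:
                per_hap_events.setdefault((pos, ra, aa), {})[h] = c

    read_events = []
    if alignments:
        for a in alignments:
            for p, kind, l, seq in a.indel_events(min_len=1):
                ra = ref.sequence[p:p + l] if kind == "D" else ""
                aa = seq if kind == "I" else ""
                p2, ra2, aa2 = left_normalize(p, ra, aa, ref.sequence)
                read_events.append((p2, len(ra2), len(aa2)))
        read_events.sort()
    rpos = np.array([e[0] for e in read_events], dtype=np.int64)

    out = []
    for (pos, ra, aa), carriers in sorted(per_hap_events.items()):
        vtype, size_class = classify_event(ra, aa)
        gt_parts = {}
        ctgs = []
        for h in (1, 2):
            if h in carriers:
                gt_parts[h] = "1"
                ctgs.append(carriers[h])
            else:
                # reference-allele evidence: consensus bases across either
                # junction (a contig need not span a multi-kb event)
                gt_parts[h] = None
                windows = [(max(pos - 1, 0),
                            min(pos + min(len(ra) or 1, 25) + 1,
                                len(ref.sequence)))]
                if len(ra) > 50:
                    end_p = pos + len(ra)
                    windows.append((max(end_p - 26, 0),
                                    min(end_p + 1, len(ref.sequence))))
                for win_s, win_e in windows:
                    c = hidx.covering(h, win_s)
                    if c is None or not c.covers(win_s, win_e):
                        continue
                    lo, hi = np.searchsorted(c.col_ref, [win_s, win_e])
                    if hi - lo >= 0.8 * (win_e - win_s):
                        gt_parts[h] = "0"
                        ctgs.append(c)
                        break
        phase_conf = all(c.phase_confident for c in ctgs) and \
            len({c.block_id for c in ctgs}) == 1
        g1, g2 = gt_parts[1], gt_parts[2]
        if g1 is None and g2 is None:
            continue
        if g1 is None or g2 is None:
            gt = g1 if g2 is None else g2
        elif phase_conf:
            gt = f"{g1}|{g2}"
        else:
            gt = "/".join(sorted((g1, g2)))
        support_n = 0
        if len(rpos):
            lo = int(np.searchsorted(rpos, pos - 25))
            hi = int(np.searchsorted(rpos, pos + 25))
            for p2, rl, al in read_events[lo:hi]:
                if abs(rl - len(ra)) <= max(2, 0.2 * len(ra)) and \
                        abs(al - len(aa)) <= max(2, 0.2 * len(aa)):
                    support_n += 1
        if alignments is not None and min_read_support and \
                support_n < min_read_support:
            continue
        support = support_n >= 2
        call = VariantCall(
            vtype, pos, pos + len(ra), ra, aa, gt, size_class=size_class,
            contig_id=",".join(sorted({c.contig_id for c in carriers.values()})),
            ccs_support=support, phase_confident=phase_conf)
        out.append(_annotate(call, ref, blocks))
    out.sort(key=lambda v: (v.start, v.end))
    return out


def detect_vdj_artifact(calls, ref, coverage=None, min_len: int = 10_000,
                        edge_window: int = 25_000):
    """Flag a single-haplotype deletion abutting the J-proximal end.

    Returns the flagged reference interval or None; deletion and
    gene-loss calls within it are marked ``vdj_suspect`` in place.
    """
    j_genes = [g for g in ref.genes if g.segment_class == "J"]
    if j_genes:
        j_end = max(g.locus_interval.end for g in j_genes)
    else:
        j_end = len(ref.sequence)
    flagged = None
    for v in calls:
        if v.type != "SV" or v.alt_allele or len(v.ref_allele) < min_len:
            continue
        # single-haplotype loss: het genotype, or haploid evidence where
        # only the carrier haplotype could be assembled (hemizygous)
        if set(v.alleles) not in ({"0", "1"}, {"1"}):
            continue
        if v.alleles == ("1", "1"):
            continue
        if abs(v.end - j_end) <= edge_window or v.end >= j_end:
            if flagged is None or len(v.ref_allele) > (
                    flagged.end - flagged.start):
                flagged = v
    if flagged is None:
        return None
    flagged.vdj_suspect = True
    for v in calls:
        if v is flagged:
            continue
        if flagged.start <= v.start < flagged.end:
            v.vdj_suspect = True
    return (flagged.start, flagged.end)


# ---------------------------------------------------------------------------
# serialization


def write_snv_vcf(calls, seq_id: str, path: str):
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={seq_id}>\n")
        for k, d in (("CONTIG", "Source contig"),
                     ("SVREGION", "Overlapping embedded SV region"),
                     ("CCSSUPPORT", "Detected in read pileup"),
                     ("FEATURE", "Gene feature class"),
                     ("REGION", "V/D/J region class"),
                     ("BLOCK", "Haplotype block")):
            f.write(f'##INFO=<ID={k},Number=1,Type=String,Description="{d}">\n')
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in sorted(calls, key=lambda x: x.start):
            info = ";".join([
                f"CONTIG={v.contig_id or '.'}",
                f"SVREGION={v.sv_id or '.'}",
                f"CCSSUPPORT={'true' if v.ccs_support else 'false'}",
                f"FEATURE={v.feature_class}",
                f"REGION={v.region_class or '.'}",
                f"BLOCK={v.block_id or '.'}"])
            f.write(f"{seq_id}\t{v.start + 1}\t.\t{v.ref_allele}\t"
                    f"{v.alt_allele}\t{v.qual:.0f}\tPASS\t{info}\tGT\t"
                    f"{v.genotype}\n")


def write_indel_sv_bed(calls, seq_id: str, path: str):
    with open(path, "w") as f:
        for v in sorted(calls, key=lambda x: (x.start, x.end)):
            f.write("\t".join(map(str, (
                seq_id, v.start, v.end, v.type, v.size_class,
                v.ref_allele or ".", v.alt_allele or ".", v.genotype,
                v.contig_id or ".", int(v.vdj_suspect)))) + "\n")
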