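"""End-to-end pipeline orchestration and the summary bundle.

``run_pipeline`` drives the stages in order — read filtering, mapping,
het-SNV detection, read phasing, block tiling, haplotype assembly with
het-signature splitting and subread-pool retry, contig QV filtering,
variant calling, embedded-SV genotyping and allele typing — from a
single :class:`RunConfig` whose defaults are the pipeline's documented
thresholds.  All stage randomness flows from the config seed.

The file-based stage wrappers used by the CLI read and write only the
standard formats (FASTA/FASTQ/SAM/VCF/BED/TSV), so any stage can be
re-run from its serialized inputs.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import alleles as alleles_mod
from . import assembly as asm
from . import phasing as ph
from . import svgeno
from . import variants as var
from .mapping import map_reads, write_tagged_sam
from .reference import LocusReference
from .synthetic import AlleleDatabase

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_summary"]


@dataclass
class RunConfig:
    # phase stage
    min_subreads: int = 2
    min_depth: int = 10
    min_alt_fraction: float = 0.15
    max_alt_fraction: float = 0.75
    min_alt_count: int = 5
    # assembly stage
    min_overlap: int = 100
    min_identity: float = 0.8
    qv_min: float = 20.0
    merge_min_overlap_bp: int = 1000
    merge_max_mismatch_rate: float = 0.002
    merge_max_gap_bases: int = 20
    signature_lo: float = 0.2
    signature_hi: float = 0.85
    signature_min_support: int = 3
    edge_trim: int = 5
    tail_trim_depth: int = 4
    # detect stage
    ccs_support_reads: int = 2
    ccs_support_fraction: float = 0.1
    snv_min_alt_reads: int = 3
    indel_min_read_support: int = 3
    event_merge_separation: int = 10
    sv_min_len: int = 50
    # SV genotyping
    sv_span_frac: float = 0.8
    sv_depth_absent: float = 0.2
    sv_depth_present: float = 0.6
    # misc
    seed: int = 0
    minimap_preset: str = "map-hifi"

    def to_yaml(self, path: str):
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str):
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    ref: LocusReference
    config: RunConfig
    alignments: list
    kept_alignments: list
    pileup: np.ndarray
    coverage: np.ndarray
    het_candidates: list
    phased_snvs: list
    partition: dict
    blocks: list
    signatures: list
    bins: list
    contigs: list
    snv_calls: list
    indel_sv_calls: list
    sv_genotypes: list
    allele_calls: list
    vdj_interval: tuple
    summary: dict


def run_pipeline(ref: LocusReference, db: AlleleDatabase, reads,
                 config: RunConfig = None) -> PipelineResult:
    """Run every stage in memory and return the full result bundle."""
    cfg = config or RunConfig()
    kept_reads = [r for r in reads if r.n_passes >= cfg.min_subreads]
    kept_names = {r.read_id for r in kept_reads}
    alns = map_reads(reads, ref, preset=cfg.minimap_preset)
    kept = [a for a in alns if a.name in kept_names]

    counts, delcov = ph.pileup_counts(kept, len(ref.sequence))
    coverage = counts.sum(axis=1).astype(np.int32)
    aligned_cov = coverage + delcov

    cands = ph.detect_het_candidates(
        kept, ref.sequence, cfg.min_depth, cfg.min_alt_fraction,
        cfg.max_alt_fraction, counts=counts,
        min_alt_count=cfg.min_alt_count)
    phased, partition = ph.assign_reads(kept, cands)
    blocks = ph.define_blocks(phased, kept, partition, len(ref.sequence),
                              coverage=aligned_cov)

    avoid = indel_avoid_intervals(kept, min_support=cfg.signature_min_support)
    # gene bodies count as boundaries-to-avoid too: allele extraction
    # needs each gene covered by contigs of one phase domain
    gene_avoid = sorted(avoid + [(g.locus_interval.start - 50,
                                  g.locus_interval.end + 50)
                                 for g in ref.genes])
    _adjust_block_boundaries(blocks, gene_avoid)

    sigs = asm.find_het_signatures(
        kept, aligned_cov, lo=cfg.signature_lo, hi=cfg.signature_hi,
        min_support=cfg.signature_min_support)
    bins = asm.build_bins(blocks, kept, partition, sigs,
                          avoid_intervals=avoid)

    from .align import seq_to_codes
    ref_codes = seq_to_codes(ref.sequence)
    contigs = []
    for b in bins:
        contigs.extend(asm.assemble_block(
            b.reads, start=b.start, end=b.end, block_id=b.block_id,
            haplotype=b.haplotype, min_overlap=cfg.min_overlap,
            min_identity=cfg.min_identity, ref_codes=ref_codes,
            phase_confident=b.phase_confident, contig_prefix=b.bin_id,
            edge_trim=cfg.edge_trim, tail_trim_depth=cfg.tail_trim_depth))
    forbidden = [(s.position, s.position + 1) for s in phased] + \
        [s.span for s in sigs]
    extra, uncovered = asm.recruit_and_retry(
        contigs, alns, len(ref.sequence), forbidden=forbidden,
        min_overlap=cfg.min_overlap, min_identity=cfg.min_identity,
        ref_codes=ref_codes, edge_trim=cfg.edge_trim)
    contigs.extend(extra)
    contigs = asm.filter_contigs(contigs, qv_min=cfg.qv_min)

    snvs = var.call_snvs(contigs, ref, blocks, pileup=counts,
                         support_reads=cfg.ccs_support_reads,
                         support_fraction=cfg.ccs_support_fraction,
                         min_alt_reads=cfg.snv_min_alt_reads)
    indels = var.call_indels_svs(contigs, ref, blocks, alignments=kept,
                                 min_separation=cfg.event_merge_separation,
                                 min_read_support=cfg.indel_min_read_support)
    vdj = var.detect_vdj_artifact(indels, ref, coverage=coverage)
    svgts = svgeno.genotype_all(ref, contigs, coverage=coverage, snvs=snvs,
                                span_frac=cfg.sv_span_frac,
                                depth_absent=cfg.sv_depth_absent,
                                depth_present=cfg.sv_depth_present)
    allele_calls = alleles_mod.call_alleles(
        contigs, ref, db, reads=kept_reads, vdj_interval=vdj,
        het_positions=[s.position for s in phased])

    summary = build_summary(ref, coverage, blocks, contigs, snvs, indels,
                            svgts, allele_calls, vdj, uncovered)
    return PipelineResult(ref, cfg, alns, kept, counts, coverage, cands,
                          phased, partition, blocks, sigs, bins, contigs,
                          snvs, indels, svgts, allele_calls, vdj, summary)


def indel_avoid_intervals(alignments, min_support: int = 3,
                          margin: int = 25):
    """Reference intervals around read-supported indel clusters; block
    and carve boundaries are shifted out of these so no consensus is cut
    through an event footprint."""
    events = []
    for a in alignments:
        for p, kind, l, _ in a.indel_events(min_len=1):
            events.append((p, l if kind == "D" else 1))
    events.sort()
    out = []
    i = 0
    while i < len(events):
        p, l = events[i]
        j = i + 1
        hi = p + l
        n = 1
        while j < len(events) and events[j][0] <= hi + 20:
            hi = max(hi, events[j][0] + events[j][1])
            n += 1
            j += 1
        if n >= min_support:
            out.append((p - margin, hi + margin))
        i = j
    return out


def _adjust_block_boundaries(blocks, avoid):
    """Move block boundaries out of indel-event footprints.

    The whole event is pushed into the homozygous side where possible,
    because hom-block assembly resolves het events via carrier/non-carrier
    splitting, while het bins only contain phased reads.
    """
    for a, b in zip(blocks, blocks[1:]):
        p = a.end
        hit = next(((s, e) for s, e in avoid if s <= p < e), None)
        if hit is None:
            continue
        s, e = hit
        left_hom = a.cls == ph.HOM_CLASS
        right_hom = b.cls == ph.HOM_CLASS
        if right_hom and not left_hom:
            p = max(s, a.start + 1)
        elif left_hom and not right_hom:
            p = min(e, b.end - 1)
        elif left_hom and right_hom:
            p = s if (p - s) <= (e - p) else e
            p = min(max(p, a.start + 1), b.end - 1)
        else:
            p = min(e, b.end - 1)
        if p != a.end and a.start < p < b.end:
            a.end = p
            b.start = p


def build_summary(ref, coverage, blocks, contigs, snvs, indels, svgts,
                  allele_calls, vdj, uncovered):
    L = len(ref.sequence)
    depth_fracs = {d: float(np.mean(coverage >= d))
                   for d in (1, 5, 10, 20, 30)}
    by_class = {}
    for v in snvs:
        by_class[v.feature_class] = by_class.get(v.feature_class, 0) + 1
    indel_counts = {"1": 0, "2-49": 0, ">=50": 0}
    for v in indels:
        indel_counts[str(v.size_class)] = \
            indel_counts.get(str(v.size_class), 0) + 1
    novel = [c for c in allele_calls if c.status == "novel"]
    return {
        "locus_length": L,
        "mean_coverage": float(np.mean(coverage)),
        "coverage_fraction_at_depth": depth_fracs,
        "n_blocks": len(blocks),
        "n_het_blocks": sum(1 for b in blocks if b.cls == ph.HET_CLASS),
        "n_contigs": len(contigs),
        "assembled_bases": int(sum(len(c) for c in contigs)),
        "uncovered_intervals": uncovered,
        "n_snvs": len(snvs),
        "snvs_by_feature": by_class,
        "n_indels_2_49": indel_counts.get("2-49", 0),
        "n_svs": indel_counts.get(">=50", 0),
        "n_1bp_events": indel_counts.get("1", 0),
        "sv_genotypes": {g.sv_id: g.genotype for g in svgts},
        "n_genes": len(ref.genes),
        "n_novel_alleles": len(novel),
        "novel_alleles": [(c.gene_name, c.haplotype, c.allele_name)
                          for c in novel],
        "vdj_interval": vdj,
    }


def write_summary(summary: dict, path: str):
    """Plain-text summary page: coverage, variant counts, alleles."""
    lines = ["# Locus analysis summary", ""]
    lines.append(f"Locus length: {summary['locus_length']}")
    lines.append(f"Mean read coverage: {summary['mean_coverage']:.1f}x")
    lines.append("")
    lines.append("Fraction of locus at or above depth:")
    for d, frac in sorted(summary["coverage_fraction_at_depth"].items()):
        lines.append(f"  >= {d:>3}x : {frac:.4f}")
    lines.append("")
    lines.append(f"Haplotype blocks: {summary['n_blocks']} "
                 f"({summary['n_het_blocks']} heterozygous)")
    lines.append(f"Contigs: {summary['n_contigs']} "
                 f"({summary['assembled_bases']} bases)")
    lines.append("")
    lines.append(f"SNVs: {summary['n_snvs']}")
    for feat, n in sorted(summary["snvs_by_feature"].items()):
        lines.append(f"  {feat:<12} {n}")
    lines.append(f"Indels (2-49 bp): {summary['n_indels_2_49']}")
    lines.append(f"SVs (>=50 bp): {summary['n_svs']}")
    lines.append(f"1 bp events: {summary['n_1bp_events']}")
    lines.append("")
    lines.append("Embedded SV genotypes:")
    for sv_id, gt in sorted(summary["sv_genotypes"].items()):
        lines.append(f"  {sv_id}: {gt}")
    lines.append("")
    lines.append(f"Genes annotated: {summary['n_genes']}")
    lines.append(f"Novel alleles: {summary['n_novel_alleles']}")
    for gene, hap, nearest in summary["novel_alleles"]:
        lines.append(f"  {gene} hap{hap} (nearest {nearest})")
    if summary.get("vdj_interval"):
        s, e = summary["vdj_interval"]
        lines.append("")
        lines.append(f"Putative V(D)J-like somatic deletion: [{s}, {e})")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contig serialization (FASTA + SAM-like alignment record)


def write_contig_fasta(contigs, path: str):
    with open(path, "w") as f:
        for c in sorted(contigs, key=lambda c: (c.ref_start, c.contig_id)):
            f.write(f">{c.contig_id} block={c.block_id} hap={c.haplotype} "
                    f"qv={c.mean_qv:.1f} phase_confident="
                    f"{int(c.phase_confident)}\n{c.sequence}\n")


def write_contig_sam(contigs, ref, path: str):
    import pysam
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.seq_id, "LN": len(ref.sequence)}],
    })
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for c in sorted(contigs, key=lambda c: (c.ref_start, c.contig_id)):
            rec = pysam.AlignedSegment(header)
            rec.query_name = c.contig_id
            rec.reference_id = 0
            rec.reference_start = c.ref_start
            rec.mapping_quality = 60
            cig, seq, quals = _contig_cigar(c)
            rec.query_sequence = seq
            rec.cigartuples = cig
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(93, int(round(q))) + 33) for q in quals))
            rec.set_tag("ZB", c.block_id)
            rec.set_tag("HP", int(c.haplotype))
            rec.set_tag("ZP", int(c.phase_confident))
            out.write(rec)


def _contig_cigar(c):
    ops = []
    seq_parts = []
    quals = []
    ins = sorted(c.insertions)
    ii = 0
    prev_col = None
    i = 0
    n = len(c.col_ref)
    while i < n:
        # insertion before this column?
        while ii < len(ins) and ins[ii][0] <= c.col_ref[i]:
            p, s, qv = ins[ii]
            ops.append((1, len(s)))
            seq_parts.append(s)
            quals.extend([qv] * len(s))
            ii += 1
        if prev_col is not None and c.col_ref[i] > prev_col + 1:
            ops.append((2, int(c.col_ref[i] - prev_col - 1)))
        # run of consecutive columns
        j = i
        while j + 1 < n and c.col_ref[j + 1] == c.col_ref[j] + 1:
            nxt = ins[ii][0] if ii < len(ins) else None
            if nxt is not None and nxt <= c.col_ref[j + 1]:
                break
            j += 1
        ops.append((0, j - i + 1))
        seq_parts.append(asm._codes_to_str(c.col_code[i:j + 1]))
        quals.extend(c.col_qv[i:j + 1].tolist())
        prev_col = int(c.col_ref[j])
        i = j + 1
    for p, s, qv in ins[ii:]:
        ops.append((1, len(s)))
        seq_parts.append(s)
        quals.extend([qv] * len(s))
    merged = []
    for op, l in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + l)
        else:
            merged.append((op, l))
    return merged, "".join(seq_parts), quals


def read_contig_sam(path: str):
    import pysam
    from .align import seq_to_codes
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            col_ref, col_code, col_qv, insertions = [], [], [], []
            r, q = rec.reference_start, 0
            for op, l in rec.cigartuples:
                if op in (0, 7, 8):
                    col_ref.append(np.arange(r, r + l, dtype=np.int64))
                    col_code.append(seq_to_codes(seq[q:q + l]))
                    col_qv.append(np.array(quals[q:q + l], dtype=np.float32))
                    r += l
                    q += l
                elif op == 1:
                    insertions.append((r, seq[q:q + l],
                                       float(np.mean(quals[q:q + l]))))
                    q += l
                elif op in (2, 3):
                    r += l
                elif op == 4:
                    q += l
            if not col_ref:
                continue
            out.append(asm.Contig(
                rec.query_name, rec.get_tag("ZB"), rec.get_tag("HP"),
                np.concatenate(col_ref), np.concatenate(col_code),
                np.concatenate(col_qv), insertions,
                bool(rec.get_tag("ZP"))))
    return out
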