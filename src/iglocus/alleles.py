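"""Gene-segment extraction and germline allele assignment.

The coding (exon) sequence of every annotated gene is projected out of
the haplotype consensus through its reference alignment
(reverse-complemented for minus-strand genes) and compared with the
allele database.  An exact full-length match is a *known* allele; any
other sequence is *novel* and reported with its nearest database allele
(by edit distance) and the substitution/indel diff list.  Genes inside a
called deletion are *deleted*; genes inside the flagged V(D)J interval
on the lost haplotype are *vdj_suspect*; genes with no covering contig
are *not_assembled*.

Read support for an allele is the number of reads containing the exact
allele sequence (or its reverse complement) as a substring — an
intentionally strict count; an approximate mode tolerating one mismatch
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .synthetic import AlleleDatabase, revcomp

__all__ = ["AlleleCall", "extract_gene_sequences", "assign_allele",
           "count_read_support", "call_alleles", "write_allele_table"]


@dataclass
class AlleleCall:
    gene_name: str
    haplotype: int
    status: str                 # known | novel | deleted | not_assembled |
                                # vdj_suspect
    allele_name: str = None     # known: database name; novel: nearest
    sequence: str = None
    diffs: tuple = ()           # novel: [(op, pos, detail)]
    tie: bool = False
    ccs_support_count: int = 0
    phase_confident: bool = True


def extract_gene_sequences(contigs, ref, deletions=(), vdj_interval=None,
                           het_positions=()):
    """Per-(gene, haplotype) coding sequence or absence reason.

    A gene interrupted by a junction between two abutting contigs of the
    same haplotype is stitched across the junction, unless a het site
    falls inside the gene and the pieces come from different phase
    domains (the labels would not be comparable).  Returns
    ``{(gene_name, hap): ("ok", seq, phase_confident) | (reason, None,
    pc)}``.
    """
    from .variants import _HapIndex
    hidx = _HapIndex(contigs)
    het_positions = np.asarray(sorted(het_positions), dtype=np.int64)
    out = {}
    for g in ref.genes:
        exon = g.exon
        iv = g.locus_interval
        lo, hi = np.searchsorted(het_positions, [iv.start, iv.end])
        gene_has_het = hi > lo
        for h in (1, 2):
            key = (g.gene_name, h)
            pieces = _tile(hidx, h, exon.start, exon.end, gene_has_het)
            if pieces is None:
                out[key] = ("not_assembled", None, True)
                continue
            # fraction of the gene body present in the consensus columns
            cols = sum(int(np.searchsorted(c.col_ref, min(iv.end, c.ref_end))
                           - np.searchsorted(c.col_ref,
                                             max(iv.start, c.ref_start)))
                       for c in pieces)
            frac = cols / len(iv)
            pc = all(c.phase_confident for c in pieces)
            if frac < 0.1:
                inside_vdj = vdj_interval and \
                    vdj_interval[0] <= iv.start and iv.end <= vdj_interval[1]
                status = "vdj_suspect" if inside_vdj else "deleted"
                out[key] = (status, None, pc)
                continue
            parts, cur = [], exon.start
            for c in pieces:
                seg_end = min(exon.end, c.ref_end)
                parts.append(c.project(cur, seg_end))
                cur = seg_end
            seq = "".join(parts)
            if g.strand == "-":
                seq = revcomp(seq)
            out[key] = ("ok", seq, pc)
    return out


def _tile(hidx, hap, start, end, gene_has_het):
    """Minimal chain of abutting same-haplotype contigs covering
    [start, end), or None.  Cross-block stitching is refused when the
    gene contains a het site (phase labels are block-local)."""
    pieces = []
    cursor = start
    guard = 0
    while cursor < end:
        c = hidx.covering(hap, cursor)
        if c is None:
            return None
        if pieces and c is pieces[-1]:
            return None
        if pieces and gene_has_het and c.block_id != pieces[-1].block_id:
            return None
        pieces.append(c)
        cursor = c.ref_end
        guard += 1
        if guard > 10:
            return None
    return pieces


def assign_allele(sequence: str, gene: str, db: AlleleDatabase) -> AlleleCall:
    """Match a coding sequence against the database for one gene."""
    alleles = db.alleles(gene)
    if not alleles:
        raise ValueError(f"no database alleles for gene {gene}")
    if not sequence:
        raise ValueError("empty gene sequence")
    for name in sorted(alleles):
        if alleles[name] == sequence:
            return AlleleCall(gene, 0, "known", name, sequence)
    # novel: nearest allele by edit distance, lexicographic tie-break
    best_name, best_d = None, None
    tie = False
    for name in sorted(alleles):
        d = edlib.align(sequence, alleles[name], mode="NW")["editDistance"]
        if best_d is None or d < best_d:
            best_name, best_d, tie = name, d, False
        elif d == best_d:
            tie = True
    diffs = _diff_list(sequence, alleles[best_name])
    return AlleleCall(gene, 0, "novel", best_name, sequence,
                      tuple(diffs), tie)


def _diff_list(seq: str, ref_allele: str):
    from .align import edlib_ops, ops_to_events
    ops, _, _ = edlib_ops(seq, ref_allele, mode="NW")
    snvs, indels = ops_to_events(ops, seq, ref_allele)
    out = [("sub", p, f"{rb}>{ab}") for p, rb, ab in snvs]
    out += [("del" if ra else "ins", p, ra or aa) for p, ra, aa in indels]
    return sorted(out, key=lambda d: d[1])


def count_read_support(allele_seq: str, reads, approximate: bool = False):
    """Number of reads containing the allele sequence as a substring.

    With ``approximate``, one mismatch/indel is tolerated (edlib infix
    search at distance <= 1).
    """
    if not allele_seq:
        return 0
    rc = revcomp(allele_seq)
    n = 0
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        if allele_seq in seq or rc in seq:
            n += 1
        elif approximate:
            for probe in (allele_seq, rc):
                res = edlib.align(probe, seq, mode="HW", k=1)
                if res["editDistance"] not in (-1, None) and \
                        res["editDistance"] <= 1:
                    n += 1
                    break
    return n


def call_alleles(contigs, ref, db: AlleleDatabase, reads=(), deletions=(),
                 vdj_interval=None, count_support: bool = True,
                 het_positions=()):
    """Full allele calling over every annotated gene, both haplotypes."""
    extracted = extract_gene_sequences(contigs, ref, deletions, vdj_interval,
                                       het_positions=het_positions)
    calls = []
    for (gene, h), (status, seq, pc) in sorted(extracted.items()):
        if status != "ok":
            calls.append(AlleleCall(gene, h, status, phase_confident=pc))
            continue
        call = assign_allele(seq, gene, db)
        call.haplotype = h
        call.phase_confident = pc
        if count_support and reads:
            call.ccs_support_count = count_read_support(seq, reads)
        calls.append(call)
    return calls


def write_allele_table(calls, path: str):
    with open(path, "w") as f:
        f.write("gene\thaplotype\tstatus\tallele\tread_support\t"
                "novel_sequence\tdiffs\n")
        for c in sorted(calls, key=lambda x: (x.gene_name, x.haplotype)):
            novel_seq = c.sequence if c.status == "novel" else "."
            diffs = ",".join(f"{op}{pos}:{d}" for op, pos, d in c.diffs) or "."
            f.write(f"{c.gene_name}\t{c.haplotype}\t{c.status}\t"
                    f"{c.allele_name or '.'}\t{c.ccs_support_count}\t"
                    f"{novel_seq}\t{diffs}\n")
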