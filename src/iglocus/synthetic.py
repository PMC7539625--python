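"""Synthetic diploid locus, truth sets and long-read simulation.

This module generates everything the pipeline consumes, with the
statistical structure of a targeted long-read capture experiment over an
immunoglobulin-type locus:

* a random base locus with V/D/J gene annotations and embedded SV
  insertion alleles (:func:`make_locus`), plus a germline allele database
  derived from the reference gene exons (:func:`build_allele_database`);
* a diploid truth set with het/hom SNVs, 2–49 bp indels, >=50 bp SVs
  (including absence alleles of the embedded SVs), substituted and novel
  gene alleles, and an optional V(D)J-like somatic deletion at the
  J-proximal end (:func:`simulate_diploid`);
* consensus-quality ("CCS-like") reads with a configurable mismatch and
  homopolymer-biased indel error model, coverage dropout intervals, and an
  optional noisy-subread mode (:func:`simulate_reads`);
* multiplex pooling at fixed total yield (:func:`simulate_multiplex`).

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import (GeneAnnotation, GenomicInterval, LocusReference,
                        build_custom_reference)

__all__ = [
    "make_locus", "build_allele_database", "default_allele_database",
    "simulate_diploid", "simulate_reads", "simulate_multiplex",
    "collapse_subreads", "apply_variants", "default_sv_spec", "default_sv_spec_for",
    "write_fastq", "read_fastq", "write_truth", "read_truth",
    "AlleleDatabase", "TruthSet", "TruthVariant", "SimulatedRead",
    "DiploidConfig", "ReadConfig", "SVSpec", "revcomp",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_sequence(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# locus construction


def _make_gene(name, seg, start, strand, rng):
    """Gene layout: LP1 - intron - exon - RS on the plus strand of the
    locus (mirrored for minus-strand genes)."""
    sizes = {"V": (60, 100, 296, 23), "D": (0, 0, 25, 12), "J": (0, 0, 51, 23)}
    lp1, intron, exon, rs = sizes[seg]
    feats = []
    pos = start
    order = [("LP1", lp1), ("intron", intron), ("exon", exon), ("RS", rs)]
    if strand == "-":
        order = order[::-1]
    for fc, ln in order:
        if ln:
            feats.append((fc, GenomicInterval("base", pos, pos + ln, strand)))
        pos += ln
    return GeneAnnotation(name, seg, GenomicInterval("base", start, pos, strand),
                          tuple(feats)), pos


def make_locus(seed: int = 0, length: int = 600_000, n_v: int = 30,
               n_d: int = 8, n_j: int = 6,
               insertion_lengths=(8_000, 15_000)) -> LocusReference:
    """Build a synthetic custom locus reference.

    V genes are spread over the left ~75% of the locus, D and J segments
    near the right end (so a V(D)J-like deletion removes the J-proximal
    end), and the configured SV insertion bodies are spliced in between V
    genes.  A few genes are placed on the minus strand to exercise
    reverse-complement extraction.
    """
    rng = np.random.default_rng(seed)
    base = random_sequence(rng, length)
    genes = []
    v_zone = int(length * 0.75)
    spacing = v_zone // (n_v + 1)
    for i in range(n_v):
        start = spacing * (i + 1) + int(rng.integers(-spacing // 4, spacing // 4))
        strand = "-" if i % 5 == 2 else "+"
        g, _ = _make_gene(f"V{i + 1}", "V", start, strand, rng)
        genes.append(g)
    d_zone0 = int(length * 0.82)
    for i in range(n_d):
        start = d_zone0 + i * 900 + int(rng.integers(0, 300))
        g, _ = _make_gene(f"D{i + 1}", "D", start, "+", rng)
        genes.append(g)
    j_zone0 = int(length * 0.90)
    for i in range(n_j):
        start = j_zone0 + i * 700 + int(rng.integers(0, 200))
        g, _ = _make_gene(f"J{i + 1}", "J", start, "+", rng)
        genes.append(g)

    # insertion sites between V genes, clear of every gene body
    occupied = sorted((g.locus_interval.start - 200, g.locus_interval.end + 200)
                      for g in genes)
    sites = []
    want = len(insertion_lengths)
    cand = np.linspace(length * 0.2, length * 0.7, want + 2)[1:-1]
    for c in cand:
        p = int(c)
        while any(s <= p < e for s, e in occupied):
            p += 500
        sites.append(p)
    insertions = [(p, random_sequence(rng, l), f"SV{i + 1}")
                  for i, (p, l) in enumerate(zip(sorted(sites), insertion_lengths))]
    return build_custom_reference(base, insertions, genes)


@dataclass
class AlleleDatabase:
    """Germline allele database: gene -> {allele name -> coding sequence}."""

    entries: dict
    version: str = "synthetic-1"

    def __post_init__(self):
        for gene, alleles in self.entries.items():
            seqs = list(alleles.values())
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"{gene}: duplicate allele sequences")
            for name, seq in alleles.items():
                if set(seq) - set("ACGT"):
                    raise ValueError(
                        f"{gene}*{name}: ambiguity codes are not supported")

    def alleles(self, gene: str) -> dict:
        return self.entries.get(gene, {})

    def to_fasta(self, path: str):
        with open(path, "w") as f:
            for gene in sorted(self.entries):
                for name, seq in sorted(self.entries[gene].items()):
                    f.write(f">{gene}*{name}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path: str, version: str = "file"):
        entries = {}
        name, chunks = None, []
        def _flush():
            if name is None:
                return
            gene, allele = name.split("*", 1)
            entries.setdefault(gene, {})[allele] = "".join(chunks)
        with open(path) as f:
            for line in f:
                line = line.strip()
                if line.startswith(">"):
                    _flush()
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        _flush()
        return cls(entries, version)


def build_allele_database(ref: LocusReference, seed: int = 0,
                          extra_alleles: int = 2):
    """Derive an allele database from the reference gene exons.

    Allele ``01`` of each gene is the reference coding sequence; each of
    the ``extra_alleles`` additional alleles differs by 1–2 exonic
    substitutions.  Returns ``(db, allele_edits)`` where ``allele_edits``
    maps ``(gene, allele)`` to the plus-strand reference edits
    ``[(ref_pos, alt_base), ...]`` that produce the allele, so a simulator
    can plant a database allele on a haplotype.
    """
    rng = np.random.default_rng(seed + 7919)
    entries, edits = {}, {}
    for g in ref.genes:
        exon = g.exon
        plus_seq = ref.sequence[exon.start:exon.end]
        coding = revcomp(plus_seq) if g.strand == "-" else plus_seq
        entries[g.gene_name] = {"01": coding}
        edits[(g.gene_name, "01")] = []
        for a in range(extra_alleles):
            name = f"{a + 2:02d}"
            while True:
                k = int(rng.integers(1, 3))
                pos = rng.choice(len(plus_seq), size=k, replace=False)
                new = list(plus_seq)
                es = []
                for p in sorted(pos.tolist()):
                    alt = _BASES[(np.flatnonzero(_BASES == new[p])[0]
                                  + rng.integers(1, 4)) % 4]
                    new[p] = alt
                    es.append((exon.start + p, str(alt)))
                cand_plus = "".join(new)
                cand = revcomp(cand_plus) if g.strand == "-" else cand_plus
                if cand not in entries[g.gene_name].values():
                    entries[g.gene_name][name] = cand
                    edits[(g.gene_name, name)] = es
                    break
    return AlleleDatabase(entries), edits


# ---------------------------------------------------------------------------
# diploid truth


@dataclass(frozen=True)
class TruthVariant:
    """One truth edit against the custom reference.

    ``start``/``end`` delimit the replaced reference span (``end ==
    start`` for pure insertions); genotype is phased ``hap1|hap2`` with 1
    meaning the alt allele.  ``origin`` records what planted it (snv,
    indel, sv, allele, vdj).
    """

    type: str               # SNV | indel | SV
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    genotype: str           # "0|1", "1|0", "1|1"
    origin: str = ""
    sv_id: str = ""

    @property
    def on_hap1(self) -> bool:
        return self.genotype[0] == "1"

    @property
    def on_hap2(self) -> bool:
        return self.genotype[2] == "1"

    def is_het(self) -> bool:
        return self.on_hap1 != self.on_hap2


@dataclass
class TruthSet:
    hap1: str
    hap2: str
    variants: list
    allele_assignments: dict    # gene -> {1: (status, payload), 2: ...}
    sv_genotypes: dict          # sv_id -> "present/present" | ...
    vdj_deletion: tuple = None  # (start, end, hap) or None
    ref: LocusReference = None

    def hap(self, h: int) -> str:
        return self.hap1 if h == 1 else self.hap2

    def variants_of(self, vtype: str):
        return [v for v in self.variants if v.type == vtype]

    def hap_edits(self, h: int):
        key = "on_hap1" if h == 1 else "on_hap2"
        return sorted((v for v in self.variants if getattr(v, key)),
                      key=lambda v: v.start)

    def ref_to_hap(self, pos: int, h: int) -> int:
        """Map a custom-reference position to the haplotype coordinate
        (position of the nearest not-deleted base at or after ``pos``)."""
        off = 0
        for v in self.hap_edits(h):
            if v.end <= pos:
                off += len(v.alt_allele) - (v.end - v.start)
            elif v.start <= pos:
                return v.start + off
            else:
                break
        return pos + off


def apply_variants(ref_seq: str, edits) -> str:
    """Apply non-overlapping ``(start, end, alt)`` edits to a sequence."""
    parts, prev = [], 0
    for start, end, alt in sorted(edits):
        if start < prev:
            raise ValueError("overlapping edits")
        parts.append(ref_seq[prev:start])
        parts.append(alt)
        prev = end
    parts.append(ref_seq[prev:])
    return "".join(parts)


@dataclass(frozen=True)
class SVSpec:
    """One structural event to plant.

    kind: ``embedded_absence`` (delete the body of embedded region
    ``sv_id``), ``deletion``, ``insertion`` or ``tandem_duplication``.
    ``genotype`` is phased (``0|1``, ``1|0`` or ``1|1``).
    """

    kind: str
    genotype: str = "0|1"
    length: int = 0
    sv_id: str = ""


@dataclass
class DiploidConfig:
    n_snv: int = 300
    het_fraction: float = 2 / 3
    n_indel: int = 20
    indel_len: tuple = (2, 49)
    indel_het_fraction: float = 0.5
    sv_spec: tuple = ()
    n_known_nonref_alleles: int = 4
    n_novel_alleles: int = 3
    novel_substitutions: tuple = (1, 3)
    vdj_deletion: bool = False
    min_separation: int = 60


def default_sv_spec_for(ref: LocusReference, seed: int = 0):
    """An SV plan adapted to a locus: every embedded region polymorphic
    plus a germline deletion and insertion sized to the locus."""
    rng = np.random.default_rng(seed)
    spec = []
    for i, sv in enumerate(ref.biallelic_svs):
        gt = "0|1" if i % 2 == 0 else "1|1"
        spec.append(SVSpec("embedded_absence", sv_id=sv.sv_id, genotype=gt))
    big = 25_000 if len(ref.sequence) >= 400_000 else \
        max(2_000, len(ref.sequence) // 30)
    spec.append(SVSpec("deletion", length=big, genotype="0|1"))
    spec.append(SVSpec("insertion", length=150, genotype="1|0"))
    spec.append(SVSpec("deletion", length=80, genotype="1|1"))
    return tuple(spec)


def default_sv_spec():
    """Study-condition SV set: both embedded SVs polymorphic, one 25 kb
    deletion, one 150 bp insertion, one 80 bp homozygous deletion."""
    return (
        SVSpec("embedded_absence", sv_id="SV1", genotype="0|1"),
        SVSpec("embedded_absence", sv_id="SV2", genotype="1|1"),
        SVSpec("deletion", length=25_000, genotype="0|1"),
        SVSpec("insertion", length=150, genotype="1|0"),
        SVSpec("deletion", length=80, genotype="1|1"),
    )


def simulate_diploid(ref: LocusReference, config: DiploidConfig,
                     seed: int = 0) -> TruthSet:
    """Plant a diploid truth set on the custom reference.

    Placement is uniform outside every previously placed footprint, gene
    bodies (gene variation enters only through allele assignments so that
    allele-level truth stays exact), embedded-SV bodies that are absent on
    either haplotype, and a margin around the locus ends.
    """
    rng = np.random.default_rng(seed)
    L = len(ref.sequence)
    variants = []
    blocked = []          # (start, end) footprints with margin

    def block(s, e, margin):
        blocked.append((max(0, s - margin), min(L, e + margin)))

    def is_free(s, e):
        return all(e <= bs or s >= be for bs, be in blocked)

    block(0, 4_000, 0)
    block(L - 4_000, L, 0)
    for g in ref.genes:
        block(g.locus_interval.start, g.locus_interval.end, 150)

    # --- structural events -------------------------------------------------
    sv_genotypes = {}
    embedded = {s.sv_id: s for s in ref.sv_regions}
    # fixed-location events first: embedded-SV absences and the V(D)J-like
    # deletion; randomly placed SVs then avoid their footprints
    for spec in config.sv_spec:
        if spec.kind != "embedded_absence":
            continue
        region = embedded[spec.sv_id]
        iv = region.interval
        variants.append(TruthVariant(
            "SV", iv.start, iv.end, ref.sequence[iv.start:iv.end], "",
            spec.genotype, origin="sv", sv_id=spec.sv_id))
        block(iv.start, iv.end, 500)
        sv_genotypes[spec.sv_id] = _presence_genotype(spec.genotype)

    vdj = None
    if config.vdj_deletion:
        j_genes = [g for g in ref.genes if g.segment_class == "J"]
        d_genes = [g for g in ref.genes if g.segment_class == "D"]
        s = min(g.locus_interval.start for g in d_genes) - 1_500
        e = max(g.locus_interval.end for g in j_genes) + 800
        variants.append(TruthVariant(
            "SV", s, e, ref.sequence[s:e], "", "0|1", origin="vdj"))
        block(s, e, 500)
        vdj = (s, e, 2)

    for spec in config.sv_spec:
        if spec.kind == "embedded_absence":
            pass
        else:
            placed = False
            for _ in range(10_000):
                s = int(rng.integers(5_000, L - 5_000))
                e = s + (spec.length if spec.kind != "insertion" else 0)
                if spec.kind == "tandem_duplication":
                    e = s + spec.length
                if is_free(s - 500, e + 500):
                    placed = True
                    break
            if not placed:
                raise ValueError(f"cannot place SV spec {spec}")
            if spec.kind == "deletion":
                v = TruthVariant("SV" if spec.length >= 50 else "indel",
                                 s, e, ref.sequence[s:e], "",
                                 spec.genotype, origin="sv")
            elif spec.kind == "insertion":
                ins = random_sequence(rng, spec.length)
                v = TruthVariant("SV" if spec.length >= 50 else "indel",
                                 s, s, "", ins, spec.genotype, origin="sv")
            elif spec.kind == "tandem_duplication":
                unit = ref.sequence[s:e]
                v = TruthVariant("SV" if spec.length >= 50 else "indel",
                                 e, e, "", unit, spec.genotype, origin="sv")
            else:
                raise ValueError(f"unknown SV kind {spec.kind!r}")
            variants.append(v)
            block(min(v.start, s), max(v.end, e), 500)
    for sv_id, region in embedded.items():
        if sv_id not in sv_genotypes:
            sv_genotypes[sv_id] = "present/present"

    # --- gene allele assignments -------------------------------------------
    db, allele_edits = build_allele_database(ref, seed=_db_seed(ref))
    assignments = {g.gene_name: {1: ("known", "01"), 2: ("known", "01")}
                   for g in ref.genes}
    genes_by_name = {g.gene_name: g for g in ref.genes}

    def hap_deleted(gene, h):
        iv = genes_by_name[gene].locus_interval
        for v in variants:
            if v.type == "SV" and not v.alt_allele and \
                    v.start <= iv.start and iv.end <= v.end and \
                    (v.on_hap1 if h == 1 else v.on_hap2):
                return v
        return None

    free_genes = [g.gene_name for g in ref.genes
                  if not hap_deleted(g.gene_name, 1)
                  and not hap_deleted(g.gene_name, 2)]
    rng.shuffle(free_genes)
    pick = iter(free_genes)
    # cap at the genes actually available on this locus
    n_known = min(config.n_known_nonref_alleles,
                  max(0, len(free_genes) - config.n_novel_alleles))
    n_novel = min(config.n_novel_alleles, len(free_genes) - n_known)
    for _ in range(n_known):
        gene = next(pick)
        h = int(rng.integers(1, 3))
        allele = str(rng.choice([a for a in db.alleles(gene) if a != "01"]))
        assignments[gene][h] = ("known", allele)
        for pos, alt in allele_edits[(gene, allele)]:
            gt = "1|0" if h == 1 else "0|1"
            variants.append(TruthVariant(
                "SNV", pos, pos + 1, ref.sequence[pos], alt, gt,
                origin="allele"))
    for _ in range(n_novel):
        gene = next(pick)
        h = int(rng.integers(1, 3))
        g = genes_by_name[gene]
        exon = g.exon
        k = int(rng.integers(config.novel_substitutions[0],
                             config.novel_substitutions[1] + 1))
        pos = sorted(rng.choice(len(exon), size=k, replace=False).tolist())
        plus = list(ref.sequence[exon.start:exon.end])
        for p in pos:
            cur = plus[p]
            alt = str(_BASES[(np.flatnonzero(_BASES == cur)[0]
                              + rng.integers(1, 4)) % 4])
            plus[p] = alt
            gt = "1|0" if h == 1 else "0|1"
            variants.append(TruthVariant(
                "SNV", exon.start + p, exon.start + p + 1, cur, alt, gt,
                origin="novel_allele"))
        novel_plus = "".join(plus)
        novel = revcomp(novel_plus) if g.strand == "-" else novel_plus
        if novel in db.alleles(gene).values():
            raise RuntimeError("novel allele collided with database")
        assignments[gene][h] = ("novel", novel)

    # mark deleted / vdj-affected genes
    for g in ref.genes:
        for h in (1, 2):
            v = hap_deleted(g.gene_name, h)
            if v is not None:
                status = "vdj" if v.origin == "vdj" else "deleted"
                assignments[g.gene_name][h] = (status, None)

    # --- small variants -----------------------------------------------------
    def place_small(n, maker):
        made = 0
        attempts = 0
        while made < n:
            attempts += 1
            if attempts > 200_000:
                raise ValueError("cannot place requested variants")
            s = int(rng.integers(4_000, L - 4_000))
            v = maker(s)
            if v is None:
                continue
            if is_free(v.start - config.min_separation,
                       max(v.end, v.start + len(v.alt_allele))
                       + config.min_separation):
                variants.append(v)
                block(v.start, max(v.end, v.start + 1), config.min_separation)
                made += 1

    n_het = round(config.n_snv * config.het_fraction)

    def snv_maker(gt):
        def make(s):
            cur = ref.sequence[s]
            alt = str(_BASES[(np.flatnonzero(_BASES == cur)[0]
                              + rng.integers(1, 4)) % 4])
            g = gt if gt != "het" else ("0|1" if rng.integers(2) else "1|0")
            return TruthVariant("SNV", s, s + 1, cur, alt, g, origin="snv")
        return make

    place_small(n_het, snv_maker("het"))
    place_small(config.n_snv - n_het, snv_maker("1|1"))

    def indel_maker(s):
        ln = int(rng.integers(config.indel_len[0], config.indel_len[1] + 1))
        het = rng.random() < config.indel_het_fraction
        gt = ("0|1" if rng.integers(2) else "1|0") if het else "1|1"
        if rng.integers(2):   # deletion
            if s + ln >= L - 4_000:
                return None
            return TruthVariant("indel", s, s + ln, ref.sequence[s:s + ln],
                                "", gt, origin="indel")
        ins = random_sequence(rng, ln)
        return TruthVariant("indel", s, s, "", ins, gt, origin="indel")

    place_small(config.n_indel, indel_maker)

    variants.sort(key=lambda v: (v.start, v.end))
    hap1 = apply_variants(ref.sequence,
                          [(v.start, v.end, v.alt_allele)
                           for v in variants if v.on_hap1])
    hap2 = apply_variants(ref.sequence,
                          [(v.start, v.end, v.alt_allele)
                           for v in variants if v.on_hap2])
    return TruthSet(hap1, hap2, variants, assignments, sv_genotypes, vdj, ref)


def _presence_genotype(gt: str) -> str:
    """Embedded-SV genotype string from the phased absence genotype."""
    h1 = "absent" if gt[0] == "1" else "present"
    h2 = "absent" if gt[2] == "1" else "present"
    return f"{h1}/{h2}"


def _db_seed(ref: LocusReference) -> int:
    # stable per-locus database: derived from sequence content
    return (len(ref.sequence) * 2654435761 + len(ref.genes)) % (2 ** 31)


def default_allele_database(ref: LocusReference) -> AlleleDatabase:
    """The canonical allele database for a locus (same one the diploid
    simulator assigns alleles from)."""
    return build_allele_database(ref, seed=_db_seed(ref))[0]


# ---------------------------------------------------------------------------
# reads


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    n_passes: int
    truth_haplotype: int
    truth_interval: tuple       # (start, end) on the source haplotype
    barcode: str = None
    subreads: tuple = None


@dataclass
class ReadConfig:
    coverage: float = 20.0          # per haplotype
    length_mean: float = 6_457.0    # observed mean CCS read length
    length_sd: float = 1_200.0
    length_max: float = None        # size-selected library; default mean+4sd
    min_length: int = 500
    mismatch_rate: float = 0.0
    indel_rate: float = 0.0
    homopolymer_bias: float = 0.0
    dropout: tuple = ()             # (ref_start, ref_end, keep_prob)
    subread_mode: bool = False
    subread_error: float = 0.05
    singleton_fraction: float = 0.0  # molecules with n_passes == 1


def homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside runs of >= min_run equal bases."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(a)
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.flatnonzero(a[1:] != a[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    mask = np.zeros(n, dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def simulate_reads(truth: TruthSet, config: ReadConfig, seed: int = 0):
    """Sample CCS-like reads from both haplotypes.

    Returns ``(reads, stats)``; stats records injected error counts,
    including how many indel errors fell in homopolymer runs (to audit the
    bias model).  With all error rates at 0 every read is an exact
    substring of its source haplotype.
    """
    rng = np.random.default_rng(seed)
    reads, stats = [], {"n_mismatch": 0, "n_indel": 0, "n_indel_hp": 0}
    total_err = config.mismatch_rate + config.indel_rate
    q = min(60, int(round(-10 * math.log10(max(total_err, 1e-6)))))
    qchar = chr(q + 33)
    mol = 0
    for h in (1, 2):
        hap = truth.hap(h)
        hp = homopolymer_mask(hap) if config.indel_rate > 0 else None
        hap_arr = np.frombuffer(hap.encode(), dtype=np.uint8)
        L = len(hap)
        n_reads = int(round(config.coverage * L / config.length_mean))
        if n_reads == 0:
            continue
        lens = rng.normal(config.length_mean, config.length_sd, n_reads)
        lmax = config.length_max or (config.length_mean
                                     + 4 * config.length_sd)
        lens = np.clip(lens, config.min_length, lmax)
        low = (-lens + config.min_length).astype(np.int64)
        starts = rng.integers(low, L - config.min_length)
        drop_ivs = [(truth.ref_to_hap(s, h), truth.ref_to_hap(e, h), p)
                    for s, e, p in config.dropout]
        for i in range(n_reads):
            s = max(0, int(starts[i]))
            e = min(L, int(starts[i] + lens[i]))
            if e - s < config.min_length:
                continue
            mid = (s + e) // 2
            keep = True
            for ds, de, kp in drop_ivs:
                if ds <= mid < de and rng.random() > kp:
                    keep = False
                    break
            if not keep:
                continue
            mol += 1
            if config.singleton_fraction and rng.random() < config.singleton_fraction:
                n_passes = 1
            else:
                n_passes = int(rng.integers(2, 16))
            frag = hap_arr[s:e]
            seq, nm, ni, nh = _inject_errors(
                frag, hp[s:e] if hp is not None else None,
                config.mismatch_rate, config.indel_rate,
                config.homopolymer_bias, rng)
            stats["n_mismatch"] += nm
            stats["n_indel"] += ni
            stats["n_indel_hp"] += nh
            subreads = None
            if config.subread_mode:
                subreads = tuple(
                    _inject_errors(frag, None, config.subread_error * 0.6,
                                   config.subread_error * 0.4, 0.0, rng)[0]
                    for _ in range(max(1, n_passes)))
            reads.append(SimulatedRead(
                f"mol{mol}", seq, qchar * len(seq), n_passes, h, (s, e),
                subreads=subreads))
    return reads, stats


def _inject_errors(frag: np.ndarray, hp_mask, mis_rate, indel_rate, bias, rng):
    n = len(frag)
    if mis_rate <= 0 and indel_rate <= 0:
        return frag.tobytes().decode(), 0, 0, 0
    seq = bytearray(frag.tobytes())
    n_mis = rng.binomial(n, mis_rate) if mis_rate > 0 else 0
    if n_mis:
        pos = rng.choice(n, size=n_mis, replace=False)
        for p in pos:
            cur = seq[p]
            choices = [b for b in b"ACGT" if b != cur]
            seq[p] = choices[rng.integers(3)]
    n_ind = rng.binomial(n, indel_rate) if indel_rate > 0 else 0
    n_hp = 0
    if n_ind:
        hp_idx = np.flatnonzero(hp_mask) if hp_mask is not None else None
        events = []
        for _ in range(n_ind):
            if hp_idx is not None and len(hp_idx) and rng.random() < bias:
                p = int(hp_idx[rng.integers(len(hp_idx))])
                n_hp += 1
            else:
                p = int(rng.integers(n))
                if hp_mask is not None and len(hp_mask) and hp_mask[p]:
                    n_hp += 1
            events.append((p, int(rng.integers(2))))
        for p, is_ins in sorted(events, reverse=True):
            if is_ins:
                seq[p:p] = seq[p:p + 1]
            else:
                del seq[p:p + 1]
    return seq.decode(), n_mis, n_ind, n_hp


def collapse_subreads(subreads) -> str:
    """Majority-vote collapse of noisy subread copies of one molecule."""
    import edlib
    from .align import edlib_ops
    if len(subreads) == 1:
        return subreads[0]
    draft = max(subreads, key=len)
    votes = [dict() for _ in range(len(draft))]
    for s in subreads:
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


def simulate_multiplex(readsets, plex_levels, seed: int = 0):
    """Pool per-sample readsets and re-partition at fixed total yield.

    Returns ``{plex: [readset_1, ..., readset_plex]}``; each readset at
    plex ``p`` holds ``total_reads // p`` reads, so per-sample coverage
    scales as total/p.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    pool = [r for rs in readsets for r in rs]
    order = rng.permutation(len(pool))
    out = {}
    for p in plex_levels:
        if p < 1:
            raise ValueError("plex level must be >= 1")
        size = len(pool) // p
        sets = []
        for i in range(p):
            idx = order[i * size:(i + 1) * size]
            sets.append([replace(pool[j], barcode=f"bc{i + 1}") for j in idx])
        out[p] = sets
    return out


# ---------------------------------------------------------------------------
# IO


def write_fastq(reads, path: str):
    with open(path, "w") as f:
        for r in reads:
            s, e = r.truth_interval
            f.write(f"@{r.read_id} np:i:{r.n_passes}\thp:i:{r.truth_haplotype}"
                    f"\tsi:Z:{s}-{e}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str):
    import pysam
    reads = []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            n_passes, hap, iv = 2, 0, (0, 0)
            if rec.comment:
                for tag in rec.comment.split("\t"):
                    if tag.startswith("np:i:"):
                        n_passes = int(tag[5:])
                    elif tag.startswith("hp:i:"):
                        hap = int(tag[5:])
                    elif tag.startswith("si:Z:"):
                        s, e = tag[5:].split("-")
                        iv = (int(s), int(e))
            reads.append(SimulatedRead(rec.name, rec.sequence,
                                       rec.quality or "I" * len(rec.sequence),
                                       n_passes, hap, iv))
    return reads


def write_truth(truth: TruthSet, outdir: str):
    os.makedirs(outdir, exist_ok=True)
    seq_id = truth.ref.seq_id if truth.ref else "custom"
    with open(os.path.join(outdir, "truth_snvs.vcf"), "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={seq_id}>\n")
        f.write("##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n")
        f.write("##INFO=<ID=ORIGIN,Number=1,Type=String,Description=\"Truth origin\">\n")
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
        for v in truth.variants:
            if v.type != "SNV":
                continue
            f.write(f"{seq_id}\t{v.start + 1}\t.\t{v.ref_allele}\t"
                    f"{v.alt_allele}\t.\tPASS\tORIGIN={v.origin}\tGT\t"
                    f"{v.genotype}\n")
    with open(os.path.join(outdir, "truth_indels_svs.bed"), "w") as f:
        for v in truth.variants:
            if v.type == "SNV":
                continue
            f.write("\t".join(map(str, (
                seq_id, v.start, v.end, v.type, v.ref_allele or ".",
                v.alt_allele or ".", v.genotype, v.origin,
                v.sv_id or "."))) + "\n")
    with open(os.path.join(outdir, "truth_alleles.tsv"), "w") as f:
        f.write("gene\thaplotype\tstatus\tallele_or_sequence\n")
        for gene in sorted(truth.allele_assignments):
            for h in (1, 2):
                status, payload = truth.allele_assignments[gene][h]
                f.write(f"{gene}\t{h}\t{status}\t{payload or '.'}\n")
    with open(os.path.join(outdir, "truth_sv_genotypes.tsv"), "w") as f:
        f.write("sv_id\tgenotype\n")
        for sv_id in sorted(truth.sv_genotypes):
            f.write(f"{sv_id}\t{truth.sv_genotypes[sv_id]}\n")
    with open(os.path.join(outdir, "truth_vdj.bed"), "w") as f:
        if truth.vdj_deletion:
            s, e, h = truth.vdj_deletion
            f.write(f"{seq_id}\t{s}\t{e}\tvdj\t0\t+\t{h}\n")


def read_truth(outdir: str, ref: LocusReference) -> TruthSet:
    variants = []
    with open(os.path.join(outdir, "truth_snvs.vcf")) as f:
        for line in f:
            if line.startswith("#"):
                continue
            c = line.rstrip("\n").split("\t")
            pos = int(c[1]) - 1
            origin = c[7].split("=", 1)[1] if "=" in c[7] else ""
            variants.append(TruthVariant("SNV", pos, pos + 1, c[3], c[4],
                                         c[9], origin=origin))
    with open(os.path.join(outdir, "truth_indels_svs.bed")) as f:
        for line in f:
            c = line.rstrip("\n").split("\t")
            variants.append(TruthVariant(
                c[3], int(c[1]), int(c[2]),
                "" if c[4] == "." else c[4], "" if c[5] == "." else c[5],
                c[6], origin=c[7], sv_id="" if c[8] == "." else c[8]))
    variants.sort(key=lambda v: (v.start, v.end))
    assignments = {}
    with open(os.path.join(outdir, "truth_alleles.tsv")) as f:
        next(f)
        for line in f:
            gene, h, status, payload = line.rstrip("\n").split("\t")
            assignments.setdefault(gene, {})[int(h)] = (
                status, None if payload == "." else payload)
    sv_genotypes = {}
    with open(os.path.join(outdir, "truth_sv_genotypes.tsv")) as f:
        next(f)
        for line in f:
            sv_id, gt = line.rstrip("\n").split("\t")
            sv_genotypes[sv_id] = gt
    vdj = None
    p = os.path.join(outdir, "truth_vdj.bed")
    if os.path.exists(p):
        with open(p) as f:
            for line in f:
                c = line.rstrip("\n").split("\t")
                vdj = (int(c[1]), int(c[2]), int(c[6]))
    hap1 = apply_variants(ref.sequence, [(v.start, v.end, v.alt_allele)
                                         for v in variants if v.on_hap1])
    hap2 = apply_variants(ref.sequence, [(v.start, v.end, v.alt_allele)
                                         for v in variants if v.on_hap2])
    return TruthSet(hap1, hap2, variants, assignments, sv_genotypes, vdj, ref)
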