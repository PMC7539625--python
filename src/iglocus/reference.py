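"""Custom locus reference with embedded structural-variant alleles.

The reference for a targeted immunoglobulin-type locus is the base genome
sequence of the locus with the bodies of known insertion SV alleles spliced
in at their breakpoints.  Every downstream stage (read mapping, phasing,
assembly, variant calling, SV genotyping, allele typing) works in the
coordinates of this *custom* sequence; a liftover table maps mappable
intervals back and forth between custom and base coordinates.

Coordinates are 0-based half-open everywhere in this package; 1-based
coordinates appear only in VCF output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "SVRegion",
    "GeneAnnotation",
    "LocusReference",
    "build_custom_reference",
]

FEATURE_CLASSES = ("exon", "intron", "LP1", "RS")
SEGMENT_CLASSES = ("V", "D", "J")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def shifted(self, offset: int, seq_id: str = None) -> "GenomicInterval":
        return GenomicInterval(seq_id or self.seq_id, self.start + offset,
                               self.end + offset, self.strand)


@dataclass(frozen=True)
class SVRegion:
    """An embedded SV body on the custom reference.

    ``alt_is_absence`` marks regions whose alternate allele is the deletion
    of the whole body (the usual case for insertion alleles spliced into the
    reference).  Only ``biallelic`` regions are exposed to the SV genotyper.
    """

    sv_id: str
    interval: GenomicInterval
    alt_is_absence: bool = True
    biallelic: bool = True
    source_label: str = ""


@dataclass(frozen=True)
class GeneAnnotation:
    """A V/D/J gene segment with its sub-features.

    ``features`` holds ``(feature_class, interval)`` pairs with
    feature_class in {exon, intron, LP1, RS}; all feature intervals lie
    within ``locus_interval``.  There is exactly one exon per gene in this
    model (leader part 2 and the V-region are merged into the exon).
    """

    gene_name: str
    segment_class: str
    locus_interval: GenomicInterval
    features: tuple = ()
    functional_class: str = "functional"

    def __post_init__(self):
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"bad segment class {self.segment_class!r}")
        exons = [f for f in self.features if f[0] == "exon"]
        if len(exons) != 1:
            raise ValueError(f"{self.gene_name}: expected exactly one exon")
        for fclass, iv in self.features:
            if fclass not in FEATURE_CLASSES:
                raise ValueError(f"bad feature class {fclass!r}")
            if iv.start < self.locus_interval.start or iv.end > self.locus_interval.end:
                raise ValueError(f"{self.gene_name}: feature outside gene interval")

    @property
    def strand(self) -> str:
        return self.locus_interval.strand

    @property
    def exon(self) -> GenomicInterval:
        return next(iv for fc, iv in self.features if fc == "exon")

    def shifted(self, offset: int, seq_id: str = None) -> "GeneAnnotation":
        return GeneAnnotation(
            self.gene_name, self.segment_class,
            self.locus_interval.shifted(offset, seq_id),
            tuple((fc, iv.shifted(offset, seq_id)) for fc, iv in self.features),
            self.functional_class)


@dataclass
class LocusReference:
    """The custom locus sequence plus annotations and the liftover map.

    ``liftover_map`` is an ordered list of ``(custom_start, custom_end,
    base_start, base_end)`` segment pairs.  Segments are non-overlapping,
    sorted, and cover the whole custom sequence except embedded-insertion
    bodies; each segment has equal length on both sides.
    """

    sequence: str
    sv_regions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    liftover_map: list = field(default_factory=list)
    seq_id: str = "custom"

    def __post_init__(self):
        self._lift = sorted(self.liftover_map)
        self._cs = np.array([s[0] for s in self._lift], dtype=np.int64)
        self._validate()
        self.genes = sorted(self.genes, key=lambda g: g.locus_interval.start)
        self._build_position_index()

    # -- validation -------------------------------------------------------

    def _validate(self):
        n = len(self.sequence)
        prev_end = -1
        for cs, ce, bs, be in self._lift:
            if ce - cs != be - bs or cs >= ce:
                raise ValueError("malformed liftover segment")
            if cs < prev_end:
                raise ValueError("liftover segments overlap")
            if ce > n:
                raise ValueError("liftover segment beyond custom sequence")
            prev_end = ce
        seen = set()
        for sv in self.sv_regions:
            if sv.sv_id in seen:
                raise ValueError(f"duplicate sv_id {sv.sv_id!r}")
            seen.add(sv.sv_id)
            if sv.interval.end > n:
                raise ValueError(f"{sv.sv_id}: interval beyond sequence")

    def _build_position_index(self):
        # flat sorted arrays for fast point annotation
        feats = []
        for g in self.genes:
            for fc, iv in g.features:
                feats.append((iv.start, iv.end, g.gene_name, fc))
            feats.append((g.locus_interval.start, g.locus_interval.end,
                          g.gene_name, None))
        self._feat_rows = sorted(feats, key=lambda f: (f[0], f[1], f[2]))
        self._region_spans = {}
        for cls in SEGMENT_CLASSES:
            gs = [g for g in self.genes if g.segment_class == cls]
            if gs:
                self._region_spans[cls] = (
                    min(g.locus_interval.start for g in gs),
                    max(g.locus_interval.end for g in gs))

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def biallelic_svs(self) -> list:
        return sorted((s for s in self.sv_regions if s.biallelic),
                      key=lambda s: s.interval.start)

    def insertion_bodies(self):
        """Custom-coordinate gaps of the liftover map (embedded SV bodies)."""
        gaps, prev = [], 0
        for cs, ce, _, _ in self._lift:
            if cs > prev:
                gaps.append((prev, cs))
            prev = ce
        if prev < len(self.sequence):
            gaps.append((prev, len(self.sequence)))
        return gaps

    def liftover(self, interval: GenomicInterval, direction: str):
        """Map an interval between custom and base coordinates.

        direction is "custom_to_base" or "base_to_custom".  Returns the
        image interval, or None when the interval cannot be mapped as a
        single contiguous segment image: custom intervals intersecting an
        insertion body, and base intervals with an insertion breakpoint
        strictly inside, are unmappable.  Round-trip liftover of any
        mappable interval is the identity.
        """
        if direction not in ("custom_to_base", "base_to_custom"):
            raise ValueError(f"bad direction {direction!r}")
        c2b = direction == "custom_to_base"
        src_len = len(self.sequence) if c2b else (
            self._lift[-1][3] if self._lift else 0)
        if interval.start < 0 or interval.end > src_len:
            raise ValueError("interval outside the source sequence")
        i0, i1 = (0, 1) if c2b else (2, 3)
        covering = [s for s in self._lift
                    if s[i0] < interval.end and interval.start < s[i1]]
        if not covering:
            return None
        # must be contiguous on BOTH sides and cover the whole interval
        if covering[0][i0] > interval.start or covering[-1][i1] < interval.end:
            return None
        for a, b in zip(covering, covering[1:]):
            # contiguity in source and in target coordinates
            src_ok = a[i1] == b[i0]
            tgt_ok = (a[3] == b[2]) if c2b else (a[1] == b[0])
            if not (src_ok and tgt_ok):
                return None
        seg = covering[0]
        off = (seg[2] - seg[0]) if c2b else (seg[0] - seg[2])
        return GenomicInterval(
            "base" if c2b else self.seq_id,
            interval.start + off, interval.end + off, interval.strand)

    def annotate_position(self, pos: int):
        """Label one custom-reference position.

        Returns ``(gene_name or None, feature_class or "intergenic",
        region_class or None, sv_id or None)``.  The innermost feature wins;
        region class is the span from the first to the last gene of each
        segment class.
        """
        if not (0 <= pos < len(self.sequence)):
            raise ValueError(f"position {pos} outside sequence")
        gene, feature = None, "intergenic"
        best = None
        for start, end, gname, fc in self._feat_rows:
            if start <= pos < end:
                width = end - start
                # sub-features (fc not None) beat the bare gene interval
                key = (fc is None, width)
                if best is None or key < best:
                    best = key
                    gene = gname
                    feature = fc if fc is not None else "intergenic"
        region = None
        for cls, (s, e) in self._region_spans.items():
            if s <= pos < e:
                region = f"{cls}-region"
                break
        sv_id, sv_w = None, None
        for sv in self.sv_regions:
            if sv.interval.contains(pos):
                w = len(sv.interval)
                if sv_w is None or w < sv_w:
                    sv_id, sv_w = sv.sv_id, w
        return gene, feature, region, sv_id

    # -- serialization ----------------------------------------------------

    def save(self, outdir: str):
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "reference.fasta"), "w") as f:
            f.write(f">{self.seq_id}\n")
            for i in range(0, len(self.sequence), 80):
                f.write(self.sequence[i:i + 80] + "\n")
        with open(os.path.join(outdir, "genes.bed"), "w") as f:
            for g in self.genes:
                rows = [("gene", g.locus_interval)] + list(g.features)
                for fc, iv in rows:
                    f.write("\t".join(map(str, (
                        self.seq_id, iv.start, iv.end, fc, 0, g.strand,
                        g.gene_name, g.segment_class, g.functional_class)))
                        + "\n")
        with open(os.path.join(outdir, "sv_regions.bed"), "w") as f:
            for sv in self.sv_regions:
                f.write("\t".join(map(str, (
                    self.seq_id, sv.interval.start, sv.interval.end,
                    sv.sv_id, 0, "+", int(sv.alt_is_absence),
                    int(sv.biallelic), sv.source_label or "."))) + "\n")
        with open(os.path.join(outdir, "liftover.tsv"), "w") as f:
            f.write("custom_start\tcustom_end\tbase_start\tbase_end\n")
            for cs, ce, bs, be in self._lift:
                f.write(f"{cs}\t{ce}\t{bs}\t{be}\n")

    @classmethod
    def load(cls, outdir: str) -> "LocusReference":
        seq_id, seq = _read_single_fasta(os.path.join(outdir, "reference.fasta"))
        genes_rows = {}
        with open(os.path.join(outdir, "genes.bed")) as f:
            for line in f:
                c = line.rstrip("\n").split("\t")
                _, s, e, fc, _, strand, gname, seg, func = c[:9]
                rec = genes_rows.setdefault(
                    gname, {"seg": seg, "func": func, "strand": strand,
                            "gene": None, "features": []})
                iv = GenomicInterval(seq_id, int(s), int(e), strand)
                if fc == "gene":
                    rec["gene"] = iv
                else:
                    rec["features"].append((fc, iv))
        genes = [GeneAnnotation(n, r["seg"], r["gene"],
                                tuple(r["features"]), r["func"])
                 for n, r in genes_rows.items()]
        svs = []
        p = os.path.join(outdir, "sv_regions.bed")
        if os.path.exists(p):
            with open(p) as f:
                for line in f:
                    c = line.rstrip("\n").split("\t")
                    svs.append(SVRegion(
                        c[3], GenomicInterval(seq_id, int(c[1]), int(c[2])),
                        bool(int(c[6])), bool(int(c[7])),
                        "" if c[8] == "." else c[8]))
        lift = []
        with open(os.path.join(outdir, "liftover.tsv")) as f:
            next(f)
            for line in f:
                lift.append(tuple(int(x) for x in line.split()))
        return cls(seq, svs, genes, lift, seq_id=seq_id)


def build_custom_reference(base_sequence: str, insertions, genes,
                           seq_id: str = "custom") -> LocusReference:
    """Splice SV insertion sequences into a base locus sequence.

    ``insertions`` is a list of ``(base_position, inserted_sequence, sv_id)``
    with positions strictly inside the base sequence, sorted strictly
    increasing.  Gene annotations are given in base coordinates and shifted
    by the cumulative inserted length to their left; a gene overlapping an
    insertion point is rejected (the splice would split its annotation).
    """
    n = len(base_sequence)
    prev = None
    seen = set()
    for pos, seq, sv_id in insertions:
        if not (0 < pos < n):
            raise ValueError(f"insertion position {pos} out of range")
        if prev is not None and pos <= prev:
            raise ValueError("insertion positions must be sorted and distinct")
        prev = pos
        if sv_id in seen:
            raise ValueError(f"duplicate sv_id {sv_id!r}")
        seen.add(sv_id)
    for g in genes:
        for pos, _, _ in insertions:
            if g.locus_interval.start < pos < g.locus_interval.end:
                raise ValueError(
                    f"gene {g.gene_name} overlaps insertion point {pos}")

    parts, lift, svs = [], [], []
    cpos, bpos = 0, 0
    for pos, seq, sv_id in insertions:
        seg = base_sequence[bpos:pos]
        parts.append(seg)
        lift.append((cpos, cpos + len(seg), bpos, pos))
        cpos += len(seg)
        parts.append(seq)
        svs.append(SVRegion(sv_id, GenomicInterval(seq_id, cpos, cpos + len(seq)),
                            alt_is_absence=True, biallelic=True))
        cpos += len(seq)
        bpos = pos
    seg = base_sequence[bpos:]
    if seg:
        parts.append(seg)
        lift.append((cpos, cpos + len(seg), bpos, n))
        cpos += len(seg)

    shifted_genes = []
    for g in genes:
        off = sum(len(seq) for pos, seq, _ in insertions
                  if pos <= g.locus_interval.start)
        shifted_genes.append(g.shifted(off, seq_id))
    return LocusReference("".join(parts), svs, shifted_genes, lift,
                          seq_id=seq_id)


def _read_single_fasta(path: str):
    name, chunks = None, []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    break
                name = line[1:].split()[0]
            elif line:
                chunks.append(line)
    return name, "".join(chunks)
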