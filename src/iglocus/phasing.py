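"""Read-backed phasing: het SNV candidates, read partitioning, blocks.

The phase stage detects candidate heterozygous SNVs from the read pileup,
partitions reads into two haplotypes by greedy agreement over the
candidate alleles, and tiles the read-covered locus into haplotype
blocks: *heterozygous* blocks (connected components of het SNVs linked by
assigned reads) and *homozygous_or_hemizygous* blocks (everything in
between — regions where both haplotypes agree, or where only one
chromosome is present; the two cannot be told apart from the pileup and
are disambiguated only downstream by SV evidence).

Only substitutions define candidates and blocks; indel heterozygosity is
handled at assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhasedSNV", "HaplotypeBlock", "filter_reads", "pileup_counts",
    "detect_het_candidates", "assign_reads", "define_blocks",
    "relabel_blocks_by_trio",
]

HET_CLASS = "heterozygous"
HOM_CLASS = "homozygous_or_hemizygous"


@dataclass
class PhasedSNV:
    position: int
    ref_base: str
    alt_base: str
    genotype: str = "0/1"
    phase: int = 0          # haplotype carrying the alt allele (1 or 2)
    block_id: str = ""


@dataclass
class HaplotypeBlock:
    block_id: str
    start: int
    end: int
    cls: str                          # HET_CLASS or HOM_CLASS
    phased_snvs: list = field(default_factory=list)
    read_partition: dict = field(default_factory=dict)

    @property
    def interval(self):
        return self.start, self.end

    def __len__(self):
        return self.end - self.start


def filter_reads(reads):
    """Keep reads built from at least 2 passes (order preserving)."""
    return [r for r in reads if getattr(r, "n_passes", 2) >= 2]


def pileup_counts(alignments, ref_len: int):
    """(ref_len, 4) base counts plus a deletion-coverage vector."""
    counts = np.zeros((ref_len, 4), dtype=np.int32)
    delcov = np.zeros(ref_len, dtype=np.int32)
    for a in alignments:
        rpos, qpos = a.matched_columns()
        codes = a.seq_codes[qpos]
        ok = codes < 4
        np.add.at(counts, (rpos[ok], codes[ok].astype(np.int64)), 1)
        for p, kind, l, _ in a.indel_events():
            if kind == "D":
                delcov[p:p + l] += 1
    return counts, delcov


def detect_het_candidates(alignments, ref_sequence: str, min_depth: int = 10,
                          min_alt_fraction: float = 0.25,
                          max_alt_fraction: float = 0.75, counts=None,
                          min_alt_count: int = 5):
    """Candidate heterozygous SNVs from the pileup.

    A position is a candidate iff base depth >= min_depth and the
    second-most-common base frequency lies in [min_alt_fraction,
    max_alt_fraction] with at least ``min_alt_count`` supporting reads
    (an absolute floor so a handful of coincident errors over a
    hemizygous stretch cannot fake a het site).  Only biallelic ref/alt
    substitutions are kept.  Returns ``(position, ref_base, alt_base)``
    tuples.
    """
    from .align import seq_to_codes
    if counts is None:
        counts, _ = pileup_counts(alignments, len(ref_sequence))
    depth = counts.sum(axis=1)
    order = np.argsort(counts, axis=1)
    top1 = order[:, -1]
    top2 = order[:, -2]
    n1 = np.take_along_axis(counts, top1[:, None], 1)[:, 0]
    n2 = np.take_along_axis(counts, top2[:, None], 1)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        f2 = np.where(depth > 0, n2 / np.maximum(depth, 1), 0.0)
    cand = (depth >= min_depth) & (f2 >= min_alt_fraction) & \
           (f2 <= max_alt_fraction) & (n2 >= min_alt_count)
    refcodes = seq_to_codes(ref_sequence)
    out = []
    bases = "ACGT"
    for p in np.flatnonzero(cand):
        rc = refcodes[p]
        a, b = top1[p], top2[p]
        if rc == a:
            alt = b
        elif rc == b:
            alt = a
        else:
            continue        # neither major allele is the reference base
        out.append((int(p), bases[rc], bases[alt]))
    return out


def assign_reads(alignments, candidates, max_rounds: int = 10):
    """Partition reads over candidate het sites by greedy agreement.

    Sites are first phased left to right within each read-connected
    component (a new site's allele is put on the haplotype favoured by
    reads covering it together with already-phased sites), then read
    assignment and per-site alleles are iterated to a fixed point.  Reads
    matching both haplotypes equally stay unassigned.

    Returns ``(phased_snvs, partition)`` with partition values 1, 2 or 0.
    """
    if not candidates:
        return [], {a.name: 0 for a in alignments}
    pos = np.array([c[0] for c in candidates], dtype=np.int64)
    nsites = len(pos)
    from .align import seq_to_codes
    alt_codes = np.array([seq_to_codes(c[2])[0] for c in candidates])
    ref_codes = np.array([seq_to_codes(c[1])[0] for c in candidates])

    # per-read observed allele at each covered site: +1 alt, -1 ref, 0 n/a
    obs = []
    for a in alignments:
        lo = np.searchsorted(pos, a.ref_start)
        hi = np.searchsorted(pos, a.ref_end)
        row = np.zeros(nsites, dtype=np.int8)
        if hi > lo:
            codes = a.base_at(pos[lo:hi])
            row[lo:hi] = np.where(codes == alt_codes[lo:hi], 1,
                                  np.where(codes == ref_codes[lo:hi], -1, 0))
        obs.append(row)
    obs = np.array(obs) if obs else np.zeros((0, nsites), dtype=np.int8)

    # connected components of sites through reads
    parent = np.arange(nsites)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row in obs:
        covered = np.flatnonzero(row)
        for a_, b_ in zip(covered, covered[1:]):
            ra, rb = find(a_), find(b_)
            if ra != rb:
                parent[rb] = ra

    # hap1 allele sign per site: +1 means hap1 carries alt
    hap1 = np.zeros(nsites, dtype=np.int8)
    comp = np.array([find(i) for i in range(nsites)])
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        hap1[members[0]] = 1
        phased = {members[0]}
        for s in members[1:]:
            vote = 0
            rows = np.flatnonzero(obs[:, s])
            for ri in rows:
                prev = [t for t in np.flatnonzero(obs[ri]) if t in phased]
                if not prev:
                    continue
                agree = sum(1 for t in prev if obs[ri, t] == hap1[t])
                side = 1 if agree * 2 >= len(prev) else -1
                vote += side * obs[ri, s]
            hap1[s] = 1 if vote >= 0 else -1
            phased.add(s)

    assign = np.zeros(len(alignments), dtype=np.int8)
    for _ in range(max_rounds):
        score = obs @ hap1.astype(np.int32)
        new_assign = np.sign(score).astype(np.int8)   # +1 hap1, -1 hap2
        # update alleles by majority of assigned reads
        new_hap1 = hap1.copy()
        for s in range(nsites):
            rows = np.flatnonzero(obs[:, s])
            v = int(np.sum(obs[rows, s] * new_assign[rows]))
            if v > 0:
                new_hap1[s] = 1
            elif v < 0:
                new_hap1[s] = -1
        stable = np.array_equal(new_assign, assign) and \
            np.array_equal(new_hap1, hap1)
        assign, hap1 = new_assign, new_hap1
        if stable:
            break

    partition = {}
    for a, s in zip(alignments, assign):
        partition[a.name] = 1 if s > 0 else (2 if s < 0 else 0)
    phased = [PhasedSNV(int(p), rb, ab, "0/1", 1 if h > 0 else 2)
              for p, rb, ab, h in zip(
                  pos, (c[1] for c in candidates),
                  (c[2] for c in candidates), hap1)]
    return phased, partition


def define_blocks(phased_snvs, alignments, partition, ref_len: int,
                  coverage=None):
    """Tile the covered locus into het and hom/hemizygous blocks.

    Two het SNVs share a block iff they are connected (transitively) by
    at least one assigned read covering both.  A het block spans its SNVs
    extended to the boundaries of the reads covering them, clipped at the
    midpoint between neighbouring blocks; the remaining covered intervals
    become homozygous_or_hemizygous blocks.
    """
    if coverage is None:
        coverage = np.zeros(ref_len, dtype=np.int32)
        for a in alignments:
            coverage[a.ref_start:a.ref_end] += 1
    cov_runs = _runs(coverage > 0)
    if not phased_snvs:
        blocks = [HaplotypeBlock(f"B{i + 1}", s, e, HOM_CLASS)
                  for i, (s, e) in enumerate(cov_runs)]
        for b in blocks:
            _fill_partition(b, alignments, partition)
        return blocks

    pos = np.array(sorted(s.position for s in phased_snvs))
    snv_by_pos = {s.position: s for s in phased_snvs}
    n = len(pos)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ext_lo = pos.copy()
    ext_hi = pos + 1
    for a in alignments:
        if partition.get(a.name, 0) == 0:
            continue
        lo = np.searchsorted(pos, a.ref_start)
        hi = np.searchsorted(pos, a.ref_end)
        if hi - lo >= 1:
            # a read's phase information stops at its own large deletion
            # when it covers no het site beyond the junction: the deleted
            # segment is hemizygous, not part of this phase domain
            lim_lo, lim_hi = a.ref_start, a.ref_end
            first_site, last_site = int(pos[lo]), int(pos[hi - 1])
            for p, kind, l, _ in a.indel_events(min_len=1_000):
                if kind != "D":
                    continue
                if p >= last_site:
                    lim_hi = min(lim_hi, p)
                if p + l <= first_site:
                    lim_lo = max(lim_lo, p + l)
            ext_lo[lo:hi] = np.minimum(ext_lo[lo:hi], lim_lo)
            ext_hi[lo:hi] = np.maximum(ext_hi[lo:hi], lim_hi)
        for x, y in zip(range(lo, hi - 1), range(lo + 1, hi)):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[ry] = rx

    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    het = []
    for members in comps.values():
        core = (int(pos[members[0]]), int(pos[members[-1]]) + 1)
        ext = (int(min(ext_lo[m] for m in members)),
               int(max(ext_hi[m] for m in members)))
        het.append({"core": core, "ext": ext, "members": members})
    het.sort(key=lambda h: h["core"][0])

    # clip extensions at midpoints between neighbouring cores
    for a, b in zip(het, het[1:]):
        mid = (a["core"][1] + b["core"][0]) // 2
        a["ext"] = (a["ext"][0], min(a["ext"][1], mid))
        b["ext"] = (max(b["ext"][0], mid), b["ext"][1])
    lo_cov = cov_runs[0][0] if cov_runs else 0
    hi_cov = cov_runs[-1][1] if cov_runs else ref_len
    blocks = []
    cursor = lo_cov
    bid = 0
    for h in het:
        s = max(h["ext"][0], lo_cov)
        if s > cursor:
            bid += 1
            blocks.append(HaplotypeBlock(f"B{bid}", cursor, s, HOM_CLASS))
        bid += 1
        e = min(h["ext"][1], hi_cov)
        blk = HaplotypeBlock(f"B{bid}", s, e, HET_CLASS)
        for m in h["members"]:
            snv = snv_by_pos[int(pos[m])]
            snv.block_id = blk.block_id
            blk.phased_snvs.append(snv)
        blocks.append(blk)
        cursor = e
    if cursor < hi_cov:
        bid += 1
        blocks.append(HaplotypeBlock(f"B{bid}", cursor, hi_cov, HOM_CLASS))
    for b in blocks:
        _fill_partition(b, alignments, partition)
    return blocks


def _fill_partition(block, alignments, partition):
    for a in alignments:
        if a.ref_start < block.end and block.start < a.ref_end:
            block.read_partition[a.name] = partition.get(a.name, 0)


def relabel_blocks_by_trio(blocks, mother: dict, father: dict):
    """Long-range phase: map block-local haplotype labels to parental
    origin by majority vote over each block's phased SNVs.

    ``mother``/``father`` map position -> genotype string.  A site votes
    when exactly one parent can have transmitted the alt allele; the
    majority over a block decides which local haplotype is maternal.
    Returns ``{block_id: {1: "maternal"|"paternal", 2: ...}}`` with
    unresolvable blocks omitted (they stay locally labeled).
    """
    out = {}
    for b in blocks:
        votes = 0          # >0: alt-carrying hap is maternal
        weight = 0
        for s in b.phased_snvs:
            m = mother.get(s.position)
            f = father.get(s.position)
            if m is None or f is None:
                continue
            m_has = "1" in m.replace("|", "/").split("/")
            f_has = "1" in f.replace("|", "/").split("/")
            if m_has == f_has:
                continue       # uninformative site
            sign = 1 if m_has else -1
            votes += sign if s.phase == 1 else -sign
            weight += 1
        if weight == 0 or votes == 0:
            continue
        hap1_is_maternal = votes > 0
        out[b.block_id] = {
            1: "maternal" if hap1_is_maternal else "paternal",
            2: "paternal" if hap1_is_maternal else "maternal",
        }
    return out


def _runs(mask: np.ndarray):
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def write_blocks_bed(blocks, seq_id: str, path: str):
    with open(path, "w") as f:
        for b in blocks:
            f.write("\t".join(map(str, (
                seq_id, b.start, b.end, b.block_id, 0, "+", b.cls,
                len(b.phased_snvs)))) + "\n")


def write_phased_vcf(phased_snvs, seq_id: str, path: str):
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={seq_id}>\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write('##FORMAT=<ID=PS,Number=1,Type=String,Description="Phase set">\n')
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for s in sorted(phased_snvs, key=lambda x: x.position):
            gt = "0|1" if s.phase == 2 else "1|0"
            f.write(f"{seq_id}\t{s.position + 1}\t.\t{s.ref_base}\t"
                    f"{s.alt_base}\t.\tPASS\t.\tGT:PS\t{gt}:{s.block_id}\n")
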