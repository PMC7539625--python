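"""Genotyping of reference-embedded biallelic SV regions.

Each embedded SV body is genotyped per haplotype from three evidence
channels, in priority order: contig span over the body (present),
junction-spanning contig alignment with a gap over >= 80% of the body
(absent), and — when contigs are silent — read depth over the body
relative to its flanks.  SNV calls inside the body corroborate a present
allele.  Conflicting channels yield a no-call with the evidence retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SVGenotype", "genotype_embedded_sv", "genotype_all",
           "write_sv_table"]

PRESENT, ABSENT, UNKNOWN = "present", "absent", None


@dataclass
class SVGenotype:
    sv_id: str
    genotype: str               # "present/present" | "present/absent" |
                                # "absent/absent" | "no-call"
    evidence: dict = field(default_factory=dict)
    phase_confident: bool = True


def _contig_state(contig, body, span_frac: float):
    """PRESENT/ABSENT/UNKNOWN from one contig over the SV body."""
    s, e = body
    cols = np.searchsorted(contig.col_ref, [s, e])
    covered = int(cols[1] - cols[0])
    length = e - s
    ov_s, ov_e = max(s, contig.ref_start), min(e, contig.ref_end)
    overlap = max(0, ov_e - ov_s)
    if overlap < 0.5 * length and covered < span_frac * length:
        # contig barely touches the body
        if contig.ref_start <= s and e <= contig.ref_end:
            pass        # spans the locus of the body: judge below
        else:
            return UNKNOWN, covered
    if contig.ref_start <= s and e <= contig.ref_end:
        if covered >= span_frac * length:
            return PRESENT, covered
        if (length - covered) >= span_frac * length:
            return ABSENT, covered
        return UNKNOWN, covered
    if covered >= span_frac * length:
        return PRESENT, covered
    return UNKNOWN, covered


def genotype_embedded_sv(sv, contigs, coverage=None, snvs=None,
                         span_frac: float = 0.8, depth_absent: float = 0.2,
                         depth_present: float = 0.6, flank: int = 2_000):
    """Genotype one embedded biallelic SV region.

    ``coverage`` is the base-supporting read depth vector; ``snvs`` the
    SNV call list (calls inside the body corroborate presence).
    """
    if not sv.biallelic:
        raise ValueError(f"{sv.sv_id}: not biallelic")
    body = (sv.interval.start, sv.interval.end)
    states = {}
    evidence = {"contigs": {}, "depth_ratio": None, "snvs_inside": 0}
    phase_conf = True
    for c in contigs:
        if c.ref_start >= body[1] or c.ref_end <= body[0]:
            continue
        state, covered = _contig_state(c, body, span_frac)
        if state is UNKNOWN:
            continue
        haps = (1, 2) if c.haplotype == 0 else (c.haplotype,)
        if not c.phase_confident:
            phase_conf = False
        for h in haps:
            prev = states.get(h)
            if prev is not None and prev != state:
                states[h] = "conflict"
            else:
                states.setdefault(h, state)
        evidence["contigs"][c.contig_id] = (state, covered)

    n_inside = 0
    if snvs:
        n_inside = sum(1 for v in snvs if body[0] <= v.start < body[1])
        evidence["snvs_inside"] = n_inside

    if coverage is not None:
        s, e = body
        fl = np.concatenate([
            coverage[max(0, s - flank):s], coverage[e:e + flank]])
        flank_depth = float(np.mean(fl)) if len(fl) else 0.0
        body_depth = float(np.mean(coverage[s:e])) if e > s else 0.0
        ratio = body_depth / flank_depth if flank_depth > 0 else None
        evidence["depth_ratio"] = ratio
    else:
        ratio = None

    if "conflict" in states.values():
        return SVGenotype(sv.sv_id, "no-call", evidence, phase_conf)
    got = [states.get(1), states.get(2)]
    if all(g is not None for g in got):
        gt = _format(got)
    elif any(g is not None for g in got):
        known = next(g for g in got if g is not None)
        # single-haplotype contig evidence: resolve the other from depth
        other = _depth_state(ratio, depth_absent, depth_present, known)
        gt = _format([known, other]) if other else "no-call"
    else:
        if ratio is None:
            return SVGenotype(sv.sv_id, "no-call", evidence, phase_conf)
        if ratio < depth_absent:
            gt = "absent/absent"
        elif ratio >= depth_present:
            gt = "present/present"
        else:
            gt = "present/absent"
        phase_conf = False
    if gt == "absent/absent" and n_inside > 0:
        return SVGenotype(sv.sv_id, "no-call", evidence, phase_conf)
    return SVGenotype(sv.sv_id, gt, evidence, phase_conf)


def _depth_state(ratio, depth_absent, depth_present, known):
    if ratio is None:
        return None
    # the known haplotype contributes roughly half the flank depth
    if known == PRESENT:
        return ABSENT if ratio < 0.5 + depth_absent / 2 else PRESENT
    return PRESENT if ratio >= depth_absent else ABSENT


def _format(states):
    order = {"present": 0, "absent": 1}
    a, b = sorted(states, key=lambda s: order[s])
    return f"{a}/{b}"


def genotype_all(ref, contigs, coverage=None, snvs=None, **kw):
    """Genotype every biallelic embedded SV, ordered by coordinate."""
    out = []
    for sv in ref.biallelic_svs:
        out.append(genotype_embedded_sv(sv, contigs, coverage, snvs, **kw))
    return out


def write_sv_table(genotypes, path: str):
    with open(path, "w") as f:
        f.write("sv_id\tgenotype\tdepth_ratio\tsnvs_inside\tcontig_evidence\n")
        for g in genotypes:
            ratio = g.evidence.get("depth_ratio")
            ev = ";".join(f"{cid}:{st}" for cid, (st, _) in
                          sorted(g.evidence.get("contigs", {}).items()))
            f.write(f"{g.sv_id}\t{g.genotype}\t"
                    f"{'' if ratio is None else f'{ratio:.3f}'}\t"
                    f"{g.evidence.get('snvs_inside', 0)}\t{ev or '.'}\n")
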