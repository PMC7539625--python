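import numpy as np
import pytest

from iglocus.pipeline import RunConfig, run_pipeline
from iglocus.synthetic import (DiploidConfig, ReadConfig, SVSpec,
                               default_allele_database, make_locus,
                               simulate_diploid, simulate_reads)


@pytest.fixture(scope="session")
def small_ref():
    """120 kb locus with one embedded SV insertion and 15 genes."""
    return make_locus(seed=101, length=120_000, n_v=8, n_d=4, n_j=3,
                      insertion_lengths=(5_000,))


@pytest.fixture(scope="session")
def small_db(small_ref):
    return default_allele_database(small_ref)


@pytest.fixture(scope="session")
def small_truth(small_ref):
    cfg = DiploidConfig(
        n_snv=60, het_fraction=2 / 3, n_indel=8,
        n_known_nonref_alleles=2, n_novel_alleles=1,
        sv_spec=(SVSpec("embedded_absence", sv_id="SV1", genotype="0|1"),
                 SVSpec("deletion", length=8_000, genotype="0|1"),
                 SVSpec("insertion", length=120, genotype="1|0"),
                 SVSpec("deletion", length=60, genotype="1|1")),
        vdj_deletion=True)
    return simulate_diploid(small_ref, cfg, seed=102)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    reads, _ = simulate_reads(small_truth, ReadConfig(coverage=20), seed=103)
    return reads


@pytest.fixture(scope="session")
def small_result(small_ref, small_db, small_truth, small_reads):
    """Noiseless end-to-end pipeline run shared across tests."""
    return run_pipeline(small_ref, small_db, small_reads, RunConfig())


def allele_truth_sets(truth):
    """Per-gene unordered truth allele sets for comparison."""
    out = {}
    for gene, hmap in truth.allele_assignments.items():
        out[gene] = sorted(
            (("vdj_suspect" if st == "vdj" else st),
             pay if st in ("known", "novel") else None)
            for st, pay in (hmap[1], hmap[2]))
    return out


def allele_call_sets(calls):
    out = {}
    for c in calls:
        payload = c.allele_name if c.status == "known" else (
            c.sequence if c.status == "novel" else None)
        out.setdefault(c.gene_name, []).append((c.status, payload))
    return {g: sorted(v) for g, v in out.items()}
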