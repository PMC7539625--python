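# Methods

This note documents the models, algorithms and numerical choices behind
`iglocus`, in the order the pipeline runs them, followed by what the
synthetic data does and does not emulate, and known limitations.

## Custom locus reference and coordinates

The working reference is the base locus sequence with known SV insertion
alleles spliced in at their breakpoints, so that reads carrying either
allele of a polymorphic insertion align contiguously.  Coordinates are
0-based half-open throughout; 1-based appears only in VCF output.  A
liftover table of `(custom, base)` segment pairs maps intervals between
coordinate systems; an interval intersecting an embedded insertion body
(custom side) or properly containing an insertion breakpoint (base side)
is unmappable, which makes round-trip liftover the identity on every
mappable interval.  Genes overlapping an insertion breakpoint are
rejected at build time rather than split — the embedded SVs of a real
capture design sit between genes, and a split annotation has no defined
meaning here.

Gene annotations are stored stranded; all internal processing is on the
plus strand of the custom sequence, and coding sequences are
reverse-complemented once at extraction time.  Position annotation
resolves the innermost feature (exon, intron, leader part 1, or
recombination signal); the V/D/J *region* classes are the spans from the
first to the last gene of each segment class, so intergenic positions
between V genes still annotate as V-region.

## Read placement

Reads are placed with minimap2 (map-hifi preset, single thread,
secondary alignments off).  Two post-processing steps matter:

* **Split-alignment stitching.**  minimap2 reports a read crossing a
  multi-kb deletion (an absent embedded-SV allele, a germline deletion,
  the V(D)J-like loss) as primary + supplementary segments.  Colinear
  same-strand segments are re-joined into a single gapped alignment,
  trimming up to 50 bp of query/reference overlap at the join; gaps up
  to 200 kb are stitched.
* **Indel left-alignment.**  Every I/D cigar op is shifted leftward
  through repeated reference context.  Different reads spanning a
  breakpoint-ambiguous deletion otherwise place it at different
  (equivalent) positions and split the consensus vote.

When voting into pileups and consensus columns, the first and last 5
aligned columns of each read are ignored (`edge_trim`): a read ending
exactly at an unrecognized breakpoint frequently gains one or two
spurious terminal matches across the junction.

## Phasing

Candidate het SNVs are pileup positions with depth >= 10 whose
second-most-common base has frequency in [0.15, 0.75] and at least 5
supporting reads.  The fraction floor is set below the conventional 0.25
because at 40x total depth the haplotype coverage ratio occasionally
dips to ~1:4, which would hide a genuine het site; the absolute floor of
5 reads prevents a handful of coincident sequencing errors over a
hemizygous stretch (local depth ~20x) from faking a site.  Only
biallelic reference/alt substitutions become candidates; indels do not
define phase.

Reads are partitioned by greedy agreement: sites are phased left to
right within each read-connected component (a new site joins the
haplotype favoured by reads that also cover already-phased sites), then
read assignment and per-site alleles are iterated to a fixed point
(<= 10 rounds).  Ties stay unassigned.  Haplotype labels are arbitrary
per block; every evaluator treats them as exchangeable.

Blocks tile the read-covered locus: het blocks are connected components
of sites linked by assigned reads, extended to the boundaries of the
reads covering them and clipped at the midpoint between neighbouring
components; the remainder is homozygous-or-hemizygous.  A read's
extension stops at its own >= 1 kb deletion junction when it covers no
het site beyond it — the deleted segment is hemizygous and belongs to no
phase domain.  Block boundaries are finally shifted out of read-supported
indel footprints and gene bodies (events are pushed into the homozygous
side, where the carrier/non-carrier machinery below resolves them; genes
must stay within one phase domain for allele extraction).

## Assembly

Assembly is reference-guided: layout is the reads' placement, and
consensus is per-column majority over each bin, with per-base quality
`min(60, -10*log10(1 - agreement))` and contig QV the mean over columns.
Contigs with mean QV < 20 are dropped (strictly below; a contig at
exactly Q20 is retained).

* **Bins.**  Het blocks get one bin per haplotype (reads whose het sites
  phased that block).  Hom blocks are assembled from all overlapping
  reads — except where a het indel *signature* (an indel shared by
  20–85% of spanning reads, >= 3 carriers, clustered by position and
  length) overlaps: the carrier span is carved out and carrier /
  non-carrier clusters are assembled separately as a locally phased pair
  (`phase_confident=False`).  This is also what isolates a somatic
  single-haplotype deletion cluster for separate reassembly.
* **Deletion columns** require a deletion majority *and* >= 3 deletion
  votes; a column with neither base support nor that much deletion
  support is uncovered and splits the contig — a single stray bridging
  read must not fabricate a deletion.  Insertions are included when
  supported by more than half the local depth; the inserted sequence is
  the most common exact string, polished by column majority when
  ambiguous, then left-normalized.
* **Thin stretches.**  Bin tails below depth 4 are trimmed, and interior
  runs >= 2 kb below depth 4 (the hemizygous interior of a large
  deletion, visible to only a few phased reads) are dropped; both are
  re-assembled by the recruitment pass.
* **Recruitment.**  Regions without consensus columns are re-assembled
  from the unfiltered read pool (including single-pass molecules, the
  stand-in for raw subreads).  A gap spanned by a single-haplotype
  contig's deletion is hemizygous: the new contig gets the complementary
  haplotype label, and reads crossing the gap as a deletion are excluded
  from its bin.  A second pass fills holes present on one haplotype only
  (variant-free spans only, so no phase information is invented).
* **Merging.**  Same-haplotype contigs overlapping >= 1000 bp merge when
  the overlap alignment has mismatch rate <= 0.002 and <= 20 gap bases
  (defaults consistent with curated-merge practice of ~5 mismatches and
  ~10 gap bases over a ~7.7 kb overlap); the higher-QV copy wins
  conflicting columns.  Discordant overlaps are reported, not merged.

## Variant detection

Because the consensus is built on reference coordinates, the contig ->
reference alignment is known by construction; SNVs are mismatch columns,
indels/SVs are the consensus deletion runs and insertion records of both
haplotypes projected against the reference (equivalent to a three-way
alignment restricted to pairwise-to-reference projection).  Events
separated by fewer than 10 matched columns merge into one replacement
event before size classification: 1 bp (reported as indel with size
class 1), 2–49 bp (indel), >= 50 bp (SV).  All events are left-aligned.

Genotypes come from the per-haplotype consensus alleles; phased (`0|1`)
within one confident block, unphased (`0/1`) across blocks or locally
phased pairs, haploid (`1`) where only one haplotype is covered.  For a
multi-kb event the reference allele needs only consensus bases across a
junction window, not a single contig spanning the whole footprint.
Assembly-only artifacts are suppressed by read-backed floors: an SNV
needs >= 3 pileup reads carrying the alt, an indel/SV >= 3 reads with a
matching event.  The `ccs_support` annotation itself keeps its
definition (>= 2 reads and >= 10% of the pileup).

A single-haplotype deletion >= 10 kb whose right edge falls within 25 kb
of the end of the J region is flagged as a putative V(D)J-like somatic
loss; calls inside it are marked artifact-suspect and affected genes
report `vdj_suspect` instead of `deleted`.

## Embedded-SV genotyping

Evidence priority is contig > junction > depth > SNV corroboration, with
thresholds exposed in the run config: a haplotype is *present* when a
contig aligns across >= 80% of the body, *absent* when a contig spans
the junction with a gap over >= 80% of the body; if contigs are silent,
the body/flank depth ratio decides (< 0.2 absent, >= 0.6 present,
between: one of each).  SNVs called inside the body veto an
absent/absent call.  Conflicting channels yield no-call with the
evidence retained.  Het calls are reported unordered
(`present/absent`), since hap labels are block-local.

## Allele assignment

The coding (exon) sequence of each gene is projected from the covering
consensus per haplotype.  A gene interrupted by a junction between
abutting same-haplotype contigs is stitched across it, unless a het site
lies inside the gene and the pieces come from different phase domains.
Matching is exact full-length against the database (IMGT-style
`gene*allele` FASTA; ambiguity codes rejected at load): any other
sequence is novel, reported with the nearest allele by edit distance
(lexicographic tie-break, tie flagged) and a substitution/indel diff
list.  Read support is the count of reads containing the exact assembled
allele sequence or its reverse complement — deliberately strict, so it
under-counts on noisy data; a one-mismatch approximate mode exists
behind a flag.

## Evaluation machinery

Genotypes compare as unordered allele multisets (phased, unphased and
haploid representations of the same call agree); matched-position,
different-genotype records are discordant and count toward both FP and
FN, never TP.  Liftover-unmappable query records occupy a separate
bucket.  The Hardy-Weinberg test is the exact conditional test (sum of
probabilities of heterozygote counts as or more extreme than observed,
computed by recurrence); the chi-square version is available and agrees
within 0.02 near Hardy-Weinberg-expected counts — the discrete test is
conservative on the het-excess side, where the two can differ by ~0.05.
Switch errors count adjacent evaluated-site pairs whose relative phase
flips; a global relabeling inverts every agreement indicator and leaves
the count unchanged, so the orientation minimum is implicit.

Assembly identity against truth is computed by alignment composition:
both a contig and a truth haplotype are edit sets on the reference, so
the error bases of a contig are the symmetric difference of the two
left-normalized edit sets over its span (large deletions compared as
interval sets, since a contig may start or end inside one).  This is
exact for sparse non-overlapping edits — the regime of a high-accuracy
consensus — and avoids quadratic alignment of megabase sequences.  The
alignment-based `assembly_concordance` is cross-checked against it in
the tests.

## Synthetic data: what it emulates, and what it does not

`make_locus` builds a random-sequence locus (default 600 kb) with 30 V
genes over the left three quarters (LP1 - intron - exon - RS layout, a
fifth of them minus-strand), 8 D and 6 J segments near the right end,
and two embedded SV insertions (8 and 15 kb).  The allele database
derives allele `*01` from each reference exon plus two alleles at 1–2
exonic substitutions.  `simulate_diploid` plants (defaults, chosen as
the study conditions): 300 SNVs (two thirds het), 20 indels of 2–49 bp,
absence alleles for both embedded SVs, a 25 kb heterozygous deletion, a
150 bp insertion, an 80 bp homozygous deletion, four known non-reference
and three novel gene alleles, and a V(D)J-like somatic deletion of the
D/J region on haplotype 2.  Variants are placed uniformly outside each
other's footprints, outside gene bodies (gene variation enters only
through allele assignments) and away from the locus ends, with >= 60 bp
separation so distinct events never merge during calling.

`simulate_reads` draws read lengths from a normal with mean 6,457 bp
(the observed CCS mean for this application class) and sd 1,200 bp,
truncated at mean + 4 sd — a size-selected library produces no
multi-mean-length molecules.  Coverage default is 20x per haplotype
(40x total).  Errors: mismatches and 1 bp indels at configurable rates,
with a configurable fraction of indels forced into homopolymer runs
(>= 3 equal bases); the noisy study condition is 0.6% mismatch + 0.4%
indel with bias 0.6.  Dropout intervals reduce sampling probability as a
capture-bias stand-in and are user-configured, not fitted.  The optional
subread mode emits noisy per-pass copies plus a majority-vote collapse,
solely to exercise the >= 2-pass filter and the recruitment fallback.

Not emulated: PCR duplicates, chimeras, barcode hopping, probe
thermodynamics, reference bias from real segmental duplications (the
random locus has no long repeats, so read placement is easier than in a
real IG locus), or per-base quality variation within a read.  Passing
tests therefore demonstrate the pipeline's logic, not its performance on
maximally repetitive real loci.

`simulate_multiplex` pools per-sample readsets and re-partitions them at
fixed total yield, so per-sample coverage scales exactly as total/plex;
the sweep in the tests uses a 100 kb locus with total yield equivalent
to 30x at 2-plex, ten pooling seeds, and scores each plex level against
both the simulator truth and the highest-coverage run.

## Problem sizes and determinism

The test suite runs the full pipeline on a 120 kb locus for unit-level
integration, the 600 kb study locus once noiseless and ten times at 1%
error for the recovery checks, and sixty small multiplex runs; the whole
suite takes about five minutes on one CPU.  All randomness flows from
explicit integer seeds; two runs with equal seeds produce byte-identical
outputs (verified in the CLI tests).

## Known limitations

* Het SNVs inside a region that looks homozygous to the pileup (e.g.
  masked by an undetected deletion on the other haplotype) are genotyped
  from single-allele evidence and emitted haploid.
* Indel calling in homopolymer runs is the weakest class on noisy data:
  alignment jitter spreads carrier support across positions, costing
  both recall and precision for 2–10 bp events; SNV and SV calls are
  unaffected.
* The evidence-combination rule for embedded-SV genotyping (priority
  cascade with 80% / 0.2x / 0.6x thresholds) is this package's own
  design; no published rule exists for combining assembly, read and SNV
  evidence at these regions.
* Complex multi-allelic SV regions are not genotyped automatically; the
  contig-merge report is the intended entry point for manual curation.
* Trio-based long-range phasing (`relabel_blocks_by_trio`) maps block
  labels to parental origin by majority vote over sites where exactly
  one parent carries the alt; blocks with no informative site stay
  locally labeled.  There is no statistical phasing across blocks.
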