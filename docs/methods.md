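# Methods

This note records the models, parameter choices and numerical conventions
behind somacall, and what the synthetic tests do and do not demonstrate.

## Windowing and read selection

The genome is processed in consecutive overlapping windows of
`window_size = 600` bp with `overlap = 250` bp (step 350). The overlap
exceeds the read length (148 bp in the default simulations), so any variant
short enough to be assembled lies fully interior to at least one window;
identical candidates discovered in two windows are deduplicated at merge
time, keeping the copy with the higher somatic score (ties: lower window
index). Windows are independent work units — a single-worker and any
multi-worker run merge to byte-identical VCFs, which the suite checks
directly.

Read selection drops duplicate/secondary/supplementary records and reads
with MAPQ < 10. Window statistics for scoring (percent "high-quality" reads)
count primary, non-duplicate reads with MAPQ ≥ 20 against all reads
overlapping the window.

A window is *active* when (a) some k-mer absent from the reference context
appears in at least `min_active_support = 2` distinct reads, or (b) any
passing read's CIGAR contains an insertion, a deletion, or a soft clip of
≥ 5 bases. Requiring two sharing reads suppresses isolated sequencing
errors. Read k-mers are compared against the window sequence padded by
300 bp on each side: reads overhang window boundaries, and without padding
every overhanging read would look novel.

## Local assembly

k is the smallest odd value in [11, 101] (step 2) for which no k-mer occurs
twice on the window's forward strand; a window with no such k (e.g. a long
homopolymer) is demoted with reason `no_k`. Bases with quality < 10 break
reads into fragments before k-merisation. Nodes carry per-sample counts
("colors"); node and edge multiplicities accumulate per occurrence, making
the graph independent of read input order.

Cleaning iterates two rules to a fixpoint: non-reference nodes with
tumor+normal count < 2 are removed, then dead-end branches of ≤ k nodes not
terminating at the window's source/sink are clipped. Reference-path nodes
are never removed, so the reference spelling always survives; cleaning is
monotone and idempotent.

Haplotype extraction enumerates all distinct simple source→sink paths
(depth-first, restricted to nodes that can reach the sink) and ranks them by
descending bottleneck support — the minimum edge traversal count along the
path, reference-only edges floored at 1 — then by length and contig string.
The top `max_paths = 16` are kept. We deliberately do not subtract extracted
paths' flow from the graph: with coverage-weighted capacities the global
coverage minimum almost always lies on *shared* reference edges, and
flow-style subtraction severs the shared chain before the alternate branch
of a heterozygous bubble can be extracted (we observed exactly this failure
on simulated het SNV windows). Windows whose graphs branch combinatorially
(more than 64 simple paths, or a blown search budget) are demoted with
reason `too_many_paths` rather than risking unbounded enumeration.

## Partial-order MSA and variant extraction

The reference seeds a partial-order graph; contigs are added in order of
descending support. Each addition is a global sequence-to-DAG alignment with
integer affine-gap scoring — match +2, mismatch −4, and a gap of length g
costs −(4 + 2g) — computed per node row with numpy (the horizontal gap state
collapses to a running maximum after rescaling out the extension decay).
Traceback re-derives decisions by exact integer comparison with a fixed
preference (diagonal > up > left, lowest predecessor first), so results are
deterministic. For a reference plus one contig the construction is exactly
Needleman–Wunsch, which the suite verifies against an independent scalar
implementation on hundreds of random pairs.

Aligned matches share nodes; mismatches join the same alignment column;
insertions add fresh nodes. Columns are the unions of mutually aligned
nodes, ordered topologically; reading each row off the column order gives
the MSA, and each row degaps back to its input sequence (property-tested).

Per non-reference row, maximal runs of difference columns (base mismatch or
one-sided gap; both-gap columns separate runs) become one event each. Runs
containing gaps are anchored on the nearest preceding column where both
rows have bases; runs at the MSA edge with no anchor are skipped. Events
are converted to VCF representation and left-normalized (trim shared
suffix, then prefix, shifting left while the spelled haplotype is
unchanged; an indel pinned at the window's first base keeps its shared
trailing base as the anchor). Normalization is idempotent and
haplotype-preserving, which the suite checks with a spell-the-haplotype
oracle on every normalization.

## Realignment genotyping

Reads are re-aligned glocally (read fully aligned, free target end gaps) to
the local reference and every contig with the same scoring as the MSA, in a
numba kernel. Alignments are ranked by gap-compressed identity
(`matches / (matches + mismatches + gap_opens)`, each gap counted once) then
score then target name. The winning target decides support: a read supports
the allele whose exact sequence it carries over the variant locus plus
`min_flank = 1` matching base on each side; when several targets tie and
disagree about the allele, the read is uninformative and counts toward depth
only. Identical target sequences are aligned once and shared; only reads
within 120 bp of a variant locus are realigned at all (others cannot
contribute support or depth).

A consequence of the exact-span rule: for alleles longer than the read
length (e.g. a 250 bp insertion with 148 bp reads) no read can span the
allele plus flanks, so such variants are discovered with correct
position/length but report depleted allele counts, and their genotype
degrades toward 0/0 (long insertions) or 1/1 (long deletions, whose alt
locus on the contig is short while the ref locus is unspannable). Genotypes
use a binomial likelihood over alt fractions {e, 0.5, 1−e} with
e = 0.001 (conventional short-read substitution scale); zero informative
reads give `./.`.

## Somatic scoring model

Seventeen features per candidate: window-level percent high-quality reads
per sample; variant type code, length, per-sample depth and absolute
tumor−normal VAF difference; per-sample allele counts, alt-read strand bias
(min(fwd,rev)/(fwd+rev), 0.5 = balanced, 0 = no alt reads), and mean alt
base/mapping quality. Zero-denominator VAFs are 0.

Training under-samples the non-somatic class to ~30 negatives per positive
(uniform, without replacement, seeded), then fits one shape function per
feature by cyclic boosting: each round visits the features in fixed order
and adds a learning-rate-scaled depth-1 split (Newton leaf values on the
logistic-loss gradient) into that feature's binned shape (quantile bins,
≤ 64). An update that would increase training loss is skipped, making the
loss history non-increasing by construction. Shapes are centered to mean
zero over the training data with offsets folded into the intercept, so a
constant feature contributes exactly zero and
`logit(p) = intercept + Σ_f shape_f(x_f)` decomposes every score exactly
(the explanation API uses the same arithmetic path; additivity is exact, not
approximate). Defaults: 500 rounds, learning rate 0.1, no interactions, no
bagging — the feature count is small and the synthetic cohorts separate
cleanly. Models serialize to a versioned JSON container; identical data and
seed reproduce identical bytes.

PASS thresholds are 0.95 for INS/DEL and 0.90 for SNV (MNV uses the SNV
cutoff, being substitution-like); both are user-overridable. Without a
model the caller emits unscored records with FILTER `PASS`.

## Two-tech rescue

Call sets from two platforms are matched by left-normalized exact
representation (chrom, pos, ref, alt) — a deliberate simplification of
haplotype-aware comparison; complex multi-variant equivalences that only a
haplotype matcher would catch are counted as platform-unique. Variants seen
by both platforms are COMMON. Platform-unique variants are rescued
(LR_ORIGIN / ILMN_ORIGIN) when the other platform's alignments show ≥ 2
exact alt-spelling reads at ≥ 20× spanning coverage (filtered depth:
primary reads, MAPQ ≥ 10 short / ≥ 5 long, allele bases ≥ Q10), else
DROPPED. Categories partition the input; the truth set is the sorted,
deduplicated union of the three kept categories.

## Synthetic data

The simulator emits uniform-random references, applies non-overlapping
variant specs to build haplotypes (germline het on haplotype 0, hom on
both), and models the tumor as a haplotype mixture: somatic variants sit on
extra haplotypes (derived from haplotype 0, grouped by VAF) whose mixture
weights equal their VAFs, so expected alt fractions are exact at somatic
loci while germline het loci stay at 0.5. Reads are paired 148-mers from
350 ± 50 bp fragments, with per-base substitution errors at a flat rate
(default 0.1%, base qualities set to the matching Phred value) and exact
positions/CIGARs derived from the haplotype→reference edit map — no
aligner touches the data. Pair counts are sized to the placeable span so
*interior* depth matches the requested coverage (80× tumor / 60× normal by
default); depth tapers at contig ends. Reads falling entirely inside a long
insertion have no reference anchor and are dropped (the mate's pair flags
are adjusted), which bounds recoverable insertions at roughly
2·(read_len − k) ≈ 280 bp — above the 250 bp sweep ceiling.

What the simulations do not model: indel sequencing errors, GC and coverage
bias, mapping ambiguity (all reads carry their true positions at MAPQ 60),
multi-clone tumors, and long-read error profiles. Passing tests therefore
demonstrate algorithmic correctness under idealized read placement, not
performance on real libraries, where mapping artifacts and systematic
errors dominate the false-positive budget.

## Problem sizes in the test suite

The suite favors many small seeded scenarios over few large ones: recovery
sweeps use 1,400 bp references with one central window per seed (20 seeds
per variant class at VAFs 0.5 and 0.25, discovery-stage assertions);
artifact-rejection runs 50 error-bearing variant-free windows against a
model trained on a 28-window synthetic cohort; the worked example uses the
full 2,000 bp two-sample pipeline. These sizes exercise every code path,
including window overlap merging and multi-worker determinism, while
keeping each scenario's arithmetic independently checkable.

## Known limitations

- Exact-match support assignment depletes allele counts for alleles longer
  than the read length (genotype, not discovery, degrades).
- Representation-based call-set matching misses haplotype-equivalent
  complex events.
- Somatic VAFs above 0.5 per clone are not expressible in the single-clone
  mixture model of the simulator.
- The caller is desk-scale: windows are recomputed independently, no
  attempt is made at whole-genome throughput.
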