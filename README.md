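# somacall

Somatic SNV and small-indel calling from matched tumor/normal short-read
data by **joint local assembly**: instead of trusting the original
alignments, somacall re-assembles every genomic window from tumor, normal
and reference k-mers jointly, so that insertions and deletions in the 30–250
bp "twilight zone" — where alignment-based callers suffer badly from
reference bias — are recovered as whole haplotypes rather than pieced
together from gapped alignments.

It is a desk-scale caller intended for methods work, teaching and synthetic
benchmarking: every stage is pure Python/numpy (with one numba kernel), fully
deterministic, and testable end-to-end against a built-in read simulator with
exact truth.

## How it works

1. **Windowing** — the genome is tiled into consecutive overlapping windows
   (default 600 bp, 250 bp overlap). A window is *active* when reads show a
   shared non-reference k-mer or indel/soft-clip CIGAR evidence.
2. **Colored de Bruijn assembly** — reference and read k-mers (smallest odd
   k with no repeated window k-mer) build a joint graph whose nodes carry
   per-sample ("color") counts. Weak non-reference nodes and dead-end tips
   are pruned; distinct source→sink haplotype paths are enumerated, ranked
   by bottleneck read support.
3. **Partial-order MSA** — the local reference and the assembled contigs are
   progressively aligned into a partial-order graph (affine-gap
   sequence-to-DAG dynamic programming; for two sequences this is exactly
   Needleman–Wunsch). Runs of difference columns become candidate variants,
   anchored and left-normalized to VCF convention.
4. **Realignment genotyping** — every read is re-aligned glocally to the
   reference and each contig; alignments are ranked by gap-compressed
   identity `matches / (matches + mismatches + gap_opens)` then score, and
   each read supports at most one allele per variant, by exact sequence
   match over the allele plus one flank base. Genotypes come from a binomial
   likelihood over {0/0, 0/1, 1/1}.
5. **Glass-box scoring** — candidates are scored by a cyclic additive
   boosting model over window-, variant- and allele-level features
   (`P(somatic) = σ(β₀ + Σ_f s_f(x_f))`), trained after random
   under-sampling of the non-somatic class to ~1:30. Every probability
   decomposes exactly into per-feature contributions. Default PASS
   thresholds: ≥ 0.95 for indels, ≥ 0.90 for substitutions.
6. **Extras** — per-window POA graphs export as GFA v1 for graph viewers; a
   "two-tech" module cross-validates two platforms' call sets, rescuing
   platform-unique variants supported by ≥ 2 alt reads at ≥ 20× coverage in
   the other platform's alignments.

## Worked example

Simulate a tumor/normal pair with a 70-bp heterozygous somatic deletion
(tumor VAF 0.5) on a 2,000 bp reference and call it:

```bash
python - <<'PY'
from somacall import simdata
ref = simdata.make_reference(2000, 7)
spec = simdata.VariantSpec(1000, ref[1000:1071], ref[1000], "het", "somatic", 0.5)
sim = simdata.simulate_pair(length=2000, specs=[spec], error_rate=0.0, seed=7)
simdata.write_fasta(ref, "chr1", "ref.fa")
simdata.write_bam(sim.tumor_reads, "chr1", 2000, "tumor.bam")
simdata.write_bam(sim.normal_reads, "chr1", 2000, "normal.bam")
PY
somacall call --tumor tumor.bam --normal normal.bam --reference ref.fa \
    --out calls.vcf --gfa-dir graphs/
```

Output (`wrote 1 records to calls.vcf`), with the VCF data line:

```
chr1  1000  .  ATCCTCTACT...(71 bp)  A  .  PASS  TYPE=DEL;LEN=70  GT:AD:DP  0/0:33,0:45  0/1:27,52:99
```

i.e. one deletion of LEN=70, genotyped heterozygous in the tumor (27 ref /
52 alt supporting reads) and absent from the normal (33 ref / 0 alt); the
anchor sits at position 1000 because left-normalization shifts the deletion
to its leftmost equivalent placement. `graphs/` holds the window's POA graph
in GFA for inspection in Bandage or a tube-map viewer.

The other subcommands: `somacall simulate` (synthetic data), `train` /
`score` (somatic model), `rescue` (two-tech truth sets). See `--help`.

## Layout

```
src/somacall/
  io_formats.py      FASTA/BAM/VCF/BED/GFA + model container
  window_engine.py   tiling, active regions, per-window calls, merging, CLI driver
  cdbg_assembly.py   colored de Bruijn graph build/clean/path enumeration
  msa_variants.py    partial-order MSA, variant extraction, left normalization
  realign_genotype.py glocal realignment, allele support, genotyping
  somatic_model.py   features, under-sampling, additive boosting, thresholds
  twotech_rescue.py  cross-platform truth-set construction
  simdata.py         seeded reference/haplotype/read simulator with exact truth
  bench.py           synthetic labeled cohorts and default model training
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
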