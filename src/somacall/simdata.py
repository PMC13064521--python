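"""Seeded tumor/normal read simulator with exact truth.

Generates a random reference, builds normal and tumor haplotypes by applying
germline and somatic variant specs, and emits paired-end reads directly with
their true alignments (positions and CIGARs derived from the haplotype→
reference edit map), so no external aligner is involved and every read's
provenance is known.  The tumor sample is a haplotype mixture: somatic
variants sit on an extra haplotype whose mixture weight equals the requested
tumor VAF.

Substitution sequencing errors only; indel errors, GC bias and long-read
error profiles are not modelled (a high ``error_rate`` crudely stands in for
a noisier platform where needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .io_formats import ReadRecord

__all__ = [
    "VariantSpec",
    "Haplotype",
    "HaplotypeSet",
    "SimResult",
    "make_reference",
    "build_haplotypes",
    "simulate_sample",
    "simulate_pair",
    "write_bam",
    "write_truth_vcf",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class VariantSpec:
    """An implanted variant; ``ref_allele`` must match the reference at pos0."""

    pos0: int
    ref_allele: str
    alt_allele: str
    zygosity: str = "het"  # het | hom
    origin: str = "somatic"  # somatic | germline
    tumor_vaf: float = 0.5  # somatic only; mixture weight of the alt haplotype

    @property
    def span(self) -> tuple[int, int]:
        return (self.pos0, self.pos0 + len(self.ref_allele))

    @property
    def vtype(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele):
            return "SNV" if len(self.ref_allele) == 1 else "MNV"
        return "INS" if len(self.alt_allele) > len(self.ref_allele) else "DEL"


# one op of a haplotype→reference edit map; M consumes both, I consumes
# haplotype only (anchored at ref_pos), D consumes reference only (anchored
# at hap_pos)
@dataclass(frozen=True)
class _EditOp:
    op: str
    hap_pos: int
    ref_pos: int
    length: int


@dataclass
class Haplotype:
    sequence: str
    ops: list[_EditOp]
    label: str

    def read_alignment(self, start: int, end: int):
        """True (ref_start, cigar) for haplotype interval [start, end).

        Returns None when the interval has no reference-consuming bases
        (a read living entirely inside an insertion).
        """
        parts: list[tuple[str, int]] = []
        ref_start = None
        for op in self.ops:
            if op.op == "D":
                if start < op.hap_pos < end:
                    parts.append(("D", op.length))
                continue
            lo = max(start, op.hap_pos)
            hi = min(end, op.hap_pos + op.length)
            if lo >= hi:
                continue
            if op.op == "M":
                if ref_start is None:
                    ref_start = op.ref_pos + (lo - op.hap_pos)
                parts.append(("M", hi - lo))
            else:  # I
                parts.append(("I", hi - lo))
        if ref_start is None:
            return None
        # strip edge deletions, soft-clip edge insertions
        while parts and parts[0][0] == "D":
            parts.pop(0)
        while parts and parts[-1][0] == "D":
            parts.pop()
        if parts and parts[0][0] == "I":
            parts[0] = ("S", parts[0][1])
        if parts and parts[-1][0] == "I":
            parts[-1] = ("S", parts[-1][1])
        merged: list[tuple[str, int]] = []
        for op_, n in parts:
            if merged and merged[-1][0] == op_:
                merged[-1] = (op_, merged[-1][1] + n)
            else:
                merged.append((op_, n))
        return ref_start, tuple(merged)


@dataclass
class HaplotypeSet:
    reference: str
    normal: list[Haplotype]
    normal_weights: list[float]
    tumor: list[Haplotype]
    tumor_weights: list[float]
    specs: list[VariantSpec]


@dataclass
class SimResult:
    reference: str
    chrom: str
    specs: list[VariantSpec]
    tumor_reads: list[ReadRecord]
    normal_reads: list[ReadRecord]
    read_haplotypes: dict[tuple[str, str], str] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def make_reference(length: int, seed: int) -> str:
    """Uniform-random ACGT sequence, deterministic per seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def _apply_variants(reference: str, specs: list[VariantSpec], label: str) -> Haplotype:
    """Apply non-overlapping specs (sorted by pos0) and build the edit map."""
    ops: list[_EditOp] = []
    pieces: list[str] = []
    cur_ref = 0
    cur_hap = 0
    for spec in sorted(specs, key=lambda s: s.pos0):
        if spec.pos0 < cur_ref:
            raise ValueError("overlapping variant specs")
        if reference[spec.pos0 : spec.pos0 + len(spec.ref_allele)] != spec.ref_allele:
            raise ValueError(f"ref allele mismatch at {spec.pos0}")
        lead = spec.pos0 - cur_ref
        if lead:
            ops.append(_EditOp("M", cur_hap, cur_ref, lead))
            pieces.append(reference[cur_ref : spec.pos0])
            cur_hap += lead
            cur_ref += lead
        ref_a, alt_a = spec.ref_allele, spec.alt_allele
        c = 0
        while c < min(len(ref_a), len(alt_a)) and ref_a[c] == alt_a[c]:
            c += 1
        mid = min(len(ref_a), len(alt_a)) - c  # mismatching M stretch
        if c + mid:
            ops.append(_EditOp("M", cur_hap, cur_ref, c + mid))
        pieces.append(alt_a)
        cur_hap += c + mid
        cur_ref += c + mid
        if len(alt_a) > len(ref_a):
            ins = len(alt_a) - len(ref_a)
            ops.append(_EditOp("I", cur_hap, cur_ref, ins))
            cur_hap += ins
        elif len(ref_a) > len(alt_a):
            dele = len(ref_a) - len(alt_a)
            ops.append(_EditOp("D", cur_hap, cur_ref, dele))
            cur_ref += dele
    if cur_ref < len(reference):
        ops.append(_EditOp("M", cur_hap, cur_ref, len(reference) - cur_ref))
        pieces.append(reference[cur_ref:])
    return Haplotype("".join(pieces), ops, label)


def build_haplotypes(reference: str, specs: list[VariantSpec]) -> HaplotypeSet:
    """Two normal haplotypes plus somatic-carrying tumor haplotypes.

    Germline het variants go on haplotype 0, hom on both.  Somatic specs are
    grouped by tumor_vaf; each group forms one extra tumor haplotype (derived
    from normal haplotype 0) whose mixture weight is that VAF, so the alt
    read fraction at each somatic locus equals the requested VAF in
    expectation while germline het loci stay at 0.5.
    """
    spans = sorted(s.span for s in specs)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("overlapping variant specs")
    germ = [s for s in specs if s.origin == "germline"]
    som = [s for s in specs if s.origin == "somatic"]
    h0_specs = germ
    h1_specs = [s for s in germ if s.zygosity == "hom"]
    h0 = _apply_variants(reference, h0_specs, "normal0")
    h1 = _apply_variants(reference, h1_specs, "normal1")

    groups: dict[float, list[VariantSpec]] = {}
    for s in som:
        groups.setdefault(round(s.tumor_vaf, 6), []).append(s)
    total_vaf = sum(groups)
    if total_vaf > 0.5 + 1e-9:
        raise ValueError("summed somatic VAFs exceed 0.5 (single-clone model)")
    tumor = [h0, h1]
    weights = [0.5 - total_vaf, 0.5]
    for i, vaf in enumerate(sorted(groups), 1):
        hap = _apply_variants(reference, h0_specs + groups[vaf], f"somatic{i}")
        tumor.append(hap)
        weights.append(vaf)
    return HaplotypeSet(
        reference=reference,
        normal=[h0, h1],
        normal_weights=[0.5, 0.5],
        tumor=tumor,
        tumor_weights=weights,
        specs=list(specs),
    )


def _phred(error_rate: float) -> int:
    if error_rate <= 0:
        return 60
    return min(60, int(round(-10.0 * math.log10(error_rate))))


def simulate_sample(
    haplotypes: list[Haplotype],
    weights: list[float],
    coverage: float,
    read_len: int,
    fragment_mean: float,
    fragment_sd: float,
    error_rate: float,
    seed: int,
    sample: str,
    chrom: str = "chr1",
    ref_len: int | None = None,
) -> tuple[list[ReadRecord], dict[tuple[str, str], str]]:
    """Paired reads from a weighted haplotype mixture with true alignments.

    Reads entirely inside an insertion have no reference anchor and are
    dropped (their mate loses proper-pair status); everything else carries
    its exact position and CIGAR.
    """
    if read_len >= fragment_mean:
        raise ValueError("read_len must be below fragment_mean")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    if ref_len is None:
        ref_len = max(len(h.sequence) for h in haplotypes)
    # fragments must fit inside the sequence, so starts span ref_len -
    # fragment_mean; sizing pairs to that span makes *interior* depth match
    # the requested coverage (edges taper)
    span = max(ref_len - fragment_mean, ref_len * 0.5)
    n_pairs = max(1, int(round(coverage * span / (2 * read_len))))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    qual = _phred(error_rate)
    reads: list[ReadRecord] = []
    assignment: dict[tuple[str, str], str] = {}
    hap_seqs = [np.frombuffer(h.sequence.encode(), dtype=np.uint8) for h in haplotypes]
    for i in range(n_pairs):
        hidx = int(rng.choice(len(haplotypes), p=w))
        hap = haplotypes[hidx]
        hlen = len(hap.sequence)
        frag = int(np.clip(round(rng.normal(fragment_mean, fragment_sd)), read_len, hlen))
        start = int(rng.integers(0, hlen - frag + 1))
        name = f"{sample}_{i:06d}"
        assignment[(sample, name)] = hap.label
        mate_info = []
        for strand, s in (("forward", start), ("reverse", start + frag - read_len)):
            seq = hap_seqs[hidx][s : s + read_len].copy()
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                for j in errs:
                    choices = _BASES[_BASES != seq[j]]
                    seq[j] = rng.choice(choices)
            aln = hap.read_alignment(s, s + read_len)
            mate_info.append((strand, seq.tobytes().decode(), aln))
        both_mapped = all(a is not None for _, _, a in mate_info)
        for strand, seqstr, aln in mate_info:
            if aln is None:
                continue
            ref_start, cigar = aln
            reads.append(
                ReadRecord(
                    name=name,
                    sequence=seqstr,
                    base_qualities=(qual,) * read_len,
                    mapping_quality=60,
                    strand=strand,
                    sample=sample,
                    chrom=chrom,
                    start=ref_start,
                    cigar=cigar,
                    proper_pair=both_mapped,
                )
            )
    reads.sort(key=lambda r: (r.start, r.name, r.strand))
    return reads, assignment


def simulate_pair(
    length: int = 2000,
    specs: list[VariantSpec] | None = None,
    tumor_coverage: float = 80.0,
    normal_coverage: float = 60.0,
    read_len: int = 148,
    fragment_mean: float = 350.0,
    fragment_sd: float = 50.0,
    error_rate: float = 0.001,
    seed: int = 7,
    chrom: str = "chr1",
) -> SimResult:
    """Reference + tumor/normal read sets for one synthetic locus."""
    specs = specs or []
    reference = make_reference(length, seed)
    haps = build_haplotypes(reference, specs)
    # sub-seeds kept below 2**31 and disjoint between samples
    tumor_reads, t_assign = simulate_sample(
        haps.tumor, haps.tumor_weights, tumor_coverage, read_len, fragment_mean,
        fragment_sd, error_rate, (seed * 2 + 1) % 2**31, "tumor", chrom, length,
    )
    normal_reads, n_assign = simulate_sample(
        haps.normal, haps.normal_weights, normal_coverage, read_len, fragment_mean,
        fragment_sd, error_rate, (seed * 2 + 2) % 2**31, "normal", chrom, length,
    )
    return SimResult(
        reference=reference,
        chrom=chrom,
        specs=specs,
        tumor_reads=tumor_reads,
        normal_reads=normal_reads,
        read_haplotypes={**t_assign, **n_assign},
    )


# ---------------------------------------------------------------------------
# on-disk outputs


def write_fasta(sequence: str, chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    pysam.faidx(str(path))


def write_bam(reads: list[ReadRecord], chrom: str, ref_len: int, path: str) -> None:
    """Coordinate-sorted, indexed BAM; deterministic for identical inputs."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": ref_len}]}
    mates: dict[str, list[ReadRecord]] = {}
    for r in reads:
        mates.setdefault(r.name, []).append(r)
    ordered = sorted(reads, key=lambda r: (r.start, r.name, r.strand))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.name
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities)
            )
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = r.mapping_quality
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            a.is_paired = True
            a.is_reverse = r.strand == "reverse"
            a.is_read1 = r.strand == "forward"
            a.is_read2 = r.strand == "reverse"
            a.is_proper_pair = r.proper_pair
            a.is_duplicate = r.duplicate
            a.is_secondary = r.secondary
            a.is_supplementary = r.supplementary
            pair = mates.get(r.name, [])
            mate = next((m for m in pair if m is not r), None)
            if mate is not None:
                a.next_reference_id = 0
                a.next_reference_start = mate.start
                a.mate_is_reverse = mate.strand == "reverse"
                span = max(r.reference_end, mate.reference_end) - min(r.start, mate.start)
                a.template_length = span if r.start <= mate.start else -span
            else:
                a.mate_is_unmapped = True
                a.next_reference_id = 0
                a.next_reference_start = r.start
            bam.write(a)
    pysam.index(str(path))


def write_truth_vcf(specs: list[VariantSpec], chrom: str, ref_len: int, path: str) -> None:
    """Truth VCF listing every implanted variant with origin and VAF."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="somatic or germline">')
    header.add_line('##INFO=<ID=ZYG,Number=1,Type=String,Description="het or hom">')
    header.add_line('##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor VAF (somatic)">')
    header.contigs.add(chrom, length=ref_len)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(specs, key=lambda v: v.pos0):
            rec = vcf.new_record(
                contig=chrom,
                start=s.pos0,
                stop=s.pos0 + len(s.ref_allele),
                alleles=(s.ref_allele, s.alt_allele),
            )
            rec.info["ORIGIN"] = s.origin
            rec.info["ZYG"] = s.zygosity
            if s.origin == "somatic":
                rec.info["TVAF"] = s.tumor_vaf
            vcf.write(rec)


def read_spec_tsv(path: str) -> list[VariantSpec]:
    """TSV columns: pos0, ref, alt, zygosity, origin, tumor_vaf."""
    specs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pos0"):
                continue
            pos0, ref, alt, zyg, origin, vaf = line.split("\t")
            specs.append(VariantSpec(int(pos0), ref, alt, zyg, origin, float(vaf)))
    return specs
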