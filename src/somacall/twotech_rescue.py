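"""Cross-platform truth-set construction ("two-tech" rescue).

Short-read and long-read call sets are matched by normalized exact
representation; variants seen by only one platform are rescued into the
truth set when the other platform's raw alignments show the alternate allele
in at least ``min_alt`` reads at ``min_cov`` or deeper coverage, and dropped
otherwise.  Matching is representation-based (left-normalized biallelic
records), not haplotype-aware, which is a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .io_formats import VcfRecord
from .msa_variants import _normalize_offsets

__all__ = [
    "CrossSupport",
    "match_callsets",
    "cross_support",
    "classify",
    "apply_exclusions",
    "build_truth_set",
]

CATEGORIES = ("COMMON", "LR_ORIGIN", "ILMN_ORIGIN", "DROPPED")


@dataclass(frozen=True)
class CrossSupport:
    alt_reads: int
    coverage: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.coverage:
            raise ValueError("alt_reads must lie in [0, coverage]")


def _normalized_key(rec: VcfRecord, reference: dict[str, str]) -> tuple:
    contig = reference[rec.chrom]
    pos0, ref_a, alt_a = _normalize_offsets(rec.pos - 1, rec.ref_allele, rec.alt_allele, contig)
    return (rec.chrom, pos0 + 1, ref_a, alt_a)


def match_callsets(
    set_a: list[VcfRecord],
    set_b: list[VcfRecord],
    reference: dict[str, str],
) -> tuple[list[VcfRecord], list[VcfRecord], list[VcfRecord]]:
    """Exact disjoint partition (common, a_only, b_only) after normalization.

    ``reference`` maps contig name to its full sequence; records whose ref
    allele disagrees with the reference raise.
    """
    keys_a = {_normalized_key(r, reference): r for r in set_a}
    keys_b = {_normalized_key(r, reference): r for r in set_b}
    common = [keys_a[k] for k in sorted(keys_a.keys() & keys_b.keys())]
    a_only = [keys_a[k] for k in sorted(keys_a.keys() - keys_b.keys())]
    b_only = [keys_b[k] for k in sorted(keys_b.keys() - keys_a.keys())]
    return common, a_only, b_only


def cross_support(
    bam_path: str,
    variant: VcfRecord,
    reference: dict[str, str],
    min_baseq: int = 10,
    min_mapq: int = 10,
) -> CrossSupport:
    """Direct allele counting from the other platform's alignments.

    Coverage counts passing primary reads whose alignment spans the variant
    locus plus one flank base on each side; alt reads are those whose
    aligned sequence between the flank anchors spells exactly
    flank + alt allele + flank, with every base at or above ``min_baseq``.
    """
    contig = reference[variant.chrom]
    pos0 = variant.pos - 1
    ref_a, alt_a = variant.ref_allele, variant.alt_allele
    f1 = max(0, pos0 - 1)
    f2 = min(len(contig) - 1, pos0 + len(ref_a))
    expected = contig[f1:pos0] + alt_a + (contig[f2] if f2 >= pos0 + len(ref_a) else "")
    coverage = 0
    alt_reads = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if variant.chrom not in bam.references:
            return CrossSupport(0, 0)
        for aln in bam.fetch(variant.chrom, f1, f2 + 1):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.reference_start > f1 or aln.reference_end < f2 + 1:
                continue
            coverage += 1
            qpos = {rp: qp for qp, rp in aln.get_aligned_pairs(matches_only=True)}
            q1, q2 = qpos.get(f1), qpos.get(f2)
            if q1 is None or q2 is None or q2 <= q1:
                continue
            seq = aln.query_sequence[q1 : q2 + 1]
            quals = aln.query_qualities[q1 : q2 + 1]
            if seq == expected and (quals is None or min(quals) >= min_baseq):
                alt_reads += 1
    return CrossSupport(alt_reads, coverage)


def classify(membership: str, support: CrossSupport | None, min_alt: int = 2, min_cov: int = 20) -> str:
    """Category per the rescue rule; boundary values are inclusive.

    both -> COMMON regardless of support; platform-unique calls need
    alt_reads >= min_alt and coverage >= min_cov in the other platform to be
    rescued, else DROPPED.
    """
    if membership == "both":
        return "COMMON"
    if membership not in ("long_only", "short_only"):
        raise ValueError(f"unknown membership {membership!r}")
    if support is not None and support.alt_reads >= min_alt and support.coverage >= min_cov:
        return "LR_ORIGIN" if membership == "long_only" else "ILMN_ORIGIN"
    return "DROPPED"


def apply_exclusions(variants: list[VcfRecord], bed_regions: list[tuple[str, int, int]]) -> list[VcfRecord]:
    """Drop variants whose 0-based position falls inside any BED region."""
    out = []
    for v in variants:
        p = v.pos - 1
        if any(c == v.chrom and s <= p < e for c, s, e in bed_regions):
            continue
        out.append(v)
    return out


def build_truth_set(
    short_records: list[VcfRecord],
    long_records: list[VcfRecord],
    short_bam: str,
    long_bam: str,
    reference: dict[str, str],
    min_alt: int = 2,
    min_cov: int = 20,
    min_baseq: int = 10,
    short_min_mapq: int = 10,
    long_min_mapq: int = 5,
    exclude: list[tuple[str, int, int]] | None = None,
) -> tuple[list[VcfRecord], list[dict]]:
    """Full rescue workflow: match, cross-count, classify, exclude.

    Returns (truth set records, per-variant report rows).  The truth set is
    COMMON ∪ LR_ORIGIN ∪ ILMN_ORIGIN, sorted and deduplicated; report rows
    cover every input variant so the categories partition the input.
    """
    if exclude:
        short_records = apply_exclusions(short_records, exclude)
        long_records = apply_exclusions(long_records, exclude)
    common, short_only, long_only = match_callsets(short_records, long_records, reference)
    rows: list[dict] = []
    truth: list[VcfRecord] = []

    def report(rec: VcfRecord, category: str, sup: CrossSupport | None):
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "vtype": rec.vtype,
                "category": category,
                "alt_reads": sup.alt_reads if sup else "",
                "coverage": sup.coverage if sup else "",
            }
        )

    for rec in common:
        report(rec, "COMMON", None)
        truth.append(rec)
    for rec in long_only:
        sup = cross_support(short_bam, rec, reference, min_baseq, short_min_mapq)
        cat = classify("long_only", sup, min_alt, min_cov)
        report(rec, cat, sup)
        if cat != "DROPPED":
            truth.append(rec)
    for rec in short_only:
        sup = cross_support(long_bam, rec, reference, min_baseq, long_min_mapq)
        cat = classify("short_only", sup, min_alt, min_cov)
        report(rec, cat, sup)
        if cat != "DROPPED":
            truth.append(rec)

    seen = set()
    unique = []
    for rec in sorted(truth, key=lambda r: r.key()):
        if rec.key() not in seen:
            seen.add(rec.key())
            unique.append(rec)
    return unique, rows
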