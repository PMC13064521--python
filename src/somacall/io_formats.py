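"""File-format boundary: FASTA, BAM, VCF, BED, GFA and the model container.

Every other module touches the filesystem only through the readers/writers
here.  Coordinates are 0-based half-open internally; the 1-based convention
appears only on the VCF boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pysam

__all__ = [
    "ReadRecord",
    "VcfRecord",
    "GfaGraph",
    "read_reference_window",
    "contig_lengths",
    "load_reads",
    "write_vcf",
    "read_vcf",
    "read_bed",
    "write_gfa",
    "parse_gfa",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class ReadRecord:
    """A selected read in reference orientation (as stored in BAM).

    ``sequence`` and ``base_qualities`` are the aligned-strand values, so
    k-mers taken from them are already in reference orientation.
    """

    name: str
    sequence: str
    base_qualities: tuple[int, ...]
    mapping_quality: int
    strand: str  # "forward" | "reverse"
    sample: str  # "tumor" | "normal"
    chrom: str
    start: int  # 0-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]  # (op, length); ops MIDNSHP=X
    duplicate: bool = False
    secondary: bool = False
    supplementary: bool = False
    proper_pair: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence/base_qualities length mismatch")
        if self.start < 0:
            raise ValueError("negative start")

    @property
    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS=X")

    @property
    def reference_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in "MDN=X")


@dataclass
class VcfRecord:
    """One biallelic VCF data line (1-based ``pos``)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    filter: str = "PASS"
    vtype: str = "SNV"  # INFO TYPE: SNV | INS | DEL | MNV
    length: int = 0  # INFO LEN = |len(alt) - len(ref)|
    score: float | None = None  # INFO SCORE: somatic probability
    samples: dict[str, dict] = field(default_factory=dict)
    # per sample: {"GT": "0/1", "AD": (ref, alt), "DP": int}

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class GfaGraph:
    segments: dict[str, str]
    links: list[tuple[str, str, str, str, str]]  # from, fo, to, to_o, overlap
    paths: dict[str, list[tuple[str, str]]]  # name -> [(segment, orient)]

    def validate(self) -> None:
        for a, _, b, _, _ in self.links:
            if a not in self.segments or b not in self.segments:
                raise ValueError(f"link references missing segment {a}/{b}")
        for name, steps in self.paths.items():
            for seg, _ in steps:
                if seg not in self.segments:
                    raise ValueError(f"path {name} references missing segment {seg}")

    def spell_path(self, name: str) -> str:
        """Concatenate segment sequences (0M overlaps, all forward)."""
        return "".join(self.segments[seg] for seg, _ in self.paths[name])


# ---------------------------------------------------------------------------
# FASTA


def read_reference_window(fasta_path: str, chrom: str, start: int, end: int) -> str:
    """Uppercase reference slice [start, end) from an indexed FASTA."""
    with pysam.FastaFile(str(fasta_path)) as fa:
        if chrom not in fa.references:
            raise KeyError(f"unknown contig {chrom!r}")
        clen = fa.get_reference_length(chrom)
        if not (0 <= start < end <= clen):
            raise ValueError(f"window [{start},{end}) out of bounds for {chrom} (len {clen})")
        return fa.fetch(chrom, start, end).upper()


def contig_lengths(fasta_path: str) -> dict[str, int]:
    with pysam.FastaFile(str(fasta_path)) as fa:
        return {name: fa.get_reference_length(name) for name in fa.references}


# ---------------------------------------------------------------------------
# BAM


_DROPPABLE = {"duplicate", "secondary", "supplementary"}


def load_reads(
    bam_path: str,
    chrom: str,
    start: int,
    end: int,
    min_mapq: int = 0,
    drop_flags: frozenset[str] | set[str] = frozenset(),
    sample: str = "tumor",
) -> list[ReadRecord]:
    """Reads overlapping [start, end) passing filters, sorted (start, name).

    The ordering is invariant to BAM record insertion order so downstream
    window calls are deterministic.
    """
    bad = set(drop_flags) - _DROPPABLE
    if bad:
        raise ValueError(f"unknown drop flags {bad}")
    out: list[ReadRecord] = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for aln in bam.fetch(chrom, start, end):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if "duplicate" in drop_flags and aln.is_duplicate:
                continue
            if "secondary" in drop_flags and aln.is_secondary:
                continue
            if "supplementary" in drop_flags and aln.is_supplementary:
                continue
            quals = aln.query_qualities
            out.append(
                ReadRecord(
                    name=aln.query_name,
                    sequence=aln.query_sequence.upper(),
                    base_qualities=tuple(quals) if quals is not None else (30,) * len(aln.query_sequence),
                    mapping_quality=aln.mapping_quality,
                    strand="reverse" if aln.is_reverse else "forward",
                    sample=sample,
                    chrom=chrom,
                    start=aln.reference_start,
                    cigar=tuple((op, n) for op, n in _cigar_ops(aln)),
                    duplicate=aln.is_duplicate,
                    secondary=aln.is_secondary,
                    supplementary=aln.is_supplementary,
                    proper_pair=aln.is_proper_pair,
                )
            )
    out.sort(key=lambda r: (r.start, r.name, r.strand))
    return out


_CIGAR_CODES = "MIDNSHP=X"


def _cigar_ops(aln: pysam.AlignedSegment):
    for code, n in aln.cigartuples or []:
        yield _CIGAR_CODES[code], n


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_LINES = [
    ('INFO', '<ID=TYPE,Number=1,Type=String,Description="Variant type (SNV/INS/DEL/MNV)">'),
    ('INFO', '<ID=LEN,Number=1,Type=Integer,Description="Absolute allele length difference">'),
    ('INFO', '<ID=SCORE,Number=1,Type=Float,Description="Somatic probability from the additive boosting model">'),
    ('FILTER', '<ID=LowScore,Description="Somatic probability below the type-specific threshold">'),
    ('FORMAT', '<ID=GT,Number=1,Type=String,Description="Genotype">'),
    ('FORMAT', '<ID=AD,Number=R,Type=Integer,Description="Ref and alt allele read depths">'),
    ('FORMAT', '<ID=DP,Number=1,Type=Integer,Description="Read depth spanning the locus">'),
]


def write_vcf(
    records: list[VcfRecord],
    sample_names: list[str],
    reference: dict[str, int] | str,
    path: str,
) -> None:
    """Write VCFv4.2; records must be sorted by (chrom, pos).

    ``reference`` is either a {contig: length} map or a FASTA path.
    Deterministic: identical inputs produce identical bytes.
    """
    if isinstance(reference, str):
        reference = contig_lengths(reference)
    order = [(r.chrom, r.pos) for r in records]
    if order != sorted(order):
        raise ValueError("records not sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    for key, line in _VCF_HEADER_LINES:
        header.add_line(f"##{key}={line}")
    for name, length in reference.items():
        header.contigs.add(name, length=length)
    for s in sample_names:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref_allele),
                alleles=(r.ref_allele, r.alt_allele),
            )
            rec.filter.add(r.filter)
            rec.info["TYPE"] = r.vtype
            rec.info["LEN"] = r.length
            if r.score is not None:
                rec.info["SCORE"] = round(float(r.score), 6)
            for s in sample_names:
                fmt = r.samples.get(s, {})
                gt = fmt.get("GT", "./.")
                rec.samples[s]["GT"] = tuple(None if g == "." else int(g) for g in gt.split("/"))
                if "AD" in fmt:
                    rec.samples[s]["AD"] = tuple(fmt["AD"])
                if "DP" in fmt:
                    rec.samples[s]["DP"] = fmt["DP"]
            vcf.write(rec)


def read_vcf(path: str) -> tuple[list[VcfRecord], list[str]]:
    """Parse a VCF written by :func:`write_vcf` (or any biallelic VCF)."""
    out: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"record at {rec.chrom}:{rec.pos} is not biallelic")
            info = dict(rec.info)
            per_sample = {}
            for s in samples:
                fmt = rec.samples[s]
                entry = {}
                gt = fmt.get("GT")
                if gt is not None:
                    entry["GT"] = "/".join("." if g is None else str(g) for g in gt)
                if fmt.get("AD") is not None:
                    entry["AD"] = tuple(fmt["AD"])
                if fmt.get("DP") is not None:
                    entry["DP"] = fmt["DP"]
                per_sample[s] = entry
            ref, alt = rec.ref, rec.alts[0]
            out.append(
                VcfRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    filter=list(rec.filter)[0] if list(rec.filter) else "PASS",
                    vtype=info.get("TYPE", _infer_vtype(ref, alt)),
                    length=int(info.get("LEN", abs(len(alt) - len(ref)))),
                    score=float(info["SCORE"]) if "SCORE" in info else None,
                    samples=per_sample,
                )
            )
    return out, samples


def _infer_vtype(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """3-column BED, 0-based half-open."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {ln}: {line!r}") from exc
            if start < 0 or end < start:
                raise ValueError(f"invalid BED interval on line {ln}")
            regions.append((parts[0], start, end))
    return regions


# ---------------------------------------------------------------------------
# GFA v1


def write_gfa(graph: GfaGraph, path: str) -> None:
    """GFA v1 with all-forward orientations and 0M overlaps."""
    graph.validate()
    lines = ["H\tVN:Z:1.0"]
    for seg in sorted(graph.segments):
        lines.append(f"S\t{seg}\t{graph.segments[seg]}")
    for a, ao, b, bo, ov in sorted(graph.links):
        lines.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t{ov}")
    for name in graph.paths:
        steps = ",".join(f"{seg}{orient}" for seg, orient in graph.paths[name])
        overlaps = ",".join(["0M"] * max(0, len(graph.paths[name]) - 1)) or "*"
        lines.append(f"P\t{name}\t{steps}\t{overlaps}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_gfa(path: str) -> GfaGraph:
    segments: dict[str, str] = {}
    links: list[tuple[str, str, str, str, str]] = []
    paths: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "S":
                segments[fields[1]] = fields[2]
            elif fields[0] == "L":
                links.append((fields[1], fields[2], fields[3], fields[4], fields[5]))
            elif fields[0] == "P":
                steps = [(s[:-1], s[-1]) for s in fields[2].split(",")]
                paths[fields[1]] = steps
    graph = GfaGraph(segments=segments, links=links, paths=paths)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# model container

_MODEL_FORMAT = "somacall-additive-model"
_MODEL_VERSION = 1


def save_model(model, path: str) -> None:
    """Serialize an additive boosting model as a versioned JSON container."""
    payload = model.to_dict()
    if not payload.get("feature_names"):
        raise ValueError("refusing to save a model with no features")
    doc = {"format": _MODEL_FORMAT, "version": _MODEL_VERSION, "model": payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str):
    from .somatic_model import EbmModel

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted model file {path}") from exc
    if doc.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path} is not a {_MODEL_FORMAT} file")
    if doc.get("version") != _MODEL_VERSION:
        raise ValueError(f"unsupported model version {doc.get('version')}")
    return EbmModel.from_dict(doc["model"])
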