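"""Genome tiling, active-region detection, per-window calling and merging.

The genome is processed in consecutive overlapping windows; each window is an
independent work unit, so a single-worker run and any multi-worker run merge
to byte-identical output.  A window showing read evidence of non-reference
sequence ("active") is assembled, aligned and genotyped; windows that fail
any stage are demoted to "no calls" with a reason code instead of raising.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace

from . import cdbg_assembly as asm
from . import io_formats as io
from . import msa_variants as mv
from . import realign_genotype as rg
from . import somatic_model as sm

logger = logging.getLogger("somacall")

__all__ = [
    "Window",
    "CallerConfig",
    "WindowResult",
    "tile_genome",
    "detect_active_region",
    "call_window",
    "merge_windows",
    "run_calling",
]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    index: int


@dataclass
class CallerConfig:
    window_size: int = 600
    overlap: int = 250
    min_mapq: int = 10
    drop_flags: frozenset = frozenset({"duplicate", "secondary", "supplementary"})
    min_active_support: int = 2
    min_clip: int = 5
    k_min: int = 11
    k_max: int = 101
    k_step: int = 2
    min_base_q: int = 10
    min_node_cov: int = 2
    max_paths: int = 16
    scoring: mv.Scoring = field(default_factory=mv.Scoring)
    min_flank: int = 1
    genotype_error_rate: float = 0.001
    hq_mapq: int = 20
    thresholds: dict = field(default_factory=lambda: dict(sm.DEFAULT_THRESHOLDS))

    @classmethod
    def from_file(cls, path: str) -> "CallerConfig":
        """key=value overrides, one per line; '#' starts a comment."""
        cfg = cls()
        numeric = {
            f: type(getattr(cfg, f))
            for f in ("window_size", "overlap", "min_mapq", "min_active_support",
                      "min_clip", "k_min", "k_max", "k_step", "min_base_q",
                      "min_node_cov", "max_paths", "min_flank",
                      "genotype_error_rate", "hq_mapq")
        }
        out = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key in numeric:
                    out[key] = numeric[key](value)
                elif key in ("threshold_snv", "threshold_indel"):
                    th = out.setdefault("thresholds", dict(sm.DEFAULT_THRESHOLDS))
                    if key == "threshold_snv":
                        th["SNV"] = th["MNV"] = float(value)
                    else:
                        th["INS"] = th["DEL"] = float(value)
                else:
                    raise KeyError(f"unknown config key {key!r}")
        return replace(cfg, **out)


@dataclass
class WindowResult:
    window: Window
    records: list[io.VcfRecord] = field(default_factory=list)
    reason: str | None = None  # no_k | too_many_paths | no_contigs | inactive
    msa: mv.Msa | None = None
    candidates: list = field(default_factory=list)  # (CandidateVariant, AlleleSupport)
    stats: dict = field(default_factory=dict)  # window-level feature inputs


# ---------------------------------------------------------------------------


def tile_genome(contig_lengths: dict[str, int], window_size: int = 600, overlap: int = 250) -> list[Window]:
    """Consecutive overlapping windows covering every contig base."""
    if overlap >= window_size:
        raise ValueError("overlap must be smaller than window_size")
    step = window_size - overlap
    windows: list[Window] = []
    index = 0
    for chrom, length in contig_lengths.items():
        start = 0
        while True:
            end = min(start + window_size, length)
            windows.append(Window(chrom, start, end, index))
            index += 1
            if end >= length:
                break
            start += step
    return windows


def detect_active_region(
    tumor_reads: list[io.ReadRecord],
    normal_reads: list[io.ReadRecord],
    ref_window: str,
    k: int,
    min_active_support: int = 2,
    min_clip: int = 5,
) -> bool:
    """True when reads show shared non-reference k-mers or indel/clip CIGARs.

    A novel k-mer seen in a single read (a lone sequencing error) does not
    trigger assembly; the same k-mer in >= min_active_support reads does.
    """
    for read in tumor_reads + normal_reads:
        for op, length in read.cigar:
            if op in "ID" or (op == "S" and length >= min_clip):
                return True
    ref_kmers = {ref_window[i : i + k] for i in range(len(ref_window) - k + 1)}
    novel_counts: dict[str, int] = {}
    for read in tumor_reads + normal_reads:
        seen: set[str] = set()
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer not in ref_kmers and kmer not in seen:
                seen.add(kmer)
                novel_counts[kmer] = novel_counts.get(kmer, 0) + 1
                if novel_counts[kmer] >= min_active_support:
                    return True
    return False


def _window_stats(tumor_all, normal_all, config: CallerConfig) -> dict:
    stats = {}
    for name, reads in (("tumor", tumor_all), ("normal", normal_all)):
        hq = sum(
            1
            for r in reads
            if r.mapping_quality >= config.hq_mapq
            and not (r.duplicate or r.secondary or r.supplementary)
        )
        stats[f"pct_hq_reads_{name}"] = 100.0 * hq / len(reads) if reads else 0.0
    return stats


def _select(reads, config: CallerConfig):
    return [
        r
        for r in reads
        if r.mapping_quality >= config.min_mapq
        and not (
            ("duplicate" in config.drop_flags and r.duplicate)
            or ("secondary" in config.drop_flags and r.secondary)
            or ("supplementary" in config.drop_flags and r.supplementary)
        )
    ]


def call_window(
    window: Window,
    tumor_reads: list[io.ReadRecord],
    normal_reads: list[io.ReadRecord],
    ref_window: str,
    config: CallerConfig = CallerConfig(),
    model: sm.EbmModel | None = None,
    genotype: bool = True,
    ref_context: str | None = None,
) -> WindowResult:
    """Assembly → POA MSA → variant extraction → realignment genotyping.

    ``tumor_reads``/``normal_reads`` are the unfiltered window reads; read
    selection, window statistics and everything downstream happen here.  No
    exception escapes: failures demote the window with a reason code.
    Without a model, records carry no score and FILTER stays PASS.

    ``ref_context`` is the window sequence padded by up to a read length on
    each side; activity detection compares read k-mers against it so reads
    overhanging the window edges do not spuriously look non-reference.
    """
    result = WindowResult(window=window)
    stats = _window_stats(tumor_reads, normal_reads, config)
    result.stats = stats
    tumor = _select(tumor_reads, config)
    normal = _select(normal_reads, config)

    try:
        k = asm.select_k(ref_window, config.k_min, config.k_max, config.k_step)
    except asm.NoUsableK:
        result.reason = "no_k"
        logger.info("window %d %s:%d-%d demoted: no_k", window.index, window.chrom, window.start, window.end)
        return result

    if not detect_active_region(tumor, normal, ref_context or ref_window, k,
                                config.min_active_support, config.min_clip):
        result.reason = "inactive"
        return result

    graph = asm.build_graph(tumor, normal, ref_window, k, config.min_base_q)
    asm.clean_graph(graph, config.min_node_cov, k)
    try:
        paths = asm.enumerate_paths(graph, config.max_paths)
    except asm.TooManyPaths:
        result.reason = "too_many_paths"
        logger.info("window %d demoted: too_many_paths", window.index)
        return result
    contigs = [p for p in paths if p.contig != ref_window]
    if not paths:
        result.reason = "no_contigs"
        return result
    if not contigs:
        return result  # only the reference haplotype: no candidate variants

    ordered = sorted(enumerate(contigs), key=lambda t: (-t[1].min_edge_support, t[0]))
    names = ["ref"] + [f"hap{i}" for i in range(1, len(ordered) + 1)]
    msa = mv.poa_msa([ref_window] + [c.contig for _, c in ordered], config.scoring, names)
    result.msa = msa
    variants = mv.call_from_msa(msa, window.chrom, window.start, ref_window)
    variants = [v for v in variants if window.start < v.pos <= window.end]
    if not variants or not genotype:
        _records_without_support(result, variants)
        return result

    support = rg.assign_allele_support(tumor + normal, msa, variants,
                                       config.scoring, config.min_flank)
    for v in variants:
        sup = support[v.key()]
        result.candidates.append((v, sup))
        gt_t = rg.genotype_sample(sup.tumor, config.genotype_error_rate)
        gt_n = rg.genotype_sample(sup.normal, config.genotype_error_rate)
        prob = None
        filt = "PASS"
        if model is not None:
            x = sm.extract_features(v, sup, stats)
            prob = sm.score(model, x)
            filt = sm.apply_threshold(prob, v.vtype, config.thresholds)
        result.records.append(
            io.VcfRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                filter=filt,
                vtype=v.vtype,
                length=v.length,
                score=prob,
                samples={
                    "normal": {"GT": gt_n.gt, "AD": (sup.normal.ref_count, sup.normal.alt_count),
                               "DP": sup.normal.depth},
                    "tumor": {"GT": gt_t.gt, "AD": (sup.tumor.ref_count, sup.tumor.alt_count),
                              "DP": sup.tumor.depth},
                },
            )
        )
    return result


def _records_without_support(result: WindowResult, variants) -> None:
    for v in variants:
        result.records.append(
            io.VcfRecord(chrom=v.chrom, pos=v.pos, ref_allele=v.ref_allele,
                         alt_allele=v.alt_allele, vtype=v.vtype, length=v.length)
        )


def merge_windows(per_window: list[WindowResult]) -> list[io.VcfRecord]:
    """Deduplicate identical variants across overlapping windows.

    The copy with the higher somatic score wins; ties (including unscored
    records) keep the copy from the lower window index.  Output is sorted
    by (chrom, pos, ref, alt).
    """
    best: dict[tuple, tuple[float, int, io.VcfRecord]] = {}
    for result in sorted(per_window, key=lambda r: r.window.index):
        for rec in result.records:
            key = rec.key()
            rank = (-(rec.score if rec.score is not None else float("-inf")), result.window.index)
            if key not in best or rank < best[key][0:2]:
                best[key] = (rank[0], rank[1], rec)
    return sorted((v[2] for v in best.values()), key=lambda r: r.key())


# ---------------------------------------------------------------------------
# whole-run driver

_WORKER_STATE: dict = {}


_CONTEXT_PAD = 300  # read-length-scale padding for activity detection


def _call_one(args):
    window, paths, config, model = args
    tumor = io.load_reads(paths["tumor"], window.chrom, window.start, window.end, 0, frozenset(), "tumor")
    normal = io.load_reads(paths["normal"], window.chrom, window.start, window.end, 0, frozenset(), "normal")
    ref_window = io.read_reference_window(paths["reference"], window.chrom, window.start, window.end)
    lengths = io.contig_lengths(paths["reference"])
    lo = max(0, window.start - _CONTEXT_PAD)
    hi = min(lengths[window.chrom], window.end + _CONTEXT_PAD)
    context = io.read_reference_window(paths["reference"], window.chrom, lo, hi)
    return call_window(window, tumor, normal, ref_window, config, model, ref_context=context)


def run_calling(
    tumor_bam: str,
    normal_bam: str,
    reference_fasta: str,
    out_vcf: str,
    region: str | None = None,
    include_bed: str | None = None,
    exclude_bed: str | None = None,
    model: sm.EbmModel | None = None,
    config: CallerConfig | None = None,
    gfa_dir: str | None = None,
    threads: int = 1,
) -> list[io.VcfRecord]:
    """Tile, call every window, merge, and write the output VCF.

    Deterministic for any worker count: windows are independent and merged
    in window-index order.
    """
    from pathlib import Path

    config = config or CallerConfig()
    lengths = io.contig_lengths(reference_fasta)
    windows = tile_genome(lengths, config.window_size, config.overlap)
    if region:
        chrom, _, span = region.partition(":")
        if span:
            beg, _, end = span.partition("-")
            lo, hi = int(beg) - 1, int(end)
        else:
            lo, hi = 0, lengths[chrom]
        windows = [w for w in windows if w.chrom == chrom and w.start < hi and w.end > lo]
    if include_bed:
        regions = io.read_bed(include_bed)
        windows = [
            w for w in windows
            if any(c == w.chrom and w.start < e and w.end > s for c, s, e in regions)
        ]

    paths = {"tumor": str(tumor_bam), "normal": str(normal_bam), "reference": str(reference_fasta)}
    jobs = [(w, paths, config, model) for w in windows]
    if threads > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(_call_one, jobs, chunksize=4))
    else:
        results = [_call_one(j) for j in jobs]

    if gfa_dir:
        Path(gfa_dir).mkdir(parents=True, exist_ok=True)
        for res in results:
            if res.msa is not None and res.records:
                gfa = mv.msa_to_gfa(res.msa)
                name = f"{res.window.chrom}_{res.window.start}_{res.window.end}.gfa"
                io.write_gfa(gfa, str(Path(gfa_dir) / name))

    merged = merge_windows(results)
    if exclude_bed:
        from .twotech_rescue import apply_exclusions

        merged = apply_exclusions(merged, io.read_bed(exclude_bed))
    io.write_vcf(merged, ["normal", "tumor"], lengths, out_vcf)
    return merged
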