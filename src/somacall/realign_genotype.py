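"""Read realignment, allele support assignment, and genotyping.

Every constituent read is re-aligned (glocal: the read fully aligned, free
target end gaps) to the local reference and to each assembled contig.
Alignments are ranked by gap-compressed identity then score; the winning
target decides which allele the read supports, by exact sequence match over
the allele plus a flank on each side, and each read contributes at most one
count per variant.  Genotypes come from a three-hypothesis binomial
likelihood (allele fractions e, 0.5, 1-e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import binom

from .io_formats import ReadRecord
from .msa_variants import CandidateVariant, Msa, Scoring

__all__ = [
    "Alignment",
    "AlleleSupport",
    "SampleSupport",
    "Genotype",
    "align_read",
    "gap_compressed_identity",
    "assign_allele_support",
    "genotype_sample",
]

_NEG = np.int32(-(10**8))


@dataclass
class Alignment:
    target: str
    score: int
    cigar: list[tuple[str, int]]  # M / I (read gap in target) / D ops
    target_start: int
    matches: int
    mismatches: int
    gap_opens: int
    gap_bases: int
    # target_pos -> read_pos for M columns; insertion boundaries as target
    # positions with a read insertion immediately before them
    pairs: dict[int, int] = field(default_factory=dict)
    insertions_before: set[int] = field(default_factory=set)

    @property
    def target_end(self) -> int:
        return self.target_start + sum(n for op, n in self.cigar if op in "MD")


@njit(cache=True)
def _gotoh_fill(read, target, match, mismatch, go, ge):
    m, n = read.shape[0], target.shape[0]
    H = np.full((m + 1, n + 1), _NEG, np.int32)
    U = np.full((m + 1, n + 1), _NEG, np.int32)
    L = np.full((m + 1, n + 1), _NEG, np.int32)
    oc = go + ge
    for j in range(n + 1):
        H[0, j] = 0
    for i in range(1, m + 1):
        U[i, 0] = go + ge * i
        for j in range(1, n + 1):
            s = match if read[i - 1] == target[j - 1] else mismatch
            d = H[i - 1, j - 1]
            if U[i - 1, j - 1] > d:
                d = U[i - 1, j - 1]
            if L[i - 1, j - 1] > d:
                d = L[i - 1, j - 1]
            H[i, j] = d + s
            u = H[i - 1, j] + oc
            if L[i - 1, j] + oc > u:
                u = L[i - 1, j] + oc
            if U[i - 1, j] + ge > u:
                u = U[i - 1, j] + ge
            U[i, j] = u
            left = H[i, j - 1] + oc
            if U[i, j - 1] + oc > left:
                left = U[i, j - 1] + oc
            if L[i, j - 1] + ge > left:
                left = L[i, j - 1] + ge
            L[i, j] = left
    return H, U, L


@njit(cache=True)
def _gotoh_traceback(H, U, L, read, target, match, mismatch, go, ge):
    """Deterministic traceback: diagonal > up > left, smallest end column.

    Returns (steps, start_j, score) with steps coded 0=M, 1=I, 2=D in
    alignment order.
    """
    m, n = read.shape[0], target.shape[0]
    oc = go + ge
    best_j = 0
    best_state = 0  # 0=H, 1=U
    best_val = H[m, 0]
    for j in range(n + 1):
        if H[m, j] > best_val:
            best_j, best_state, best_val = j, 0, H[m, j]
        if U[m, j] > best_val:
            best_j, best_state, best_val = j, 1, U[m, j]
    i, j, state = m, best_j, best_state
    steps = np.empty(m + n + 2, np.int8)
    k = 0
    while i > 0:
        if state == 0:
            steps[k] = 0
            k += 1
            s = match if read[i - 1] == target[j - 1] else mismatch
            prev = H[i, j] - s
            if H[i - 1, j - 1] == prev:
                state = 0
            elif U[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            steps[k] = 1
            k += 1
            if H[i - 1, j] + oc == U[i, j]:
                state = 0
            elif L[i - 1, j] + oc == U[i, j]:
                state = 2
            else:
                state = 1
            i -= 1
        else:
            steps[k] = 2
            k += 1
            if H[i, j - 1] + oc == L[i, j]:
                state = 0
            elif U[i, j - 1] + oc == L[i, j]:
                state = 1
            else:
                state = 2
            j -= 1
    return steps[:k][::-1].copy(), j, best_val


def align_read(read_sequence: str, target_sequence: str, scoring: Scoring = Scoring(),
               target_name: str = "target") -> Alignment:
    """Optimal glocal alignment of the read against the target.

    Ties in the traceback prefer diagonal > up > left, and the smallest end
    column, so the result is deterministic.
    """
    if not read_sequence or not target_sequence:
        raise ValueError("empty sequence")
    read = np.frombuffer(read_sequence.encode(), dtype=np.uint8)
    target = np.frombuffer(target_sequence.encode(), dtype=np.uint8)
    H, U, L = _gotoh_fill(read, target, scoring.match, scoring.mismatch,
                          scoring.gap_open, scoring.gap_extend)
    steps, start_j, best_val = _gotoh_traceback(
        H, U, L, read, target, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    ops: list[tuple[str, int]] = []
    pairs: dict[int, int] = {}
    ins_before: set[int] = set()
    matches = mismatches = gap_opens = gap_bases = 0
    i, j = 0, start_j
    prev_op = -1
    for code in steps:
        if code == 0:
            pairs[j] = i
            if read_sequence[i] == target_sequence[j]:
                matches += 1
            else:
                mismatches += 1
            if prev_op == 0:
                ops[-1] = ("M", ops[-1][1] + 1)
            else:
                ops.append(("M", 1))
            i += 1
            j += 1
        elif code == 1:
            ins_before.add(j)
            gap_bases += 1
            if prev_op != 1:
                gap_opens += 1
                ops.append(("I", 1))
            else:
                ops[-1] = ("I", ops[-1][1] + 1)
            i += 1
        else:
            gap_bases += 1
            if prev_op != 2:
                gap_opens += 1
                ops.append(("D", 1))
            else:
                ops[-1] = ("D", ops[-1][1] + 1)
            j += 1
        prev_op = code
    return Alignment(
        target=target_name,
        score=int(best_val),
        cigar=ops,
        target_start=start_j,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gap_bases=gap_bases,
        pairs=pairs,
        insertions_before=ins_before,
    )


def gap_compressed_identity(alignment: Alignment) -> float:
    """matches / (matches + mismatches + gap openings); gaps count once."""
    denom = alignment.matches + alignment.mismatches + alignment.gap_opens
    if denom == 0:
        raise ValueError("degenerate alignment with no aligned columns")
    return alignment.matches / denom


# ---------------------------------------------------------------------------
# allele support


@dataclass
class SampleSupport:
    ref_fwd: int = 0
    ref_rev: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    alt_base_quals: list[int] = field(default_factory=list)
    alt_map_quals: list[int] = field(default_factory=list)
    ref_base_quals: list[int] = field(default_factory=list)
    ref_map_quals: list[int] = field(default_factory=list)
    depth: int = 0

    @property
    def ref_count(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def vaf(self) -> float:
        total = self.ref_count + self.alt_count
        return self.alt_count / total if total else 0.0


@dataclass
class AlleleSupport:
    tumor: SampleSupport = field(default_factory=SampleSupport)
    normal: SampleSupport = field(default_factory=SampleSupport)

    def sample(self, name: str) -> SampleSupport:
        return self.tumor if name == "tumor" else self.normal


def replace_target(aln: Alignment, name: str) -> Alignment:
    """Shallow copy of an alignment attributed to an identical target."""
    from dataclasses import replace

    return replace(aln, target=name)


@dataclass(frozen=True)
class _Locus:
    start: int  # target coordinates
    end: int
    allele: str
    kind: str | None  # "ref" | "alt" | None (some other allele)


def _variant_loci(msa: Msa, variant: CandidateVariant) -> dict[str, _Locus]:
    """Per MSA row: the allele the row carries over the variant's columns."""
    first = variant.anchor_col if variant.anchor_col is not None else variant.msa_cols[0]
    end_col = variant.msa_cols[1]
    ref_allele = msa.rows[0][first:end_col].replace("-", "")
    src_row = msa.row_names.index(variant.source_rows[0])
    alt_allele = msa.rows[src_row][first:end_col].replace("-", "")
    loci: dict[str, _Locus] = {}
    for name, row in zip(msa.row_names, msa.rows):
        t_start = len(row[:first].replace("-", ""))
        allele = row[first:end_col].replace("-", "")
        kind = "ref" if allele == ref_allele else ("alt" if allele == alt_allele else None)
        loci[name] = _Locus(t_start, t_start + len(allele), allele, kind)
    return loci


def _read_matches_span(aln: Alignment, target: str, read: ReadRecord, start: int, end: int):
    """Exact-match check of the read against target positions [start, end).

    Returns the minimum base quality over the span when the read matches
    exactly (no mismatches, no gaps), else None.
    """
    if start < 0 or end > len(target):
        return None
    min_q = 99
    for t in range(start, end):
        q = aln.pairs.get(t)
        if q is None or read.sequence[q] != target[t]:
            return None
        min_q = min(min_q, read.base_qualities[q])
    for t in range(start + 1, end):
        if t in aln.insertions_before:
            return None
    return min_q


def assign_allele_support(
    reads: list[ReadRecord],
    msa: Msa,
    variants: list[CandidateVariant],
    scoring: Scoring = Scoring(),
    min_flank: int = 1,
) -> dict[tuple, AlleleSupport]:
    """Realign reads to reference + contigs and tally per-allele support.

    The winning target is the alignment with the highest (gap-compressed
    identity, score); when several targets tie, the read is informative for
    a variant only if all tied targets agree on the allele it carries there.
    Each read increments at most one allele counter per variant; order of
    read processing does not change the totals.
    """
    targets = {name: row.replace("-", "") for name, row in zip(msa.row_names, msa.rows)}
    loci = {v.key(): _variant_loci(msa, v) for v in variants}
    support: dict[tuple, AlleleSupport] = {v.key(): AlleleSupport() for v in variants}
    if not variants:
        return support
    # only reads near a variant locus can contribute support or depth
    slack = 120
    lo = min(v.pos for v in variants) - 1 - slack
    hi = max(v.pos - 1 + len(v.ref_allele) for v in variants) + slack
    # identical target sequences (e.g. the reference haplotype re-assembled
    # as a contig) are aligned once and shared
    unique_seqs: dict[str, list[str]] = {}
    for name, seq in targets.items():
        unique_seqs.setdefault(seq, []).append(name)
    for read in reads:
        if read.reference_end < lo or read.start > hi:
            continue
        alns = []
        for seq, names in unique_seqs.items():
            base = align_read(read.sequence, seq, scoring, target_name=names[0])
            alns.append(base)
            for extra in names[1:]:
                alns.append(replace_target(base, extra))
        ranked = sorted(
            alns, key=lambda a: (-gap_compressed_identity(a), -a.score, a.target)
        )
        best_rank = (gap_compressed_identity(ranked[0]), ranked[0].score)
        tied = [a for a in ranked if (gap_compressed_identity(a), a.score) == best_rank]
        primary = tied[0]
        for variant in variants:
            vloci = loci[variant.key()]
            locus = vloci[primary.target]
            spans = primary.target_start <= locus.start and primary.target_end >= locus.end
            if not spans:
                continue
            sample = support[variant.key()].sample(read.sample)
            sample.depth += 1
            # all tied winners must agree on the allele carried here
            verdicts = set()
            quals = []
            for aln in tied:
                tl = vloci[aln.target]
                q = _read_matches_span(
                    aln, targets[aln.target], read, tl.start - min_flank, tl.end + min_flank
                )
                verdicts.add(tl.kind if q is not None else None)
                if q is not None:
                    quals.append(q)
            if len(verdicts) != 1:
                continue
            kind = verdicts.pop()
            if kind is None:
                continue
            fwd = read.strand == "forward"
            q = min(quals)
            if kind == "alt":
                if fwd:
                    sample.alt_fwd += 1
                else:
                    sample.alt_rev += 1
                sample.alt_base_quals.append(q)
                sample.alt_map_quals.append(read.mapping_quality)
            else:
                if fwd:
                    sample.ref_fwd += 1
                else:
                    sample.ref_rev += 1
                sample.ref_base_quals.append(q)
                sample.ref_map_quals.append(read.mapping_quality)
    for sup in support.values():
        for s in (sup.tumor, sup.normal):
            assert s.ref_count + s.alt_count <= s.depth
    return support


# ---------------------------------------------------------------------------
# genotyping


@dataclass(frozen=True)
class Genotype:
    gt: str  # 0/0 | 0/1 | 1/1 | ./.
    vaf: float


def genotype_sample(sample: SampleSupport, error_rate: float = 0.001) -> Genotype:
    """Maximum-binomial-likelihood genotype over {0/0, 0/1, 1/1}."""
    n = sample.ref_count + sample.alt_count
    if n == 0:
        return Genotype("./.", 0.0)
    k = sample.alt_count
    hypotheses = [("0/0", error_rate), ("0/1", 0.5), ("1/1", 1.0 - error_rate)]
    best = max(hypotheses, key=lambda h: binom.logpmf(k, n, h[1]))
    return Genotype(best[0], k / n)
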