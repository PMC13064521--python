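"""Partial-order alignment of {local reference, contigs} and variant calling.

The reference seeds a partial-order graph; each contig is then aligned to the
graph by global sequence-to-DAG dynamic programming with affine gaps and fused
into it (matched bases share nodes, mismatches join the same alignment column,
insertions add fresh nodes).  Reading the graph off in topological column
order yields the MSA.  For a reference plus a single contig this reduces
exactly to Needleman–Wunsch global alignment.

Candidate variants are maximal runs of difference columns between a contig
row and the reference row, anchored and left-normalized to the VCF
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GfaGraph

__all__ = [
    "Scoring",
    "PoaGraph",
    "Msa",
    "CandidateVariant",
    "poa_msa",
    "call_from_msa",
    "left_normalize",
    "msa_to_gfa",
]

NEG = np.int32(-(10**9))


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scores; a gap of length g costs gap_open + g*gap_extend."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2


@dataclass
class _PoaNode:
    base: str
    index: int  # creation order; used for deterministic topological sorting
    aligned_to: set[int] = field(default_factory=set)


@dataclass
class PoaGraph:
    nodes: list[_PoaNode] = field(default_factory=list)
    edges: dict[tuple[int, int], int] = field(default_factory=dict)
    traversals: list[list[int]] = field(default_factory=list)
    row_names: list[str] = field(default_factory=list)

    def add_node(self, base: str) -> int:
        idx = len(self.nodes)
        self.nodes.append(_PoaNode(base, idx))
        return idx

    def add_edge(self, u: int, v: int) -> None:
        self.edges[(u, v)] = self.edges.get((u, v), 0) + 1

    def successors(self) -> dict[int, list[int]]:
        succ: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for (u, v) in self.edges:
            succ[u].append(v)
        for lst in succ.values():
            lst.sort()
        return succ

    def predecessors(self) -> dict[int, list[int]]:
        pred: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for (u, v) in self.edges:
            pred[v].append(u)
        for lst in pred.values():
            lst.sort()
        return pred

    def topological_order(self) -> list[int]:
        import heapq

        pred = self.predecessors()
        succ = self.successors()
        indeg = {i: len(pred[i]) for i in range(len(self.nodes))}
        heap = [i for i, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order = []
        while heap:
            u = heapq.heappop(heap)
            order.append(u)
            for v in succ[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    heapq.heappush(heap, v)
        if len(order) != len(self.nodes):
            raise RuntimeError("partial-order graph contains a cycle")
        return order


@dataclass
class Msa:
    rows: list[str]
    row_names: list[str]
    col_to_ref_offset: list[int]  # -1 where the reference row has a gap
    graph: PoaGraph

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("MSA rows have unequal width")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class CandidateVariant:
    chrom: str
    pos: int  # 1-based VCF anchor position
    ref_allele: str
    alt_allele: str
    vtype: str  # SNV | INS | DEL | MNV
    length: int
    msa_cols: tuple[int, int]  # [start, end) difference-column run
    anchor_col: int | None
    source_rows: list[str]

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# sequence-to-graph affine alignment (integer DP, vectorised per node row)


def _align_to_graph(graph: PoaGraph, sequence: str, scoring: Scoring):
    """Global alignment of ``sequence`` to the DAG.

    Returns (score, moves) where moves walk from alignment start to end as
    ('match', node, j) | ('delete', node, None) | ('insert', None, j).
    Tie-breaking is fixed (diagonal > up > left; lowest predecessor first)
    so the traceback is deterministic.
    """
    order = graph.topological_order()
    rank = {n: r + 1 for r, n in enumerate(order)}  # row 0 = virtual start
    pred_nodes = graph.predecessors()
    succ_nodes = graph.successors()
    n = len(order)
    L = len(sequence)
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    go, ge = scoring.gap_open, scoring.gap_extend
    open_cost = go + ge

    H = np.full((n + 1, L + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, L + 1), NEG, dtype=np.int32)
    E = np.full((n + 1, L + 1), NEG, dtype=np.int32)
    H[0, 0] = 0
    if L:
        E[0, 1:] = go + ge * np.arange(1, L + 1, dtype=np.int32)

    preds: list[list[int]] = [[]]  # row-index predecessors, row 0 unused
    bases = np.empty(n + 1, dtype=np.uint8)
    for node_id in order:
        r = rank[node_id]
        ps = [rank[p] for p in pred_nodes[node_id]] or [0]
        preds.append(sorted(ps))
        bases[r] = ord(graph.nodes[node_id].base)

    jidx = np.arange(L + 1, dtype=np.int32)
    for node_id in order:
        r = rank[node_id]
        ps = preds[r]
        best_prev = np.full(L + 1, NEG, dtype=np.int32)  # max state at preds
        best_gap = np.full(L + 1, NEG, dtype=np.int32)  # F source at preds
        for p in ps:
            m = np.maximum(np.maximum(H[p], E[p]), F[p])
            np.maximum(best_prev, m, out=best_prev)
            g = np.maximum(np.maximum(H[p], E[p]) + open_cost, F[p] + ge)
            np.maximum(best_gap, g, out=best_gap)
        sub = np.where(seq == bases[r], scoring.match, scoring.mismatch).astype(np.int32)
        H[r, 1:] = best_prev[:-1] + sub
        F[r] = best_gap
        # E within the row: E[j] = max_{j'<j} max(H,F)[j'] + go + ge*(j-j'),
        # computed as a running max after rescaling out the extension decay
        A = np.maximum(H[r], F[r])
        B = A - ge * jidx
        C = np.maximum.accumulate(B)
        E[r, 1:] = C[:-1] + go + ge * jidx[1:]

    end_rows = [rank[i] for i in range(len(graph.nodes)) if not succ_nodes[i]]
    best = None
    for r in sorted(end_rows):
        for state, V in (("H", H), ("F", F), ("E", E)):
            if best is None or V[r, L] > best[0]:
                best = (int(V[r, L]), r, state)
    score, r, state = best

    # deterministic traceback by exact integer re-derivation
    moves = []
    j = L
    row_node = {rank[i]: i for i in order}
    while not (r == 0 and j == 0 and state == "H"):
        if state == "H":
            node = row_node[r]
            sub = scoring.match if sequence[j - 1] == graph.nodes[node].base else scoring.mismatch
            moves.append(("match", node, j - 1))
            target = H[r, j] - sub
            nr = nstate = None
            for p in preds[r]:
                for s, V in (("H", H), ("F", F), ("E", E)):
                    if V[p, j - 1] == target:
                        nr, nstate = p, s
                        break
                if nr is not None:
                    break
            r, j, state = nr, j - 1, nstate
        elif state == "F":
            node = row_node[r]
            moves.append(("delete", node, None))
            nr = nstate = None
            for p in preds[r]:
                if H[p, j] == F[r, j] - open_cost:
                    nr, nstate = p, "H"
                    break
                if F[p, j] == F[r, j] - ge:
                    nr, nstate = p, "F"
                    break
                if E[p, j] == F[r, j] - open_cost:
                    nr, nstate = p, "E"
                    break
            r, state = nr, nstate
        else:  # E: sequence char consumed against a graph gap
            moves.append(("insert", None, j - 1))
            if H[r, j - 1] == E[r, j] - open_cost:
                state = "H"
            elif F[r, j - 1] == E[r, j] - open_cost:
                state = "F"
            else:
                state = "E"
            j -= 1
    moves.reverse()
    return score, moves


def _fuse(graph: PoaGraph, sequence: str, moves, name: str) -> None:
    """Thread the aligned sequence into the graph, fusing matched columns."""
    path: list[int] = []
    for kind, node, j in moves:
        if kind == "delete":
            continue
        base = sequence[j]
        if kind == "match":
            target = graph.nodes[node]
            if target.base == base:
                chosen = node
            else:
                chosen = None
                for other in sorted(target.aligned_to):
                    if graph.nodes[other].base == base:
                        chosen = other
                        break
                if chosen is None:
                    chosen = graph.add_node(base)
                    column = {node} | set(target.aligned_to)
                    for member in column:
                        graph.nodes[member].aligned_to.add(chosen)
                        graph.nodes[chosen].aligned_to.add(member)
        else:  # insert
            chosen = graph.add_node(base)
        path.append(chosen)
    for u, v in zip(path, path[1:]):
        graph.add_edge(u, v)
    graph.traversals.append(path)
    graph.row_names.append(name)


def poa_msa(
    sequences: list[str],
    scoring: Scoring = Scoring(),
    names: list[str] | None = None,
) -> Msa:
    """Progressive partial-order MSA; row 0 must be the local reference."""
    if not sequences:
        raise ValueError("need at least one sequence")
    if any(not s for s in sequences):
        raise ValueError("empty sequence in MSA input")
    if names is None:
        names = ["ref"] + [f"hap{i}" for i in range(1, len(sequences))]
    graph = PoaGraph()
    first = [graph.add_node(b) for b in sequences[0]]
    for u, v in zip(first, first[1:]):
        graph.add_edge(u, v)
    graph.traversals.append(first)
    graph.row_names.append(names[0])
    for seq, name in zip(sequences[1:], names[1:]):
        _, moves = _align_to_graph(graph, seq, scoring)
        _fuse(graph, seq, moves, name)
    return _read_msa(graph)


def _columns(graph: PoaGraph) -> tuple[list[list[int]], dict[int, int]]:
    """Union mutually aligned nodes into columns, topologically ordered."""
    parent = list(range(len(graph.nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for node in graph.nodes:
        for other in node.aligned_to:
            union(node.index, other)
    groups: dict[int, list[int]] = {}
    for i in range(len(graph.nodes)):
        groups.setdefault(find(i), []).append(i)

    # DAG over columns from node edges, topo-sorted with the smallest member
    # index as deterministic tie-break
    import heapq

    col_succ: dict[int, set[int]] = {g: set() for g in groups}
    indeg = {g: 0 for g in groups}
    for (u, v) in graph.edges:
        gu, gv = find(u), find(v)
        if gu != gv and gv not in col_succ[gu]:
            col_succ[gu].add(gv)
            indeg[gv] += 1
    heap = [g for g, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    ordered: list[list[int]] = []
    col_of: dict[int, int] = {}
    while heap:
        g = heapq.heappop(heap)
        for member in groups[g]:
            col_of[member] = len(ordered)
        ordered.append(groups[g])
        for nxt in col_succ[g]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                heapq.heappush(heap, nxt)
    if len(ordered) != len(groups):
        raise RuntimeError("column graph contains a cycle")
    return ordered, col_of


def _read_msa(graph: PoaGraph) -> Msa:
    ordered, col_of = _columns(graph)
    width = len(ordered)
    rows: list[str] = []
    for path in graph.traversals:
        row = ["-"] * width
        for node in path:
            row[col_of[node]] = graph.nodes[node].base
        rows.append("".join(row))
    col_to_ref: list[int] = []
    ref_cols = {col_of[n]: i for i, n in enumerate(graph.traversals[0])}
    for c in range(width):
        col_to_ref.append(ref_cols.get(c, -1))
    return Msa(rows=rows, row_names=list(graph.row_names), col_to_ref_offset=col_to_ref, graph=graph)


# ---------------------------------------------------------------------------
# variant extraction


def call_from_msa(msa: Msa, chrom: str, window_start: int, ref_window: str | None = None) -> list[CandidateVariant]:
    """Candidate variants from MSA columns, anchored and left-normalized.

    Maximal runs of difference columns (base mismatch or one-sided gap)
    become one event each; runs touching the MSA edge without a preceding
    anchored reference base are skipped.  Identical normalized events from
    several contigs are emitted once with all source rows recorded.
    """
    if ref_window is None:
        ref_window = msa.rows[0].replace("-", "")
    ref_row = msa.rows[0]
    found: dict[tuple, CandidateVariant] = {}
    for r in range(1, len(msa.rows)):
        row = msa.rows[r]
        name = msa.row_names[r]
        c = 0
        w = msa.width
        while c < w:
            if _is_diff(ref_row[c], row[c]):
                start = c
                while c < w and _is_diff(ref_row[c], row[c]):
                    c += 1
            else:
                c += 1
                continue
            end = c
            ref_bases = ref_row[start:end].replace("-", "")
            alt_bases = row[start:end].replace("-", "")
            if len(ref_bases) == len(alt_bases) and "-" not in ref_row[start:end] + row[start:end]:
                pos0 = msa.col_to_ref_offset[start]
                variant = _make_candidate(chrom, window_start, pos0, ref_bases, alt_bases,
                                          (start, end), None, name, ref_window)
            else:
                anchor = start - 1
                while anchor >= 0 and (ref_row[anchor] == "-" or row[anchor] == "-"):
                    anchor -= 1
                if anchor < 0:
                    continue  # unanchorable event at the window edge
                pos0 = msa.col_to_ref_offset[anchor]
                variant = _make_candidate(
                    chrom, window_start, pos0,
                    ref_row[anchor] + ref_bases, row[anchor] + alt_bases,
                    (start, end), anchor, name, ref_window,
                )
            if variant is None:
                continue
            prev = found.get(variant.key())
            if prev is None:
                found[variant.key()] = variant
            elif name not in prev.source_rows:
                prev.source_rows.append(name)
    return sorted(found.values(), key=lambda v: v.key())


def _is_diff(a: str, b: str) -> bool:
    if a == "-" and b == "-":
        return False
    return a != b


def _make_candidate(chrom, window_start, pos0, ref_a, alt_a, cols, anchor_col, name, ref_window):
    if ref_a == alt_a:
        return None
    pos0, ref_a, alt_a = _normalize_offsets(pos0, ref_a, alt_a, ref_window)
    diff = len(alt_a) - len(ref_a)
    if diff == 0:
        vtype = "SNV" if len(ref_a) == 1 else "MNV"
    else:
        vtype = "INS" if diff > 0 else "DEL"
    return CandidateVariant(
        chrom=chrom,
        pos=window_start + pos0 + 1,
        ref_allele=ref_a,
        alt_allele=alt_a,
        vtype=vtype,
        length=abs(diff),
        msa_cols=cols,
        anchor_col=anchor_col,
        source_rows=[name],
    )


def _normalize_offsets(pos0: int, ref_a: str, alt_a: str, window: str) -> tuple[int, str, str]:
    """Left-align an event within the window, preserving the spelled haplotype."""
    if window[pos0 : pos0 + len(ref_a)] != ref_a:
        raise ValueError(f"ref allele {ref_a!r} inconsistent with window at {pos0}")
    while True:
        if (
            len(ref_a) != 1 or len(alt_a) != 1
        ) and ref_a and alt_a and ref_a[-1] == alt_a[-1]:
            trimmed = ref_a[-1]
            ref_a, alt_a = ref_a[:-1], alt_a[:-1]
            if not ref_a or not alt_a:
                if pos0 == 0:
                    # no base to the left: keep the shared base as the anchor
                    ref_a, alt_a = ref_a + trimmed, alt_a + trimmed
                    break
                pos0 -= 1
                base = window[pos0]
                ref_a, alt_a = base + ref_a, base + alt_a
            continue
        break
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[0] == alt_a[0]:
        ref_a, alt_a = ref_a[1:], alt_a[1:]
        pos0 += 1
    return pos0, ref_a, alt_a


def left_normalize(variant: CandidateVariant, ref_window: str, window_start: int) -> CandidateVariant:
    """Idempotent VCF-style left normalization of one candidate."""
    pos0 = variant.pos - 1 - window_start
    pos0, ref_a, alt_a = _normalize_offsets(pos0, variant.ref_allele, variant.alt_allele, ref_window)
    diff = len(alt_a) - len(ref_a)
    vtype = ("SNV" if len(ref_a) == 1 else "MNV") if diff == 0 else ("INS" if diff > 0 else "DEL")
    return CandidateVariant(
        chrom=variant.chrom,
        pos=window_start + pos0 + 1,
        ref_allele=ref_a,
        alt_allele=alt_a,
        vtype=vtype,
        length=abs(diff),
        msa_cols=variant.msa_cols,
        anchor_col=variant.anchor_col,
        source_rows=list(variant.source_rows),
    )


# ---------------------------------------------------------------------------
# GFA export


def msa_to_gfa(msa: Msa) -> GfaGraph:
    """Unitig-compacted GFA view of the POA graph with one path per row."""
    graph = msa.graph
    succ = graph.successors()
    pred = graph.predecessors()
    starts = {t[0] for t in graph.traversals if t}
    ends = {t[-1] for t in graph.traversals if t}

    def mergeable(u: int, v: int) -> bool:
        # u→v can share a segment only if every traversal passes through
        # both consecutively: unbranched, and no path starts at v or ends at u
        return (
            len(succ[u]) == 1 and succ[u][0] == v and len(pred[v]) == 1
            and u not in ends and v not in starts
        )

    # break chains at branch points so each segment is an unbranched run
    seg_of: dict[int, str] = {}
    segments: dict[str, str] = {}
    seg_nodes: dict[str, list[int]] = {}
    counter = 0
    for node in range(len(graph.nodes)):
        if node in seg_of:
            continue
        if len(pred[node]) == 1 and mergeable(pred[node][0], node):
            continue  # interior of a chain; handled from its head
        chain = [node]
        cur = node
        while len(succ[cur]) == 1 and mergeable(cur, succ[cur][0]):
            cur = succ[cur][0]
            chain.append(cur)
        counter += 1
        name = f"s{counter}"
        segments[name] = "".join(graph.nodes[i].base for i in chain)
        seg_nodes[name] = chain
        for i in chain:
            seg_of[i] = name
    links: set[tuple[str, str, str, str, str]] = set()
    for (u, v) in graph.edges:
        su, sv = seg_of[u], seg_of[v]
        if su != sv:
            links.add((su, "+", sv, "+", "0M"))
    paths: dict[str, list[tuple[str, str]]] = {}
    for name, path in zip(graph.row_names, graph.traversals):
        steps: list[tuple[str, str]] = []
        for node in path:
            seg = seg_of[node]
            if not steps or steps[-1][0] != seg:
                steps.append((seg, "+"))
        paths[name] = steps
    return GfaGraph(segments=segments, links=sorted(links), paths=paths)
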