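"""Joint tumor/normal colored de Bruijn graph assembly for one window.

Nodes are k-mers in reference orientation carrying per-sample ("color")
occurrence counts; edges are (k-1)-mer overlaps with traversal counts.  The
reference path from the window's first to last k-mer is protected through
cleaning, and haplotype contigs are pulled out by iterative shortest-path
extraction with capacity decrement (a max-flow-style augmentation: each
extracted path subtracts its bottleneck capacity from every edge it uses).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .io_formats import ReadRecord

__all__ = [
    "ColoredDbg",
    "HaplotypePath",
    "NoUsableK",
    "TooManyPaths",
    "select_k",
    "build_graph",
    "clean_graph",
    "enumerate_paths",
]


class NoUsableK(Exception):
    """Every candidate k has a repeated k-mer in the reference window."""


class TooManyPaths(Exception):
    """The sink is still reachable after extracting max_paths contigs."""


@dataclass
class Node:
    tumor: int = 0
    normal: int = 0
    on_reference: bool = False

    @property
    def total(self) -> int:
        return self.tumor + self.normal


@dataclass
class ColoredDbg:
    k: int
    nodes: dict[str, Node]
    # edges[(u, v)] = traversal count; u, v overlap by k-1
    edges: dict[tuple[str, str], int]
    source: str
    sink: str
    succ: dict[str, list[str]] = field(default_factory=dict)
    pred: dict[str, list[str]] = field(default_factory=dict)

    def rebuild_adjacency(self) -> None:
        self.succ = {n: [] for n in self.nodes}
        self.pred = {n: [] for n in self.nodes}
        for (u, v) in self.edges:
            self.succ[u].append(v)
            self.pred[v].append(u)
        for lst in self.succ.values():
            lst.sort()
        for lst in self.pred.values():
            lst.sort()

    def spell_reference_path(self, ref_window: str) -> str:
        """Walk the reference k-mers and check the chain is intact."""
        k = self.k
        seq = self.source
        prev = self.source
        for i in range(1, len(ref_window) - k + 1):
            kmer = ref_window[i : i + k]
            if (prev, kmer) not in self.edges:
                raise ValueError(f"reference chain broken at offset {i}")
            seq += kmer[-1]
            prev = kmer
        return seq


@dataclass(frozen=True)
class HaplotypePath:
    nodes: tuple[str, ...]
    contig: str
    min_edge_support: int


# ---------------------------------------------------------------------------


def select_k(ref_window: str, k_min: int = 11, k_max: int = 101, step: int = 2) -> int:
    """Smallest odd k for which every forward k-mer of the window is unique."""
    if k_min % 2 == 0:
        raise ValueError("k_min must be odd")
    if step % 2 != 0:
        raise ValueError("step must be even to preserve odd k")
    for k in range(k_min, min(k_max, len(ref_window)) + 1, step):
        seen: set[str] = set()
        ok = True
        for i in range(len(ref_window) - k + 1):
            kmer = ref_window[i : i + k]
            if kmer in seen:
                ok = False
                break
            seen.add(kmer)
        if ok:
            return k
    raise NoUsableK(f"no repeat-free k in [{k_min},{k_max}]")


def _quality_fragments(read: ReadRecord, min_base_q: int):
    """Split the read sequence at low-quality bases; yields substrings."""
    seq = read.sequence
    quals = read.base_qualities
    start = None
    for i, q in enumerate(quals):
        if q >= min_base_q and seq[i] in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None:
                yield seq[start:i]
                start = None
    if start is not None:
        yield seq[start:]


def build_graph(
    tumor_reads: list[ReadRecord],
    normal_reads: list[ReadRecord],
    ref_window: str,
    k: int,
    min_base_q: int = 10,
) -> ColoredDbg:
    """Accumulate reference and read k-mers with per-color counts.

    Low-quality bases break reads into fragments before k-merisation; the
    resulting graph is independent of read input order.
    """
    nodes: dict[str, Node] = {}
    edges: dict[tuple[str, str], int] = {}

    def add_sequence(seq: str, color: str | None) -> None:
        prev = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            node = nodes.get(kmer)
            if node is None:
                node = nodes[kmer] = Node()
            if color == "tumor":
                node.tumor += 1
            elif color == "normal":
                node.normal += 1
            else:
                node.on_reference = True
            if prev is not None:
                edges[(prev, kmer)] = edges.get((prev, kmer), 0) + 1
            prev = kmer

    add_sequence(ref_window, None)
    for read in sorted(tumor_reads, key=lambda r: (r.name, r.strand)):
        for frag in _quality_fragments(read, min_base_q):
            add_sequence(frag, "tumor")
    for read in sorted(normal_reads, key=lambda r: (r.name, r.strand)):
        for frag in _quality_fragments(read, min_base_q):
            add_sequence(frag, "normal")

    source = ref_window[:k]
    sink = ref_window[-k:]
    graph = ColoredDbg(k=k, nodes=nodes, edges=edges, source=source, sink=sink)
    graph.rebuild_adjacency()
    return graph


def clean_graph(graph: ColoredDbg, min_node_cov: int = 2, max_tip_len: int | None = None) -> ColoredDbg:
    """Iterated coverage pruning + tip clipping to fixpoint.

    Non-reference nodes with combined color count below ``min_node_cov`` are
    dropped, then dead-end branches of at most ``max_tip_len`` nodes that do
    not terminate at the source/sink are clipped.  Reference nodes are never
    removed, so the reference path always survives.  Idempotent.
    """
    if max_tip_len is None:
        max_tip_len = graph.k
    changed = True
    while changed:
        changed = False
        weak = [
            n for n, node in graph.nodes.items()
            if not node.on_reference and node.total < min_node_cov
        ]
        if weak:
            _remove_nodes(graph, weak)
            changed = True
        tips = _find_tips(graph, max_tip_len)
        if tips:
            _remove_nodes(graph, tips)
            changed = True
    return graph


def _remove_nodes(graph: ColoredDbg, victims: list[str]) -> None:
    vs = set(victims)
    for n in vs:
        del graph.nodes[n]
    graph.edges = {e: c for e, c in graph.edges.items() if e[0] not in vs and e[1] not in vs}
    graph.rebuild_adjacency()


def _find_tips(graph: ColoredDbg, max_tip_len: int) -> list[str]:
    tips: list[str] = []
    for terminal, neighbours in (("sink", graph.succ), ("source", graph.pred)):
        anchor = graph.sink if terminal == "sink" else graph.source
        back = graph.pred if terminal == "sink" else graph.succ
        for n in sorted(graph.nodes):
            if neighbours.get(n):
                continue
            if n == anchor or graph.nodes[n].on_reference:
                continue
            # walk backwards along the unbranched dead-end chain
            chain = [n]
            cur = n
            while len(chain) <= max_tip_len:
                prevs = back.get(cur, [])
                if len(prevs) != 1:
                    break
                p = prevs[0]
                fwd = neighbours.get(p, [])
                if len(fwd) != 1 or graph.nodes[p].on_reference:
                    break
                chain.append(p)
                cur = p
            if len(chain) <= max_tip_len:
                tips.extend(chain)
    return sorted(set(tips))


# ---------------------------------------------------------------------------
# path enumeration


def _bfs_dist_to_sink(succ, pred, sink) -> dict[str, int]:
    dist = {sink: 0}
    queue = deque([sink])
    while queue:
        v = queue.popleft()
        for u in pred.get(v, []):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def enumerate_paths(
    graph: ColoredDbg,
    max_paths: int = 16,
    hard_cap: int | None = None,
    step_budget: int = 200_000,
) -> list[HaplotypePath]:
    """Distinct source→sink haplotype paths ranked by read support.

    All simple paths are enumerated by depth-first search (restricted to
    nodes that can still reach the sink), then ranked by descending
    bottleneck support (minimum edge traversal count along the path,
    reference edges floored at 1), shorter paths and lexicographically
    smaller contigs first, and truncated to ``max_paths``.  A window whose
    graph branches combinatorially — more than ``hard_cap`` simple paths, or
    a blown search budget — raises TooManyPaths and is demoted by the
    caller.
    """
    if hard_cap is None:
        hard_cap = max(64, 4 * max_paths)
    cap: dict[tuple[str, str], int] = {}
    for (u, v), c in graph.edges.items():
        if graph.nodes[u].on_reference and graph.nodes[v].on_reference:
            c = max(c, 1)
        cap[(u, v)] = c
    succ = {u: sorted(vs) for u, vs in graph.succ.items()}
    pred = {v: sorted(us) for v, us in graph.pred.items()}
    reaches_sink = set(_bfs_dist_to_sink(succ, pred, graph.sink))
    if graph.source not in reaches_sink:
        return []

    found: list[tuple[str, ...]] = []
    steps = 0
    # iterative DFS over simple paths, successors in lexicographic order
    path = [graph.source]
    on_path = {graph.source}
    iters = [iter([v for v in succ.get(graph.source, []) if v in reaches_sink])]
    while iters:
        steps += 1
        if steps > step_budget:
            raise TooManyPaths("path search budget exceeded")
        nxt = next(iters[-1], None)
        if nxt is None:
            iters.pop()
            on_path.discard(path.pop())
            continue
        if nxt in on_path:
            continue  # cycle through repeated read k-mers
        path.append(nxt)
        if nxt == graph.sink:
            found.append(tuple(path))
            if len(found) > hard_cap:
                raise TooManyPaths(f"more than {hard_cap} haplotype paths")
            path.pop()
            continue
        on_path.add(nxt)
        iters.append(iter([v for v in succ.get(nxt, []) if v in reaches_sink]))

    ranked: dict[str, HaplotypePath] = {}
    for node_path in found:
        support = min(cap[(u, v)] for u, v in zip(node_path, node_path[1:]))
        contig = node_path[0] + "".join(n[-1] for n in node_path[1:])
        prev = ranked.get(contig)
        if prev is None or support > prev.min_edge_support:
            ranked[contig] = HaplotypePath(node_path, contig, support)
    ordered = sorted(
        ranked.values(), key=lambda p: (-p.min_edge_support, len(p.nodes), p.contig)
    )
    return ordered[:max_paths]
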