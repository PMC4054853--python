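"""Exact colored subgraph census for sizes 1-3.

Counts connected induced directed subgraphs on 1, 2 or 3 nodes, with node
colors given by regulatory type.  Two modes:

``plain``
    Self-loops are ignored entirely; 3-node classes carry no loop
    information (the convention of loop-unaware enumeration tools).
``decorated``
    A TF carrying a self-loop is recolored as a fourth color before
    enumeration and the loop edges themselves are dropped, so, e.g., the
    miRNA-mediated feed-forward loop targeting a TF splits into four
    distinct classes (no decoration, either single TF decorated, both).

Counts are exact integers end to end; frequencies are never stored, which
avoids precision loss for rarely observed classes.  Enumeration is
ESU-style over the undirected skeleton (each connected induced subgraph is
produced exactly once); a brute-force all-triples oracle lives in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

from .network import NodeType, RegulatoryNetwork

__all__ = [
    "SubgraphClass",
    "CensusResult",
    "canonical_class",
    "census1",
    "census2",
    "census3",
    "DECORATED_TF",
]

# Color codes: NodeType values 0/1/2; a self-loop-decorated TF sorts last.
DECORATED_TF = 3
_COLOR_LABELS = {0: "TF", 1: "miRNA", 2: "gene", 3: "TF@loop"}


@dataclass(frozen=True)
class SubgraphClass:
    """Canonical encoding of a colored directed subgraph of size <= 3."""

    size: int
    colors: tuple[int, ...]
    adjacency: tuple[tuple[int, ...], ...]
    canonical_id: str

    def __str__(self) -> str:
        return self.canonical_id


def canonical_class(
    colors: tuple[int, ...] | list[int],
    adjacency: tuple[tuple[int, ...], ...] | list[list[int]],
) -> SubgraphClass:
    """Canonicalize a colored adjacency matrix under node relabeling.

    Brute force over the at most 3! = 6 permutations; the canonical form is
    the lexicographically smallest (colors, flattened adjacency) pair, so
    isomorphic colored subgraphs always share one ``canonical_id``.
    """
    k = len(colors)
    if k > 3:
        raise ValueError("subgraph classes are defined for sizes 1-3 only")
    colors = tuple(int(c) for c in colors)
    adj = tuple(tuple(int(x) for x in row) for row in adjacency)
    if len(adj) != k or any(len(row) != k for row in adj):
        raise ValueError("adjacency must be size x size")

    best: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    best_adj = adj
    for perm in permutations(range(k)):
        p_colors = tuple(colors[i] for i in perm)
        p_adj = tuple(tuple(adj[i][j] for j in perm) for i in perm)
        key = (p_colors, tuple(x for row in p_adj for x in row))
        if best is None or key < best:
            best = key
            best_adj = p_adj
    assert best is not None
    c_colors, flat = best
    cid = "|".join(_COLOR_LABELS[c] for c in c_colors) + ":" + "".join(map(str, flat))
    return SubgraphClass(size=k, colors=c_colors, adjacency=best_adj, canonical_id=cid)


@dataclass
class CensusResult:
    """Per-class subgraph counts for one network."""

    counts: dict[str, int]
    mode: str
    size: int
    tag: str = ""

    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, canonical_id: str) -> int:
        return self.counts.get(canonical_id, 0)


def _colored_view(
    net: RegulatoryNetwork, mode: str
) -> tuple[dict[str, int], set[tuple[str, str]]]:
    """Node colors and loop-free edge set under the requested mode."""
    if mode not in ("plain", "decorated"):
        raise ValueError(f"unknown census mode {mode!r}")
    loops = {s for s, t in net.edges if s == t}
    colors = {}
    for n, t in net.nodes.items():
        if mode == "decorated" and n in loops and t is NodeType.TF:
            colors[n] = DECORATED_TF
        else:
            colors[n] = int(t)
    edges = {(s, t) for s, t in net.edges if s != t}
    return colors, edges


def _skeleton(edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {}
    for s, t in edges:
        nbrs.setdefault(s, set()).add(t)
        nbrs.setdefault(t, set()).add(s)
    return nbrs


def _connected_subsets(
    nodes: list[str], nbrs: dict[str, set[str]], k: int
):
    """ESU enumeration of connected k-subsets of the undirected skeleton.

    Each subset is yielded exactly once: subgraphs are grown only from
    their minimum-index vertex, and extension candidates are restricted to
    exclusive neighbors with a larger index.  Size 3 is specialized (it is
    the inner loop of every motif run); other sizes use the generic
    recursion.
    """
    index = {v: i for i, v in enumerate(nodes)}
    if k == 3:
        yield from _connected_triples(nodes, nbrs, index)
        return

    def extend(sub: list[str], ext: set[str], v_idx: int):
        if len(sub) == k:
            yield tuple(sub)
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            sub_nbrs = set().union(*(nbrs.get(u, set()) for u in sub))
            excl = {
                u
                for u in nbrs.get(w, set())
                if index[u] > v_idx and u not in sub and u not in sub_nbrs
            }
            yield from extend(sub + [w], ext | excl, v_idx)

    for v in nodes:
        if v not in nbrs:
            continue
        ext0 = {u for u in nbrs[v] if index[u] > index[v]}
        yield from extend([v], ext0, index[v])


def _connected_triples(nodes, nbrs, index):
    # Unrolled ESU at k=3: a triple {v,u,w} is rooted at its minimum-index
    # vertex v and reached either through two neighbors of v (u popped
    # before w) or through an exclusive neighbor w of u.
    for v in nodes:
        nv = nbrs.get(v)
        if not nv:
            continue
        iv = index[v]
        ext = sorted((u for u in nv if index[u] > iv), key=index.__getitem__)
        for i, u in enumerate(ext):
            for w in ext[i + 1 :]:
                yield (v, u, w)
            for w in nbrs[u]:
                if index[w] > iv and w != v and w not in nv:
                    yield (v, u, w)


_canon_cache: dict[tuple, str] = {}


def census3(net: RegulatoryNetwork, mode: str = "plain") -> CensusResult:
    """Count every connected induced 3-node colored subgraph exactly once."""
    colors, edges = _colored_view(net, mode)
    nbrs = _skeleton(edges)
    nodes = sorted(net.nodes)
    counts: dict[str, int] = {}
    for a, b, c in _connected_subsets(nodes, nbrs, 3):
        key = (
            colors[a], colors[b], colors[c],
            (a, b) in edges, (a, c) in edges,
            (b, a) in edges, (b, c) in edges,
            (c, a) in edges, (c, b) in edges,
        )
        cid = _canon_cache.get(key)
        if cid is None:
            e = key[3:]
            adj = [[0, e[0], e[1]], [e[2], 0, e[3]], [e[4], 0, 0]]
            adj[2][1] = e[5]
            cid = canonical_class(key[:3], adj).canonical_id
            _canon_cache[key] = cid
        counts[cid] = counts.get(cid, 0) + 1
    return CensusResult(counts=counts, mode=mode, size=3)


def census2(net: RegulatoryNetwork, mode: str = "plain") -> CensusResult:
    """Count connected 2-node colored subgraphs.

    Single directed edges and mutual two-loop pairs fall into distinct
    classes; the two-loop between TFs is the skeleton of the lock-on
    bi-stable switch.
    """
    colors, edges = _colored_view(net, mode)
    counts: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for s, t in edges:
        pair = (s, t) if s < t else (t, s)
        if pair in seen:
            continue
        seen.add(pair)
        a, b = pair
        adj = [
            [0, 1 if (a, b) in edges else 0],
            [1 if (b, a) in edges else 0, 0],
        ]
        cid = canonical_class([colors[a], colors[b]], adj).canonical_id
        counts[cid] = counts.get(cid, 0) + 1
    return CensusResult(counts=counts, mode=mode, size=2)


def census1(net: RegulatoryNetwork) -> CensusResult:
    """Count self-loops per node color (autoregulation census)."""
    counts: dict[str, int] = {}
    for s, t in net.edges:
        if s == t:
            cid = canonical_class([int(net.nodes[s])], [[1]]).canonical_id
            counts[cid] = counts.get(cid, 0) + 1
    return CensusResult(counts=counts, mode="plain", size=1)


# Reference classes used throughout tests and examples -----------------------

def mirna_ffl_class(target: NodeType = NodeType.GENE) -> SubgraphClass:
    """TF → miRNA, TF → target, miRNA → target (miRNA-mediated FFL)."""
    return canonical_class(
        [int(NodeType.TF), int(NodeType.MIRNA), int(target)],
        [[0, 1, 1], [0, 0, 1], [0, 0, 0]],
    )


def sustained_input_class(target: NodeType = NodeType.GENE) -> SubgraphClass:
    """Two mutually regulating TFs that co-target a third entity."""
    return canonical_class(
        [int(NodeType.TF), int(NodeType.TF), int(target)],
        [[0, 1, 1], [1, 0, 1], [0, 0, 0]],
    )


def lock_on_class() -> SubgraphClass:
    """Two TFs regulating each other (two-loop, bi-stable switch skeleton)."""
    return canonical_class(
        [int(NodeType.TF), int(NodeType.TF)], [[0, 1], [1, 0]]
    )
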