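"""Typed multi-layer regulatory network model.

A regulatory network over three node types — transcription factors (TFs),
microRNAs (miRNAs) and non-TF protein-coding genes — decomposes into five
biologically distinct interaction layers (TF→TF, TF→miRNA, TF→gene,
miRNA→TF, miRNA→gene).  Genes never regulate, and the TF→TF layer is the
only one in which self-loops (autoregulation) can occur.  Each layer is a
directed bipartite graph characterised by its out-degree sequence on
sources and in-degree sequence on targets; the randomizers in
:mod:`warswap.sampler` and :mod:`warswap.edge_switch` operate layer by
layer so that recombining independently randomized layers can never create
a duplicate edge.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "NodeType",
    "LayerKind",
    "RegulatoryNetwork",
    "BipartiteLayer",
    "DegreeSequence",
    "NetworkError",
    "read_network",
    "write_network",
    "decompose_layers",
]


class NetworkError(ValueError):
    """Raised when a network or its on-disk representation is invalid."""


class NodeType(enum.IntEnum):
    """The three regulatory node classes; ordering is fixed (TF < MIRNA < GENE)
    because canonical subgraph encodings depend on it."""

    TF = 0
    MIRNA = 1
    GENE = 2

    @classmethod
    def parse(cls, text: str) -> "NodeType":
        key = text.strip().lower()
        try:
            return _TYPE_ALIASES[key]
        except KeyError:
            raise NetworkError(f"unknown node type {text!r}") from None

    @property
    def label(self) -> str:
        return {NodeType.TF: "TF", NodeType.MIRNA: "miRNA", NodeType.GENE: "gene"}[self]


_TYPE_ALIASES = {
    "tf": NodeType.TF,
    "mirna": NodeType.MIRNA,
    "mir": NodeType.MIRNA,
    "microrna": NodeType.MIRNA,
    "gene": NodeType.GENE,
}


class LayerKind(enum.Enum):
    """The five source-type → target-type interaction layers."""

    TF_TF = (NodeType.TF, NodeType.TF)
    TF_MIRNA = (NodeType.TF, NodeType.MIRNA)
    TF_GENE = (NodeType.TF, NodeType.GENE)
    MIRNA_TF = (NodeType.MIRNA, NodeType.TF)
    MIRNA_GENE = (NodeType.MIRNA, NodeType.GENE)

    @property
    def source_type(self) -> NodeType:
        return self.value[0]

    @property
    def target_type(self) -> NodeType:
        return self.value[1]

    @property
    def allows_self_loops(self) -> bool:
        # Only TF→TF pairs a node with itself; autoregulation is real biology.
        return self is LayerKind.TF_TF

    @classmethod
    def of(cls, source: NodeType, target: NodeType) -> "LayerKind":
        for kind in cls:
            if kind.value == (source, target):
                return kind
        raise NetworkError(f"no layer for {source.label} → {target.label}")


LAYER_ORDER: tuple[LayerKind, ...] = (
    LayerKind.TF_TF,
    LayerKind.TF_MIRNA,
    LayerKind.TF_GENE,
    LayerKind.MIRNA_TF,
    LayerKind.MIRNA_GENE,
)


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A validated directed network over typed nodes.

    Invariants (enforced by :meth:`validate`):

    * every edge endpoint is a declared node;
    * edges are unique ordered pairs;
    * GENE nodes have out-degree 0 (genes are never regulators);
    * self-loops occur only on TF nodes.
    """

    nodes: Mapping[str, NodeType]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_data(
        cls,
        nodes: Mapping[str, NodeType],
        edges: Iterable[tuple[str, str]],
    ) -> "RegulatoryNetwork":
        net = cls(nodes=dict(nodes), edges=frozenset(edges))
        net.validate()
        return net

    def validate(self) -> None:
        for s, t in self.edges:
            if s not in self.nodes:
                raise NetworkError(f"edge source {s!r} has no declared type")
            if t not in self.nodes:
                raise NetworkError(f"edge target {t!r} has no declared type")
            if self.nodes[s] is NodeType.GENE:
                raise NetworkError(f"gene as regulator: {s!r} -> {t!r}")
            if s == t and self.nodes[s] is not NodeType.TF:
                raise NetworkError(f"self-loop on non-TF node {s!r}")

    def layer_of(self, edge: tuple[str, str]) -> LayerKind:
        s, t = edge
        return LayerKind.of(self.nodes[s], self.nodes[t])

    def nodes_of_type(self, node_type: NodeType) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t is node_type)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return dict(self.nodes) == dict(other.nodes) and self.edges == other.edges

    def __hash__(self) -> int:  # frozen dataclass with Mapping field
        return hash((frozenset(self.nodes.items()), self.edges))


@dataclass
class BipartiteLayer:
    """One source-type → target-type layer with its degree requirements.

    ``source_degrees`` / ``target_degrees`` cover *all* nodes of the layer's
    source / target type, including zero-degree nodes (these matter for the
    widened in-degree permutation universe).  ``m`` is the layer edge count.
    """

    kind: LayerKind
    source_degrees: dict[str, int]
    target_degrees: dict[str, int]
    edges: frozenset[tuple[str, str]]

    @property
    def m(self) -> int:
        # Required edge count; equals len(edges) for layers carrying their
        # realized edge set, but degree-only layers (no edges yet) work too.
        return sum(self.source_degrees.values())

    def validate(self) -> None:
        if self.edges and len(self.edges) != self.m:
            raise NetworkError(f"{self.kind.name}: edge count does not match degrees")
        if sum(self.target_degrees.values()) != self.m:
            raise NetworkError(f"{self.kind.name}: in-degrees do not sum to m")
        if any(d < 0 for d in self.source_degrees.values()) or any(
            d < 0 for d in self.target_degrees.values()
        ):
            raise NetworkError(f"{self.kind.name}: negative degree")
        for s, t in self.edges:
            if s == t and not self.kind.allows_self_loops:
                raise NetworkError(f"{self.kind.name}: illegal self-loop on {s!r}")


@dataclass
class DegreeSequence:
    """A bare degree-sequence specification for uniformity experiments.

    When ``shared_node_identity`` is true, sources and targets are the same
    labeled nodes and position ``i`` carries both ``out_degrees[i]`` and
    ``in_degrees[i]`` (so a self-loop ties a node's own out- and in-slots).
    Otherwise sources and targets are disjoint labeled sets.
    """

    out_degrees: list[int]
    in_degrees: list[int]
    allow_self_loops: bool = False
    shared_node_identity: bool = False

    def __post_init__(self) -> None:
        if sum(self.out_degrees) != sum(self.in_degrees):
            raise NetworkError("out- and in-degree sums differ")
        if self.shared_node_identity and len(self.out_degrees) != len(self.in_degrees):
            raise NetworkError("shared-node sequence needs equal-length degree lists")
        if self.allow_self_loops and not self.shared_node_identity:
            raise NetworkError("self-loops require shared node identity")

    @property
    def m(self) -> int:
        return sum(self.out_degrees)

    @classmethod
    def from_json(cls, path: str | Path) -> "DegreeSequence":
        spec = json.loads(Path(path).read_text())
        return cls(
            out_degrees=list(spec["out"]),
            in_degrees=list(spec["in"]),
            allow_self_loops=bool(spec.get("allow_self_loops", False)),
            shared_node_identity=bool(spec.get("shared_nodes", False)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "out": self.out_degrees,
                    "in": self.in_degrees,
                    "allow_self_loops": self.allow_self_loops,
                    "shared_nodes": self.shared_node_identity,
                },
                indent=1,
            )
        )


def _parse_tsv_rows(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            yield line.split("\t")


def read_network(edge_path: str | Path, type_path: str | Path) -> RegulatoryNetwork:
    """Read a network from an edge-list TSV and a node-type TSV.

    Duplicate edge rows collapse to a single edge with a logged warning.
    An optional header row in the type table is detected when the second
    column is not a recognised type keyword.
    """
    nodes: dict[str, NodeType] = {}
    for i, row in enumerate(_parse_tsv_rows(type_path)):
        if len(row) < 2:
            raise NetworkError(f"{type_path}: type row {i + 1} needs 2 columns")
        name, type_text = row[0].strip(), row[1]
        if i == 0 and type_text.strip().lower() not in _TYPE_ALIASES:
            continue  # header row
        nodes[name] = NodeType.parse(type_text)

    edges: list[tuple[str, str]] = []
    for i, row in enumerate(_parse_tsv_rows(edge_path)):
        if len(row) < 2:
            raise NetworkError(f"{edge_path}: edge row {i + 1} needs 2 columns")
        edges.append((row[0].strip(), row[1].strip()))

    unique = set(edges)
    if len(unique) < len(edges):
        logger.warning(
            "collapsed %d duplicate edge rows in %s", len(edges) - len(unique), edge_path
        )
    for s, t in unique:
        for endpoint in (s, t):
            if endpoint not in nodes:
                raise NetworkError(f"node {endpoint!r} referenced by an edge has no type")
    return RegulatoryNetwork.from_data(nodes, unique)


def write_network(
    net: RegulatoryNetwork, edge_path: str | Path, type_path: str | Path
) -> None:
    """Write a network as edge-list and node-type TSVs (round-trips with
    :func:`read_network`)."""
    with open(edge_path, "w") as fh:
        for s, t in sorted(net.edges):
            fh.write(f"{s}\t{t}\n")
    with open(type_path, "w") as fh:
        for n in sorted(net.nodes):
            fh.write(f"{n}\t{net.nodes[n].label}\n")


def decompose_layers(net: RegulatoryNetwork) -> list[BipartiteLayer]:
    """Split a network into its five layers.

    Every edge lands in exactly one layer (determined by its endpoint
    types); empty layers are returned with ``m == 0``.  Degree maps cover
    all nodes of the relevant type, including unconnected ones.
    """
    by_kind: dict[LayerKind, set[tuple[str, str]]] = {k: set() for k in LAYER_ORDER}
    for edge in net.edges:
        by_kind[net.layer_of(edge)].add(edge)

    layers = []
    for kind in LAYER_ORDER:
        sources = net.nodes_of_type(kind.source_type)
        targets = net.nodes_of_type(kind.target_type)
        out_deg = {s: 0 for s in sources}
        in_deg = {t: 0 for t in targets}
        for s, t in by_kind[kind]:
            out_deg[s] += 1
            in_deg[t] += 1
        layer = BipartiteLayer(
            kind=kind,
            source_degrees=out_deg,
            target_degrees=in_deg,
            edges=frozenset(by_kind[kind]),
        )
        layer.validate()
        layers.append(layer)
    return layers


def recombine_layers(
    net: RegulatoryNetwork, layer_edges: Mapping[LayerKind, Iterable[tuple[str, str]]]
) -> RegulatoryNetwork:
    """Assemble a network with the original node set and per-layer edge sets."""
    edges: set[tuple[str, str]] = set()
    for kind_edges in layer_edges.values():
        edges.update(kind_edges)
    return RegulatoryNetwork.from_data(net.nodes, edges)
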