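"""Edge-switching baseline randomizer.

The classic null model behind most motif-discovery tools: repeatedly pick
two edges (s1,t1), (s2,t2) and exchange their endpoints to (s1,t2),
(s2,t1).  A switch that would create a duplicate edge or a disallowed
self-loop fails and leaves the graph unchanged; failures are counted, and
on hub-heavy networks the failed fraction becomes large — the diagnostic
symptom this package's weighted sampler is designed to avoid.  Switching
preserves every node's exact in- and out-degree.  Switches are drawn
within a layer, which keeps node-type constraints satisfied automatically.

Self-loops are excluded from switching (and removed from the network in
this mode), matching the comparison convention of loop-unaware tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    LayerKind,
    RegulatoryNetwork,
    decompose_layers,
    recombine_layers,
)

__all__ = ["SwitchStats", "attempt_switch", "randomize_by_switching"]


@dataclass
class SwitchStats:
    """Outcome accounting for a switching run."""

    attempts: int = 0
    successes: int = 0
    failures: int = 0

    @property
    def failed_fraction(self) -> float:
        return self.failures / self.attempts if self.attempts else 0.0

    def __add__(self, other: "SwitchStats") -> "SwitchStats":
        return SwitchStats(
            self.attempts + other.attempts,
            self.successes + other.successes,
            self.failures + other.failures,
        )


def attempt_switch(
    edges: set[tuple[str, str]],
    e1: tuple[str, str],
    e2: tuple[str, str],
    allow_self_loops: bool = False,
    allowed: "callable | None" = None,
) -> bool:
    """Try to switch the endpoints of two edges in place.

    Returns True on success.  Fails (leaving ``edges`` unchanged) when the
    switch would create a duplicate edge, a disallowed self-loop, an edge
    rejected by the optional ``allowed(source, target)`` type predicate, or
    when the proposed edges already exist (switches sharing an endpoint
    reproduce the original pair and are counted failed).
    """
    if e1 == e2:
        raise ValueError("attempt_switch needs two distinct edges")
    s1, t1 = e1
    s2, t2 = e2
    new1, new2 = (s1, t2), (s2, t1)
    if new1 == new2:
        return False
    if new1 in edges or new2 in edges:  # covers shared-endpoint no-ops
        return False
    if not allow_self_loops and (s1 == t2 or s2 == t1):
        return False
    if allowed is not None and not (allowed(*new1) and allowed(*new2)):
        return False
    edges.discard(e1)
    edges.discard(e2)
    edges.add(new1)
    edges.add(new2)
    return True


def switch_edge_set(
    edges: set[tuple[str, str]],
    attempts: int,
    rng: np.random.Generator,
    allow_self_loops: bool = False,
) -> SwitchStats:
    """Run a budget of switch attempts on one edge set, in place."""
    stats = SwitchStats()
    pool = sorted(edges)
    if len(pool) < 2:
        return stats
    for _ in range(attempts):
        i, j = rng.choice(len(pool), size=2, replace=False)
        e1, e2 = pool[i], pool[j]
        stats.attempts += 1
        if attempt_switch(edges, e1, e2, allow_self_loops=allow_self_loops):
            stats.successes += 1
            s1, t1 = e1
            s2, t2 = e2
            pool[i] = (s1, t2)
            pool[j] = (s2, t1)
        else:
            stats.failures += 1
    return stats


def randomize_by_switching(
    net: RegulatoryNetwork,
    attempts_per_edge: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[RegulatoryNetwork, SwitchStats]:
    """Randomize a network layer by layer with edge switching.

    ``attempts_per_edge`` scales the attempt budget per layer to
    ``attempts_per_edge * m``.  Self-loops are removed first (they cannot
    take part in degree-preserving switches without changing loop counts).
    """
    if attempts_per_edge < 1:
        raise ValueError("attempts_per_edge must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    net = RegulatoryNetwork.from_data(net.nodes, {e for e in net.edges if e[0] != e[1]})
    total = SwitchStats()
    edges_by_kind: dict[LayerKind, set[tuple[str, str]]] = {}
    for layer in decompose_layers(net):
        edges = set(layer.edges)
        total = total + switch_edge_set(
            edges, attempts_per_edge * layer.m, rng, allow_self_loops=False
        )
        edges_by_kind[layer.kind] = edges
    return recombine_layers(net, edges_by_kind), total
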