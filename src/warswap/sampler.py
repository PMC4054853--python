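"""Weighted-and-Reverse-Swap (WaRSwap) randomization.

The core method draws a random simple directed bipartite graph realizing a
prescribed out-degree sequence on sources and in-degree sequence on
targets.  Sources are visited once, heaviest first; each source fills its
out-degree by weighted sampling without replacement, where a target's
"attraction" is

    weight = cap(S_i) * cap(T_j) * (1 - deg(S_i) * deg(T_j) / (p * m))

with ``cap`` the residual (unfilled) capacities, ``deg`` the total required
degrees, ``m`` the layer edge count and ``p`` an integer multiplier chosen
so the bracketed correction stays in (0, 1].  The correction damps the
otherwise overwhelming tendency to wire hubs to hubs, which is what lets
the sampler stay near-uniform on hub-heavy degree sequences.  When a
source still has edges to place but every unsaturated target is already
one of its targets, a reverse swap relocates an already-placed edge so the
pass can finish; the algorithm always terminates after one pass over the
sources.

The complete method randomizes a multi-layer network by permuting each
layer's target in-degrees (preserving the in-degree *distribution* rather
than each node's exact in-degree — target sites are gained and lost over
evolutionary time) and then applying the core method per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .network import (
    LAYER_ORDER,
    BipartiteLayer,
    LayerKind,
    RegulatoryNetwork,
    decompose_layers,
    recombine_layers,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "SampleState",
    "RandomizationResult",
    "InfeasibleLayerError",
    "sampling_weight",
    "effective_p",
    "permute_in_degrees",
    "randomize_layer",
    "reverse_swap",
    "randomize_network",
]


class InfeasibleLayerError(RuntimeError):
    """The degree sequence of a layer admits no simple realization (or no
    valid reverse swap existed for a stuck state)."""


@dataclass
class SamplerConfig:
    """Tunables of the sampler.

    weight_multiplier_p
        Base integer multiplier ``p`` of the edge count in the weight
        correction ``1 - deg(S)deg(T)/(p*m)``; 6 is the smallest integer
        that keeps the correction inside (0, 1) for the hub-heavy
        regulatory networks this method was built for.
    auto_escalate_p
        Raise ``p`` per layer (with a log message) whenever the configured
        value would let the correction factor reach zero or go negative.
    permute_in_degrees
        Apply the in-degree permutation of the complete method.
    include_zero_degree_targets
        Widen the permutation universe from targets with at least one edge
        to every node of the layer's target type, allowing target-set
        turnover in randomized networks.
    drop_self_loops
        Strip self-loops before randomizing and forbid them in output
        (comparison mode mirroring edge-switch tools that ignore loops).
    """

    weight_multiplier_p: int = 6
    auto_escalate_p: bool = True
    permute_in_degrees: bool = True
    include_zero_degree_targets: bool = False
    drop_self_loops: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weight_multiplier_p < 1:
            raise ValueError("weight multiplier p must be >= 1")


@dataclass
class SampleState:
    """Mutable state of one layer randomization pass."""

    deg_source: dict[str, int]
    deg_target: dict[str, int]
    cap_source: dict[str, int]
    cap_target: dict[str, int]
    targets_of: dict[str, set[str]]
    edges: set[tuple[str, str]]
    allow_self_loops: bool
    swap_count: int = 0

    def check(self) -> None:
        assert all(0 <= c <= self.deg_source[s] for s, c in self.cap_source.items())
        assert all(0 <= c <= self.deg_target[t] for t, c in self.cap_target.items())
        assert sum(self.cap_source.values()) == sum(self.cap_target.values())


@dataclass
class RandomizationResult:
    """A randomized network plus per-layer diagnostics."""

    network: RegulatoryNetwork
    swap_counts: dict[LayerKind, int]
    effective_p: dict[LayerKind, int]
    permutations: dict[LayerKind, dict[str, int]]

    @property
    def total_swaps(self) -> int:
        return sum(self.swap_counts.values())


def sampling_weight(
    deg_s: int, deg_t: int, cap_s: int, cap_t: int, m: int, p: int
) -> float:
    """Attraction weight of target T for source S.

    Zero exactly when either residual capacity is exhausted.  Raises if the
    correction factor is not positive — the caller should have escalated
    ``p`` first.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    correction = 1.0 - (deg_s * deg_t) / (p * m)
    if correction <= 0.0 and cap_s > 0 and cap_t > 0:
        raise InfeasibleLayerError(
            f"weight correction {correction:.3f} <= 0 for deg {deg_s}x{deg_t}, "
            f"p*m = {p * m}; p must be escalated"
        )
    return cap_s * cap_t * correction


def effective_p(layer: BipartiteLayer, config: SamplerConfig) -> int:
    """Smallest valid multiplier not below the configured ``p``.

    Valid means ``max deg(S)·deg(T) / (q·m) < 1`` so the correction factor
    stays strictly positive for every source-target pair.
    """
    m = layer.m
    if m == 0:
        return config.weight_multiplier_p
    max_out = max(layer.source_degrees.values(), default=0)
    max_in = max(layer.target_degrees.values(), default=0)
    needed = (max_out * max_in) // m + 1  # smallest q with max_prod/(q*m) < 1
    if needed > config.weight_multiplier_p:
        if not config.auto_escalate_p:
            raise InfeasibleLayerError(
                f"{layer.kind.name}: p={config.weight_multiplier_p} too small "
                f"(needs {needed}) and auto-escalation is off"
            )
        logger.info(
            "%s: escalating weight multiplier p from %d to %d",
            layer.kind.name,
            config.weight_multiplier_p,
            needed,
        )
        return needed
    return config.weight_multiplier_p


def permute_in_degrees(
    layer: BipartiteLayer,
    rng: np.random.Generator,
    include_zero_degree_targets: bool = False,
) -> dict[str, int]:
    """Uniformly permute the layer's in-degrees over the target universe.

    The value multiset is preserved exactly; only the assignment of
    in-degrees to target ids changes.  By default the universe is the
    targets that carry at least one edge; widening it lets previously
    untargeted nodes of the target type receive positive in-degree.
    """
    if include_zero_degree_targets:
        universe = sorted(layer.target_degrees)
    else:
        universe = sorted(t for t, d in layer.target_degrees.items() if d > 0)
    values = [layer.target_degrees[t] for t in universe]
    order = rng.permutation(len(universe))
    permuted = dict(layer.target_degrees)
    for slot, idx in zip(universe, order):
        permuted[slot] = values[idx]
    return permuted


def _draw_weighted(
    rng: np.random.Generator, candidates: list[str], weights: list[float]
) -> str:
    total = float(sum(weights))
    if total <= 0.0:
        raise InfeasibleLayerError("all candidate weights are zero")
    r = rng.random() * total
    acc = 0.0
    for cand, w in zip(candidates, weights):
        acc += w
        if r < acc:
            return cand
    return candidates[-1]  # numerical edge case


def reverse_swap(
    state: SampleState, stuck_source: str, rng: np.random.Generator
) -> SampleState:
    """Resolve one unplaced edge of a stuck source by relocating a placed edge.

    Preconditions: the stuck source has residual out-capacity and every
    unsaturated target is already among its targets.  A target T_si of the
    stuck source with residual capacity is chosen uniformly; a placed edge
    S' → T_s' with T_s' not targeted by the stuck source and T_si not
    targeted by S' is drawn uniformly among all such edges; the placed edge
    is redirected to T_si and the stuck source's edge goes to T_s'.
    """
    s = stuck_source
    if state.cap_source[s] < 1:
        raise RuntimeError("reverse swap called for a source with no unplaced edges")
    unsat = [t for t, c in state.cap_target.items() if c > 0]
    # In the stuck state every unsaturated target is already targeted by the
    # stuck source — except possibly the source's own in-slot when loops are
    # disallowed (untargetable directly, but a fine destination for the
    # relocated edge of another source).
    stray = [
        t
        for t in unsat
        if t not in state.targets_of[s] and (state.allow_self_loops or t != s)
    ]
    if stray:
        raise RuntimeError(
            "reverse swap precondition violated: unsaturated target "
            f"{stray[0]!r} is not yet targeted by {s!r}"
        )

    for t_si in rng.permutation(sorted(unsat)):
        t_si = str(t_si)
        candidates = sorted(
            (sp, tp)
            for sp, tp in state.edges
            if tp not in state.targets_of[s]
            and t_si not in state.targets_of[sp]
            and sp != s
            and (state.allow_self_loops or (sp != t_si and s != tp))
        )
        if not candidates:
            continue
        sp, tp = candidates[rng.integers(len(candidates))]
        state.edges.remove((sp, tp))
        state.targets_of[sp].remove(tp)
        state.edges.add((sp, t_si))
        state.targets_of[sp].add(t_si)
        state.edges.add((s, tp))
        state.targets_of[s].add(tp)
        state.cap_source[s] -= 1
        state.cap_target[t_si] -= 1
        state.swap_count += 1
        return state
    raise InfeasibleLayerError(
        f"no valid reverse swap exists for stuck source {s!r}"
    )


def randomize_layer(
    layer: BipartiteLayer,
    config: SamplerConfig,
    rng: np.random.Generator,
    target_degrees: dict[str, int] | None = None,
) -> tuple[set[tuple[str, str]], int]:
    """Draw one random realization of a layer's degree sequence.

    Returns the edge set and the number of reverse swaps used.  Out-degrees
    are realized exactly; in-degrees follow ``target_degrees`` (the
    permuted requirement) or the layer's own in-degrees when not given.
    """
    m = layer.m
    if m == 0:
        return set(), 0
    deg_t = dict(target_degrees) if target_degrees is not None else dict(layer.target_degrees)
    if sorted(deg_t.values()) != sorted(layer.target_degrees.values()):
        raise ValueError("permuted in-degrees must preserve the multiset")
    allow_loops = layer.kind.allows_self_loops and not config.drop_self_loops
    p = effective_p(layer, config)

    state = SampleState(
        deg_source=dict(layer.source_degrees),
        deg_target=deg_t,
        cap_source=dict(layer.source_degrees),
        cap_target=dict(deg_t),
        targets_of={s: set() for s in layer.source_degrees},
        edges=set(),
        allow_self_loops=allow_loops,
    )

    # Step 0: heaviest sources first; lexicographic tie-break for determinism.
    order = sorted(
        (s for s, d in layer.source_degrees.items() if d > 0),
        key=lambda s: (-layer.source_degrees[s], s),
    )
    active_targets = sorted(t for t, d in deg_t.items() if d > 0)

    for s in order:
        d = state.deg_source[s]

        def admissible() -> list[str]:
            return [
                t
                for t in active_targets
                if state.cap_target[t] > 0
                and t not in state.targets_of[s]
                and (allow_loops or t != s)
            ]

        unsaturated = admissible()
        if d <= len(unsaturated):
            # Step 2: weighted draws without replacement, weights recomputed
            # after each placement (capacities shrink as edges land).
            for _ in range(d):
                cands = admissible()
                weights = [
                    sampling_weight(
                        state.deg_source[s],
                        state.deg_target[t],
                        state.cap_source[s],
                        state.cap_target[t],
                        m,
                        p,
                    )
                    for t in cands
                ]
                t = _draw_weighted(rng, cands, weights)
                state.edges.add((s, t))
                state.targets_of[s].add(t)
                state.cap_source[s] -= 1
                state.cap_target[t] -= 1
        else:
            # Step 3a: fill every admissible target.
            for t in unsaturated:
                state.edges.add((s, t))
                state.targets_of[s].add(t)
                state.cap_source[s] -= 1
                state.cap_target[t] -= 1
            # Step 3b: reverse swaps for the remaining unplaced edges.
            while state.cap_source[s] > 0:
                reverse_swap(state, s, rng)

    state.check()
    return state.edges, state.swap_count


def randomize_network(
    net: RegulatoryNetwork,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> RandomizationResult:
    """Randomize every layer of a network (the complete method)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.drop_self_loops:
        net = RegulatoryNetwork.from_data(
            net.nodes, {e for e in net.edges if e[0] != e[1]}
        )
    layers = decompose_layers(net)
    edges_by_kind: dict[LayerKind, set[tuple[str, str]]] = {}
    swaps: dict[LayerKind, int] = {}
    p_used: dict[LayerKind, int] = {}
    perms: dict[LayerKind, dict[str, int]] = {}
    for layer in layers:
        try:
            if config.permute_in_degrees and layer.m > 0:
                deg_t = permute_in_degrees(
                    layer, rng, config.include_zero_degree_targets
                )
            else:
                deg_t = dict(layer.target_degrees)
            perms[layer.kind] = deg_t
            p_used[layer.kind] = effective_p(layer, config) if layer.m else config.weight_multiplier_p
            edges, n_swaps = randomize_layer(layer, config, rng, target_degrees=deg_t)
        except InfeasibleLayerError as exc:
            raise InfeasibleLayerError(f"layer {layer.kind.name}: {exc}") from exc
        edges_by_kind[layer.kind] = edges
        swaps[layer.kind] = n_swaps
    randomized = recombine_layers(net, edges_by_kind)
    return RandomizationResult(
        network=randomized,
        swap_counts=swaps,
        effective_p=p_used,
        permutations=perms,
    )


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Derive independent per-replicate seeds from a master seed.

    Counter-based: replicate ``i`` gets an independent stream regardless of
    how many replicates run or in what order, so parallel execution is
    reproducible.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
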