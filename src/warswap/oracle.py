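"""Brute-force enumeration of degree-sequence realizations and uniformity metrics.

For small degree sequences every simple labeled realization can be listed
exhaustively, which turns "does this sampler draw uniformly?" into a
measurable question: draw many graphs, map each to its realization
fingerprint, and compare the empirical frequencies with the uniform
reference (total-variation distance, chi-square goodness of fit, never-
sampled realizations).

Three canonical example sequences are packaged (``canonical_example``): a
small near-regular bipartite sequence with 13 realizations, a slightly
larger one with 58, and an extreme large-hub sequence on a shared node
set — an out-hub of degree 10, an in-hub of degree 10 and ten degree-1/1
spokes — with 101 realizations when self-loops are allowed (91 without;
10 contain a self-loop).  The large-hub sequence has exactly one
realization with no hub-to-hub edge, the regime where edge switching
under-samples.  The printed totals are asserted at fixture load so a
mistranscription fails loudly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sp_stats

from .network import DegreeSequence

__all__ = [
    "RealizationSet",
    "UniformityReport",
    "enumerate_realizations",
    "evaluate_sampler",
    "canonical_example",
    "CANONICAL_EXAMPLES",
]

Fingerprint = tuple[tuple[int, int], ...]

_SEARCH_BOUND = 10**7  # DFS node-expansion budget


@dataclass
class RealizationSet:
    """All labeled simple graphs realizing a degree sequence."""

    sequence: DegreeSequence
    fingerprints: list[Fingerprint]

    def __post_init__(self) -> None:
        if len(set(self.fingerprints)) != len(self.fingerprints):
            raise ValueError("duplicate realization fingerprints")

    @property
    def count(self) -> int:
        return len(self.fingerprints)

    def index(self) -> dict[Fingerprint, int]:
        return {fp: i for i, fp in enumerate(self.fingerprints)}

    def with_self_loop(self) -> list[Fingerprint]:
        if not self.sequence.shared_node_identity:
            return []
        return [fp for fp in self.fingerprints if any(s == t for s, t in fp)]


@dataclass
class UniformityReport:
    """Sampled frequencies against the uniform reference."""

    n_draws: int
    frequencies: np.ndarray
    uniform: float
    tv_distance: float
    chi2_stat: float
    chi2_p: float
    never_sampled: list[int]

    @property
    def max_relative_deviation(self) -> float:
        return float(np.max(np.abs(self.frequencies - self.uniform)) / self.uniform)


def enumerate_realizations(seq: DegreeSequence) -> RealizationSet:
    """Exhaustively enumerate every labeled simple realization.

    Depth-first assignment of each source's target set, sources in
    descending degree order with capacity pruning.  Nodes are indices:
    for a shared-identity sequence, source i and target i are the same
    node; otherwise the index spaces are disjoint and self-loops cannot
    arise.  Raises if the pruned search exceeds the expansion budget;
    returns an empty set for infeasible sequences.
    """
    outs = list(seq.out_degrees)
    ins = list(seq.in_degrees)
    nt = len(ins)

    order = sorted(range(len(outs)), key=lambda i: (-outs[i], i))
    caps = list(ins)
    found: list[Fingerprint] = []
    expansions = 0

    def rec(k: int, edges: list[tuple[int, int]]) -> None:
        nonlocal expansions
        expansions += 1
        if expansions > _SEARCH_BOUND:
            raise ValueError("enumeration search exceeded its expansion budget")
        if k == len(order):
            found.append(tuple(sorted(edges)))
            return
        s = order[k]
        d = outs[s]
        if d == 0:
            rec(k + 1, edges)
            return
        avail = [
            j
            for j in range(nt)
            if caps[j] > 0
            and (not seq.shared_node_identity or seq.allow_self_loops or j != s)
        ]
        if d > len(avail):
            return
        for combo in itertools.combinations(avail, d):
            for j in combo:
                caps[j] -= 1
            rec(k + 1, edges + [(s, j) for j in combo])
            for j in combo:
                caps[j] += 1

    rec(0, [])
    return RealizationSet(sequence=seq, fingerprints=sorted(found))


def evaluate_sampler(
    sampler: Callable[[DegreeSequence, np.random.Generator], Fingerprint],
    seq: DegreeSequence,
    n_draws: int,
    seed: int | np.random.Generator = 0,
    realizations: RealizationSet | None = None,
) -> UniformityReport:
    """Draw ``n_draws`` graphs and compare their frequencies with uniform.

    Every sampled graph must map to a known realization — anything else
    means the sampler violated the degree constraints, which is a hard
    error rather than a statistic.
    """
    rs = realizations if realizations is not None else enumerate_realizations(seq)
    if rs.count == 0:
        raise ValueError("degree sequence has no realizations")
    index = rs.index()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = np.zeros(rs.count, dtype=np.int64)
    for _ in range(n_draws):
        fp = tuple(sorted(sampler(seq, rng)))
        try:
            hits[index[fp]] += 1
        except KeyError:
            raise RuntimeError(
                "sampler produced a graph outside the realization set "
                f"(degree constraints violated): {fp}"
            ) from None
    freqs = hits / n_draws
    uniform = 1.0 / rs.count
    tv = 0.5 * float(np.abs(freqs - uniform).sum())
    chi2_stat, chi2_p = sp_stats.chisquare(hits)
    return UniformityReport(
        n_draws=n_draws,
        frequencies=freqs,
        uniform=uniform,
        tv_distance=tv,
        chi2_stat=float(chi2_stat),
        chi2_p=float(chi2_p),
        never_sampled=[i for i, h in enumerate(hits) if h == 0],
    )


# ---------------------------------------------------------------------------
# Canonical example sequences (uniformity validation protocol).
#
# small_bipartite: out (3,2,1,1) / in (3,2,1,1); 13 realizations, exactly
#   one of which has no edge between the degree-3 source and the degree-3
#   target.
# medium_bipartite: out (3,2,2,1) / in (3,2,1,1,1); 58 realizations.
# large_hub: shared node set with node 0 = out-hub (out 10, in 0), node 1 =
#   in-hub (out 0, in 10), nodes 2-11 = spokes (out 1, in 1).  101
#   realizations with self-loops allowed, 91 without, 10 containing a
#   self-loop; the unique no-hub-hub realization is the double star
#   (hub 0 -> every spoke, every spoke -> hub 1).

CANONICAL_EXAMPLES: dict[str, dict] = {
    "small_bipartite": {
        "sequence": dict(
            out_degrees=[3, 2, 1, 1],
            in_degrees=[3, 2, 1, 1],
            allow_self_loops=False,
            shared_node_identity=False,
        ),
        "expected_count": 13,
        "no_hub_hub_edge": (0, 0),  # exactly one realization lacks it
    },
    "medium_bipartite": {
        "sequence": dict(
            out_degrees=[3, 2, 2, 1],
            in_degrees=[3, 2, 1, 1, 1],
            allow_self_loops=False,
            shared_node_identity=False,
        ),
        "expected_count": 58,
    },
    "large_hub": {
        "sequence": dict(
            out_degrees=[10, 0] + [1] * 10,
            in_degrees=[0, 10] + [1] * 10,
            allow_self_loops=True,
            shared_node_identity=True,
        ),
        "expected_count": 101,
        "expected_count_no_loops": 91,
        "expected_with_self_loop": 10,
        "no_hub_hub_edge": (0, 1),
    },
}


def canonical_example(name: str) -> tuple[DegreeSequence, RealizationSet]:
    """Load a canonical example sequence, asserting its printed totals."""
    spec = CANONICAL_EXAMPLES[name]
    seq = DegreeSequence(**spec["sequence"])
    rs = enumerate_realizations(seq)
    if rs.count != spec["expected_count"]:
        raise AssertionError(
            f"{name}: enumeration gives {rs.count}, expected {spec['expected_count']}"
        )
    if "expected_count_no_loops" in spec:
        seq_nl = DegreeSequence(
            out_degrees=seq.out_degrees,
            in_degrees=seq.in_degrees,
            allow_self_loops=False,
            shared_node_identity=seq.shared_node_identity,
        )
        rs_nl = enumerate_realizations(seq_nl)
        if rs_nl.count != spec["expected_count_no_loops"]:
            raise AssertionError(
                f"{name}: loopless enumeration gives {rs_nl.count}, "
                f"expected {spec['expected_count_no_loops']}"
            )
        if len(rs.with_self_loop()) != spec["expected_with_self_loop"]:
            raise AssertionError(f"{name}: self-loop realization count mismatch")
    if "no_hub_hub_edge" in spec:
        hub_edge = tuple(spec["no_hub_hub_edge"])
        missing = [fp for fp in rs.fingerprints if hub_edge not in fp]
        if len(missing) != 1:
            raise AssertionError(
                f"{name}: {len(missing)} realizations lack the hub-hub edge, expected 1"
            )
    return seq, rs


def no_hub_hub_realization(name: str) -> Fingerprint:
    """The unique realization without the hub-to-hub edge (where defined)."""
    spec = CANONICAL_EXAMPLES[name]
    seq, rs = canonical_example(name)
    hub_edge = tuple(spec["no_hub_hub_edge"])
    (fp,) = [f for f in rs.fingerprints if hub_edge not in f]
    return fp


# ---------------------------------------------------------------------------
# Sampler adapters: run the package's randomizers on a bare degree sequence
# so evaluate_sampler can compare them on identical footing.


def _sequence_layer(seq: DegreeSequence):
    """Build a single synthetic layer realizing a degree sequence.

    Shared-identity sequences map onto the TF→TF layer (the only layer
    where a node is both source and target); disjoint sequences map onto a
    cross-type layer.  Returns (layer, to_fingerprint) where the second
    element converts a sampled edge set back to index pairs.
    """
    from .network import BipartiteLayer, LayerKind

    if seq.shared_node_identity:
        ids = [f"n{i:03d}" for i in range(len(seq.out_degrees))]
        layer = BipartiteLayer(
            kind=LayerKind.TF_TF,
            source_degrees={ids[i]: d for i, d in enumerate(seq.out_degrees)},
            target_degrees={ids[i]: d for i, d in enumerate(seq.in_degrees)},
            edges=frozenset(),
        )
        back = {ids[i]: i for i in range(len(ids))}
        return layer, lambda edges: tuple(
            sorted((back[s], back[t]) for s, t in edges)
        )
    s_ids = [f"s{i:03d}" for i in range(len(seq.out_degrees))]
    t_ids = [f"t{j:03d}" for j in range(len(seq.in_degrees))]
    layer = BipartiteLayer(
        kind=LayerKind.TF_MIRNA,
        source_degrees={s_ids[i]: d for i, d in enumerate(seq.out_degrees)},
        target_degrees={t_ids[j]: d for j, d in enumerate(seq.in_degrees)},
        edges=frozenset(),
    )
    s_back = {sid: i for i, sid in enumerate(s_ids)}
    t_back = {tid: j for j, tid in enumerate(t_ids)}
    return layer, lambda edges: tuple(
        sorted((s_back[s], t_back[t]) for s, t in edges)
    )


def warswap_sequence_sampler(config=None):
    """WaRSwap core method as a degree-sequence sampler (no permutation —
    uniformity is defined on fixed degrees)."""
    from .sampler import SamplerConfig, randomize_layer

    cfg = config or SamplerConfig(permute_in_degrees=False)
    cache: dict[int, tuple] = {}

    def draw(seq: DegreeSequence, rng: np.random.Generator) -> Fingerprint:
        key = id(seq)
        if key not in cache:
            cache[key] = _sequence_layer(seq)
        layer, to_fp = cache[key]
        edges, _ = randomize_layer(layer, cfg, rng)
        return to_fp(edges)

    return draw


def edge_switch_sequence_sampler(
    attempts_per_edge: int = 3, start: Fingerprint | None = None
):
    """Edge-switching as a degree-sequence sampler.

    Each draw starts from the same initial realization (``start``, or the
    lexicographically first realization when omitted) and runs the default
    switch budget — mirroring how switching tools are applied to a given
    input graph.
    """
    from .edge_switch import switch_edge_set

    cache: dict[int, Fingerprint] = {}

    def draw(seq: DegreeSequence, rng: np.random.Generator) -> Fingerprint:
        key = id(seq)
        if key not in cache:
            if start is not None:
                cache[key] = start
            else:
                cache[key] = enumerate_realizations(seq).fingerprints[0]
        if seq.shared_node_identity:
            edges = {(("N", s), ("N", t)) for s, t in cache[key]}
        else:
            edges = {(("S", s), ("T", t)) for s, t in cache[key]}
        switch_edge_set(
            edges,
            attempts_per_edge * seq.m,
            rng,
            allow_self_loops=seq.allow_self_loops,
        )
        return tuple(sorted((s[1], t[1]) for s, t in edges))

    return draw


def uniform_reference_sampler(realizations: RealizationSet):
    """Exact-uniform draws over the enumerated realizations (metric calibration)."""

    def draw(seq: DegreeSequence, rng: np.random.Generator) -> Fingerprint:
        return realizations.fingerprints[int(rng.integers(realizations.count))]

    return draw
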