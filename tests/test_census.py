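"""Colored subgraph census: canonical classes, exact counts, oracle equivalence."""

from itertools import combinations, permutations

import pytest

from warswap.census import (
    DECORATED_TF,
    canonical_class,
    census1,
    census2,
    census3,
    lock_on_class,
    mirna_ffl_class,
    sustained_input_class,
)
from warswap.network import NodeType, RegulatoryNetwork
from warswap.synth import toy_chain, toy_ffl, toy_lock_on

from conftest import random_colored_network

TF, MIR, GENE = int(NodeType.TF), int(NodeType.MIRNA), int(NodeType.GENE)


def brute_force_census3(net, mode):
    """Independent oracle: iterate all node triples, keep weakly connected
    induced colored subgraphs, classify each."""
    loops = {s for s, t in net.edges if s == t}
    colors = {}
    for n, t in net.nodes.items():
        colors[n] = (
            DECORATED_TF if (mode == "decorated" and n in loops and t is NodeType.TF) else int(t)
        )
    edges = {(s, t) for s, t in net.edges if s != t}
    counts = {}
    for triple in combinations(sorted(net.nodes), 3):
        present = [(a, b) for a in triple for b in triple if a != b and (a, b) in edges]
        # weak connectivity on 3 nodes: every node touched and not two components
        touched = {x for e in present for x in e}
        if touched != set(triple):
            continue
        skel = {frozenset(e) for e in present}
        if len(skel) < 2:
            continue
        adj = [[1 if (a, b) in edges else 0 for b in triple] for a in triple]
        cid = canonical_class([colors[v] for v in triple], adj).canonical_id
        counts[cid] = counts.get(cid, 0) + 1
    return counts


class TestCanonicalClass:
    def test_ffl_invariant_under_node_order(self):
        base = mirna_ffl_class().canonical_id
        nodes = [TF, MIR, GENE]
        adj = [[0, 1, 1], [0, 0, 1], [0, 0, 0]]
        for perm in permutations(range(3)):
            p_colors = [nodes[i] for i in perm]
            p_adj = [[adj[i][j] for j in perm] for i in perm]
            assert canonical_class(p_colors, p_adj).canonical_id == base

    def test_mutual_tf_pair_symmetric(self):
        a = canonical_class([TF, TF], [[0, 1], [1, 0]])
        b = canonical_class([TF, TF], [[0, 1], [1, 0]])
        assert a.canonical_id == b.canonical_id == lock_on_class().canonical_id

    def test_decorated_ffl_splits_into_four_classes(self):
        """A TF-TF-target FFL with self-loop decorations on neither, either,
        or both TFs gives four distinct classes."""
        ids = set()
        for c1 in (TF, DECORATED_TF):
            for c2 in (TF, DECORATED_TF):
                ids.add(
                    canonical_class(
                        [c1, c2, GENE], [[0, 1, 1], [0, 0, 1], [0, 0, 0]]
                    ).canonical_id
                )
        assert len(ids) == 4

    def test_size_limit(self):
        with pytest.raises(ValueError):
            canonical_class([TF] * 4, [[0] * 4] * 4)


class TestCensus3:
    def test_toy_ffl_counted_once(self):
        result = census3(toy_ffl())
        assert result.total() == 1
        (cid,) = result.counts
        assert cid == canonical_class(
            [TF, TF, GENE], [[0, 1, 1], [0, 0, 1], [0, 0, 0]]
        ).canonical_id

    def test_chain_counts_one_connected_triple(self):
        result = census3(toy_chain())
        assert result.total() == 1

    def test_disconnected_triples_not_counted(self):
        net = RegulatoryNetwork.from_data(
            {
                "a": NodeType.TF,
                "b": NodeType.TF,
                "g": NodeType.GENE,
                "lone": NodeType.GENE,
            },
            {("a", "b"), ("a", "g"), ("b", "g")},
        )
        assert census3(net).total() == 1  # the a-b-g triangle only

    @pytest.mark.parametrize("mode", ["plain", "decorated"])
    def test_matches_brute_force_oracle(self, rng, mode):
        for _ in range(25):
            net = random_colored_network(rng)
            assert census3(net, mode).counts == brute_force_census3(net, mode)

    def test_plain_census_ignores_self_loops(self, rng):
        net = random_colored_network(rng, loop_prob=0.8)
        stripped = RegulatoryNetwork.from_data(
            net.nodes, {e for e in net.edges if e[0] != e[1]}
        )
        assert census3(net, "plain").counts == census3(stripped, "plain").counts

    def test_invariant_under_node_relabeling(self, rng):
        net = random_colored_network(rng)
        mapping = {n: f"z{i:03d}" for i, n in enumerate(sorted(net.nodes, key=hash))}
        relabeled = RegulatoryNetwork.from_data(
            {mapping[n]: t for n, t in net.nodes.items()},
            {(mapping[s], mapping[t]) for s, t in net.edges},
        )
        assert census3(net).counts == census3(relabeled).counts


class TestCensus12:
    def test_two_loop_counted_as_lock_on_skeleton(self):
        result = census2(toy_lock_on())
        assert result.counts == {lock_on_class().canonical_id: 1}

    def test_single_edges_distinct_from_two_loops(self):
        net = RegulatoryNetwork.from_data(
            {"a": NodeType.TF, "b": NodeType.TF, "c": NodeType.TF},
            {("a", "b"), ("b", "a"), ("a", "c")},
        )
        result = census2(net)
        assert result.counts[lock_on_class().canonical_id] == 1
        single = canonical_class([TF, TF], [[0, 1], [0, 0]]).canonical_id
        assert result.counts[single] == 1

    def test_self_loop_census(self):
        net = RegulatoryNetwork.from_data({"a": NodeType.TF}, {("a", "a")})
        result = census1(net)
        assert result.total() == 1

    def test_loops_do_not_leak_into_plain_triples(self):
        nodes = {f"t{i}": NodeType.TF for i in range(5)}
        loops = {(n, n) for n in nodes}
        net = RegulatoryNetwork.from_data(nodes, loops)
        assert census1(net).total() == 5
        assert census3(net, "plain").total() == 0
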