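"""Weighted sampler: weight formula, escalation, permutation, layer draws,
reverse swaps, full-network randomization."""

import numpy as np
import pytest

from warswap.network import (
    BipartiteLayer,
    LayerKind,
    NodeType,
    RegulatoryNetwork,
    decompose_layers,
)
from warswap.sampler import (
    InfeasibleLayerError,
    SampleState,
    SamplerConfig,
    effective_p,
    permute_in_degrees,
    randomize_layer,
    randomize_network,
    reverse_swap,
    sampling_weight,
)

from conftest import random_feasible_layer


def make_layer(out_degs, in_degs, kind=LayerKind.TF_MIRNA):
    if kind is LayerKind.TF_TF:
        ids = [f"n{i}" for i in range(max(len(out_degs), len(in_degs)))]
        src = {ids[i]: d for i, d in enumerate(out_degs)}
        tgt = {ids[i]: d for i, d in enumerate(in_degs)}
    else:
        src = {f"s{i}": d for i, d in enumerate(out_degs)}
        tgt = {f"t{j}": d for j, d in enumerate(in_degs)}
    return BipartiteLayer(kind=kind, source_degrees=src, target_degrees=tgt, edges=frozenset())


class TestSamplingWeight:
    def test_direct_substitution(self):
        # 3*3 * (1 - 3*3 / (6*5)) = 9 * 0.7 = 6.3
        assert sampling_weight(3, 3, 3, 3, m=5, p=6) == pytest.approx(6.3)

    def test_saturated_target_has_zero_attraction(self):
        assert sampling_weight(3, 3, 3, 0, m=5, p=6) == 0.0

    def test_invalid_correction_factor_raises(self):
        # 1 - 16/12 < 0: p too small for this degree product
        with pytest.raises(InfeasibleLayerError, match="escalat"):
            sampling_weight(4, 4, 4, 4, m=2, p=6)


class TestEffectiveP:
    def test_no_escalation_when_valid(self):
        layer = make_layer([3, 1, 1], [3, 1, 1])  # max product 9, m=5: 9/30 < 1
        assert effective_p(layer, SamplerConfig()) == 6

    def test_escalation_arithmetic(self):
        # The rule only involves max degrees and m; emulate max product 25
        # with m=4 via a stub: 25/24 >= 1 at p=6 but 25/28 < 1 at p=7.
        class Stub:
            m = 4
            kind = LayerKind.TF_MIRNA
            source_degrees = {"s0": 5}
            target_degrees = {"t0": 5}

        assert effective_p(Stub(), SamplerConfig()) == 7

    def test_hub_layer_no_escalation_needed(self):
        # max product 16, m=4: 16/24 < 1 already at p=6
        layer = make_layer([4], [1, 1, 1, 1])
        assert effective_p(layer, SamplerConfig()) == 6

    def test_single_edge_layer_stays_at_default(self):
        layer = make_layer([1], [1])
        assert effective_p(layer, SamplerConfig()) == 6

    def test_escalation_disabled_raises(self):
        class Stub:
            m = 4
            kind = LayerKind.TF_MIRNA
            source_degrees = {"s0": 5}
            target_degrees = {"t0": 5}

        with pytest.raises(InfeasibleLayerError):
            effective_p(Stub(), SamplerConfig(auto_escalate_p=False))


class TestPermuteInDegrees:
    def test_multiset_preserved(self, rng):
        layer = make_layer([3, 1, 1], [3, 1, 1])
        permuted = permute_in_degrees(layer, rng)
        assert sorted(permuted.values()) == sorted(layer.target_degrees.values())

    def test_constant_multiset_forces_identity(self, rng):
        layer = make_layer([2, 2], [2, 2])
        assert permute_in_degrees(layer, rng) == layer.target_degrees

    def test_zero_degree_universe_widens(self, rng):
        layer = make_layer([2, 1], [2, 1, 0])  # t2 unconnected
        # default universe never gives t2 a positive degree
        for _ in range(20):
            assert permute_in_degrees(layer, rng)["t2"] == 0
        # widened universe eventually does, preserving the multiset with zero
        seen_positive = False
        for _ in range(50):
            permuted = permute_in_degrees(layer, rng, include_zero_degree_targets=True)
            assert sorted(permuted.values()) == [0, 1, 2]
            if permuted["t2"] > 0:
                seen_positive = True
        assert seen_positive


class TestRandomizeLayer:
    def test_unique_realization_is_found(self, rng):
        layer = make_layer([2, 1], [2, 1])
        edges, swaps = randomize_layer(layer, SamplerConfig(), rng)
        assert edges == {("s0", "t0"), ("s0", "t1"), ("s1", "t0")}

    def test_all_13_realizations_of_small_example_are_hit(self, rng):
        layer = make_layer([3, 2, 1, 1], [3, 2, 1, 1])
        seen = set()
        for _ in range(2000):
            edges, _ = randomize_layer(layer, SamplerConfig(), rng)
            seen.add(frozenset(edges))
        assert len(seen) == 13

    def test_degree_conservation_on_random_layers(self, rng):
        for i in range(200):
            layer = random_feasible_layer(
                rng,
                n_sources=int(rng.integers(2, 7)),
                n_targets=int(rng.integers(2, 8)),
                m=int(rng.integers(1, 14)),
            )
            edges, _ = randomize_layer(layer, SamplerConfig(), rng)
            out = {s: 0 for s in layer.source_degrees}
            inn = {t: 0 for t in layer.target_degrees}
            for s, t in edges:
                out[s] += 1
                inn[t] += 1
            assert out == layer.source_degrees
            assert inn == layer.target_degrees
            assert len(edges) == layer.m

    def test_stuck_state_resolves_via_swap(self, rng):
        # out (2,2) / in (2,1,1): when the first source takes {t1,t2}, the
        # second source finds a single unsaturated target and must swap.
        layer = make_layer([2, 2], [2, 1, 1])
        swap_seen = False
        for seed in range(200):
            edges, swaps = randomize_layer(
                layer, SamplerConfig(), np.random.default_rng(seed)
            )
            out = {s: 0 for s in layer.source_degrees}
            inn = {t: 0 for t in layer.target_degrees}
            for s, t in edges:
                out[s] += 1
                inn[t] += 1
            assert out == layer.source_degrees and inn == layer.target_degrees
            if swaps >= 1:
                swap_seen = True
        assert swap_seen

    def test_infeasible_sequence_raises(self, rng):
        # T0 needs in-degree 3 but only two sources exist
        layer = make_layer([2, 2], [3, 1])
        with pytest.raises(InfeasibleLayerError):
            randomize_layer(layer, SamplerConfig(), rng)

    def test_self_loops_only_in_tf_tf(self, rng):
        layer = random_feasible_layer(rng, kind=LayerKind.TF_TF, n_sources=6, m=14)
        saw_loop = False
        for _ in range(50):
            edges, _ = randomize_layer(layer, SamplerConfig(), rng)
            saw_loop = saw_loop or any(s == t for s, t in edges)
        # loops are legal here; with drop_self_loops they must vanish
        for _ in range(50):
            edges, _ = randomize_layer(layer, SamplerConfig(drop_self_loops=True), rng)
            assert not any(s == t for s, t in edges)


class TestReverseSwap:
    @staticmethod
    def build_state(edges, deg_s, deg_t, allow_self=False):
        cap_s = dict(deg_s)
        cap_t = dict(deg_t)
        targets_of = {s: set() for s in deg_s}
        for s, t in edges:
            cap_s[s] -= 1
            cap_t[t] -= 1
            targets_of[s].add(t)
        return SampleState(
            deg_source=dict(deg_s),
            deg_target=dict(deg_t),
            cap_source=cap_s,
            cap_target=cap_t,
            targets_of=targets_of,
            edges=set(edges),
            allow_self_loops=allow_self,
        )

    def test_unique_swap_is_forced(self, rng):
        # S stuck with one unplaced edge; only T1 unsaturated and S->T1 placed;
        # the only movable edge is S'->T2.
        state = self.build_state(
            edges={("S", "T1"), ("Sp", "T2")},
            deg_s={"S": 2, "Sp": 1},
            deg_t={"T1": 2, "T2": 1},
        )
        out = reverse_swap(state, "S", rng)
        assert ("Sp", "T1") in out.edges and ("S", "T2") in out.edges
        assert ("Sp", "T2") not in out.edges
        assert out.swap_count == 1
        assert out.cap_source["S"] == 0

    def test_swap_edge_drawn_uniformly(self):
        # two symmetric candidate edges; each should win about half the time
        wins = {"Sa": 0, "Sb": 0}
        for seed in range(400):
            state = self.build_state(
                edges={("S", "T1"), ("Sa", "T2"), ("Sb", "T3")},
                deg_s={"S": 2, "Sa": 1, "Sb": 1},
                deg_t={"T1": 2, "T2": 1, "T3": 1},
            )
            out = reverse_swap(state, "S", np.random.default_rng(seed))
            winner = "Sa" if ("Sa", "T1") in out.edges else "Sb"
            wins[winner] += 1
        assert 120 < wins["Sa"] < 280

    def test_precondition_violation_raises(self, rng):
        # T2 is unsaturated but not targeted by S: step 2/3a should have
        # placed there, so reverse_swap must refuse.
        state = self.build_state(
            edges={("S", "T1")},
            deg_s={"S": 2, "Sp": 1},
            deg_t={"T1": 1, "T2": 2},
        )
        with pytest.raises(RuntimeError, match="precondition"):
            reverse_swap(state, "S", rng)


class TestRandomizeNetwork:
    def test_per_layer_edge_counts_preserved(self, small_net, rng):
        result = randomize_network(small_net, SamplerConfig(), rng)
        orig = {l.kind: l.m for l in decompose_layers(small_net)}
        rand = {l.kind: l.m for l in decompose_layers(result.network)}
        assert orig == rand
        assert set(result.network.nodes) == set(small_net.nodes)

    def test_out_degrees_exact_in_degrees_multiset(self, small_net, rng):
        result = randomize_network(small_net, SamplerConfig(), rng)
        for before, after in zip(
            decompose_layers(small_net), decompose_layers(result.network)
        ):
            assert before.source_degrees == after.source_degrees
            assert sorted(before.target_degrees.values()) == sorted(
                after.target_degrees.values()
            )

    def test_exact_in_degrees_without_permutation(self, small_net, rng):
        result = randomize_network(
            small_net, SamplerConfig(permute_in_degrees=False), rng
        )
        for before, after in zip(
            decompose_layers(small_net), decompose_layers(result.network)
        ):
            assert before.target_degrees == after.target_degrees

    def test_single_self_loop_network_is_reproduced(self, rng):
        net = RegulatoryNetwork.from_data({"A": NodeType.TF}, {("A", "A")})
        result = randomize_network(net, SamplerConfig(), rng)
        assert result.network.edges == net.edges

    def test_reverse_swaps_rare_on_hub_heavy_network(self):
        """Sorting heavy sources first keeps repair swaps rare even on a
        hub-dominated 570-node network (well under one per replicate on
        average)."""
        from warswap.synth import GeneratorConfig, generate

        net = generate(GeneratorConfig(seed=7))
        swaps = [
            randomize_network(net, SamplerConfig(), np.random.default_rng(s)).total_swaps
            for s in range(20)
        ]
        assert np.mean(swaps) < 2.0

    def test_recombined_network_is_valid(self, small_net, rng):
        for seed in range(5):
            result = randomize_network(
                small_net, SamplerConfig(), np.random.default_rng(seed)
            )
            result.network.validate()  # no duplicate edges, typed constraints
            for s, t in result.network.edges:
                if s == t:
                    assert small_net.nodes[s] is NodeType.TF
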