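import numpy as np
import pytest

from warswap.network import LayerKind, NodeType, RegulatoryNetwork
from warswap.synth import GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_net():
    """Mixed-type network exercising all five layers plus a TF self-loop."""
    return RegulatoryNetwork.from_data(
        {
            "tfA": NodeType.TF,
            "tfB": NodeType.TF,
            "mir1": NodeType.MIRNA,
            "mir2": NodeType.MIRNA,
            "g1": NodeType.GENE,
            "g2": NodeType.GENE,
        },
        {
            ("tfA", "tfA"),
            ("tfA", "tfB"),
            ("tfA", "mir1"),
            ("tfB", "mir2"),
            ("tfA", "g1"),
            ("tfB", "g1"),
            ("mir1", "tfB"),
            ("mir1", "g2"),
            ("mir2", "g1"),
        },
    )


SMALL_BUDGETS = {
    LayerKind.TF_TF: 25,
    LayerKind.TF_MIRNA: 15,
    LayerKind.TF_GENE: 90,
    LayerKind.MIRNA_TF: 10,
    LayerKind.MIRNA_GENE: 25,
}


@pytest.fixture
def small_config():
    return GeneratorConfig(
        n_tf=15,
        n_mirna=8,
        n_gene=60,
        layer_budgets=dict(SMALL_BUDGETS),
        seed=3,
    )


@pytest.fixture
def small_net(small_config):
    return generate(small_config)


def random_feasible_layer(rng, kind=LayerKind.TF_MIRNA, n_sources=6, n_targets=8, m=12):
    """A random feasible bipartite layer built by realizing a random graph
    first, so its degree sequence is feasible by construction."""
    from warswap.network import BipartiteLayer

    sources = [f"s{i}" for i in range(n_sources)]
    targets = [f"t{j}" for j in range(n_targets)]
    if kind is LayerKind.TF_TF:
        targets = sources = [f"n{i}" for i in range(max(n_sources, n_targets))]
    all_pairs = [
        (s, t) for s in sources for t in targets if kind.allows_self_loops or s != t
    ]
    m = min(m, len(all_pairs))
    picked = [all_pairs[i] for i in rng.choice(len(all_pairs), size=m, replace=False)]
    out_deg = {s: 0 for s in sources}
    in_deg = {t: 0 for t in targets}
    for s, t in picked:
        out_deg[s] += 1
        in_deg[t] += 1
    return BipartiteLayer(
        kind=kind,
        source_degrees=out_deg,
        target_degrees=in_deg,
        edges=frozenset(picked),
    )


def random_colored_network(rng, n_nodes=12, edge_prob=0.25, loop_prob=0.3):
    """Random valid typed network for census oracle tests."""
    types = [NodeType.TF, NodeType.MIRNA, NodeType.GENE]
    nodes = {
        f"v{i:02d}": types[int(rng.integers(3))] for i in range(n_nodes)
    }
    edges = set()
    ids = sorted(nodes)
    for s in ids:
        if nodes[s] is NodeType.GENE:
            continue
        for t in ids:
            if s == t:
                if nodes[s] is NodeType.TF and rng.random() < loop_prob * edge_prob:
                    edges.add((s, s))
                continue
            if rng.random() < edge_prob:
                edges.add((s, t))
    return RegulatoryNetwork.from_data(nodes, edges)
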