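from itertools import product

import numpy as np
import pytest

from motifmod.network import CompositeNetwork, LayerSpec


@pytest.fixture
def rp_layers():
    return [LayerSpec("R", True), LayerSpec("P", False)]


@pytest.fixture
def toy_net(rp_layers):
    """Small mixed network: one TF fanning out over a P-linked target set."""
    net = CompositeNetwork(layers=rp_layers)
    for u, v, l in [
        ("tf1", "g1", "R"), ("tf1", "g2", "R"), ("tf1", "g3", "R"),
        ("g1", "g2", "P"), ("g2", "g3", "P"), ("g1", "g3", "P"),
        ("g3", "g4", "P"),
    ]:
        net.add_edge(u, v, l)
    return net


def random_composite_network(rng, n_nodes, layers, density=0.15):
    """Uniform random composite network for oracle comparisons."""
    net = CompositeNetwork(layers=list(layers))
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    net.nodes.update(nodes)
    for spec in layers:
        if spec.directed:
            for u in nodes:
                for v in nodes:
                    if u != v and rng.random() < density / 2:
                        net.add_edge(u, v, spec.letter)
        else:
            for i in range(n_nodes):
                for j in range(i + 1, n_nodes):
                    if rng.random() < density:
                        net.add_edge(nodes[i], nodes[j], spec.letter)
    return net


def brute_force_three_node(net):
    """Independent oracle: scan every node triple and every combination
    of one concrete edge per pair; returns a set of frozen edge sets."""
    nodes = sorted(net.nodes)
    found = set()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            for k in range(j + 1, len(nodes)):
                triple = (nodes[i], nodes[j], nodes[k])
                per_pair = []
                for a, b in ((0, 1), (0, 2), (1, 2)):
                    u, v = triple[a], triple[b]
                    options = []
                    for spec in net.layers:
                        es = net.edges[spec.letter]
                        if spec.directed:
                            if (u, v) in es:
                                options.append((u, v, spec.letter, True))
                            if (v, u) in es:
                                options.append((v, u, spec.letter, True))
                        else:
                            key = (u, v) if u <= v else (v, u)
                            if key in es:
                                options.append((key[0], key[1], spec.letter, False))
                    per_pair.append(options)
                if any(not opts for opts in per_pair):
                    continue
                for combo in product(*per_pair):
                    found.add(frozenset(combo))
    return found


def brute_force_two_node(net):
    """Independent oracle for DD / DU pairs: scan every node pair."""
    nodes = sorted(net.nodes)
    dd, du = set(), set()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            fwd, rev, und = [], [], []
            for spec in net.layers:
                es = net.edges[spec.letter]
                if spec.directed:
                    if (u, v) in es:
                        fwd.append((u, v, spec.letter, True))
                    if (v, u) in es:
                        rev.append((v, u, spec.letter, True))
                else:
                    if (u, v) in es:
                        und.append((u, v, spec.letter, False))
            for f in fwd:
                for r in rev:
                    dd.add(frozenset((f, r)))
            for d in fwd + rev:
                for w in und:
                    du.add(frozenset((d, w)))
    return dd, du


@pytest.fixture(scope="session")
def planted_fixture():
    """Shared planted-module network, truth and derived modules."""
    from motifmod.pipeline import PipelineConfig, derive_modules
    from motifmod.synth import FixtureConfig, generate_composite_network

    cfg = FixtureConfig(seed=0)
    net, truth = generate_composite_network(cfg)
    pc = PipelineConfig(layers=list(cfg.layers), seed=0)
    by_pool = derive_modules(net, pc, pools=("COM", "COR", "FFL"))
    modules = [m for mods in by_pool.values() for m in mods]
    return {"cfg": cfg, "net": net, "truth": truth, "modules": modules,
            "pipeline_config": pc}
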