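"""Edge-to-node-ratio hypergraph clustering of subgraph instances.

Every enumerated subgraph instance becomes one hyperedge (its 2 or 3
nodes); clusters are extracted greedily, each maximizing the ratio

    (total weight of hyperedges fully inside S) / |S|

over node sets S.  The candidate S is found by a nonlinear power
iteration (Perron vector of the hypergraph) followed by a scan over
score-ordered prefixes.  Extracted hyperedges are removed and the
procedure repeats, so a node can reappear in later clusters through its
surviving hyperedges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .motifs import SubgraphInstance
from .network import CompositeNetwork


@dataclass
class Hypergraph:
    """Node sets of size 2–3 with positive weights over a hypernode universe."""

    hyperedges: list[frozenset]
    weights: list[float] = field(default_factory=list)
    payloads: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = [1.0] * len(self.hyperedges)
        if not self.payloads:
            self.payloads = list(range(len(self.hyperedges)))
        if any(w <= 0 for w in self.weights):
            raise ValueError("hyperedge weights must be positive")

    @property
    def hypernodes(self) -> set:
        return {n for e in self.hyperedges for n in e}

    def __len__(self) -> int:
        return len(self.hyperedges)


@dataclass
class ClusteringParams:
    """Settings of the iterative extraction.

    ``p`` is the exponent of the Perron update (default 1, the reference
    setting); ``tol``/``max_iter`` control power-iteration convergence.
    ``seed`` only matters for optional random restarts; the default start
    vector is uniform, so runs are deterministic.
    """

    p: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-9
    seed: int = 0
    #: below this many surviving hypernodes the ratio maximization is
    #: solved exactly over all node subsets instead of by spectral prefix
    exact_max_nodes: int = 12

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("p must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class Cluster:
    nodes: set
    hyperedges: list[frozenset]
    payloads: list
    ratio: float


@dataclass
class Module:
    """Filtered cluster: named node set with member subgraphs and typed edges."""

    name: str
    topo_type: str
    nodes: set
    subgraphs: list[SubgraphInstance]
    internal_edges: list[tuple[str, str, str, bool]]  # (u, v, letter, directed)


def build_hypergraph(
    instances: Sequence[SubgraphInstance], pool: str = "ALL"
) -> Hypergraph:
    """One unit-weight hyperedge per instance of the requested pool.

    ``pool`` is one of the eight topological types or "ALL"; ALL takes
    every instance (including DD pairs), a typed pool takes exactly the
    instances of that type.
    """
    if pool == "ALL":
        selected = list(instances)
    else:
        selected = [i for i in instances if i.topo_type == pool]
    return Hypergraph(
        hyperedges=[frozenset(i.nodes) for i in selected],
        weights=[1.0] * len(selected),
        payloads=list(selected),
    )


def _perron_scores(
    edges: list[frozenset], weights: list[float], params: ClusteringParams
) -> dict:
    """Nonlinear power iteration x_i ← Σ_{e∋i} w_e Π_{j∈e\\{i}} x_j^p.

    The update is damped with the previous iterate (same fixed points,
    suppresses period-two oscillation on bipartite-like structures) and
    L2-normalized each step.
    """
    nodes = sorted({n for e in edges for n in e})
    index = {n: k for k, n in enumerate(nodes)}
    idx_edges = [np.array([index[n] for n in e]) for e in edges]
    w = np.asarray(weights, dtype=float)
    x = np.full(len(nodes), 1.0 / max(len(nodes), 1))
    for _ in range(params.max_iter):
        new = np.zeros_like(x)
        for e, we in zip(idx_edges, w):
            vals = x[e] ** params.p
            prod = np.prod(vals)
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(vals > 0, prod / vals, 0.0)
            # recompute exactly when a member score is zero
            if np.any(vals == 0):
                contrib = np.array(
                    [np.prod(np.delete(vals, k)) for k in range(len(e))]
                )
            new[e] += we * contrib
        new = new + x  # damping; fixed points unchanged
        norm = np.linalg.norm(new)
        if norm == 0:
            break
        new /= norm
        if np.max(np.abs(new - x)) < params.tol:
            x = new
            break
        x = new
    else:
        import logging

        logging.getLogger(__name__).warning(
            "power iteration did not converge in %d steps; using last iterate",
            params.max_iter,
        )
    return dict(zip(nodes, x))


def _best_prefix(
    edges: list[frozenset], weights: list[float], order: list
) -> tuple[set, float]:
    """Prefix of ``order`` maximizing inside-weight / prefix-size."""
    remaining = [set(e) for e in edges]
    pending = {n: [] for n in order}
    for k, e in enumerate(remaining):
        for n in e:
            pending[n].append(k)
    missing = [len(e) for e in remaining]
    inside = 0.0
    best_ratio, best_len = -1.0, 0
    for i, n in enumerate(order):
        for k in pending[n]:
            missing[k] -= 1
            if missing[k] == 0:
                inside += weights[k]
        ratio = inside / (i + 1)
        if ratio > best_ratio + 1e-12:
            best_ratio, best_len = ratio, i + 1
    return set(order[:best_len]), best_ratio


def _exact_best_subset(
    edges: list[frozenset], weights: list[float]
) -> tuple[set, float]:
    """Exact ratio maximization by bitmask scan (small hypergraphs)."""
    nodes = sorted({n for e in edges for n in e})
    pos = {n: k for k, n in enumerate(nodes)}
    masks = [sum(1 << pos[n] for n in e) for e in edges]
    best_ratio, best_mask = -1.0, 0
    for subset in range(1, 1 << len(nodes)):
        inside = sum(w for m, w in zip(masks, weights) if m & subset == m)
        ratio = inside / subset.bit_count()
        if ratio > best_ratio + 1e-12:
            best_ratio, best_mask = ratio, subset
    return {n for n in nodes if best_mask >> pos[n] & 1}, best_ratio


def schype_cluster(
    h: Hypergraph, params: ClusteringParams | None = None
) -> list[Cluster]:
    """Iterative ratio-maximizing extraction until no hyperedge remains.

    Each round the best-ratio node set of the surviving hypergraph is
    emitted as a cluster together with its internal hyperedges, which
    are then removed; every hyperedge ends up in exactly one cluster.
    The candidate set comes from an exact subset scan when few
    hypernodes survive, otherwise from Perron scores with nodes sorted
    by descending score (ties broken lexicographically) and the
    best-ratio prefix taken.
    """
    params = params or ClusteringParams()
    edges = list(h.hyperedges)
    weights = list(h.weights)
    payloads = list(h.payloads)
    clusters: list[Cluster] = []
    while edges:
        n_nodes = len({n for e in edges for n in e})
        if n_nodes <= params.exact_max_nodes:
            prefix, ratio = _exact_best_subset(edges, weights)
        else:
            scores = _perron_scores(edges, weights, params)
            order = sorted(scores, key=lambda n: (-scores[n], n))
            prefix, ratio = _best_prefix(edges, weights, order)
        in_idx = [k for k, e in enumerate(edges) if e <= prefix]
        if not in_idx:  # cannot happen: full prefix contains every edge
            in_idx = list(range(len(edges)))
        member_edges = [edges[k] for k in in_idx]
        clusters.append(
            Cluster(
                nodes=set().union(*member_edges),
                hyperedges=member_edges,
                payloads=[payloads[k] for k in in_idx],
                ratio=ratio,
            )
        )
        keep = [k for k in range(len(edges)) if k not in set(in_idx)]
        edges = [edges[k] for k in keep]
        weights = [weights[k] for k in keep]
        payloads = [payloads[k] for k in keep]
    return clusters


def exhaustive_best_ratio(h: Hypergraph) -> tuple[set, float]:
    """Brute-force densest node set (independent oracle for small inputs)."""
    nodes = sorted(h.hypernodes)
    best, best_ratio = set(), -1.0
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            s = set(subset)
            inside = sum(
                w for e, w in zip(h.hyperedges, h.weights) if e <= s
            )
            ratio = inside / r
            if ratio > best_ratio + 1e-12:
                best, best_ratio = s, ratio
    return best, best_ratio


def internal_edges_of(
    nodes: set, net: CompositeNetwork
) -> list[tuple[str, str, str, bool]]:
    """All network edges with both endpoints inside ``nodes``."""
    out = []
    for spec in net.layers:
        for u, v in net.edges[spec.letter]:
            if u in nodes and v in nodes:
                out.append((u, v, spec.letter, spec.directed))
    return sorted(out)


def filter_modules(
    clusters: Sequence[Cluster],
    net: CompositeNetwork,
    pool: str,
    min_size: int = 5,
    max_size: int = 50,
    max_homology_fraction: float = 0.9,
    homology_letter: str = "H",
) -> list[Module]:
    """Size filter (5–50 nodes kept) and homology filter (> 90% H-layer
    internal edges dropped); survivors named ``<TYPE>_<index>``, 1-based
    in extraction order."""
    modules: list[Module] = []
    index = 0
    for cl in clusters:
        if not (min_size <= len(cl.nodes) <= max_size):
            continue
        internal = internal_edges_of(cl.nodes, net)
        if internal:
            n_h = sum(1 for _u, _v, letter, _d in internal if letter == homology_letter)
            if n_h / len(internal) > max_homology_fraction:
                continue
        index += 1
        modules.append(
            Module(
                name=f"{pool}_{index}",
                topo_type=pool,
                nodes=set(cl.nodes),
                subgraphs=[p for p in cl.payloads if isinstance(p, SubgraphInstance)],
                internal_edges=internal,
            )
        )
    return modules


def cluster_pool(
    instances: Sequence[SubgraphInstance],
    net: CompositeNetwork,
    pool: str,
    params: ClusteringParams | None = None,
    **filter_kw,
) -> list[Module]:
    """Convenience: build hypergraph, cluster, filter, for one pool."""
    h = build_hypergraph(instances, pool)
    if len(h) == 0:
        return []
    clusters = schype_cluster(h, params)
    return filter_modules(clusters, net, pool, **filter_kw)
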