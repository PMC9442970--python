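"""Composite-subgraph catalogue, enumeration and topological typing.

A 3-node composite subgraph is a triangle whose three edges may come
from different network layers.  It is written as a three-letter code,
one letter per node pair in slot order (0,1), (0,2), (1,2); a lowercase
letter marks a directed edge running against the slot order.  Codes
related by a relabelling of the three slots describe the same subgraph
(PPC, PCP and CPP collapse to one class), so the catalogue keeps one
canonical — lexicographically minimal — representative per class.

Eight topological types are distinguished:

========  =======================================================
COM       three undirected edges (complex)
COP       two directed edges converging on a target, regulators linked
COR       one regulator directing two interacting targets
FFL       transitive directed triangle (feed-forward loop)
CIR       cyclic directed triangle
FBU       directed two-step cascade closed by an undirected edge
FB2U      one directed plus two undirected edges
2FB       two-node pair: one directed plus one undirected edge
========  =======================================================

Two-node pairs with antiparallel directed edges (DD) are enumerated as
well; they join the joint (ALL) clustering pool only.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterable, Sequence

from .network import CompositeNetwork, ConfigurationError

#: slot pairs of a 3-node subgraph, in code-letter order
_PAIRS = ((0, 1), (0, 2), (1, 2))
_PERMS = tuple(permutations(range(3)))

TOPO_TYPES_3 = ("COP", "COR", "FFL", "CIR", "FBU", "FB2U", "COM")
TOPO_TYPES = TOPO_TYPES_3 + ("2FB",)
POOLS = TOPO_TYPES + ("ALL",)


@dataclass(frozen=True)
class SubgraphInstance:
    """One enumerated 2- or 3-node subgraph occurrence.

    ``edges`` holds concrete edges as (u, v, letter, directed); directed
    edges run u→v, undirected ones store the smaller node first.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str, bool], ...]
    code: str
    topo_type: str

    def __str__(self) -> str:  # instance dump dialect
        n3 = self.nodes[2] if len(self.nodes) == 3 else ""
        return f"{self.code}\t{self.nodes[0]}\t{self.nodes[1]}\t{n3}"


# ---------------------------------------------------------------------------
# canonical codes
# ---------------------------------------------------------------------------

def _code_from_assignment(
    assign: Sequence[tuple[str, int]], perm: tuple[int, int, int]
) -> str:
    """Code string after relabelling slots by ``perm`` (new slot i = old perm[i])."""
    chars = []
    old_pair_index = {frozenset(p): k for k, p in enumerate(_PAIRS)}
    for i, j in _PAIRS:
        a, b = perm[i], perm[j]
        letter, orient = assign[old_pair_index[frozenset((a, b))]]
        if a > b:
            orient = -orient
        chars.append(letter.lower() if orient < 0 else letter)
    return "".join(chars)


def canonicalize(
    assign: Sequence[tuple[str, int]]
) -> tuple[str, tuple[int, int, int]]:
    """Minimal code over slot relabellings, with the permutation achieving it.

    ``assign`` lists (letter, orient) per slot pair in ``_PAIRS`` order;
    orient is 0 for undirected, +1 along slot order, -1 against it.
    Ties between permutations are broken by the permutation itself so the
    result is unique.
    """
    best = min((_code_from_assignment(assign, p), p) for p in _PERMS)
    return best


def classify_assignment(assign: Sequence[tuple[str, int]]) -> str:
    """Topological type of a 3-edge triangle from its orientation pattern."""
    directed = [(pair, o) for pair, (_, o) in zip(_PAIRS, assign) if o != 0]
    k = len(directed)
    if k == 0:
        return "COM"
    if k == 1:
        return "FB2U"
    # ordered (src, dst) slot pairs of the directed edges
    arcs = [(p[0], p[1]) if o > 0 else (p[1], p[0]) for p, o in directed]
    if k == 3:
        indeg = Counter(dst for _, dst in arcs)
        return "CIR" if all(indeg[n] == 1 for n in range(3)) else "FFL"
    # k == 2: the two directed pairs always share exactly one slot
    (s1, d1), (s2, d2) = arcs
    if d1 == d2:
        return "COP"
    if s1 == s2:
        return "COR"
    return "FBU"


def classify_subgraph(instance: SubgraphInstance) -> str:
    """Type of an enumerated instance (relabelling-invariant)."""
    if len(instance.nodes) == 2:
        n_dir = sum(1 for *_, d in instance.edges if d)
        if n_dir == 1:
            return "2FB"
        if n_dir == 2:
            return "DD"
        raise ConfigurationError("unclassifiable 2-node edge pattern")
    assign = _assignment_for_nodes(instance.nodes, instance.edges)
    return classify_assignment(assign)


def generate_nonredundant_codes(
    directed_letters: set[str], undirected_letters: set[str]
) -> list[str]:
    """One canonical code per isomorphism class of 3-node, 3-edge subgraphs.

    Every combination of one edge per slot pair is generated and collapsed
    to its canonical representative; users may subtract unwanted codes
    from the returned catalogue before enumeration.
    """
    if directed_letters & undirected_letters:
        raise ConfigurationError(
            f"letters in both sets: {directed_letters & undirected_letters}"
        )
    if not (directed_letters | undirected_letters):
        raise ConfigurationError("no layer letters given")
    options: list[tuple[str, int]] = [(l, 0) for l in sorted(undirected_letters)]
    for l in sorted(directed_letters):
        options.extend([(l, 1), (l, -1)])
    codes = {canonicalize(assign)[0] for assign in product(options, repeat=3)}
    return sorted(codes)


def code_type(code: str, directed_letters: set[str]) -> str:
    """Topological type of a code given which letters are directed."""
    assign = [
        (ch.upper(), (0 if ch.upper() not in directed_letters else (-1 if ch.islower() else 1)))
        for ch in code
    ]
    return classify_assignment(assign)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _pair_edge_index(
    net: CompositeNetwork,
) -> tuple[dict[str, set[str]], dict[frozenset, list[tuple[str, tuple[str, str] | None]]]]:
    """Union adjacency plus, per node pair, the list of concrete edges."""
    adj: dict[str, set[str]] = defaultdict(set)
    pair_edges: dict[frozenset, list[tuple[str, tuple[str, str] | None]]] = defaultdict(list)
    for spec in net.layers:
        for u, v in net.edges[spec.letter]:
            adj[u].add(v)
            adj[v].add(u)
            pair_edges[frozenset((u, v))].append(
                (spec.letter, (u, v) if spec.directed else None)
            )
    return adj, pair_edges


def _assignment_for_nodes(
    nodes: Sequence[str], edges: Iterable[tuple[str, str, str, bool]]
) -> list[tuple[str, int]]:
    """(letter, orient) per slot pair for concrete nodes/edges."""
    slot = {n: i for i, n in enumerate(nodes)}
    assign: list[tuple[str, int] | None] = [None, None, None]
    idx = {frozenset(p): k for k, p in enumerate(_PAIRS)}
    for u, v, letter, directed in edges:
        k = idx[frozenset((slot[u], slot[v]))]
        if not directed:
            assign[k] = (letter, 0)
        else:
            assign[k] = (letter, 1 if slot[u] < slot[v] else -1)
    if any(a is None for a in assign):
        raise ConfigurationError("triangle is missing an edge assignment")
    return assign  # type: ignore[return-value]


def enumerate_all_three_node(net: CompositeNetwork) -> list[SubgraphInstance]:
    """Every 3-node, 3-edge composite subgraph instance in the network.

    Matching is non-induced: extra edges on a triple never disqualify it,
    and one triple contributes one instance per distinct choice of one
    concrete edge on each of its three pairs.
    """
    adj, pair_edges = _pair_edge_index(net)
    instances: list[SubgraphInstance] = []
    for a in sorted(adj):
        nbrs_a = {n for n in adj[a] if n > a}
        for b in sorted(nbrs_a):
            common = nbrs_a & adj[b]
            for c in sorted(n for n in common if n > b):
                triple = (a, b, c)
                opts = [
                    pair_edges[frozenset((triple[i], triple[j]))]
                    for i, j in _PAIRS
                ]
                for combo in product(*opts):
                    instances.append(_make_instance(triple, combo))
    return instances


def _make_instance(
    triple: tuple[str, str, str],
    combo: Sequence[tuple[str, tuple[str, str] | None]],
) -> SubgraphInstance:
    assign: list[tuple[str, int]] = []
    edges: list[tuple[str, str, str, bool]] = []
    for (i, j), (letter, arc) in zip(_PAIRS, combo):
        u, v = triple[i], triple[j]
        if arc is None:
            assign.append((letter, 0))
            edges.append((u, v, letter, False))
        else:
            assign.append((letter, 1 if arc == (u, v) else -1))
            edges.append((arc[0], arc[1], letter, True))
    code, perm = canonicalize(assign)
    nodes = tuple(triple[k] for k in perm)
    return SubgraphInstance(
        nodes=nodes,
        edges=tuple(sorted(edges)),
        code=code,
        topo_type=classify_assignment(assign),
    )


def enumerate_three_node_subgraphs(
    net: CompositeNetwork, code: str
) -> list[SubgraphInstance]:
    """All instances matching one canonical code."""
    letters = {ch.upper() for ch in code}
    unknown = letters - set(net.letters)
    if unknown:
        raise ConfigurationError(f"code {code} uses undeclared layers {unknown}")
    return [inst for inst in enumerate_all_three_node(net) if inst.code == code]


def enumerate_two_node_subgraphs(net: CompositeNetwork) -> list[SubgraphInstance]:
    """DD (antiparallel directed) and DU/2FB (directed + undirected) pairs.

    Each qualifying combination of two concrete edges on a pair is one
    instance.
    """
    _, pair_edges = _pair_edge_index(net)
    instances: list[SubgraphInstance] = []
    for pair in sorted(pair_edges, key=sorted):
        u, v = sorted(pair)
        edges = pair_edges[pair]
        fwd = [(l, a) for l, a in edges if a == (u, v)]
        rev = [(l, a) for l, a in edges if a == (v, u)]
        und = [(l, a) for l, a in edges if a is None]
        for lf, af in fwd:
            for lr, ar in rev:
                instances.append(
                    SubgraphInstance(
                        nodes=(u, v),
                        edges=tuple(sorted([(u, v, lf, True), (v, u, lr, True)])),
                        code="DD",
                        topo_type="DD",
                    )
                )
        for ld, arc in fwd + rev:
            for lu, _ in und:
                instances.append(
                    SubgraphInstance(
                        nodes=(u, v),
                        edges=tuple(sorted([(arc[0], arc[1], ld, True), (u, v, lu, False)])),
                        code="DU",
                        topo_type="2FB",
                    )
                )
    return instances


def enumerate_instances(
    net: CompositeNetwork, codes: Iterable[str] | None = None
) -> list[SubgraphInstance]:
    """Full census: all 3-node instances (optionally restricted to a code
    catalogue) plus all 2-node instances."""
    three = enumerate_all_three_node(net)
    if codes is not None:
        allowed = set(codes)
        three = [i for i in three if i.code in allowed]
    return three + enumerate_two_node_subgraphs(net)


def count_by_code(instances: Iterable[SubgraphInstance]) -> Counter:
    return Counter(inst.code for inst in instances)


def count_by_type(instances: Iterable[SubgraphInstance]) -> Counter:
    return Counter(inst.topo_type for inst in instances)


def write_instances(instances: Iterable[SubgraphInstance], path) -> None:
    """Stable-sorted instance dump: ``code<TAB>n1<TAB>n2<TAB>n3``."""
    lines = sorted(str(inst) for inst in instances)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
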