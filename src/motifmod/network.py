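"""Multi-layer composite network: loading, validation, canonical form.

A composite network is a set of nodes plus one typed edge set per
interaction *layer*.  Each layer carries a one-letter code (e.g. R for
TF→target, P for protein–protein) and a directedness flag.  Node
identifiers are opaque strings, so gene IDs and miRNA names coexist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid layer specification or input dialect."""


@dataclass(frozen=True)
class LayerSpec:
    """One input interaction layer.

    Parameters
    ----------
    letter : str
        Single uppercase character identifying the layer.
    directed : bool
        Whether edges in this layer carry a direction.
    path : str or Path, optional
        Edge-list file backing the layer (two tab-separated columns).
    """

    letter: str
    directed: bool
    path: str | Path | None = None

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isupper():
            raise ConfigurationError(
                f"layer letter must be a single uppercase character, got {self.letter!r}"
            )


def canonical_edge(u: str, v: str, directed: bool) -> tuple[str, str]:
    """Canonical stored orientation: as-is if directed, sorted otherwise."""
    if directed or u <= v:
        return (u, v)
    return (v, u)


@dataclass
class CompositeNetwork:
    """Multi-layer graph with per-layer typed edge sets.

    ``edges[letter]`` is a set of node pairs; for undirected layers the
    lexicographically smaller node is stored first, for directed layers
    the pair is (source, target).  Self-loops are never stored.
    """

    layers: list[LayerSpec]
    edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        letters = [s.letter for s in self.layers]
        if len(letters) != len(set(letters)):
            raise ConfigurationError(f"duplicate layer letters: {letters}")
        if not letters:
            raise ConfigurationError("at least one layer is required")
        for letter in letters:
            self.edges.setdefault(letter, set())

    # -- construction -------------------------------------------------
    def add_edge(self, u: str, v: str, letter: str) -> bool:
        """Add one edge; returns False for a rejected self-loop."""
        spec = self.layer(letter)
        if u == v:
            return False
        self.edges[letter].add(canonical_edge(u, v, spec.directed))
        self.nodes.add(u)
        self.nodes.add(v)
        return True

    # -- queries -------------------------------------------------------
    def layer(self, letter: str) -> LayerSpec:
        for spec in self.layers:
            if spec.letter == letter:
                return spec
        raise ConfigurationError(f"unknown layer letter {letter!r}")

    @property
    def letters(self) -> list[str]:
        return [s.letter for s in self.layers]

    @property
    def directed_letters(self) -> set[str]:
        return {s.letter for s in self.layers if s.directed}

    @property
    def undirected_letters(self) -> set[str]:
        return {s.letter for s in self.layers if not s.directed}

    def n_edges(self, letter: str | None = None) -> int:
        if letter is not None:
            return len(self.edges[letter])
        return sum(len(e) for e in self.edges.values())

    def summary(self) -> "pandas.DataFrame":  # noqa: F821 - lazy import
        """Per-layer node/edge/regulator counts (input-table shape)."""
        import pandas as pd

        rows = []
        for spec in self.layers:
            es = self.edges[spec.letter]
            nodeset = {n for e in es for n in e}
            row = {
                "letter": spec.letter,
                "directed": spec.directed,
                "nodes": len(nodeset),
                "edges": len(es),
            }
            if spec.directed:
                row["regulators"] = len({u for u, _ in es})
                row["targets"] = len({v for _, v in es})
            rows.append(row)
        return pd.DataFrame(rows)


def _iter_edge_lines(path: str | Path) -> Iterable[tuple[str, ...]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ConfigurationError(f"malformed edge line in {path}: {line!r}")
            yield tuple(parts)


def load_composite_network(layer_specs: list[LayerSpec]) -> CompositeNetwork:
    """Load per-layer edge lists into a canonical composite network.

    Undirected duplicates (A–B vs B–A) are merged, self-loops dropped
    with a logged count, and the node set is the union over layers.
    """
    net = CompositeNetwork(layers=list(layer_specs))
    for spec in layer_specs:
        if spec.path is None:
            continue
        n_lines = n_self = 0
        for parts in _iter_edge_lines(spec.path):
            n_lines += 1
            if not net.add_edge(parts[0], parts[1], spec.letter):
                n_self += 1
        if n_lines == 0:
            logger.warning("layer %s: empty input file %s", spec.letter, spec.path)
        if n_self:
            logger.info("layer %s: dropped %d self-loop(s)", spec.letter, n_self)
        n_kept = len(net.edges[spec.letter])
        logger.info(
            "layer %s: %d lines -> %d edges (%d self-loops, %d duplicates)",
            spec.letter, n_lines, n_kept, n_self, n_lines - n_self - n_kept,
        )
    return net


def load_composite_file(
    path: str | Path, layer_specs: list[LayerSpec]
) -> CompositeNetwork:
    """Load the merged dialect ``source<TAB>target<TAB>letter``."""
    known = {s.letter for s in layer_specs}
    net = CompositeNetwork(layers=list(layer_specs))
    for parts in _iter_edge_lines(path):
        if len(parts) < 3:
            raise ConfigurationError(f"composite file needs 3 columns, got {parts!r}")
        u, v, letter = parts[0], parts[1], parts[2]
        if letter not in known:
            raise ConfigurationError(f"unknown layer letter {letter!r} in {path}")
        net.add_edge(u, v, letter)
    return net


def write_composite_file(net: CompositeNetwork, path: str | Path) -> None:
    """Serialize to the canonical composite TSV, deterministically sorted."""
    with open(path, "w") as fh:
        for spec in net.layers:
            for u, v in sorted(net.edges[spec.letter]):
                fh.write(f"{u}\t{v}\t{spec.letter}\n")


def regulators(net: CompositeNetwork, letter: str) -> set[str]:
    """All nodes with at least one outgoing edge in a directed layer."""
    spec = net.layer(letter)
    if not spec.directed:
        raise ConfigurationError(f"layer {letter} is undirected; it has no regulators")
    return {u for u, _ in net.edges[letter]}


def all_regulators(net: CompositeNetwork) -> dict[str, set[str]]:
    """Regulator sets per directed layer (e.g. TFs in R, miRNAs in M)."""
    return {l: regulators(net, l) for l in net.directed_letters}
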