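"""Cytoscape export: NNF module networks, NOA node attributes, style XML.

The NNF (nested network format) file lists one parent entry per module
and one line per internal typed edge; isolated module nodes appear as
single-member lines.  The NOA file annotates each node with its
category (TF, miRNA or gene, inferred from the out-nodes of the
directed layers), display name and optional description.  The style
sheet maps layer letters to edge colors/arrow shapes.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping, Sequence

from .cluster import Module
from .network import CompositeNetwork, LayerSpec, all_regulators

#: fixed default palette per layer letter (overridable via ``colors=``)
DEFAULT_COLORS = {
    "R": "#D62728", "M": "#9467BD", "H": "#7F7F7F",
    "P": "#1F77B4", "C": "#2CA02C",
}
_FALLBACK_COLORS = ["#8C564B", "#E377C2", "#BCBD22", "#17BECF", "#FF7F0E"]


def node_categories(
    net: CompositeNetwork,
    tf_layer: str = "R",
    mirna_layer: str = "M",
) -> dict[str, str]:
    """TF = out-node of the TF layer, miRNA = out-node of the miRNA
    layer, everything else gene.  miRNA wins on conflicts (naming
    conventions keep the sets disjoint in practice)."""
    regs = all_regulators(net)
    cats = {n: "gene" for n in net.nodes}
    for n in regs.get(tf_layer, ()):  # type: ignore[union-attr]
        cats[n] = "TF"
    for n in regs.get(mirna_layer, ()):
        cats[n] = "miRNA"
    return cats


def write_nnf(
    modules: Sequence[Module], net: CompositeNetwork, path
) -> None:
    """One line per internal edge ``module<TAB>source<TAB>letter<TAB>target``;
    module nodes without surviving internal edges become single-member
    lines.  Output order is deterministic."""
    if not modules:
        raise ValueError("no modules to export")
    lines = []
    for m in sorted(modules, key=lambda m: m.name):
        edged = set()
        for u, v, letter, _directed in sorted(m.internal_edges):
            lines.append(f"{m.name}\t{u}\t{letter}\t{v}")
            edged |= {u, v}
        for n in sorted(m.nodes - edged):
            lines.append(f"{m.name}\t{n}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_noa(
    modules: Sequence[Module],
    net: CompositeNetwork,
    path,
    names: Mapping[str, str] | None = None,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Node attributes for every module node: category, name, description."""
    cats = node_categories(net)
    nodes = sorted(set().union(*(m.nodes for m in modules)) if modules else set())
    with open(path, "w") as fh:
        fh.write("node\tcategory\tname\tdescription\n")
        for n in nodes:
            name = (names or {}).get(n, n)
            desc = (descriptions or {}).get(n, "")
            fh.write(f"{n}\t{cats.get(n, 'gene')}\t{name}\t{desc}\n")


def write_style_xml(
    layer_specs: Sequence[LayerSpec],
    path,
    colors: Mapping[str, str] | None = None,
) -> None:
    """Cytoscape vizmap-style sheet: one edge color/arrow mapping per
    layer letter and node shapes per category; well-formed XML."""
    palette = dict(DEFAULT_COLORS)
    palette.update(colors or {})
    fallback = iter(_FALLBACK_COLORS)
    root = ET.Element("vizmap", attrib={"documentVersion": "3.0"})
    style = ET.SubElement(root, "visualStyle", attrib={"name": "motifmod"})
    edge = ET.SubElement(style, "edge")
    paint = ET.SubElement(
        edge, "discreteMapping",
        attrib={"attributeName": "interaction",
                "visualProperty": "EDGE_STROKE_UNSELECTED_PAINT"},
    )
    arrow = ET.SubElement(
        edge, "discreteMapping",
        attrib={"attributeName": "interaction",
                "visualProperty": "EDGE_TARGET_ARROW_SHAPE"},
    )
    for spec in layer_specs:
        color = palette.get(spec.letter) or next(fallback)
        ET.SubElement(
            paint, "discreteMappingEntry",
            attrib={"attributeValue": spec.letter, "value": color},
        )
        ET.SubElement(
            arrow, "discreteMappingEntry",
            attrib={"attributeValue": spec.letter,
                    "value": "DELTA" if spec.directed else "NONE"},
        )
    node = ET.SubElement(style, "node")
    shape = ET.SubElement(
        node, "discreteMapping",
        attrib={"attributeName": "category",
                "visualProperty": "NODE_SHAPE"},
    )
    for category, value in (
        ("TF", "TRIANGLE"), ("miRNA", "DIAMOND"), ("gene", "ELLIPSE")
    ):
        ET.SubElement(
            shape, "discreteMappingEntry",
            attrib={"attributeValue": category, "value": value},
        )
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_nnf(path) -> dict[str, dict]:
    """Parse an NNF file back into {module: {nodes, edges}} (round-trip
    support)."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            entry = out.setdefault(parts[0], {"nodes": set(), "edges": set()})
            if len(parts) == 2:
                entry["nodes"].add(parts[1])
            elif len(parts) == 4:
                u, letter, v = parts[1:4]
                entry["edges"].add((u, letter, v))
                entry["nodes"] |= {u, v}
    return out
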