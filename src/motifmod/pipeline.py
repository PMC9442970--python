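"""End-to-end orchestration: enumerate → cluster → filter → statistics.

The pipeline is deterministic under a fixed seed and fixed inputs; a
manifest of parameters and seeds is written next to every run.  The
per-module stages (superview, enrichment) can fan out over processes
via joblib, which does not change results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cluster import ClusteringParams, Module, cluster_pool
from .enrichment import AnnotationSet, background_genes, enrich_modules
from .export import write_nnf, write_noa, write_style_xml
from .motifs import POOLS, count_by_code, count_by_type, enumerate_instances, write_instances
from .network import CompositeNetwork, LayerSpec, load_composite_network
from .superview import regulator_strength_table, superview_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    layers: list[LayerSpec] = field(default_factory=list)
    code_blacklist: set[str] = field(default_factory=set)
    pools: Sequence[str] = POOLS
    min_size: int = 5
    max_size: int = 50
    max_homology_fraction: float = 0.9
    homology_letter: str = "H"
    B: int = 1000
    seed: int = 0
    cores: int = 1
    background: str = "network"
    annotation_path: str | None = None
    obo_path: str | None = None
    background_file: str | None = None
    outdir: str = "motifmod_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        layers = [
            LayerSpec(d["letter"], bool(d["directed"]), d.get("path"))
            for d in raw.pop("layers", [])
        ]
        blacklist = set(raw.pop("code_blacklist", []) or [])
        return cls(layers=layers, code_blacklist=blacklist, **raw)


def derive_modules(
    net: CompositeNetwork,
    cfg: PipelineConfig,
    pools: Sequence[str] | None = None,
) -> dict[str, list[Module]]:
    """Enumerate instances once, then cluster and filter every pool."""
    instances = enumerate_instances(net)
    if cfg.code_blacklist:
        instances = [i for i in instances if i.code not in cfg.code_blacklist]
    params = ClusteringParams(seed=cfg.seed)
    out: dict[str, list[Module]] = {}
    for pool in pools or cfg.pools:
        out[pool] = cluster_pool(
            instances, net, pool, params,
            min_size=cfg.min_size, max_size=cfg.max_size,
            max_homology_fraction=cfg.max_homology_fraction,
            homology_letter=cfg.homology_letter,
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the static stages and write all artifacts to the output
    directory; a failing stage halts with partial outputs retained."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    net = load_composite_network(cfg.layers)
    net.summary().to_csv(out / "network_summary.tsv", sep="\t", index=False)

    instances = enumerate_instances(net)
    if cfg.code_blacklist:
        instances = [i for i in instances if i.code not in cfg.code_blacklist]
    write_instances(instances, out / "subgraphs.tsv")
    pd.Series(count_by_code(instances)).sort_index().to_csv(
        out / "subgraph_code_counts.tsv", sep="\t", header=["count"]
    )
    pd.Series(count_by_type(instances)).sort_index().to_csv(
        out / "subgraph_type_counts.tsv", sep="\t", header=["count"]
    )

    params = ClusteringParams(seed=cfg.seed)
    modules_by_pool: dict[str, list[Module]] = {}
    for pool in cfg.pools:
        modules_by_pool[pool] = cluster_pool(
            instances, net, pool, params,
            min_size=cfg.min_size, max_size=cfg.max_size,
            max_homology_fraction=cfg.max_homology_fraction,
            homology_letter=cfg.homology_letter,
        )
    with open(out / "modules.tsv", "w") as fh:
        for pool in cfg.pools:
            for m in modules_by_pool[pool]:
                for n in sorted(m.nodes):
                    fh.write(f"{m.name}\t{n}\n")
    with open(out / "module_subgraphs.tsv", "w") as fh:
        for pool in cfg.pools:
            for m in modules_by_pool[pool]:
                for sg in m.subgraphs:
                    fh.write(f"{m.name}\t{sg.code}\t{','.join(sg.nodes)}\n")

    for pool in cfg.pools:
        mods = modules_by_pool[pool]
        if len(mods) >= 2:
            sv = superview_table(mods, net, B=cfg.B, seed=cfg.seed)
            sv.to_csv(out / f"superview_{pool}.tsv", sep="\t", index=False)
    all_modules = [m for pool in cfg.pools for m in modules_by_pool[pool]]
    if all_modules:
        regulator_strength_table(all_modules, net).to_csv(
            out / "regulator_strength.tsv", sep="\t", index=False
        )

    if cfg.annotation_path:
        ann = AnnotationSet.from_table(cfg.annotation_path)
        if cfg.obo_path:
            ann = ann.with_ontology(cfg.obo_path)
        bg = background_genes(
            cfg.background, modules=all_modules,
            network_nodes=net.nodes, user_file=cfg.background_file,
        )
        enrich_modules(all_modules, ann, bg).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )

    if all_modules:
        write_nnf(all_modules, net, out / "modules.nnf")
        write_noa(all_modules, net, out / "modules.noa")
    write_style_xml(cfg.layers, out / "style.xml")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "B": cfg.B,
        "pools": list(cfg.pools),
        "filters": {
            "min_size": cfg.min_size, "max_size": cfg.max_size,
            "max_homology_fraction": cfg.max_homology_fraction,
        },
        "layers": [
            {"letter": s.letter, "directed": s.directed, "path": str(s.path)}
            for s in cfg.layers
        ],
        "n_instances": len(instances),
        "n_modules": {pool: len(modules_by_pool[pool]) for pool in cfg.pools},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
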