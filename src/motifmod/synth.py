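"""Synthetic multi-layer networks with planted topological modules.

The generator plants dense subgraph communities of chosen topological
types (COM: undirected cliques-at-density; COR: a regulator fanning out
over interacting targets; FFL: a two-regulator cascade over shared
targets), sprinkles uniform background edges per layer, and emits
matching expression matrices in which module genes share a latent
factor and "active" modules gain a condition mean shift.  Every stage
of the pipeline is thereby testable without external downloads.

The expression model is a latent-factor Gaussian — a deliberate
stand-in that exercises correlation- and p-value-based scores, not a
claim about real transcriptomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Module, internal_edges_of
from .network import CompositeNetwork, LayerSpec

DEFAULT_LAYERS = (
    LayerSpec("R", True),
    LayerSpec("M", True),
    LayerSpec("H", False),
    LayerSpec("P", False),
    LayerSpec("C", False),
)


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults follow the planted-recovery setting used throughout the
    test suite: 10 modules of sizes 6–12, intra-module subgraph density
    0.8, background edge rate 0.02 per undirected layer.
    """

    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    modules_per_type: dict = field(
        default_factory=lambda: {"COM": 5, "COR": 3, "FFL": 2}
    )
    size_range: tuple[int, int] = (6, 12)
    intra_density: float = 0.8
    background_density: dict = field(
        default_factory=lambda: {"P": 0.02, "C": 0.02, "H": 0.005, "R": 0.002, "M": 0.002}
    )
    n_background_nodes: int = 30
    n_regulators: int = 10
    samples_per_condition: int = 10
    correlation_strength: float = 0.8
    effect_size: float = 2.0
    n_active_modules: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (5 <= lo <= hi <= 50):
            raise ValueError("planted module sizes must stay within [5, 50]")
        if not 0 <= self.intra_density <= 1:
            raise ValueError("intra_density must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground-truth membership of the planted modules."""

    modules: dict[str, dict]  # name -> {"type", "nodes", "regulators"}
    active: list[str]

    def as_module_list(self, net: CompositeNetwork) -> list[Module]:
        out = []
        for name, info in self.modules.items():
            nodes = set(info["nodes"])
            out.append(
                Module(name, info["type"], nodes, [], internal_edges_of(nodes, net))
            )
        return out


def _plant_com(net, nodes, density, rng, letter="P"):
    for u, v in combinations(nodes, 2):
        if rng.random() < density:
            net.add_edge(u, v, letter)


def _plant_cor(net, regulator, targets, density, rng):
    for t in targets:
        net.add_edge(regulator, t, "R")
    for u, v in combinations(targets, 2):
        if rng.random() < density:
            net.add_edge(u, v, "P")


def _plant_ffl(net, r1, r2, targets, density, rng):
    net.add_edge(r1, r2, "R")
    for t in targets:
        if rng.random() < density:
            net.add_edge(r1, t, "R")
            net.add_edge(r2, t, "R")


def generate_composite_network(
    cfg: FixtureConfig,
) -> tuple[CompositeNetwork, PlantedTruth]:
    """Planted-module composite network plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    net = CompositeNetwork(layers=list(cfg.layers))
    truth_modules: dict[str, dict] = {}
    gene_counter = 0
    reg_pool = [f"tf{k:03d}" for k in range(cfg.n_regulators)]
    reg_cursor = 0

    def next_genes(k: int) -> list[str]:
        nonlocal gene_counter
        out = [f"g{gene_counter + i:04d}" for i in range(k)]
        gene_counter += k
        return out

    def next_regs(k: int) -> list[str]:
        nonlocal reg_cursor
        if reg_cursor + k > len(reg_pool):
            raise ValueError("not enough designated regulators for the plan")
        out = reg_pool[reg_cursor:reg_cursor + k]
        reg_cursor += k
        return out

    idx = 0
    for topo, count in cfg.modules_per_type.items():
        for _ in range(count):
            idx += 1
            size = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
            name = f"planted_{idx}"
            if topo == "COM":
                nodes = next_genes(size)
                _plant_com(net, nodes, cfg.intra_density, rng)
                truth_modules[name] = {"type": "COM", "nodes": nodes, "regulators": []}
            elif topo == "COR":
                (reg,) = next_regs(1)
                targets = next_genes(size - 1)
                _plant_cor(net, reg, targets, cfg.intra_density, rng)
                truth_modules[name] = {
                    "type": "COR", "nodes": [reg] + targets, "regulators": [reg]
                }
            elif topo == "FFL":
                r1, r2 = next_regs(2)
                targets = next_genes(size - 2)
                _plant_ffl(net, r1, r2, targets, cfg.intra_density, rng)
                truth_modules[name] = {
                    "type": "FFL", "nodes": [r1, r2] + targets,
                    "regulators": [r1, r2],
                }
            else:
                raise ValueError(f"unsupported planted type {topo!r}")
    # background nodes and uniform background edges
    bg_nodes = next_genes(cfg.n_background_nodes)
    net.nodes.update(bg_nodes)
    all_nodes = sorted(net.nodes)
    unused_regs = reg_pool[reg_cursor:]
    net.nodes.update(unused_regs)
    for spec in cfg.layers:
        rate = cfg.background_density.get(spec.letter, 0.0)
        if rate <= 0:
            continue
        if spec.directed:
            sources = reg_pool
            for s in sources:
                for t in all_nodes:
                    if t != s and rng.random() < rate:
                        net.add_edge(s, t, spec.letter)
        else:
            for u, v in combinations(all_nodes, 2):
                if rng.random() < rate:
                    net.add_edge(u, v, spec.letter)
    active = sorted(truth_modules)[: cfg.n_active_modules]
    return net, PlantedTruth(truth_modules, active)


def generate_expression(
    truth: PlantedTruth,
    net: CompositeNetwork,
    cfg: FixtureConfig,
) -> tuple["ExpressionMatrix", dict[str, dict[str, float]]]:  # noqa: F821
    """Module-correlated expression plus per-gene differential p-values.

    Genes of one module share a latent factor with weight
    √correlation_strength; genes of the modules listed as active are
    mean-shifted by ``effect_size`` standard deviations in the case
    condition.  p-values come from a per-gene two-sample t-test, so
    activity-score recovery is testable end to end.
    """
    from .context import ExpressionMatrix

    rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(net.nodes)
    n_case = n_ctrl = cfg.samples_per_condition
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_ctrl)
    ]
    n_samp = len(samples)
    rho = cfg.correlation_strength
    factors = {
        name: rng.normal(size=n_samp) for name in sorted(truth.modules)
    }
    first_module = {}
    for name in sorted(truth.modules):
        for g in truth.modules[name]["nodes"]:
            first_module.setdefault(g, name)
    values = np.empty((len(genes), n_samp))
    for i, g in enumerate(genes):
        noise = rng.normal(size=n_samp)
        m = first_module.get(g)
        if m is None:
            values[i] = noise
        else:
            values[i] = np.sqrt(rho) * factors[m] + np.sqrt(1 - rho) * noise
            if m in truth.active:
                values[i, :n_case] += cfg.effect_size
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples),
    )
    tt = stats.ttest_ind(values[:, :n_case], values[:, n_case:], axis=1)
    pvals = {"case_vs_control": dict(zip(genes, tt.pvalue))}
    return expr, pvals


def write_fixture(
    net: CompositeNetwork, truth: PlantedTruth, outdir
) -> None:
    """Write the TSV dialects the pipeline reads plus a truth JSON."""
    import json
    from pathlib import Path

    from .network import write_composite_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_composite_file(net, outdir / "composite.tsv")
    for spec in net.layers:
        with open(outdir / f"layer_{spec.letter}.tsv", "w") as fh:
            for u, v in sorted(net.edges[spec.letter]):
                fh.write(f"{u}\t{v}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {"modules": truth.modules, "active": truth.active}, fh, indent=1
        )
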