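"""Module–module and regulator–module connectivity statistics.

For every module pair and layer the observed number of crossing edges
is compared with a sampling null: 1000 draws of two disjoint uniform
node sets of the same sizes.  The z-score (x − μ)/σ is converted to a
right-tail p-value with the standard normal CDF; pairs with no crossing
edges are fixed at (z, p) = (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Module
from .network import CompositeNetwork

#: z surrogate when the null is degenerate (σ = 0) but x exceeds μ
Z_CAP = 1e6


@dataclass(frozen=True)
class SuperviewRecord:
    module_a: str
    module_b: str
    layer: str
    x: int
    mu: float
    sigma: float
    z: float
    p: float


def count_shared_edges(
    a: Module | set, b: Module | set, net: CompositeNetwork, layer: str
) -> int:
    """Layer edges with one endpoint in each module (directions pooled).

    An edge counts once regardless of direction; edges whose endpoints
    both lie in the module intersection count once as well (inclusive
    convention for overlapping modules).
    """
    na = a.nodes if isinstance(a, Module) else a
    nb = b.nodes if isinstance(b, Module) else b
    return sum(
        1
        for u, v in net.edges[layer]
        if (u in na and v in nb) or (u in nb and v in na)
    )


class _LayerIndex:
    """Vectorized crossing-edge counting for repeated null draws."""

    def __init__(self, net: CompositeNetwork):
        self.nodes = sorted(net.nodes)
        self.index = {n: k for k, n in enumerate(self.nodes)}
        self.edges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for spec in net.layers:
            es = sorted(net.edges[spec.letter])
            u = np.array([self.index[e[0]] for e in es], dtype=np.int64)
            v = np.array([self.index[e[1]] for e in es], dtype=np.int64)
            self.edges[spec.letter] = (u, v)

    def crossing_counts(
        self, sets_a: np.ndarray, sets_b: np.ndarray, layer: str
    ) -> np.ndarray:
        """Counts for B (mask_a, mask_b) pairs; masks are (B, n) booleans."""
        u, v = self.edges[layer]
        if len(u) == 0:
            return np.zeros(sets_a.shape[0], dtype=np.int64)
        au, av = sets_a[:, u], sets_a[:, v]
        bu, bv = sets_b[:, u], sets_b[:, v]
        return np.sum((au & bv) | (bu & av), axis=1)


def superview_null(
    size_a: int,
    size_b: int,
    net: CompositeNetwork,
    layer: str,
    B: int = 1000,
    seed: int = 0,
    index: _LayerIndex | None = None,
) -> tuple[float, float]:
    """Null moments of the crossing count for two disjoint uniform node
    sets of the given sizes."""
    index = index or _LayerIndex(net)
    n = len(index.nodes)
    if size_a + size_b > n:
        raise ValueError("module sizes exceed the node universe")
    rng = np.random.default_rng(seed)
    mask_a = np.zeros((B, n), dtype=bool)
    mask_b = np.zeros((B, n), dtype=bool)
    for t in range(B):
        pick = rng.choice(n, size=size_a + size_b, replace=False)
        mask_a[t, pick[:size_a]] = True
        mask_b[t, pick[size_a:]] = True
    counts = index.crossing_counts(mask_a, mask_b, layer)
    return float(np.mean(counts)), float(np.std(counts))


def superview_score(x: int, mu: float, sigma: float) -> tuple[float, float]:
    """(z, p) under the sampling null; x = 0 forces (0, 1)."""
    if x == 0:
        return 0.0, 1.0
    if sigma == 0:
        z = 0.0 if x == mu else (Z_CAP if x > mu else -Z_CAP)
    else:
        z = (x - mu) / sigma
    return z, float(stats.norm.sf(z))


def superview_table(
    modules: Sequence[Module],
    net: CompositeNetwork,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All unordered module pairs × layers, with null moments cached per
    (size_a, size_b) pair so each distinct geometry is sampled once."""
    index = _LayerIndex(net)
    null_cache: dict[tuple[int, int, str], tuple[float, float]] = {}
    rows = []
    for i in range(len(modules)):
        for j in range(i + 1, len(modules)):
            a, b = modules[i], modules[j]
            sa, sb = sorted((len(a.nodes), len(b.nodes)))
            for letter in net.letters:
                key = (sa, sb, letter)
                if key not in null_cache:
                    null_cache[key] = superview_null(
                        sa, sb, net, letter, B=B,
                        seed=seed + 7919 * len(null_cache), index=index,
                    )
                mu, sigma = null_cache[key]
                x = count_shared_edges(a, b, net, letter)
                z, p = superview_score(x, mu, sigma)
                rows.append(
                    SuperviewRecord(a.name, b.name, letter, x, mu, sigma, z, p)
                )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# regulator statistics
# ---------------------------------------------------------------------------

def regulator_module_strength(
    regulator: str, module: Module, net: CompositeNetwork, layer: str
) -> float:
    """Fraction of module nodes receiving a layer edge from the regulator."""
    if not net.layer(layer).directed:
        raise ValueError(f"layer {layer} is undirected")
    if not module.nodes:
        raise ValueError(f"module {module.name} is empty")
    targets = {v for u, v in net.edges[layer] if u == regulator}
    return len(targets & module.nodes) / len(module.nodes)


def module_regulator_specificity(
    module: Module, all_regs: Mapping[str, set], net: CompositeNetwork
) -> float:
    """(regulators with ≥1 edge into the module) / (all regulators).

    Regulators that are themselves module members still count when they
    target a co-member.
    """
    total = sum(len(r) for r in all_regs.values())
    if total == 0:
        raise ValueError("empty regulator universe")
    hitting = set()
    for layer, regs in all_regs.items():
        for u, v in net.edges[layer]:
            if u in regs and v in module.nodes:
                hitting.add(u)
    return len(hitting) / total


def regulator_specificity(
    regulator: str, modules: Sequence[Module], net: CompositeNetwork,
    layers: Iterable[str] | None = None,
) -> float:
    """Fraction of modules receiving ≥1 edge from the regulator."""
    if not modules:
        raise ValueError("empty module list")
    layers = list(layers) if layers is not None else sorted(net.directed_letters)
    targets = {
        v for l in layers for u, v in net.edges[l] if u == regulator
    }
    hit = sum(1 for m in modules if targets & m.nodes)
    return hit / len(modules)


def regulator_strength_table(
    modules: Sequence[Module], net: CompositeNetwork
) -> pd.DataFrame:
    """Strength per (regulator, module, layer), nonzero rows only."""
    rows = []
    for layer in sorted(net.directed_letters):
        by_reg: dict[str, set] = {}
        for u, v in net.edges[layer]:
            by_reg.setdefault(u, set()).add(v)
        for m in modules:
            for reg, targets in sorted(by_reg.items()):
                k = len(targets & m.nodes)
                if k:
                    rows.append(
                        {"regulator": reg, "module": m.name, "layer": layer,
                         "strength": k / len(m.nodes)}
                    )
    return pd.DataFrame(rows, columns=["regulator", "module", "layer", "strength"])


# ---------------------------------------------------------------------------
# module-set statistics
# ---------------------------------------------------------------------------

def connectivity_ci(mean: float, sd: float, B: int) -> tuple[float, float]:
    """95% CI on the mean of the random-set distribution."""
    half = 1.96 * sd / np.sqrt(B)
    return mean - half, mean + half


def module_set_connectivity_test(
    selected: set[str],
    superview: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed within-set superview edge counts per layer and in total,
    versus B random same-size module sets.

    Returns one row per layer plus a Total row with columns observed,
    random_mean, random_sd, ci_low, ci_high and fold_change =
    observed / ci_high (infinite fold changes are flagged as inf).
    """
    all_modules = sorted(set(superview.module_a) | set(superview.module_b))
    if not selected <= set(all_modules):
        raise ValueError("selected modules missing from the superview table")
    if len(selected) < 2:
        raise ValueError("need at least two selected modules")
    layers = sorted(superview.layer.unique())
    mod_index = {m: k for k, m in enumerate(all_modules)}
    # per-layer pair count matrix lookup
    pair_x = {
        layer: {} for layer in layers
    }
    for row in superview.itertuples(index=False):
        pair_x[row.layer][(mod_index[row.module_a], mod_index[row.module_b])] = row.x

    def set_counts(members: set[int]) -> dict[str, int]:
        out = {}
        for layer in layers:
            out[layer] = sum(
                x for (i, j), x in pair_x[layer].items()
                if i in members and j in members
            )
        return out

    sel_idx = {mod_index[m] for m in selected}
    observed = set_counts(sel_idx)
    rng = np.random.default_rng(seed)
    draws = {layer: np.empty(B) for layer in layers}
    for t in range(B):
        members = set(rng.choice(len(all_modules), size=len(selected), replace=False))
        counts = set_counts(members)
        for layer in layers:
            draws[layer][t] = counts[layer]
    rows = []
    tot_draws = np.sum([draws[layer] for layer in layers], axis=0)
    for layer in layers + ["Total"]:
        if layer == "Total":
            obs = sum(observed.values())
            d = tot_draws
        else:
            obs = observed[layer]
            d = draws[layer]
        mean, sd = float(np.mean(d)), float(np.std(d))
        lo, hi = connectivity_ci(mean, sd, B)
        fold = obs / hi if hi > 0 else float("inf")
        rows.append(
            {"layer": layer, "observed": obs, "random_mean": mean,
             "random_sd": sd, "ci_low": lo, "ci_high": hi, "fold_change": fold}
        )
    return pd.DataFrame(rows)


def de_gene_set_enrichment(
    selected_modules: Sequence[Module],
    all_modules: Sequence[Module],
    de_genes: set[str],
) -> tuple[float, float]:
    """Over-representation of differentially expressed genes inside the
    selected module set versus genes of all other modules.

    Returns (fold_change, one-sided hypergeometric p).
    """
    if not de_genes:
        raise ValueError("empty DE gene set")
    sel_names = {m.name for m in selected_modules}
    in_genes = set().union(*(m.nodes for m in selected_modules))
    out_genes = set().union(
        *(m.nodes for m in all_modules if m.name not in sel_names)
    ) - in_genes
    n_in, n_out = len(in_genes), len(out_genes)
    k_in = len(in_genes & de_genes)
    k_out = len(out_genes & de_genes)
    N = n_in + n_out
    K = k_in + k_out
    p = float(stats.hypergeom.sf(k_in - 1, N, K, n_in))
    if n_out == 0 or k_out == 0:
        return float("inf") if k_in else 1.0, p
    fold = (k_in / n_in) / (k_out / n_out)
    return fold, p
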