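"""Expression overlay: co-expression, differential correlation, activity.

Three per-module scores contextualize static modules with expression
data, each standardized against 1000 size-matched random gene sets:

* **nPCC** — mean pairwise Pearson correlation over module genes.
* **ECD**  — expression correlation differential: mean over internal
  module edges of PCC(condition) − PCC(control); bounded in [−2, 2].
* **activity score s_a** — per-gene p-values are mapped to z-scores via
  the inverse normal CDF of 1 − p, summed and scaled by 1/√k (Stouffer
  aggregation), then standardized by the moments (μ_k, σ_k) of random
  size-k gene sets.  High s_a flags condition-active modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Module

P_CLAMP = 1e-16  # guards Φ⁻¹ against p = 0 / p = 1 exports


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with condition labels."""

    values: pd.DataFrame  # index = genes, columns = samples
    conditions: pd.Series  # index = samples, value = condition label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene rows in expression matrix")
        self.conditions = self.conditions.reindex(self.values.columns)

    @classmethod
    def from_tsv(cls, expr_path, sheet_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path, sep="\t", index_col=0)
        return cls(values, sheet.iloc[:, 0])

    def subset(self, condition: str) -> pd.DataFrame:
        cols = self.conditions[self.conditions == condition].index
        return self.values[cols]

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)


def _mean_pairwise_pcc(mat: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation of rows (≥2 rows)."""
    c = np.corrcoef(mat)
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def _edge_coverage(module: Module, genes: set[str]) -> float:
    """Fraction of internal module edges with expression for both ends."""
    if not module.internal_edges:
        return 0.0
    ok = sum(
        1 for u, v, *_ in module.internal_edges if u in genes and v in genes
    )
    return ok / len(module.internal_edges)


def npcc(
    module: Module,
    expr: ExpressionMatrix,
    B: int = 1000,
    seed: int = 0,
    _null_cache: dict | None = None,
) -> dict:
    """Module co-expression versus size-matched random gene sets.

    Returns npcc, z, right-tail p and edge-wise coverage; NA scores when
    fewer than two module genes have expression.
    """
    have = sorted(module.nodes & expr.genes)
    coverage = _edge_coverage(module, expr.genes)
    if len(have) < 2 or expr.values.shape[1] < 3:
        return {"npcc": np.nan, "npcc_z": np.nan, "npcc_p": np.nan,
                "coverage": coverage, "k": len(have)}
    mat = expr.values.loc[have].to_numpy()
    value = _mean_pairwise_pcc(mat)
    k = len(have)
    cache_key = ("npcc", k)
    if _null_cache is not None and cache_key in _null_cache:
        mu, sigma = _null_cache[cache_key]
    else:
        rng = np.random.default_rng(seed)
        pool = expr.values.to_numpy()
        draws = np.empty(B)
        for t in range(B):
            idx = rng.choice(pool.shape[0], size=k, replace=False)
            draws[t] = _mean_pairwise_pcc(pool[idx])
        mu, sigma = float(np.mean(draws)), float(np.std(draws))
        if _null_cache is not None:
            _null_cache[cache_key] = (mu, sigma)
    z = 0.0 if sigma == 0 else (value - mu) / sigma
    return {"npcc": value, "npcc_z": z, "npcc_p": float(stats.norm.sf(z)),
            "coverage": coverage, "k": k}


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(a, b)[0, 1]
    return float(r) if np.isfinite(r) else np.nan


def ecd(
    module: Module,
    expr_condition: pd.DataFrame,
    expr_control: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Differential correlation over internal module edges.

    Per qualifying edge: PCC in condition samples minus PCC in control
    samples; the module score is the mean over edges.  The null draws B
    random gene sets of the same size and scores the same number of
    random gene pairs inside each.
    """
    genes = set(expr_condition.index) & set(expr_control.index)
    edges = [
        (u, v) for u, v, *_ in module.internal_edges if u in genes and v in genes
    ]
    if not edges:
        return {"ecd": np.nan, "ecd_z": np.nan, "ecd_p": np.nan, "n_edges": 0}

    cond = expr_condition.loc[sorted(genes)]
    ctrl = expr_control.loc[sorted(genes)]
    gene_idx = {g: i for i, g in enumerate(cond.index)}
    cm, km = cond.to_numpy(), ctrl.to_numpy()

    def edge_mean(pairs: Sequence[tuple[int, int]]) -> float:
        deltas = [
            _pcc(cm[i], cm[j]) - _pcc(km[i], km[j]) for i, j in pairs
        ]
        deltas = [d for d in deltas if np.isfinite(d)]
        return float(np.mean(deltas)) if deltas else np.nan

    value = edge_mean([(gene_idx[u], gene_idx[v]) for u, v in edges])
    size = len(module.nodes & genes)
    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    n_genes = cm.shape[0]
    for t in range(B):
        members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
        pairs = [
            tuple(rng.choice(members, size=2, replace=False))
            for _ in range(len(edges))
        ]
        draws[t] = edge_mean(pairs)
    draws = draws[np.isfinite(draws)]
    mu, sigma = float(np.mean(draws)), float(np.std(draws))
    z = 0.0 if sigma == 0 else (value - mu) / sigma
    return {"ecd": value, "ecd_z": z, "ecd_p": float(stats.norm.sf(z)),
            "n_edges": len(edges)}


def activity_score(
    module: Module,
    gene_pvalues: Mapping[str, float],
    B: int = 1000,
    seed: int = 0,
    _null_cache: dict | None = None,
) -> dict:
    """Normalized module activity s_a for one contrast.

    z_i = Φ⁻¹(1 − p_i) per module gene with a p-value (clamped away from
    0 and 1), z_a = Σ z_i / √k, and s_a = (z_a − μ_k)/σ_k against B
    random size-k gene sets drawn from all genes with p-values.
    """
    if _null_cache is not None and "z_by_gene" in _null_cache:
        z_all = _null_cache["z_by_gene"]
    else:
        genes = sorted(gene_pvalues)
        p_arr = np.clip(
            np.array([gene_pvalues[g] for g in genes]), P_CLAMP, 1 - P_CLAMP
        )
        z_all = dict(zip(genes, stats.norm.ppf(1 - p_arr)))
        if _null_cache is not None:
            _null_cache["z_by_gene"] = z_all
    have = sorted(module.nodes & z_all.keys())
    k = len(have)
    if k == 0:
        return {"s_a": np.nan, "z_a": np.nan, "k": 0}
    z_a = sum(z_all[g] for g in have) / np.sqrt(k)
    cache_key = ("sa", k)
    if _null_cache is not None and cache_key in _null_cache:
        mu, sigma = _null_cache[cache_key]
    else:
        rng = np.random.default_rng(seed)
        zv = np.array([z_all[g] for g in sorted(z_all)])
        draws = np.empty(B)
        for t in range(B):
            picks = rng.choice(len(zv), size=k, replace=False)
            draws[t] = zv[picks].sum()
        draws /= np.sqrt(k)
        mu, sigma = float(np.mean(draws)), float(np.std(draws))
        if _null_cache is not None:
            _null_cache[cache_key] = (mu, sigma)
    s_a = 0.0 if sigma == 0 else (z_a - mu) / sigma
    return {"s_a": float(s_a), "z_a": float(z_a), "k": k}


def context_scores(
    modules: Sequence[Module],
    expr: ExpressionMatrix | None = None,
    pvalue_tables: Mapping[str, Mapping[str, float]] | None = None,
    condition_pairs: Mapping[str, tuple[str, str]] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per module: nPCC (+ z, p, coverage), ECD per condition
    pair, and s_a per contrast.  Background moments are cached per
    distinct module size, so they are a pure function of (data, seed)."""
    caches: dict[str, dict] = {}
    rows = []
    for m in modules:
        row: dict = {"module": m.name}
        if expr is not None:
            row.update(
                npcc(m, expr, B=B, seed=seed,
                     _null_cache=caches.setdefault("npcc", {}))
            )
            for label, (cond, ctrl) in (condition_pairs or {}).items():
                res = ecd(
                    m, expr.subset(cond), expr.subset(ctrl), B=B, seed=seed
                )
                row.update({f"{key}_{label}": v for key, v in res.items()})
        for contrast, table in (pvalue_tables or {}).items():
            res = activity_score(
                m, table, B=B, seed=seed,
                _null_cache=caches.setdefault(f"sa:{contrast}", {}),
            )
            row[f"s_a_{contrast}"] = res["s_a"]
            row[f"k_{contrast}"] = res["k"]
        rows.append(row)
    return pd.DataFrame(rows)


def select_active_modules(
    scores: pd.DataFrame, contrasts: Sequence[str]
) -> set[str]:
    """Modules with s_a > 0 in every listed contrast."""
    cols = [f"s_a_{c}" for c in contrasts]
    mask = np.ones(len(scores), dtype=bool)
    for c in cols:
        mask &= scores[c].to_numpy() > 0
    return set(scores.loc[mask, "module"])


def load_pvalue_table(path) -> dict[str, dict[str, float]]:
    """gene<TAB>contrast<TAB>p TSV → {contrast: {gene: p}}."""
    df = pd.read_csv(path, sep="\t", names=["gene", "contrast", "p"], header=0)
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.contrast, {})[row.gene] = float(row.p)
    return out
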