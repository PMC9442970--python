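"""Per-module GO over-representation analysis.

One-sided hypergeometric tests per GO term against a configurable gene
background, Benjamini–Hochberg correction within each module, a 1-based
rank over ascending adjusted p-values, and a log2 fold-change
log2((k/n)/(K/N)) per retained term.  Annotations can optionally be
propagated to ancestor terms along ``is_a`` links of an OBO ontology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationSet:
    """Gene→GO-term mapping with optional term names and parent links."""

    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str]
    parents: dict[str, set[str]] | None = None

    @classmethod
    def from_table(
        cls, path: str | Path, term_names: Mapping[str, str] | None = None
    ) -> "AnnotationSet":
        """Two-column gene<TAB>term TSV (extra columns ignored)."""
        gene_to_terms: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or line.startswith("#"):
                    continue
                gene_to_terms.setdefault(parts[0], set()).add(parts[1])
        return cls(gene_to_terms, dict(term_names or {}))

    def with_ontology(self, obo_path: str | Path) -> "AnnotationSet":
        """Propagate annotations to all ``is_a`` ancestors of each term."""
        import obonet

        graph = obonet.read_obo(obo_path)
        parents = {
            t: {v for _u, v, key in graph.out_edges(t, keys=True) if key == "is_a"}
            for t in graph.nodes
        }
        names = {t: d.get("name", t) for t, d in graph.nodes(data=True)}
        anc_cache: dict[str, set[str]] = {}

        def ancestors(t: str) -> set[str]:
            if t not in anc_cache:
                anc_cache[t] = set()
                for p in parents.get(t, ()):  # noqa: B023
                    anc_cache[t] |= {p} | ancestors(p)
            return anc_cache[t]

        propagated = {
            g: set().union(terms, *(ancestors(t) for t in terms))
            for g, terms in self.gene_to_terms.items()
        }
        merged_names = {**names, **self.term_names}
        return AnnotationSet(propagated, merged_names, parents)

    def term_name(self, term: str) -> str:
        return self.term_names.get(term, term)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_raw, dtype=float), method="fdr_bh")[1]


def log2_fold_change(k: int, n: int, K: int, N: int) -> float:
    """log2 of the study-rate over population-rate ratio, (k/n)/(K/N)."""
    return float(np.log2((k / n) / (K / N)))


ENRICHMENT_COLUMNS = [
    "module", "term", "term_name", "study_count", "study_n",
    "pop_count", "pop_n", "p_raw", "p_adj", "rank", "log2_fc",
]


def enrich_module(
    module_name: str,
    module_genes: set[str],
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.05,
    keep: str = "less",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each annotated term.

    Only terms with at least one study hit are tested; BH correction is
    applied across the module's tested terms and rows with adjusted
    p-value below ``alpha`` are retained (``keep="greater"`` inverts the
    comparator).  Genes outside the annotated background are ignored.
    """
    ann = annotations.gene_to_terms
    bg = {g for g in background if g in ann}
    study = {g for g in module_genes if g in bg}
    if not study:
        import logging

        logging.getLogger(__name__).warning(
            "module %s has no annotated genes in the background", module_name
        )
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for g in bg:
        for t in ann[g]:
            term_pop[t] = term_pop.get(t, 0) + 1
            if g in study:
                term_study[t] = term_study.get(t, 0) + 1
    N, n = len(bg), len(study)
    terms = sorted(term_study)
    p_raw = np.array(
        [stats.hypergeom.sf(term_study[t] - 1, N, term_pop[t], n) for t in terms]
    )
    if len(terms) == 0:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    p_adj = bh_adjust(p_raw)
    rows = []
    for t, pr, pa in zip(terms, p_raw, p_adj):
        k, K = term_study[t], term_pop[t]
        rows.append(
            {
                "module": module_name, "term": t,
                "term_name": annotations.term_name(t),
                "study_count": k, "study_n": n, "pop_count": K, "pop_n": N,
                "p_raw": pr, "p_adj": pa,
                "log2_fc": log2_fold_change(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows)
    mask = df.p_adj < alpha if keep == "less" else df.p_adj > alpha
    df = df[mask].sort_values(["p_adj", "p_raw", "term"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[ENRICHMENT_COLUMNS]


def enrich_modules(
    modules: Sequence,
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment table over a list of Module objects."""
    parts = [
        enrich_module(m.name, m.nodes, annotations, background, alpha=alpha)
        for m in modules
    ]
    if not parts:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def select_modules_by_keyword(
    enrichments: pd.DataFrame, keyword: str
) -> set[str]:
    """Modules with ≥1 retained term whose name contains the keyword
    (case-insensitive)."""
    if enrichments.empty:
        return set()
    hit = enrichments.term_name.str.contains(keyword, case=False, regex=False)
    return set(enrichments.loc[hit, "module"])


def background_genes(
    choice: str,
    modules: Sequence | None = None,
    network_nodes: set[str] | None = None,
    user_file: str | Path | None = None,
) -> set[str]:
    """The three background options: genes of a module pool, all input-
    network genes, or a user file (one gene per line)."""
    if choice == "modules":
        return set().union(*(m.nodes for m in modules)) if modules else set()
    if choice == "network":
        return set(network_nodes or set())
    if choice == "file":
        with open(user_file) as fh:
            return {line.strip() for line in fh if line.strip()}
    raise ValueError(f"unknown background choice {choice!r}")
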