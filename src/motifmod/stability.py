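"""Edge-resampling robustness of module inference.

Fractions 0.1–0.9 of the pooled edge multiset are sampled without
replacement (ten repetitions each), the pipeline is re-run on every
reduced network, and each re-derived module is scored against
ground-truth modules — the full-network modules restricted to the
sampled edges — by its best match under Jaccard index, adjusted Rand
index or adjusted mutual information.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .cluster import Module
from .network import CompositeNetwork


def subsample_edges(
    net: CompositeNetwork, fraction: float, seed: int
) -> CompositeNetwork:
    """Uniform sample of ⌊fraction·total⌋ edges from the pooled multiset
    across layers; layer membership preserved, node set retained."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    pooled = [
        (u, v, spec.letter)
        for spec in net.layers
        for u, v in sorted(net.edges[spec.letter])
    ]
    rng = np.random.default_rng(seed)
    n_keep = int(fraction * len(pooled))
    chosen = rng.choice(len(pooled), size=n_keep, replace=False)
    sub = CompositeNetwork(layers=list(net.layers))
    for k in chosen:
        u, v, letter = pooled[k]
        sub.add_edge(u, v, letter)
    sub.nodes |= net.nodes  # isolated nodes stay in the universe
    return sub


def ground_truth_restriction(
    full_modules: Sequence[Module], sampled: CompositeNetwork
) -> list[Module]:
    """Full-network modules with non-sampled internal edges removed.

    Nodes left without any internal edge are dropped; modules whose edge
    set empties out disappear.  Restriction never re-splits a module.
    """
    sampled_sets = {l: sampled.edges[l] for l in sampled.letters}
    restricted = []
    for m in full_modules:
        kept = [
            (u, v, letter, d)
            for u, v, letter, d in m.internal_edges
            if (u, v) in sampled_sets.get(letter, set())
        ]
        if not kept:
            continue
        nodes = {n for u, v, *_ in kept for n in (u, v)}
        restricted.append(
            Module(m.name, m.topo_type, nodes, m.subgraphs, kept)
        )
    return restricted


def _pair_score(a: set, b: set, universe: list, metric: str) -> float:
    if metric == "JI":
        return len(a & b) / len(a | b) if a | b else 0.0
    la = [1 if n in a else 0 for n in universe]
    lb = [1 if n in b else 0 for n in universe]
    if metric == "ARI":
        return float(adjusted_rand_score(la, lb))
    if metric == "AMI":
        return float(adjusted_mutual_info_score(la, lb))
    raise ValueError(f"unknown metric {metric!r}")


def best_match_scores(
    test_modules: Sequence[Module],
    truth_modules: Sequence[Module],
    metric: str = "JI",
    universe: set | None = None,
) -> pd.DataFrame:
    """Per test module, the maximum score against any truth module.

    ARI/AMI are computed on binary in/out membership labelings over the
    node ``universe`` (default: union of both sides); JI is set-based.
    Returns a frame with one row per test module plus the mean in
    ``df.attrs['mean']``.
    """
    if not test_modules or not truth_modules:
        raise ValueError("both module sets must be nonempty")
    uni = sorted(
        universe
        if universe is not None
        else set().union(*(m.nodes for m in list(test_modules) + list(truth_modules)))
    )
    rows = []
    for tm in test_modules:
        best = max(
            _pair_score(tm.nodes, gt.nodes, uni, metric) for gt in truth_modules
        )
        rows.append({"module": tm.name, "metric": metric, "best_score": best})
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(df.best_score.mean())
    return df


def stability_run(
    net: CompositeNetwork,
    full_modules: Sequence[Module],
    rerun,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    repetitions: int = 10,
    metrics: Sequence[str] = ("JI", "ARI", "AMI"),
    seed: int = 0,
) -> pd.DataFrame:
    """Full harness: per (fraction, repetition) subsample, re-derive
    modules via ``rerun(subnetwork)`` and score against the restricted
    ground truth.  Long-format output ready for box/violin plotting."""
    universe = set(net.nodes)
    rows = []
    for fraction in fractions:
        for rep in range(1, repetitions + 1):
            sub = subsample_edges(net, fraction, seed=seed + rep)
            truth = ground_truth_restriction(full_modules, sub)
            test = rerun(sub)
            if not truth or not test:
                continue
            for metric in metrics:
                scored = best_match_scores(test, truth, metric, universe)
                for r in scored.itertuples(index=False):
                    rows.append(
                        {"fraction": fraction, "repetition": rep,
                         "metric": metric, "module": r.module,
                         "best_score": r.best_score}
                    )
    return pd.DataFrame(rows)


def stability_summary(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean best-match score per (fraction, metric)."""
    return (
        runs.groupby(["fraction", "metric"], as_index=False)["best_score"]
        .mean()
        .rename(columns={"best_score": "mean_best_score"})
    )
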