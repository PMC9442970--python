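# motifmod

Composite-subgraph module inference for multi-layer biological networks.

## The problem

Cellular regulation is not captured by any single interaction type.
Transcription-factor→target edges, miRNA→mRNA repression, protein–protein
interactions, co-functional links and homology relations each describe a
different slice of the same system, and biologically meaningful units —
a co-regulated target set, a feed-forward loop and its downstream complex —
only become visible when those layers are superimposed.  `motifmod`
implements that superposition end to end:

1. **Composite network assembly** — per-layer edge lists (one uppercase
   letter per layer, directed or undirected) merged over a shared node set.
2. **Composite subgraph enumeration** — all non-induced 2- and 3-node
   subgraphs whose edges may come from different layers, encoded by
   canonical letter codes and classified into eight topological types
   (COM, COP, COR, FFL, CIR, FBU, FB2U, 2FB).
3. **Hypergraph clustering** — every subgraph instance becomes a
   hyperedge; a nonlinear spectral iteration extracts clusters that
   maximize the edge-to-node ratio, pooled per topological type and
   over all types jointly (ALL).
4. **Module filtering and naming** — clusters of 5–50 nodes that are not
   dominated (>90%) by homology edges become modules named `<TYPE>_<index>`.
5. **Superview statistics** — per-layer crossing-edge z-scores between
   modules against a random-node-set null, regulator→module connection
   strength and specificity, and module-set connectivity tests.
6. **Annotation and contextualization** — per-module GO
   over-representation (hypergeometric + Benjamini–Hochberg), module
   co-expression (nPCC), differential correlation (ECD) and activity
   scores (s_a) from per-gene p-values.
7. **Stability** — edge-resampling robustness with best-match
   Jaccard/ARI/AMI scoring.
8. **Export** — Cytoscape NNF/NOA files and a style sheet.

See `docs/methods.md` for the formal model and every numeric default.

## Worked example

A transcription factor fanning out over an interacting target set forms
COR (co-regulated) subgraphs; clustering them recovers the regulon as a
single module:

```python
from motifmod.cluster import ClusteringParams, cluster_pool
from motifmod.motifs import count_by_type, enumerate_instances
from motifmod.network import CompositeNetwork, LayerSpec
from motifmod.superview import regulator_module_strength

net = CompositeNetwork(layers=[LayerSpec("R", True), LayerSpec("P", False)])
edges = [
    ("tf1", "g1", "R"), ("tf1", "g2", "R"), ("tf1", "g3", "R"),
    ("tf1", "g4", "R"), ("g1", "g2", "P"), ("g1", "g3", "P"),
    ("g2", "g3", "P"), ("g3", "g4", "P"), ("g2", "g4", "P"),
    ("x1", "x2", "P"),
]
for u, v, letter in edges:
    net.add_edge(u, v, letter)

instances = enumerate_instances(net)
print("subgraph instances by type:", dict(sorted(count_by_type(instances).items())))

modules = cluster_pool(instances, net, "COR", ClusteringParams(seed=0))
for m in modules:
    print(f"{m.name}: nodes={sorted(m.nodes)}")
    print(f"  tf1 strength = {regulator_module_strength('tf1', m, net, 'R'):.2f}")
```

Output:

```
subgraph instances by type: {'COM': 2, 'COR': 5}
COR_1: nodes=['g1', 'g2', 'g3', 'g4', 'tf1']
  tf1 strength = 0.80
```

The unrelated `x1–x2` edge is left out, and the regulator's connection
strength reports that `tf1` targets 4 of the 5 module nodes.

## Command line

The `motifmod` entry point wraps every stage:

```bash
motifmod simulate --outdir fixture --seed 0     # synthetic planted-module data
motifmod codes --directed R --undirected PC     # 3-node code catalogue
motifmod enumerate --network fixture/composite.tsv \
    --layer R:directed --layer M:directed --layer H:undirected \
    --layer P:undirected --layer C:undirected --out subgraphs.tsv
motifmod run --config config.yaml               # full pipeline + artifacts
motifmod stability --config config.yaml --out stability.tsv
```

`run` writes subgraph censuses, module tables, superview statistics,
regulator strengths, optional GO enrichment, Cytoscape exports and a
`manifest.json` recording all parameters and seeds.

## Reproduction

The repository is fully self-verifying on synthetic data — no downloads
are required:

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per headline guarantee
(brute-force enumeration oracle, exhaustive clustering
optimality, planted-module recovery ≥ 0.8 mean Jaccard over 20 seeds,
null calibration of the superview and activity-score statistics, fixed
worked-statistic values, and the stability trend across sampling
fractions).  `scripts/acceptance.py` recomputes the same quantities from
scratch and reports them as JSON; with `--seed 1` it yields, among
others, `recovery_mean_jaccard ≈ 0.95`, `superview_p_lt_005_rate ≈ 0.044`
and `activity_null_sd ≈ 1.007`.  Results are deterministic for a fixed
seed.  Full-scale reproduction on real multi-omics compendia is outside
the desk-scale scope of this repository; the synthetic fixture generator
(`motifmod.synth`) is the supported benchmark substrate.
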