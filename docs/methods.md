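# Methods

This note states the model implemented by `motifmod`, every numeric
default, and the numerical choices that affect results.

## 1. Composite networks

A composite network is a multi-layer graph over one node universe.
Each layer is identified by a single uppercase letter and a
directedness flag (conventionally: `R` TF→target, `M` miRNA→mRNA,
both directed; `H` homology, `P` protein–protein, `C` co-functional,
undirected).  Per-layer edge lists are TSV files; self-loops are
dropped, undirected duplicates (`a b` / `b a`) are merged, and
antiparallel directed edges are kept as distinct.  The node set is the
union over layers, so nodes isolated in one layer still participate in
statistics.

## 2. Composite subgraph enumeration

Three-node subgraphs are encoded by a 3-letter code over the slot pairs
(0,1), (0,2), (1,2); a lowercase letter marks a directed edge running
against slot order.  The canonical code is the lexicographic minimum
over all six node permutations.  Matching is **non-induced**: for every
node triple, every combination of one concrete edge per connected pair
yields one instance, so parallel edges in different layers multiply the
instance count.  Two-node subgraphs are pairs with either two opposing
directed edges (DD) or one directed plus one undirected edge (DU).

Each instance carries one of eight topological types:

| type | pattern |
|------|---------|
| COM  | three undirected edges |
| COP  | two directed edges converging on one target, regulators linked |
| COR  | two directed edges diverging from one regulator, targets linked |
| FFL  | three directed edges, transitive (A→B, A→C, B→C) |
| CIR  | three directed edges forming a cycle |
| FBU  | directed cascade plus one undirected edge |
| FB2U | one directed plus two undirected edges |
| 2FB  | two-node DU pair |

DD pairs carry no type of their own and contribute only to the joint
ALL pool.

## 3. Hypergraph clustering

Each instance's node set is a hyperedge (weight 1).  Scores follow the
nonlinear power iteration

x_i ← Σ_{e∋i} w_e Π_{j∈e\{i}} x_j^p,

with exponent `p = 1`, followed by additive damping (`new ← new + x`,
which has the same fixed points but suppresses 2-cycles) and L2
normalization; convergence tolerance `1e-9`, at most `1000` iterations
(a warning is logged and the last iterate used otherwise).  The
candidate cluster is the best score-ordered prefix by edge-to-node
ratio (total weight of hyperedges fully inside the set divided by set
size).  When at most `exact_max_nodes = 12` hypernodes survive, an
exact bitmask scan over all subsets replaces the spectral prefix and
guarantees the globally optimal ratio.  Extraction is iterative:
assigned hyperedges are removed and the procedure repeats until none
remain.  Ties in the score ordering break lexicographically by node
name, making results deterministic for a fixed seed.

Clusters become modules if they have 5–50 nodes (`min_size`,
`max_size`) and at most 90% of their internal edges in the homology
layer (`max_homology_fraction = 0.9`, strict comparison: exactly 90%
is kept).  Surviving clusters are named `<TYPE>_<index>` with 1-based
indices over survivors in extraction order.

## 4. Superview statistics

For each unordered module pair and layer, the observed statistic x is
the number of layer edges with one endpoint in each module (directions
pooled; edges inside the module intersection count once).  The null
draws `B = 1000` pairs of disjoint uniform node sets of the same sizes
and records the crossing-count mean μ and standard deviation σ; nulls
are cached per (size_a, size_b, layer).  z = (x − μ)/σ and
p = 1 − Φ(z); x = 0 forces (z, p) = (0, 1), and σ = 0 with x > μ is
capped at z = 10⁶.

Regulator statistics: **connection strength** is the fraction of module
nodes targeted by a regulator in a directed layer; **module
specificity** is (regulators with ≥1 edge into the module)/(all
regulators); **regulator specificity** is (modules receiving ≥1 edge
from the regulator)/(all modules).

The module-set connectivity test sums within-set superview counts per
layer (plus a Total row) and compares against B random same-size module
sets; the 95% CI on the random mean is mean ± 1.96·sd/√B and the fold
change is observed/CI-upper.

## 5. Annotation

Per module, each annotated term with ≥1 study hit is tested with the
one-sided hypergeometric distribution against a configurable
background (module-pool genes, all network genes, or a user file).
Benjamini–Hochberg correction is applied within the module; terms with
adjusted p < 0.05 are retained (strict, configurable), ranked 1-based
by ascending adjusted p, and annotated with
log2 FC = log2((k/n)/(K/N)).  Annotations can be propagated to `is_a`
ancestors of an OBO ontology (via `obonet`).

## 6. Contextualization

* **nPCC** — mean pairwise Pearson correlation of module genes'
  expression, z-scored against `B = 1000` size-matched random gene
  sets (null moments cached per module size).
* **ECD** — mean over covered internal module edges of
  PCC(condition) − PCC(control), bounded in [−2, 2]; the null draws
  random gene sets of the same size and scores the same number of
  random pairs within each.
* **Activity score** — per-gene p-values (clamped to
  [10⁻¹⁶, 1 − 10⁻¹⁶]) map to z_i = Φ⁻¹(1 − p_i); z_a = Σ z_i / √k,
  and s_a = (z_a − μ_k)/σ_k against random size-k gene sets.  Under
  uniform p-values s_a is calibrated to mean ≈ 0, sd ≈ 1.  Modules
  with s_a > 0 in every requested contrast are called active.

## 7. Stability

⌊fraction·total⌋ edges are sampled without replacement from the pooled
multiset across layers (fractions 0.1–0.9, 10 repetitions each by
default; sub-seed = seed + repetition).  The pipeline re-runs on each
reduced network and every re-derived module is scored by its best
match against the ground truth — the full-network modules restricted to
sampled edges, with edge-less nodes dropped — under Jaccard, adjusted
Rand, and adjusted mutual information (ARI/AMI on binary membership
labelings over the full node universe).

## 8. Synthetic fixtures

The generator plants COM (undirected near-clique), COR (regulator
fan-out over interacting targets) and FFL (two-regulator cascade over
shared targets) modules — defaults 5/3/2 modules of sizes 6–12 at
intra-density 0.8 — plus uniform background edges (P/C 0.02, H 0.005,
R/M 0.002) and 30 background nodes.  Expression follows a
latent-factor Gaussian: module genes share a factor with weight √ρ
(ρ = 0.8), active modules gain a +2 SD case shift, and per-gene
p-values come from two-sample t-tests.  This is a deliberate stand-in
that exercises the statistics, not a transcriptome model.

## 9. Design decisions and limitations

* Determinism: all stochastic steps take explicit seeds; a pipeline
  run writes a `manifest.json` with every parameter.
* The exact-subset fallback bounds the spectral heuristic's optimality
  gap on small pools; on large pools the spectral prefix is a
  heuristic, as in the underlying clustering literature.
* The superview null assumes uniformly exchangeable nodes; degree-
  preserving nulls are out of scope.
* GO semantics beyond `is_a` propagation (part_of, relationship
  qualifiers, evidence codes) are not interpreted.
* Only 2- and 3-node subgraphs are enumerated; larger motifs arise via
  clustering, not direct matching.
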