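# aknno

Adaptive k-nearest-neighbor graph clustering for single-cell and spatial
transcriptomics that detects **abundant and rare cell populations in a single
run**.

## The problem

Community-detection clustering (the Seurat/scanpy workflow) first connects
every cell to its *k* nearest neighbors in PCA space and then groups densely
connected cells. A single global *k* cannot serve both population scales:
with the usual *k* = 20, a population of 5–10 cells is forced into spurious
long-range edges and gets absorbed by its abundant neighbors, while shrinking
*k* for everyone shatters the abundant populations into noise clusters.

## The method

Instead of one global *k*, each cell *i* gets its own neighbor count from its
local distance profile. With the sorted distances
*d*<sub>*i*1</sub> ≤ … ≤ *d*<sub>*iK*<sub>max</sub></sub> to its
*K*<sub>max</sub> nearest neighbors, the per-cell cutoff is

```
cutoff_i = ( Σ_l √d_il / (K_max − 1 − δ) )²
```

and cell *i* keeps exactly the neighbors with *d*<sub>*ij*</sub> <
cutoff<sub>*i*</sub> (closed-form solution of a neighbor-assignment objective
under KKT conditions). Cells in tight rare clusters — whose distances jump
sharply once their few true neighbors are exhausted — automatically get a
small *k*<sub>*i*</sub>; cells inside abundant clusters keep
*k*<sub>*i*</sub> = *K*<sub>max</sub>. The hyperparameter δ ≤ 0 (default
−0.5) tunes the sensitivity: more negative → smaller cutoff → fewer
neighbors. The directed adaptive graph is reweighted by the Jaccard
similarity of neighbor sets (shared-nearest-neighbor graph, pruned at 1/15)
and clustered with seeded Louvain community detection at a chosen resolution.
An optional grid search decreases δ and stops just before the community
count jumps sharply (the signature of overclustering), picking the δ that
balances sensitivity and specificity.

## Worked example

```python
import aknno as ak

# simulated dataset: two abundant types (200 cells each) + 10 rare cells,
# 1000 genes, 5% type-specific markers at 8-fold
counts = ak.simulate_nb_counts(ak.SimulationDesign(seed=0))

# adaptive graph at the default delta = -0.5
res = ak.run_aknno(counts=counts, n_hvg=100, n_pcs=20, resolution=0.1, seed=0)
print(res.n_communities)                                          # 3
print(ak.adjusted_rand_index(res.labels, counts.labels))          # 1.0
print(ak.rare_accuracy(res.labels, counts.labels, rare_type="type_2"))  # 1.0

# fixed-k baseline on the same data at the same low resolution
base = ak.run_aknno(counts=counts, n_hvg=100, n_pcs=20, resolution=0.1,
                    seed=0, fixed_k=20)
print(ak.rare_accuracy(base.labels, counts.labels, rare_type="type_2"))  # 0.0
```

The adaptive graph isolates the 10 rare cells as their own community even at
resolution 0.1 (rare-cell accuracy 1.0, perfect agreement with the planted
labels), while the fixed-*k* = 20 graph merges them into an abundant cluster
(accuracy 0.0) — the failure mode the adaptive rule exists to fix.

The same is available from the shell:

```bash
aknno simulate --seed 0 --out sim/
aknno run --input sim/ --hvg 100 --n-pcs 20 --resolution 0.1 --out labels.tsv
aknno evaluate --pred labels.tsv --truth sim/truth.tsv --rare-type type_2
```

plus `aknno optimize-delta` (δ grid-search trace) and `aknno benchmark`
(the two-setting rare-cell sweep).

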