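# Methods

## Model

Given cells embedded in a low-dimensional space (top principal components of
the log-normalized, HVG-restricted expression matrix), the method builds a
nearest-neighbor graph in which the neighbor count is chosen per cell.

For cell *i* with sorted Euclidean distances d_i1 ≤ … ≤ d_iKmax to its
K_max nearest neighbors, the cutoff

    cutoff_i = ( Σ_{l=1..Kmax} √d_il / (K_max − 1 − δ) )²

derives from minimizing Σ_ij Σ_m d_ij s_ij^m over connection indicators
s_ij ∈ [0,1] with rows summing to 1 (KKT conditions give the closed form;
the power m cancels and is not a runtime parameter). Cell *i* connects to
neighbor *j* iff d_ij < cutoff_i, so

    k_i = #{ l : d_il < cutoff_i },  clipped to [1, K_max].

The count formulation is equivalent to the piecewise statement "k = K_max if
d_Kmax < cutoff, else the j with d_j < cutoff ≤ d_{j+1}" because the
distances are sorted. Two boundary rules are ours:

* **Floor of 1.** When even d_i1 ≥ cutoff_i (locally uniform distances at a
  negative δ) the closed form yields zero neighbors; we keep the single
  nearest neighbor so no vertex is isolated, which would otherwise produce
  spurious singleton communities for *abundant* cells.
* **Strict inequality.** An edge is kept iff d_ij < cutoff_i; a distance
  exactly at the cutoff is excluded.

The directed graph is then reweighted by the Jaccard similarity of retained
neighbor sets, each set including the cell itself (so two cells that merely
point at each other still share members), over every pair connected in the
union of directed edges; weights ≤ 1/15 are pruned. Louvain community
detection with the Reichardt–Bornholdt resolution parameter runs on this
symmetric weighted graph.

## Parameters

| parameter | default | meaning |
|---|---|---|
| K_max | 20 | upper bound on per-cell neighbors; also the baseline's fixed k. The adaptive rule is insensitive to K_max over 10–50 on the simulations here. |
| δ | −0.5 | cutoff sensitivity; more negative → smaller cutoffs → fewer neighbors. δ ≤ 0 required. |
| prune | 1/15 | SNN Jaccard pruning threshold (edges with weight ≤ prune removed). |
| resolution | 0.8 | Louvain resolution; the method's rare-cell accuracy is nearly resolution-independent because rare clusters become disconnected components of the adaptive graph. |
| δ grid | 0.0, −0.5, …, −5.0 | brackets the default generously; the search stops at the first rapid community-count increase. |

**Jump rule.** "Rapid increase" is operationalized as: the community count
grows by ≥ 5 *and* by a factor ≥ 1.5 over the previous grid value (both
configurable). Requiring both an absolute and a proportional increase keeps
the rule meaningful on small datasets (where +5 alone is easy to hit from a
base of 3) and on large ones (where ×1.5 alone could fire on 100 → 150
without any overclustering signature). The chosen δ is the grid value
*before* the jump; if no jump fires, the most negative value is returned.
Whether δ should be re-optimized per resolution is open; we optimize once at
the run's resolution.

## Preprocessing

Standard UMI workflow: cells expressing < 200 genes and genes detected in
< 3 cells are removed (cells first, then genes, matching the common
CreateSeuratObject behavior; thresholds strict as stated); counts are scaled
to 10,000 per cell and log1p-transformed; the top 2000 HVGs are selected by
the vst standardized-variance ranking on raw counts; genes are centered,
scaled to unit variance, clipped at +10; PCA uses the top 50 components by
default. For spatial data an additional ≥ 10%-of-spots gene filter and 3000
HVGs are used; normalization is the same log-normalization (SCTransform is
not implemented — a documented deviation recorded in provenance).

Numerical choices: the vst trend is a local *linear* regression of
log10(variance) on log10(mean) with span 0.3 (statsmodels lowess; a
degree-1 local fit rather than the degree-2 loess of the original vst
description). Standardized values are clipped at √n_cells before the
variance is taken; zero-variance genes rank last. The SVD sign is fixed by
making each component's largest-magnitude loading positive, which makes the
embedding byte-reproducible and invariant to cell-order permutations.
Neighbor search is exact brute-force Euclidean with stable argsort, so ties
break toward the smaller cell index; duplicated coordinates are allowed
(zero distances, self still excluded). Count matrices are held dense, which
is comfortable to a few thousand cells/genes — the scale of everything this
package computes — but not for atlas-scale data.

## Synthetic data

`simulate_nb_counts` emulates the structure of an annotated PBMC-like UMI
matrix: lognormal(0, 1) baseline gene means, lognormal(0, 0.3) cell size
factors, counts drawn NB(mean, size = 10) via the gamma–Poisson mixture
(moderate overdispersion typical of UMI data), and disjoint per-type marker
sets — `marker_fraction` (default 5%) of genes split across types and
upregulated 2^`log2_fc` (default 8-fold). The default design plants two
abundant types of 200 cells and one rare type of 10.

What it does **not** emulate: dropout beyond NB sampling, per-gene
dispersion variation, continuous/transitional states, doublets, batch
effects, and correlated marker programs. Passing the recovery tests
therefore shows the graph construction does what it claims when discrete,
separated populations exist — not that any particular real tissue will
yield them.

The subsampling benchmark draws, without replacement, two abundant types
(200 + 200 cells) plus 2–20 rare cells from a labeled reference, in two
settings: rare-similar-to-abundant (setting 1, NK vs naive CD4 T) and
rare-distinct (setting 2, CD14+ monocytes). The built-in
`standin_reference` is a synthetic four-type matrix (344/697/155/480 cells)
in which the NK stand-in shares half of its 50 markers with naive CD4 T,
reproducing the similarity structure that makes setting 1 harder. Replicate
r uses seed `seed_base + r`.

**Analysis configuration for simulations.** The 1000-gene simulated
matrices are analyzed with 100 HVGs (10% of genes, mirroring the
2000-of-~20k real-data convention) and 20 PCs. Fifty PCs of a 1000-gene,
three-type simulation are mostly noise directions; they inflate all
pairwise distances equally and blur the local distance jump the adaptive
rule reads. Real datasets, with signal spread over many more genes, use the
standard 2000/50.

## Evaluation

ARI is the standard permutation-model pair-counting index computed from the
contingency table. Rare-cell accuracy counts a rare cell as recognized iff
its predicted cluster's ground-truth composition has the rare type as the
unique plurality — pure rare clusters and rare-dominated mixed clusters
score as hits, absorption into an abundant cluster does not; ties count as
misses. A `strict` flag instead requires the cluster to contain only rare
cells. The per-cluster plurality mapping was chosen over per-cell matching
because it is the natural cluster-level reading of "correctly recognized"
and is insensitive to cluster label permutations.

## Determinism

All stochastic steps (simulation, subsampling, Louvain) are seeded;
`(data, config, seed)` reproduces a `ClusteringResult` byte-for-byte in
serialized form. Louvain runs single-threaded through igraph with the seed
applied to its RNG for the duration of the call.

## Known limitations

* Dense in-memory matrices; no sparse or out-of-core path.
* Exact O(n²) neighbor search — fine to ~10⁴ cells, no approximate backend.
* Louvain only; the SNN graph is exported so Leiden/spectral methods can be
  applied externally.
* SCTransform, batch correction and doublet removal are out of scope.
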