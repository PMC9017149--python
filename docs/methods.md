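# Methods

## Model overview

`linfuse` represents each CITE-seq modality by its condensed matrix of
pairwise cell–cell distances and integrates at the distance level.  The
premise is asymmetric noise sensitivity: with F_ADT ≈ 10–50 features
against ~2000 highly variable genes, a unit of per-feature noise perturbs
the ADT Euclidean distance by O(1/√F_ADT) of its magnitude versus
O(1/√F_RNA) for RNA.  The kernel therefore (i) shrinks noise-scale ADT
differences nonlinearly, (ii) rescales the two distance matrices onto a
common level with one convex weight, and (iii) takes the entrywise maximum
so that each pair of cells is separated by whichever modality genuinely
distinguishes them.

### Sigmoid filter

The gate f(x) = 1/(1 + b^(−n(x−k))) is applied to each per-feature
absolute difference x ≥ 0, giving the filtered difference F(x) = x·f(x)
with 0 ≤ F(x) ≤ x, monotone in x.  Defaults: steepness n = 10, midpoint
k = 0.5, base b = 2.72.  The base is deliberately the truncated constant
rather than `math.e`, so that printed reference values (e.g. F(1) =
0.99333) are matched bit-comparably; it is configurable.  On
CLR-normalized ADT values, technical noise differences typically fall at
0.1–0.4 — deep in the shrinkage zone — while genuine positive-vs-negative
shifts (≳ 1 log unit) pass almost unchanged.

The optional `sigmoid_threshold` mode adds a per-feature positive/negative
cut c (default 1.0, scalar or per-feature): a difference d = |p−q| with
d ≥ c is always kept raw, a difference d < c is kept raw when min(p,q) < c
< max(p,q) (the pair straddles the gate, so the difference is likely a real
negative-to-positive transition) and filtered by F otherwise.  The
composition of the per-feature rule with the vector filter is not uniquely
determined by its verbal description; this per-feature branch rule is one
consistent reading and is the documented behavior.  `sigmoid` remains the
pipeline default, with the threshold mode opt-in.

### Scaling and fusion

α minimizes (1/2m)‖α·D_RNA − (1−α)·D_ADT‖² on [0,1].  The objective is a
one-dimensional convex quadratic, so the default solver is the closed form
α* = clip₀¹(Σ d_a(d_r+d_a) / Σ (d_r+d_a)²); projected gradient descent
(step 0.1/L with L = Σ(d_r+d_a)²/m, stop at |Δα| < 1e−8, ≤ 10⁴
iterations) is retained and serves as the independent check — the two
agree to < 1e−6 on random instances.  If both matrices are all-zero the
objective is constant and α = 0.5 is returned with a warning.

Fusion is entrywise: Linf → max(a,b) (default), L1 → a+b, L2 → √(a²+b²).
The comparator norms exist for evaluation only.  The maximum of two metrics
is again a metric, which the tests verify on random point-cloud instances.

Contributions are defined for Linf fusion as the percentage of pairs where
the joint entry equals the scaled modality entry.  An exact-zero L0-style
count is numerically fragile, so equality is declared within a relative
tolerance |d_joint − d′| ≤ 1e−12·max(1, d_joint); ties count for both
modalities, hence the two percentages sum to ≥ 100%.  Restricted
contributions between two clusters A and B default to inter-cluster pairs
(one cell in each); `pairs="union"` instead uses all pairs within A ∪ B.
Both are exposed because either reading is defensible for summarizing which
modality separates two particular subsets.

### Purity scores

ADT: per cluster, S_ADT = 1 − ΣᵢSDᵢⁿ/(ΣᵢSDᵢⁿ + K_ADT), where SDᵢ is the
within-cluster standard deviation of feature i and K_ADT is the identical
quantity over all cells, computed on the same normalized matrix with the
same SD convention (sample SDs, n−1 denominator, by default; population
SDs behind a flag).  The score is a strictly decreasing function of the
cluster's ΣSDⁿ, lies in [0,1], and equals exactly 0.5 when the cluster's
powered-SD sum equals the dataset's.  Singleton clusters score 1 (zero
dispersion).  The rank n ≥ 1 controls how strongly single high-variance
features dominate; the suggestion floor(ln(#features)) is clamped to a
minimum of 1 because rank 0 would degenerate every score to 0.5.

RNA: S_RNA = 1 − Σ_sig ds/(Σ_sig ds + K) over significant per-gene entropy
reductions ds within the cluster.  The default estimator is deliberately
simple and documented as an approximation: per gene, the observed
"entropy" is mean_c ln(1+x) on the de-logged normalized scale, the expected
value is a lowess fit (frac 0.5) of that quantity against ln(1+mean
expression) across genes, ds = expected − observed, and significance is a
one-sided normal test on the residuals with Benjamini–Hochberg control at
0.05.  Heterogeneous (e.g. bimodal) genes fall significantly below the
fit; a homogeneous cluster yields an empty significant set and S_RNA → 1.
Two caveats are inherent to any empirical fit: genes far outside the bulk
expression range can be absorbed by the curve, and the residual SD is
estimated globally.  Passing precomputed ds values per cluster
(`ds_by_cluster`) bypasses the estimator entirely and is the
higher-fidelity path.  K is technology dependent and has no universal
value; the default K = 1.0 was fixed once by requiring that a random
half-split of a homogeneous simulated dataset score ≥ 0.9 (it scores 1.0,
since the null produces no significant reductions).

Combined: the geometric mean of the per-modality scores, extending to M
modalities as (Π scores)^(1/M).

## Pre-processing defaults

- QC keeps cells with detected-gene counts in [200, 2500] inclusive (the
  exclusion rule is strictly below/above) and mitochondrial fraction at or
  below min(95th percentile, 10%) — a soft threshold that adapts to each
  dataset's quality but is sealed at 10%.  Mitochondrial genes are
  recognized by a configurable, case-insensitive identifier prefix
  (default "MT-").
- RNA: per-cell log normalization ln(1 + x·10⁴/total); the 10⁴ scale
  factor is the droplet-toolkit convention, not a derived quantity.
- ADT: per-cell CLR across features with a +1 pseudocount,
  yᵢ = ln((xᵢ+1)/gm(x+1)); each cell's values sum to zero.  CLR also
  cancels per-cell staining-depth factors exactly.  ADT values are *not*
  z-scored before the distance (that would destroy the meaning of k and
  c); a z-scoring flag exists for completeness.
- HVG: standardized dispersion (variance/mean of log-normalized
  expression) z-scored within up to 20 equal-occupancy mean-expression
  bins (at least 10 genes per bin); top 2000 by default, clamped to the
  gene count; stable tie-breaking by gene index.
- PCA: per-gene z-score clipped at ±10, full SVD, top 20 components, each
  component's sign fixed so its largest-magnitude loading is positive.
- Clustering: SNN graph (neighbor sets = self + 20 nearest, ties broken by
  cell index, Jaccard edge weights, pruning below 1/15) and Louvain
  multilevel at resolution 0.9, seeded; labels contiguous from 0 in
  decreasing cluster size.
- Embeddings run on the precomputed distance matrix (t-SNE with perplexity
  min(30, (N−1)/3), UMAP with random init for very small N, metric MDS).

## Simulators

`simulate_adt` draws |Normal(μ, σ)| values per cluster/feature.  The three
built-in designs have 6 clusters of sizes (100, 50, 200, 50, 100, 100)
over 9 features with σ tiers 0.5 (low), 1.0 (mid), 1.5 (high): cluster 1
all-low; cluster 2 mid on one feature; cluster 3 high on one feature;
clusters 4/5/6 mid on 2/3/4 features; designs 2 and 3 append 9 and 18
all-low "negative" features.  All means default to 0 — the variance tiers
carry the entire structure — and any mean or σ can be overridden through a
custom `SimSpec`.  The specific features carrying each cluster's elevated
variance are an arbitrary fixed assignment; scoring depends only on the
per-cluster SD multiset.

`simulate_citeseq` is fixture machinery for end-to-end tests, not a model
of any particular tissue.  RNA counts are negative binomial (default
shape 30) with log-normal size factors (σ = 0.3) over 400 genes with
log-normal baseline means; ADT counts are negative binomial around
log-normal per-feature baselines (mean 300 counts, shape 60), with two
features carrying extra overdispersion (shape 20) to emulate dominant
noisy surface markers.  At these depths the between-cell CLR noise
differences sit at ~0.15–0.5 — below the sigmoid midpoint, which is the
regime the filter is designed for — while planted shifts (20-fold) land
near ln(20) ≈ 3, far above it.  Designs: `cd4_pair` plants 10 genes at
2-fold (baseline mean 30) and no ADT difference; `nk_pair` plants one
20-fold ADT shift and no gene difference; `four_blob` plants both kinds of
structure across four clusters.  The generator does not emulate real
marker panels, gene–gene correlation structure, doublets, or ambient
counts, so passing tests demonstrate the kernel's behavior under clean
planted structure, not performance on real tissue.

The headline behavioral check reproduces the filter's purpose
synthetically: on `cd4_pair` fixtures (300 cells, 10 seeds) the full joint
pipeline with the sigmoid filter recovers the planted RNA-exclusive pair
(mean adjusted Rand index ≥ 0.8) while the same pipeline with the plain
Euclidean ADT distance merges it (mean ARI ≤ 0.2), because the unfiltered
ADT noise — amplified by the dominant noisy features — wins the entrywise
maximum on enough cell pairs to mask a 10-gene signal.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale — hundreds of cells,
hundreds of genes, ≤ 27 ADT features — where every stage is exact and fast;
the distance kernel is row-chunked so memory stays at O(N·F) per block plus
the m-length condensed output.  Distance matrices are condensed upper
triangles in `scipy` pdist order throughout.  Determinism: all simulators
take explicit seeds (NumPy `default_rng`), Louvain seeds igraph's RNG,
embeddings pass `random_state`, and rerunning the pipeline with the same
config and seed is bit-identical.  Degenerate inputs are defined rather
than accidental: empty ADT blocks read with a warning, zero-total-count
cells are an error naming the barcode, all-zero distance pairs give
α = 0.5 with a warning, singleton clusters score S_ADT = 1.

## Known limitations

- Pairwise distances are quadratic in cell number; the design targets
  datasets up to a few tens of thousands of cells and small ADT panels,
  not atlas-scale data.
- The RNA purity estimator is an approximation (see above); precomputed
  entropy reductions are first-class inputs for users with a dedicated
  entropy model.
- Fusion is two-modality; the data model and the geometric-mean purity
  combination extend to more modalities, but the α scaling is pairwise by
  construction.
- Batch correction is out of scope: the pipeline accepts externally
  corrected expression or PC matrices as the RNA input, which is the
  intended integration point.
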