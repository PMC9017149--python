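# linfuse

Joint analysis of CITE-seq data by L∞ fusion of per-modality cell–cell
distances, with a sigmoid-filtered ADT distance and cluster purity scoring.

## The problem

CITE-seq measures, in each cell, the whole transcriptome (RNA counts) and a
small panel of surface proteins through antibody-derived tags (ADTs).  The
two modalities disagree on scale and dimensionality: RNA distances are
computed over ~2000 highly variable genes, ADT distances over 10–50
features.  Random noise in a *single* ADT feature therefore moves the ADT
distance between two cells far more than noise in a single gene moves the
RNA distance, and naive integration lets a noisy dominant surface marker
mask cell subsets that differ only in a few genes.

`linfuse` addresses this with a distance-level integration kernel:

1. **Sigmoid-filtered ADT distance.**  For two cells with CLR-normalized
   ADT vectors *P*, *Q*, every per-feature absolute difference *x* is
   shrunk by the logistic gate *f(x) = 1 / (1 + e^(−n(x−k)))* before the
   Euclidean norm:

       D_ADT(P, Q) = sqrt( Σᵢ [ |pᵢ − qᵢ| · f(|pᵢ − qᵢ|) ]² )

   with defaults *n* = 10, *k* = 0.5 (and base *e* ≈ 2.72).  Noise-scale
   differences (≪ *k*) collapse toward zero; genuine positive/negative
   differences pass essentially unchanged.  An optional threshold *c*
   (default 1) additionally keeps raw any difference that straddles the
   positive/negative boundary, like a flow-cytometry gate.
2. **Convex scaling.**  A single weight α ∈ [0, 1] minimizes
   ‖α·D_RNA − (1−α)·D_ADT‖² / 2m over the m = N(N−1)/2 cell pairs
   (closed form, with a gradient-descent reference implementation).
3. **L∞ fusion.**  The joint distance is the entrywise maximum of the two
   scaled matrices: each cell pair keeps whichever modality separates it
   more strongly.  L1 and L2 comparator norms are available.
4. **Modality contributions.**  The percentage of cell pairs whose joint
   distance equals a modality's scaled distance (ties count for both, so
   the percentages sum to ≥ 100%), optionally restricted to the pairs
   linking two chosen clusters.
5. **Purity scores.**  Per cluster: an ADT score
   *S_ADT = 1 − ΣSDⁿ / (ΣSDⁿ + K_ADT)* comparing powered per-feature
   standard deviations against the whole-dataset constant K_ADT
   (rank heuristic *n* = floor(ln #features)); an RNA score
   *S_RNA = 1 − Σ_sig ds / (Σ_sig ds + K)* from significant per-gene
   entropy reductions; and their geometric mean *S = √(S_ADT · S_RNA)*.
   A cluster whose variation matches the whole dataset scores exactly 0.5.

Downstream, the joint distance feeds a shared-nearest-neighbor graph with
Louvain community detection and t-SNE/UMAP/MDS embeddings computed directly
on the precomputed distances.  Simulators for ADT-only variance designs and
for paired CITE-seq data with planted modality-exclusive subpopulations
make every stage testable without downloads.

## Worked example

Simulate 300 cells in two subpopulations that share every gene's expression
but differ strongly in one surface protein (an "NK-like" pair, separable
only through the ADT modality), then run the full pipeline:

```sh
linfuse simulate --design nk_pair --n-cells 300 --seed 0 --out data
linfuse run --input data --out run --no-qc
```

prints

```
2 clusters over 300 cells; alpha=0.1025
```

The pipeline recovered exactly the two planted subpopulations.  The fusion
metadata (`run/fusion.json`) shows α ≈ 0.102 — RNA distances are ~9× the
ADT scale here, so the solver down-weights them to match — and balanced
modality contributions (RNA 51.2%, ADT 48.8%).  The purity report
(`run/purity.csv`) reads

```
cluster,n_cells,S_RNA,S_ADT,S
1,149,1.000000,0.902962,0.950243
0,151,1.000000,0.882258,0.939286
```

Both clusters are transcriptionally homogeneous (S_RNA = 1: no significant
entropy reduction) and much tighter than the dataset as a whole on the ADT
panel (S_ADT ≈ 0.9 ≫ 0.5), as expected when the planted ADT shift is the
only structure.  The same library surface is available in Python
(`linfuse.run_pipeline`, `linfuse.fuse`, `linfuse.purity_report`, …), and
`linfuse run --adt-mode plain` reruns the pipeline without the sigmoid
filter for comparison.

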