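# Methods

`momhca` classifies cell types from paired single-cell multi-omics data —
scRNA-seq and scATAC-seq measured in the same cells — by learning a fused
per-cell embedding with bidirectional multi-head cross-attention, building a
consensus cell-similarity graph with similarity network fusion (SNF), and
classifying cells transductively with a graph convolutional network (GCN).
This note records the model, its assumptions, the defaults and why, the
numerical choices, and the places where the design was genuinely open.

## Preprocessing

The two modalities are preprocessed separately before integration.

**scRNA-seq.** Cells are retained with 300–10,000 detected genes and <5%
mitochondrial reads (mitochondrial genes matched by the `MT-`/`mt-` prefix,
configurable); genes expressed in no cell are dropped. Counts are
normalised with global LogNormalize, `x → ln(1 + 10^4 · x / cell_total)`.
Highly variable genes are ranked by variance-stabilised standardized
variance: a degree-2 polynomial trend of log10 variance against log10 mean
is fit across genes, each gene's counts are standardised by the
trend-predicted sd with clipping at √N, and genes are ranked by the
variance of the clipped values. The top 2000 HVGs (default) are centred,
scaled to unit variance with clipping at ±10, and reduced by PCA to 50
components (default).

**scATAC-seq.** Cells are retained with 2,000–20,000 fragments in peaks,
blacklist fraction <5%, nucleosome signal <4 and TSS enrichment >3. TSS
enrichment and nucleosome signal are consumed as precomputed per-cell
metadata; fragment-file parsing is out of scope. The top 25% of peaks by
detection count are kept, TF-IDF is applied in the chromatin-toolkit
dialect `ln(1 + TF · IDF · 10^4)` (the plain `TF · IDF` variant is
available via `tfidf_variant: plain`), and LSI (truncated SVD without
centring) reduces to 50 components after dropping the first component,
which tracks sequencing depth (`lsi_drop_first: false` keeps it). LSI
scores are then standardised per component with the same ±10 clipping.

QC bounds are calibrated to real sequencing depth. The synthetic benchmark
generates already-clean cells at much smaller depth, so QC filtering
defaults off in the pipeline configuration and is switched on for real
datasets. When enabled, only cells passing both modalities' bounds are
kept, preserving the one-to-one pairing.

Component signs in PCA/LSI are fixed by making the largest-magnitude
loading positive, so embeddings are deterministic.

## Dual autoencoders

One encoder–decoder pair per modality, d_m → 512 → 128 with batch
normalisation and GELU after the hidden layer; the decoder mirrors the
encoder with a linear output layer. Weights are not shared between
modalities. Both pathways are trained jointly on

    L = α · MSE(X_i, X_i′) + β · MSE(X_j, X_j′),   α + β = 1,

with α = β = 0.5 by default. Training is full-batch Adam at lr 10⁻³ for
200 epochs. The latent dimension is fixed at 128.

Because the neural stages run on a small NumPy reverse-mode autodiff engine
(`momhca.nn`), everything is CPU-only, full-batch and bit-reproducible
given a seed; there is no minibatching or GPU path.

## Multi-head cross-attention fusion

RNA latents query ATAC keys/values and vice versa:

    head_i^h = Attention(Z_i W_Q^h, Z_j W_K^h, Z_j W_V^h),
    head_j^h = Attention(Z_j W_Q^h, Z_i W_K^h, Z_i W_V^h),
    Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V,

with 4 heads of dimension d_k = d/h = 32 by default and separate
projection parameters per direction (no weight sharing between the two
attention directions). Every cell attends
over all N cells of the other modality; the score matrices are full N × N.
Heads are concatenated and projected to d, wrapped in a residual connection
with layer normalisation (learnable affine parameters — a choice; the
alternative is a flag away in the code), and the two directions are fused
by a two-layer feed-forward network on their concatenation (hidden size
256 = 2d, ReLU).

**Supervised contrastive refinement.** Embeddings are L2-normalised and
compared by cosine similarity at temperature τ = 0.5. Contrastive losses
are often written with a single positive per anchor, but with class labels
an anchor generally has many positives, so the standard multi-positive
(SupCon-style) generalisation is used: the per-pair term

    −log[ exp(s(a,a⁺)/τ) / (exp(s(a,a⁺)/τ) + Σ_neg exp(s(a,a⁻)/τ)) ]

is averaged over all anchor–positive pairs, with negatives = all
different-class cells. Anchors without positives are skipped with a
warning. The fusion stage minimises L_total = L_recon + λ_c·L_contrastive
with λ_c = 1 (configurable). Contrastive supervision uses
training-mask cells only; test labels are never read (verified by a
bit-identity test).

The reconstruction term at the fusion stage is the weighted joint AE
objective with the encoders fine-tuned (default; `freeze_encoders` fixes
them, in which case linear heads reconstruct the input latents from the
fused embedding instead). The default schedule is: pretrain the
autoencoders, then fine-tune them during fusion training. Fusion trains
for 60 full-batch epochs at lr 10⁻³ by default — enough for the
contrastive term to plateau at desk scale while keeping an N=1000 run in
tens of seconds per stage.

**Baseline fusers.** Concatenation (+ learned 2d → d projection), sum,
average (+ learned d → d projection) and single-modality self-attention on
the concatenated features are available under the identical training
protocol for ablation.

## Similarity network fusion

Per modality, Euclidean distances on the *reduced* representations
(PCA/LSI scores; the reduced layer is chosen over raw or normalised counts
for noise robustness, and is configurable) feed a locally scaled Gaussian
kernel

    W(i,j) = exp(−ρ(i,j)² / (μ · ε_ij)),
    ε_ij = (mean K-NN distance of i + mean K-NN distance of j + ρ(i,j)) / 3.

This is the canonical SNF local scale, consistent with the K-neighbour /
μ parameterisation used throughout. Defaults: K = 9, μ = 0.5. Coincident points floor ε at machine epsilon with
a warning. Two kernels follow: the full kernel P (diagonal 1/2,
off-diagonal rows summing to 1/2) and the kNN kernel S (row-stochastic on
the K nearest neighbours; ties at the boundary break to the smaller
index). Cross-diffusion iterates

    P₁ ← S₁ · P₂ · S₁ᵀ,   P₂ ← S₂ · P₁ · S₂ᵀ

as simultaneous updates from the previous iterates. After each step the
iterates are renormalised back to the full-kernel structure — without this
the iterates drift from stochasticity; `renormalize: false` keeps the bare
updates. The iteration count defaults to t = 20 with early stop
when ‖P₁−P₂‖_F/‖P₁‖_F < 10⁻⁶. The fused matrix (P₁+P₂)/2 is symmetrised
and, with self-loops added, is the GCN adjacency; top-K sparsification is
available but off by default.

## GCN classification

Two graph convolutions H^(l) = σ(Ã H^(l−1) W^(l)) with
Ã = D^(−1/2) A D^(−1/2), ELU activations, dropout 0.5 (conventional)
between them, and a distinct fully connected output layer rather than a
merged output transform. Hidden dimension 64; softmax cross-entropy on
train-mask nodes only; Adam with lr 0.001, weight decay 0.01, 150 epochs.
Bias terms are included in all layers.

Training is transductive: the graph and features cover all cells, test
*labels* are masked. Under donor-grouped CV this means test-donor cells
contribute edges and features but never supervision. A strict-inductive
variant (graph over training cells only, test cells attached at inference)
is a known alternative and is not implemented; at desk scale the
transductive graph is the protocol this package defines.

## Evaluation protocol

Integration is scored by k-means (k-means++ init, best of 10 restarts) on
the fused embedding with k set to the true number of cell types
(configurable), then ARI, NMI (arithmetic normalisation) and AMI.
Classification is scored by accuracy, support-weighted F1 and
support-weighted precision (support weighting keeps the three metrics
consistent; a macro-unweighted flag exists). Cross-validation: stratified 5-fold, or donor-grouped
k-fold in which all of a donor's cells share a fold; experiments repeat
over seeds and report mean/sd/range per metric. Paired t-tests and
Wilcoxon signed-rank tests compare methods on matched fold×seed
observations; all-zero differences leave the Wilcoxon statistic undefined
and it is reported as NaN. Clustering can be scored on all cells or on
test folds only; `all` is the default scope.

## Synthetic benchmark

The generator emulates the structure of paired multiome datasets:

* k planted, near-balanced cell types shared by both modalities;
* RNA: negative-binomial counts (gamma–Poisson, dispersion r = 2) with
  per-gene log-normal baselines; each type's marker genes (60 per type by
  default, disjoint blocks) get a positive log-fold shift scaled by
  `type_signal_strength`; per-cell library sizes are log-normal around
  2000 counts;
* ATAC: near-binary sparse counts — Bernoulli peak opening at probability
  0.25 for a type's marker peaks and 0.02 background, times 1 + Poisson
  extra counts; ≥80% zeros at the default spec;
* modality-specific noise: per-entry log-normal jitter on RNA means (sd
  0.2) and mixing of ATAC open probabilities toward the type-free mean
  (weight 0.1);
* donors: balanced assignment with mild per-donor log-normal gene/peak
  factors (sd 0.1);
* cross-modal coupling: a fraction (0.8) of each type's marker peaks is
  aligned with that type's marker-gene program; the rest are assigned to a
  permuted type.

The default benchmark is 1000 cells, 5 types, 2000 genes, 5000 peaks and
4 donors — sized for minutes-scale single-CPU runs. Runs that need
donor-grouped 5-fold CV use a 10-donor variant, since 4 donors cannot fill
5 donor-disjoint folds. A separability ladder regenerates the same seed at increasing
signal strengths with identical labels, enabling monotonicity tests.

What the generator does **not** emulate: batch effects beyond donor
factors, doublets, ambient contamination, peak–gene genomic distance
structure, or realistic library-size/detection covariation. Passing tests
therefore demonstrate correctness of the algorithms and recovery of
planted structure, not performance on real tissue atlases.

A note on supervised refinement and clustering scores: with all-cells
scoring, the contrastive term can push training cells of a class together
even when the data carry no class signal, inflating ARI through label
memorisation. The separability-ladder check therefore scores held-out
cells only, where memorisation cannot contribute; the zero-signal level
then sits at ARI ≈ 0 as it should.

## Problem sizes and defaults used in checks

End-to-end checks run the full benchmark (n = 1000) for integration
recovery (3 seeds) and donor-grouped classification (5 folds); the
ablation (asymmetric modality noise: RNA jitter 0.5, ATAC mixing 0.9, weak
peak signal) and the separability ladder run at n = 400, and the
determinism check at n = 250 with shortened training. These sizes are the
package's standard desk-scale settings.

## Known limitations

* Full N×N attention and SNF matrices are dense; memory and time are
  quadratic in cells. The implementation targets desk-scale data
  (thousands of cells), not atlas scale.
* The autodiff engine implements exactly the operations the models need;
  it is not a general deep-learning framework.
* Exactly two modalities are supported — the cross-diffusion updates are
  written for two.
* No doublet detection, peak calling, or fragment-level QC computation.
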