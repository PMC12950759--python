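# momhca

Multi-omics integration and cell-type classification for **paired**
single-cell data — scRNA-seq and scATAC-seq measured in the same cells.
The package is aimed at computational biologists who have a cell-matched
expression matrix and peak-accessibility matrix (plus optional cell-type
labels and donor IDs) and want a fused per-cell embedding, a consensus
cell-similarity graph, and supervised cell-type predictions with honest
cross-validation.

## Method

Given RNA counts `X_i ∈ R^{N×D1}` and ATAC peak counts `X_j ∈ R^{N×D2}`
for the same `N` cells, the pipeline runs:

1. **Preprocessing** — RNA: QC → LogNormalize → VST highly-variable genes →
   scale → PCA. ATAC: QC → top peaks → TF-IDF (`ln(1 + TF·IDF·10⁴)`) →
   LSI (depth component dropped) → scale.
2. **Dual autoencoders** — one `d_m → 512 → 128` encoder/decoder per
   modality, trained jointly on
   `L = α·MSE(X_i, X_i′) + β·MSE(X_j, X_j′)` with `α + β = 1`, yielding
   latents `Z_i, Z_j ∈ R^{N×128}`.
3. **Multi-head cross-attention fusion** — RNA queries attend over ATAC
   keys/values and vice versa,
   `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V` per head (4 heads), heads
   concatenated and projected, residual + LayerNorm, then a two-layer FFN
   on `[head_i′ ‖ head_j′]` produces the fused embedding `Z`. A supervised
   contrastive loss (cosine similarity, τ = 0.5, multi-positive SupCon) on
   training cells sharpens class structure; total objective
   `L_recon + λ_c·L_contrastive`.
4. **Similarity network fusion** — per-modality affinities
   `W(i,j) = exp(−ρ²/(μ·ε_ij))` with the standard local scale, full kernel
   `P` (diagonal ½) and kNN kernel `S` (K = 9), cross-diffusion
   `P₁ ← S₁P₂S₁ᵀ`, `P₂ ← S₂P₁S₂ᵀ`, fused `P = (P₁+P₂)/2` — the GCN
   adjacency.
5. **GCN classification** — two graph convolutions
   `H^(l) = σ(Ã H^(l−1) W^(l))`, `Ã = D^{−1/2}AD^{−1/2}`, ELU, dropout,
   linear output head; transductive training with cross-entropy on
   train-mask cells only.

Evaluation follows the field's protocol: k-means on the fused embedding
scored with ARI/NMI/AMI, classification scored with accuracy / weighted F1
/ weighted precision under stratified or donor-grouped cross-validation,
plus paired t-tests and Wilcoxon signed-rank comparisons. A built-in
generator produces paired synthetic benchmarks with planted cell types,
donors and tunable separability; see `docs/methods.md` for the model and
all defaults.

The neural stages run on a small NumPy reverse-mode autodiff engine
(`momhca.nn`) — CPU-only, full-batch, bit-reproducible from a seed.

## Worked example

Run the full pipeline on a small synthetic benchmark (300 cells, 3 planted
types, 3-fold stratified CV):

```python
from momhca import PipelineConfig, SyntheticSpec
from momhca.pipeline import run

cfg = PipelineConfig()
cfg.synth = SyntheticSpec(n_cells=300, n_types=3, n_genes=400, n_peaks=800,
                          n_donors=4, markers_per_type_genes=40,
                          markers_per_type_peaks=80, seed=0)
cfg.preprocess.n_hvg = 300; cfg.preprocess.n_pcs = 25; cfg.preprocess.n_lsi = 25
cfg.ae.epochs = 100; cfg.fusion.epochs = 30; cfg.gcn.epochs = 100
cfg.eval.n_folds = 3; cfg.eval.seeds = [0]
cfg.outdir = "demo_out"
out = run(cfg)
print(out["summary"].to_string(index=False))
```

which prints

```
     metric  mean  sd  min  max  n
        ari   1.0 0.0  1.0  1.0  3
        nmi   1.0 0.0  1.0  1.0  3
        ami   1.0 0.0  1.0  1.0  3
        acc   1.0 0.0  1.0  1.0  3
weighted_f1   1.0 0.0  1.0  1.0  3
  precision   1.0 0.0  1.0  1.0  3
```

`ari/nmi/ami` score k-means clusters of the fused embedding against the
planted cell types (1.0 = perfect recovery of the 3 types); `acc`,
`weighted_f1` and `precision` score the GCN's held-out fold predictions.
At this separability the planted structure is recovered exactly; lowering
`type_signal_strength` or raising the modality noise degrades the scores
smoothly. Per-fold rows land in `demo_out/metrics.csv` alongside a run
manifest with the config hash and seed.

The same workflow is available from the shell:

```bash
momhca synth --seed 0 --out data/          # write 10x-style MTX triplets
momhca run --config config.yaml --seed 0 --out results/
momhca sweep --parameter heads --values 1,2,4,8,16 --config config.yaml
```

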