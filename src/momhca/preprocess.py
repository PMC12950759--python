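"""Modality-specific preprocessing for paired scRNA-seq / scATAC-seq data.

The RNA arm follows the standard Seurat-style recipe: QC on detected genes
and mitochondrial fraction, global LogNormalize (scale factor 10,000),
variance-stabilised (VST) highly-variable-gene selection, PCA, then
centre/scale with clipping. The ATAC arm follows the Signac-style recipe:
QC on fragments-in-peaks, blacklist fraction, nucleosome signal and TSS
enrichment, TF-IDF normalisation, top-peak selection by detection rate,
then LSI (truncated SVD with the depth-tracking first component dropped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

__all__ = [
    "OmicsMatrix",
    "CellQCRecord",
    "QCThresholds",
    "LatentEmbedding",
    "filter_cells",
    "lognormalize",
    "select_hvg_vst",
    "tfidf",
    "select_top_peaks",
    "reduce",
    "scale_features",
]

MITO_PREFIX_RE = re.compile(r"^(MT-|mt-)")


@dataclass
class OmicsMatrix:
    """A cells × features matrix for one modality.

    `values` may be dense or scipy-sparse; `layer` records where in the
    preprocessing chain the matrix sits (counts → normalized → scaled →
    reduced).
    """

    values: np.ndarray | sp.spmatrix
    modality: str  # "rna" | "atac"
    cell_ids: list[str]
    feature_ids: list[str]
    layer: str = "counts"

    def __post_init__(self):
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"modality must be 'rna' or 'atac', got {self.modality!r}")
        n, d = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {d} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids are not unique")
        if self.layer == "counts" and self.values.shape[0] and self.values.shape[1]:
            if sp.issparse(self.values):
                vmin = self.values.data.min() if self.values.nnz else 0.0
            else:
                vmin = self.values.min()
            if vmin < 0:
                raise ValueError("negative entries in a counts-layer matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def subset_cells(self, idx: np.ndarray) -> "OmicsMatrix":
        vals = self.values[idx] if not sp.issparse(self.values) else self.values.tocsr()[idx]
        return replace(self, values=vals, cell_ids=[self.cell_ids[i] for i in idx])

    def subset_features(self, idx: np.ndarray) -> "OmicsMatrix":
        vals = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx]
        return replace(self, values=vals, feature_ids=[self.feature_ids[i] for i in idx])


@dataclass
class LatentEmbedding:
    """An N × d per-cell embedding (PCA/LSI scores, AE latents, fused Z...)."""

    values: np.ndarray
    source: str  # "rna" | "atac" | "fused" | "head"
    cell_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")
        if self.cell_ids is not None and len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match embedding rows")


@dataclass
class CellQCRecord:
    cell_id: str
    n_genes_detected: int = 0
    pct_mito: float = 0.0
    n_fragments_in_peaks: int = 0
    blacklist_fraction: float = 0.0
    nucleosome_signal: float = 0.0
    tss_enrichment: float = 0.0

    def __post_init__(self):
        for name in ("pct_mito", "blacklist_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] for cell {self.cell_id}")
        for name in ("n_genes_detected", "n_fragments_in_peaks",
                     "nucleosome_signal", "tss_enrichment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative for cell {self.cell_id}")


@dataclass
class QCThresholds:
    """Retention bounds: 300–10,000 detected genes, <5% mitochondrial reads
    for RNA; 2,000–20,000 fragments in peaks, <5% blacklist fraction,
    nucleosome signal <4 and TSS enrichment >3 for ATAC."""

    rna_genes_min: int = 300
    rna_genes_max: int = 10_000
    rna_mito_max: float = 0.05
    atac_frag_min: int = 2_000
    atac_frag_max: int = 20_000
    atac_blacklist_max: float = 0.05
    atac_nucleosome_max: float = 4.0
    atac_tss_min: float = 3.0

    def __post_init__(self):
        if not self.rna_genes_min < self.rna_genes_max:
            raise ValueError("rna_genes_min must be < rna_genes_max")
        if not self.atac_frag_min < self.atac_frag_max:
            raise ValueError("atac_frag_min must be < atac_frag_max")

    def passes(self, rec: CellQCRecord, modality: str) -> bool:
        if modality == "rna":
            return (self.rna_genes_min <= rec.n_genes_detected <= self.rna_genes_max
                    and rec.pct_mito < self.rna_mito_max)
        return (self.atac_frag_min <= rec.n_fragments_in_peaks <= self.atac_frag_max
                and rec.blacklist_fraction < self.atac_blacklist_max
                and rec.nucleosome_signal < self.atac_nucleosome_max
                and rec.tss_enrichment > self.atac_tss_min)


def compute_qc_records(rna: OmicsMatrix, atac: OmicsMatrix | None = None,
                       mito_regex: str | re.Pattern = MITO_PREFIX_RE) -> dict[str, CellQCRecord]:
    """Derive the RNA-side QC quantities (and ATAC fragments-in-peaks proxy)
    directly from count matrices. TSS enrichment and nucleosome signal come
    from fragment files upstream and default to permissive values here."""
    pat = re.compile(mito_regex) if isinstance(mito_regex, str) else mito_regex
    X = rna.dense()
    mito_cols = [i for i, f in enumerate(rna.feature_ids) if pat.search(f)]
    totals = X.sum(axis=1)
    mito = X[:, mito_cols].sum(axis=1) if mito_cols else np.zeros(rna.n_cells)
    recs: dict[str, CellQCRecord] = {}
    frags = atac.dense().sum(axis=1) if atac is not None else None
    for i, cid in enumerate(rna.cell_ids):
        recs[cid] = CellQCRecord(
            cell_id=cid,
            n_genes_detected=int((X[i] > 0).sum()),
            pct_mito=float(mito[i] / totals[i]) if totals[i] > 0 else 0.0,
            n_fragments_in_peaks=int(frags[i]) if frags is not None else 0,
            tss_enrichment=10.0, nucleosome_signal=1.0, blacklist_fraction=0.0,
        )
    return recs


def filter_cells(matrix: OmicsMatrix, qc: list[CellQCRecord] | dict[str, CellQCRecord],
                 thresholds: QCThresholds | None = None) -> OmicsMatrix:
    """Drop cells failing the modality-relevant QC bounds (order preserved);
    for RNA additionally drop genes with zero total count."""
    thresholds = thresholds or QCThresholds()
    by_id = qc if isinstance(qc, dict) else {r.cell_id: r for r in qc}
    keep = []
    for i, cid in enumerate(matrix.cell_ids):
        if cid not in by_id:
            raise KeyError(f"no QC record for cell {cid!r}")
        if thresholds.passes(by_id[cid], matrix.modality):
            keep.append(i)
    out = matrix.subset_cells(np.asarray(keep, dtype=int))
    if matrix.modality == "rna":
        totals = np.asarray(out.values.sum(axis=0)).ravel()
        out = out.subset_features(np.flatnonzero(totals > 0))
    return out


def lognormalize(matrix: OmicsMatrix, scale_factor: float = 1e4) -> OmicsMatrix:
    """Global LogNormalize: x → ln(1 + scale_factor · x / cell_total)."""
    if matrix.modality != "rna":
        raise ValueError("lognormalize applies to RNA counts")
    if matrix.layer != "counts":
        raise ValueError(f"expected counts layer, got {matrix.layer!r}")
    X = matrix.dense()
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = matrix.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total count; QC-filter first")
    out = np.log1p(scale_factor * X / totals[:, None])
    return replace(matrix, values=out, layer="normalized")


def select_hvg_vst(matrix: OmicsMatrix, n_features: int,
                   clip: str | float = "sqrt") -> np.ndarray:
    """Rank genes by variance-stabilised standardized variance.

    A degree-2 polynomial is fit to log10(variance) vs log10(mean) over
    genes with positive variance; each gene's counts are standardised by the
    trend-predicted sd, clipped at sqrt(N), and genes are ranked by the
    variance of the clipped values. Returns indices of the top
    `n_features` genes (descending standardized variance).
    """
    if n_features > matrix.n_features:
        raise ValueError(f"n_features={n_features} exceeds {matrix.n_features} genes")
    X = matrix.dense()
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    std_var = np.zeros(X.shape[1])
    ok = (var > 0) & (mean > 0)
    if ok.sum() >= 3:
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        coef = np.polyfit(lm, lv, deg=2)
        pred_sd = np.sqrt(10.0 ** np.polyval(coef, lm))
        clip_val = np.sqrt(n) if clip == "sqrt" else float(clip)
        Z = (X[:, ok] - mean[ok]) / pred_sd
        np.clip(Z, -clip_val, clip_val, out=Z)
        std_var[ok] = Z.var(axis=0, ddof=1)
    # stable ordering: descending standardized variance, ties by index
    order = np.lexsort((np.arange(X.shape[1]), -std_var))
    return order[:n_features]


def tfidf(matrix: OmicsMatrix, variant: str = "signac",
          scale_factor: float = 1e4) -> OmicsMatrix:
    """TF-IDF normalisation for peak counts.

    `signac` (default): ln(1 + TF · IDF · scale_factor) with TF the
    within-cell frequency and IDF = N / n_cells_detecting_peak.
    `plain`: TF · IDF without the log transform.
    """
    if matrix.modality != "atac":
        raise ValueError("tfidf applies to ATAC counts")
    if matrix.layer != "counts":
        raise ValueError(f"expected counts layer, got {matrix.layer!r}")
    X = matrix.dense()
    det = (X > 0).sum(axis=0)
    if np.any(det == 0):
        bad = matrix.feature_ids[int(np.argmax(det == 0))]
        raise ValueError(f"peak {bad!r} detected in zero cells; pre-filter peaks")
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = matrix.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total count; QC-filter first")
    tf = X / totals[:, None]
    idf = matrix.n_cells / det
    prod = tf * idf
    if variant == "signac":
        out = np.log1p(prod * scale_factor)
    elif variant == "plain":
        out = prod
    else:
        raise ValueError(f"unknown tfidf variant {variant!r}")
    return replace(matrix, values=out, layer="normalized")


def select_top_peaks(matrix: OmicsMatrix, fraction: float = 0.25) -> np.ndarray:
    """Indices of the most informative peaks by detection count
    (top `fraction` of peaks, FindTopFeatures-style)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    X = matrix.values
    det = np.asarray((X > 0).sum(axis=0)).ravel()
    n_keep = max(1, int(round(fraction * matrix.n_features)))
    order = np.lexsort((np.arange(matrix.n_features), -det))
    return np.sort(order[:n_keep])


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-magnitude loading positive
    for c in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    return scores, loadings


def reduce(matrix: OmicsMatrix, n_components: int, method: str = "pca",
           lsi_drop_first: bool = True) -> LatentEmbedding:
    """Linear dimensionality reduction: PCA (centred) for RNA, LSI
    (truncated SVD, no centring, first component dropped by default — it
    tracks sequencing depth) for ATAC. Component signs are fixed so the
    largest-magnitude loading is positive."""
    X = matrix.dense()
    n, d = X.shape
    if n_components >= min(n, d):
        raise ValueError(f"n_components={n_components} must be < min(N, D)={min(n, d)}")
    if method == "pca":
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        scores, _ = _fix_signs(scores, pca.components_.copy())
    elif method == "lsi":
        extra = 1 if lsi_drop_first else 0
        if n_components + extra >= min(n, d):
            raise ValueError("n_components too large for LSI after dropping component 1")
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        scores_all = U * s
        scores = scores_all[:, extra:n_components + extra].copy()
        scores, _ = _fix_signs(scores, Vt[extra:n_components + extra].copy())
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return LatentEmbedding(scores, source=matrix.modality, cell_ids=list(matrix.cell_ids))


def scale_features(matrix: OmicsMatrix, clip: float = 10.0) -> OmicsMatrix:
    """Centre each feature to mean 0 / unit sd (constant features → 0) and
    clip to ±`clip` to damp extreme values."""
    if clip <= 0:
        raise ValueError("clip must be positive")
    X = matrix.dense()
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mean[nz]) / sd[nz]
    np.clip(out, -clip, clip, out=out)
    return replace(matrix, values=out, layer="scaled")
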