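"""Readers and writers for the standard on-disk formats: 10x-style MTX
triplets (matrix.mtx + barcodes.tsv + features.tsv), dense CSV
(cells × features, header row = feature ids), and AnnData HDF5 (.h5ad)."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .preprocess import OmicsMatrix

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_csv_matrix",
    "write_csv_matrix",
    "read_h5ad",
    "write_h5ad",
    "write_qc_report",
    "write_predictions",
    "write_dataset_10x",
]


def _maybe_gz(path: Path) -> Path:
    if path.exists():
        return path
    gz = path.with_name(path.name + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(path)


def read_mtx_triplet(directory: str | os.PathLike, modality: str) -> OmicsMatrix:
    """Read a 10x-style triplet. The MTX on disk is features × cells
    (10x convention); the returned matrix is cells × features."""
    d = Path(directory)
    mat = mmread(_maybe_gz(d / "matrix.mtx")).tocsr()
    barcodes = pd.read_csv(_maybe_gz(d / "barcodes.tsv"), sep="\t", header=None)[0].tolist()
    feat_df = pd.read_csv(_maybe_gz(d / "features.tsv"), sep="\t", header=None)
    features = feat_df[0].tolist()
    return OmicsMatrix(mat.T.tocsr(), modality, barcodes, features)


def write_mtx_triplet(matrix: OmicsMatrix, directory: str | os.PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = matrix.values if sp.issparse(matrix.values) else sp.csr_matrix(matrix.values)
    mmwrite(str(d / "matrix.mtx"), X.T.tocoo())
    pd.Series(matrix.cell_ids).to_csv(d / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(matrix.feature_ids).to_csv(d / "features.tsv", sep="\t",
                                         index=False, header=False)


def read_csv_matrix(path: str | os.PathLike, modality: str) -> OmicsMatrix:
    df = pd.read_csv(path, index_col=0)
    return OmicsMatrix(df.to_numpy(dtype=np.float64), modality,
                       [str(i) for i in df.index], [str(c) for c in df.columns])


def write_csv_matrix(matrix: OmicsMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(matrix.dense(), index=matrix.cell_ids,
                 columns=matrix.feature_ids).to_csv(path)


def read_h5ad(path: str | os.PathLike, modality: str) -> OmicsMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if sp.issparse(X):
        X = X.tocsr()
    return OmicsMatrix(X, modality, [str(i) for i in adata.obs_names],
                       [str(v) for v in adata.var_names])


def write_h5ad(matrix: OmicsMatrix, path: str | os.PathLike) -> None:
    import anndata as ad

    X = matrix.values if sp.issparse(matrix.values) else np.asarray(matrix.values)
    adata = ad.AnnData(X=X)
    adata.obs_names = matrix.cell_ids
    adata.var_names = matrix.feature_ids
    adata.uns["modality"] = matrix.modality
    adata.uns["layer"] = matrix.layer
    adata.write_h5ad(path)


def write_qc_report(records, path: str | os.PathLike) -> None:
    rows = records.values() if isinstance(records, dict) else records
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, sep="\t", index=False)


def write_predictions(cell_ids, true_labels, pred_labels, probs,
                      path: str | os.PathLike) -> None:
    """TSV: cell_id, true_label (−1 if unknown), predicted_label,
    max_probability."""
    pd.DataFrame({
        "cell_id": cell_ids,
        "true_label": np.asarray(true_labels),
        "predicted_label": np.asarray(pred_labels),
        "max_probability": np.asarray(probs).max(axis=1),
    }).to_csv(path, sep="\t", index=False)


def write_similarity(S: np.ndarray, path: str | os.PathLike,
                     fmt: str = "mtx") -> None:
    """Export a fused similarity / adjacency matrix as MatrixMarket
    (`mtx`), dense CSV (`csv`), or a (i, j, weight) edge-list TSV over the
    nonzero entries (`edges`)."""
    S = np.asarray(S, dtype=np.float64)
    if fmt == "mtx":
        mmwrite(str(path), sp.coo_matrix(S))
    elif fmt == "csv":
        pd.DataFrame(S).to_csv(path, index=False, header=False)
    elif fmt == "edges":
        i, j = np.nonzero(S)
        pd.DataFrame({"i": i, "j": j, "weight": S[i, j]}).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown similarity export format {fmt!r}")


def write_dataset_10x(dataset, directory: str | os.PathLike) -> None:
    """Persist a synthetic paired dataset as two MTX triplets plus
    labels/donors TSV, exercising the same reader path as real 10x data."""
    d = Path(directory)
    write_mtx_triplet(dataset.rna, d / "rna")
    write_mtx_triplet(dataset.atac, d / "atac")
    pd.DataFrame({"cell_id": dataset.rna.cell_ids,
                  "label": dataset.labels,
                  "donor": dataset.donors}).to_csv(d / "cells.tsv", sep="\t",
                                                   index=False)
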