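"""Evaluation protocol: k-means on the fused embedding for integration
quality (ARI/NMI/AMI), held-out classification metrics (ACC, weighted F1,
support-weighted precision), stratified and donor-grouped cross-validation,
a seed-averaged end-to-end experiment runner, and paired significance
tests (paired t-test and Wilcoxon signed-rank)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import (
    accuracy_score,
    adjusted_mutual_info_score,
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
    precision_score,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold

__all__ = [
    "MetricsRecord",
    "CVPlan",
    "kmeans_cluster",
    "clustering_metrics",
    "classification_metrics",
    "make_cv_plan",
    "run_experiment",
    "paired_tests",
    "summarize",
]


@dataclass
class MetricsRecord:
    ari: float = np.nan
    nmi: float = np.nan
    ami: float = np.nan
    acc: float = np.nan
    weighted_f1: float = np.nan
    precision: float = np.nan
    fold: int = -1
    seed: int = -1


@dataclass
class CVPlan:
    scheme: str  # "stratified_kfold" | "grouped_kfold"
    n_folds: int
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=lambda: [0])


def kmeans_cluster(Z: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Lloyd's k-means with k-means++ initialisation, best of `n_init`
    restarts by inertia; deterministic given seed."""
    Z = np.asarray(Z, dtype=np.float64)
    if k > Z.shape[0]:
        raise ValueError(f"k={k} exceeds number of cells {Z.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    return km.fit_predict(Z)


def clustering_metrics(true_labels: np.ndarray, pred_labels: np.ndarray
                       ) -> tuple[float, float, float]:
    """(ARI, NMI, AMI) with standard normalisations; permutation invariant."""
    true_labels, pred_labels = np.asarray(true_labels), np.asarray(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors have different lengths")
    return (float(adjusted_rand_score(true_labels, pred_labels)),
            float(normalized_mutual_info_score(true_labels, pred_labels,
                                               average_method="arithmetic")),
            float(adjusted_mutual_info_score(true_labels, pred_labels)))


def classification_metrics(true_labels: np.ndarray, pred_labels: np.ndarray,
                           average: str = "weighted") -> tuple[float, float, float]:
    """(ACC, weighted F1, support-weighted precision). Classes absent from
    the predictions contribute precision 0 with a warning."""
    true_labels, pred_labels = np.asarray(true_labels), np.asarray(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors have different lengths")
    missing = set(np.unique(true_labels)) - set(np.unique(pred_labels))
    if missing:
        warnings.warn(f"classes never predicted (precision counted as 0): {sorted(missing)}")
    acc = accuracy_score(true_labels, pred_labels)
    f1 = f1_score(true_labels, pred_labels, average=average, zero_division=0)
    prec = precision_score(true_labels, pred_labels, average=average, zero_division=0)
    return float(acc), float(f1), float(prec)


def make_cv_plan(labels: np.ndarray, donors: np.ndarray | None, scheme: str,
                 n_folds: int, seed: int = 0) -> CVPlan:
    """Stratified folds preserve class proportions; grouped folds keep every
    donor's cells in a single fold (donor-disjoint train/test)."""
    labels = np.asarray(labels)
    n = len(labels)
    if scheme == "stratified_kfold":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(np.zeros(n), labels)]
    elif scheme == "grouped_kfold":
        if donors is None:
            raise ValueError("grouped CV requires donor ids")
        donors = np.asarray(donors)
        n_donors = len(np.unique(donors))
        if n_donors < n_folds:
            raise ValueError(f"{n_donors} donors cannot fill {n_folds} grouped folds")
        splitter = GroupKFold(n_splits=n_folds)
        folds = [(tr, te) for tr, te in splitter.split(np.zeros(n), labels, groups=donors)]
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    return CVPlan(scheme=scheme, n_folds=n_folds, folds=folds)


def paired_tests(metric_a: np.ndarray, metric_b: np.ndarray
                 ) -> tuple[float, float, float, float]:
    """Paired t-test and Wilcoxon signed-rank on matched per-fold×seed
    observations; returns (t, p_t, W, p_w). With all differences zero the
    Wilcoxon statistic is undefined and reported as NaN."""
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if len(a) != len(b):
        raise ValueError("paired vectors have different lengths")
    if len(a) < 5:
        raise ValueError("need at least 5 paired observations")
    t_res = stats.ttest_rel(a, b)
    d = a - b
    if np.allclose(d, 0.0):
        warnings.warn("all paired differences are zero; Wilcoxon undefined")
        w_stat, p_w = np.nan, np.nan
    else:
        w_res = stats.wilcoxon(a, b)
        w_stat, p_w = float(w_res.statistic), float(w_res.pvalue)
    t_stat = float(t_res.statistic) if np.isfinite(t_res.statistic) else 0.0
    return t_stat, float(t_res.pvalue), w_stat, p_w


def summarize(records: list[MetricsRecord]) -> pd.DataFrame:
    """Mean, sd and range per metric across seed×fold rows."""
    df = pd.DataFrame([r.__dict__ for r in records])
    metrics = ["ari", "nmi", "ami", "acc", "weighted_f1", "precision"]
    rows = []
    for m in metrics:
        vals = df[m].dropna()
        if len(vals) == 0:
            continue
        rows.append({"metric": m, "mean": vals.mean(), "sd": vals.std(ddof=0),
                     "min": vals.min(), "max": vals.max(), "n": len(vals)})
    return pd.DataFrame(rows)


def run_experiment(rna, atac, labels: np.ndarray, donors: np.ndarray | None,
                   config=None, scheme: str = "stratified_kfold",
                   n_folds: int = 5, seeds: list[int] | None = None,
                   clustering_scope: str = "all",
                   ) -> tuple[list[MetricsRecord], pd.DataFrame]:
    """Full protocol: for each seed and fold run
    preprocess → dual AE → MHCA fusion (contrastive on train cells only) →
    SNF → GCN, score the held-out fold, and score integration by k-means on
    the fused embedding with k = number of true classes.

    `clustering_scope` chooses whether clustering metrics are computed on
    all cells (default) or the test fold only.
    """
    from .pipeline import PipelineConfig, build_fused_graph, preprocess_stage, run_fold

    config = config or PipelineConfig()
    seeds = seeds if seeds is not None else list(config.eval.seeds)
    labels = np.asarray(labels)

    pair = preprocess_stage(rna, atac, config.preprocess)
    labels = labels[pair.keep_idx]
    donors = np.asarray(donors)[pair.keep_idx] if donors is not None else None
    k = len(np.unique(labels))
    # the SNF graph depends only on the deterministic preprocessed
    # representations, so it is shared across seeds and folds
    adjacency = build_fused_graph(pair.rna, pair.atac, config.snf)

    records: list[MetricsRecord] = []
    for seed in seeds:
        plan = make_cv_plan(labels, donors, scheme, n_folds, seed=seed)
        for fold_id, (train_idx, test_idx) in enumerate(plan.folds):
            res = run_fold(pair.rna, pair.atac, labels, train_idx, test_idx,
                           config, seed=seed, adjacency=adjacency)
            acc, f1, prec = classification_metrics(labels[test_idx],
                                                   res["pred"][test_idx])
            scope = slice(None) if clustering_scope == "all" else test_idx
            km = kmeans_cluster(res["fused"][scope], k, seed=seed,
                                n_init=config.eval.kmeans_n_init)
            ari, nmi, ami = clustering_metrics(labels[scope], km)
            records.append(MetricsRecord(ari=ari, nmi=nmi, ami=ami, acc=acc,
                                         weighted_f1=f1, precision=prec,
                                         fold=fold_id, seed=seed))
    return records, summarize(records)
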