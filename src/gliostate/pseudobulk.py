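"""Pseudobulk differential expression and preranked gene-set enrichment.

Cells are collapsed to per-sample summed counts; per-gene differential
expression fits an ordinary least-squares model on log2(CPM + 1) of
``expression ~ treatment + replicate``, reporting the treatment
coefficient as log2 fold change with a t-test p-value and
Benjamini-Hochberg adjustment. DE calls use strict thresholds
(adjusted p < alpha and |log2FC| > lfc). Enrichment uses the weighted
Kolmogorov-Smirnov running-sum statistic with a seeded gene-label
permutation null and sign-matched normalization (NES).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_pseudobulk",
    "bh_adjust",
    "differential_expression",
    "call_de_genes",
    "enrichment_score",
    "gsea_preranked",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def aggregate_pseudobulk(adata, sample_labels: pd.Series) -> pd.DataFrame:
    """Sum raw counts per gene per sample; returns gene x sample integers.

    Samples with zero member cells are dropped with a warning.
    """
    labels = sample_labels.reindex(adata.obs_names)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    cols = {}
    for sample in pd.unique(labels.dropna()):
        rows = np.flatnonzero((labels == sample).to_numpy())
        if rows.size == 0:
            warnings.warn(f"sample {sample!r} has no cells; dropped", UserWarning)
            continue
        cols[sample] = np.asarray(X[rows].sum(axis=0)).ravel().astype(np.int64)
    if not cols:
        raise ValueError("no samples with cells")
    return pd.DataFrame(cols, index=adata.var_names)


def differential_expression(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    treatment_col: str = "treatment",
    treated_label: str = "ribociclib",
    replicate_col: str = "replicate",
    min_total_count: int = 10,
) -> pd.DataFrame:
    """Per-gene OLS on log2(CPM + 1): expression ~ treatment + replicate.

    The treatment coefficient is the log2 fold change (treated vs
    control); its t-test p-value (residual df) is BH-adjusted across
    tested genes. Genes with total pseudobulk count below
    ``min_total_count`` are excluded before testing. A design in which
    treatment is aliased with replicate raises an error.
    """
    samples = list(counts.columns)
    meta = metadata.loc[samples]
    treat = (meta[treatment_col] == treated_label).to_numpy(dtype=float)
    if treat.sum() < 2 or (len(samples) - treat.sum()) < 2:
        raise ValueError("need >= 2 samples per treatment arm")

    reps = pd.get_dummies(meta[replicate_col], drop_first=True, dtype=float)
    design = np.column_stack([np.ones(len(samples)), treat, reps.to_numpy()])
    # confounding check: treatment must add rank beyond intercept+replicate
    base = np.column_stack([np.ones(len(samples)), reps.to_numpy()])
    if np.linalg.matrix_rank(design) <= np.linalg.matrix_rank(base):
        raise ValueError("treatment is confounded with replicate structure")

    keep = counts.sum(axis=1).to_numpy() >= min_total_count
    kept = counts.loc[keep]
    cpm = kept.to_numpy(dtype=float) / counts.sum(axis=0).to_numpy() * 1e6
    Y = np.log2(cpm + 1.0)  # genes x samples

    n, p = design.shape
    dof = n - p
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(design)
    beta = Y @ pinv.T  # genes x p
    resid = Y - beta @ design.T
    sigma2 = (resid**2).sum(axis=1) / dof
    XtX_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
    tstat = beta[:, 1] / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    padj = bh_adjust(pvals)

    out = pd.DataFrame(
        {
            "log2fc": beta[:, 1],
            "t": tstat,
            "p": pvals,
            "padj": padj,
        },
        index=kept.index,
    )
    return out


def call_de_genes(
    results: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.0
) -> tuple[list[str], list[str]]:
    """Strict-threshold DE gene lists: (upregulated, downregulated).

    up iff padj < alpha AND log2fc > lfc; down iff padj < alpha AND
    log2fc < -lfc. Both inequalities strict, so boundary values are not
    called.
    """
    if "padj" not in results.columns:
        raise KeyError("results lack an adjusted p column")
    sig = results["padj"] < alpha
    up = results.index[sig & (results["log2fc"] > lfc)].tolist()
    down = results.index[sig & (results["log2fc"] < -lfc)].tolist()
    return up, down


def enrichment_score(
    ranked_genes, ranking_values, gene_set, weight: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score of one gene set.

    Walking down the ranking, set members increment the running sum in
    proportion to |ranking value|^weight (normalized over the set) and
    non-members decrement by 1/(n - n_set); ES is the extremum of the
    running sum with the largest magnitude.
    """
    ranked_genes = list(ranked_genes)
    values = np.abs(np.asarray(ranking_values, dtype=float)) ** weight
    in_set = np.fromiter((g in gene_set for g in ranked_genes), bool, len(ranked_genes))
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == len(ranked_genes):
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    hit_norm = values[in_set].sum()
    if hit_norm == 0:
        hit_norm = 1.0
    step = np.where(in_set, values / hit_norm, -1.0 / (len(ranked_genes) - n_hit))
    running = np.cumsum(step)
    return float(running[np.abs(running).argmax()])


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranking`` maps gene -> finite DE statistic, sorted or not (it is
    sorted descending internally). For each retained set (size within
    [min_size, max_size] after intersecting the ranking), the null is
    built from ``n_perm`` random same-size gene sets; NES = ES divided
    by the mean |null ES| of matching sign, and the permutation p is the
    fraction of same-sign null ES at least as extreme, lower-bounded by
    1/(n_perm + 1).
    """
    if not np.isfinite(ranking.to_numpy(dtype=float)).all():
        raise ValueError("ranking metric must be finite for all genes")
    ranking = ranking.sort_values(ascending=False)
    genes = list(ranking.index)
    values = ranking.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        members = set(members) & set(genes)
        if not (min_size <= len(members) <= max_size):
            warnings.warn(
                f"gene set {name!r} outside size bounds after intersection; skipped",
                UserWarning,
            )
            continue
        es = enrichment_score(genes, values, members, weight=weight)
        k = len(members)
        # vectorized gene-label permutation null: k random positions per draw
        n = len(genes)
        pos_scores = np.abs(values) ** weight
        in_mat = np.zeros((n_perm, n), dtype=bool)
        idx = rng.random((n_perm, n)).argpartition(k - 1, axis=1)[:, :k]
        np.put_along_axis(in_mat, idx, True, axis=1)
        hit = in_mat * pos_scores
        hit_norm = hit.sum(axis=1, keepdims=True)
        hit_norm[hit_norm == 0] = 1.0
        step = hit / hit_norm - (~in_mat) / (n - k)
        running = np.cumsum(step, axis=1)
        null = running[np.arange(n_perm), np.abs(running).argmax(axis=1)]
        same_sign = null[np.sign(null) == np.sign(es)]
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
        p = max(n_extreme / max(same_sign.size, 1), 1.0 / (n_perm + 1))
        rows.append((name, es, nes, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["gene_set", "es", "nes", "p"]).set_index(
        "gene_set"
    )
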