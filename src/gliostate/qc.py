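"""Per-cell QC, doublet scoring, graph clustering and cell-type annotation.

The QC contract reads the filtering criteria literally: genes-detected
bounds are strict (> 500, < 10 000) while the mitochondrial bound is the
maximum allowed (<= 5% for nuclei, <= 10% for the in vitro preset).
Clustering is Louvain modularity optimization (igraph multilevel) on a
kNN graph built from PCA of log-normalized, scaled expression.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .scoring import module_score

__all__ = [
    "CELL_TYPE_VOCABULARY",
    "ClusterAssignment",
    "compute_qc_metrics",
    "apply_qc_filters",
    "score_doublets",
    "cluster_cells",
    "annotate_cell_types",
    "IN_VITRO_MAX_PCT_MITO",
]

CELL_TYPE_VOCABULARY = (
    "neurons",
    "oligodendrocytes",
    "astrocytes",
    "myeloid",
    "lymphocytes",
    "endothelial",
    "mural",
    "malignant-candidate",
)

#: relaxed mitochondrial bound for cultured (in vitro) cells
IN_VITRO_MAX_PCT_MITO = 10.0


@dataclass
class ClusterAssignment:
    """Barcode -> cluster id plus cluster -> cell-type label."""

    clusters: pd.Series  # index barcode, int cluster id
    labels: dict[int, str] | None = None  # cluster id -> vocabulary label

    def cell_labels(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("clusters have not been annotated")
        return self.clusters.map(self.labels)


def compute_qc_metrics(adata) -> pd.DataFrame:
    """Per-cell QC metrics from the raw integer matrix.

    Returns a table indexed by barcode with ``n_genes_detected``
    (genes with count > 0), ``pct_mito`` (percent of counts from
    mitochondrial genes; 0 and flagged degenerate for empty cells) and a
    ``degenerate`` flag.
    """
    if "mito" not in adata.var.columns:
        raise ValueError("gene annotation lacks the 'mito' flag column")
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy().astype(bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    degenerate = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(degenerate, 0.0, 100.0 * mito_counts / np.where(total == 0, 1, total))
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct,
            "degenerate": degenerate,
        },
        index=adata.obs_names,
    )


def apply_qc_filters(
    qc: pd.DataFrame,
    min_genes: int = 500,
    max_genes: int = 10_000,
    max_pct_mito: float = 5.0,
    doublet_scores: pd.Series | None = None,
    doublet_cutoff: float | None = None,
) -> pd.Index:
    """Barcodes passing QC.

    A cell is retained iff ``n_genes_detected > min_genes`` and
    ``< max_genes`` (both strict), ``pct_mito <= max_pct_mito``
    (boundary allowed), and — when doublet scores are supplied — its
    doublet score is below the cutoff.
    """
    if min_genes <= 0 or max_genes <= 0:
        raise ValueError("gene-count thresholds must be positive")
    if min_genes >= max_genes:
        raise ValueError("min_genes must be smaller than max_genes")
    keep = (
        (qc["n_genes_detected"] > min_genes)
        & (qc["n_genes_detected"] < max_genes)
        & (qc["pct_mito"] <= max_pct_mito)
    )
    if doublet_scores is not None:
        if doublet_cutoff is None:
            raise ValueError("doublet_cutoff required when doublet_scores given")
        keep &= doublet_scores.reindex(qc.index) < doublet_cutoff
    return qc.index[keep.to_numpy()]


def _lognorm_dense(X) -> np.ndarray:
    """counts-per-10k, log1p, dense."""
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return np.log1p(X / total * 1e4)


def score_doublets(
    adata,
    k_neighbors: int = 20,
    artificial_fraction: float = 0.25,
    n_pcs: int = 30,
    seed: int = 0,
) -> pd.Series:
    """Artificial-nearest-neighbor doublet scores in [0, 1].

    Artificial doublets are averages of random cell pairs in
    log-normalized space; each real cell is scored as the fraction of
    its ``k_neighbors`` nearest neighbors (in a joint PCA embedding)
    that are artificial, rescaled by the artificial fraction so a score
    of 1 means an all-artificial neighborhood.
    """
    n = adata.n_obs
    if n < 2:
        raise ValueError("doublet scoring needs at least 2 cells")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells ({n})")
    if artificial_fraction == 0.0:
        return pd.Series(np.zeros(n), index=adata.obs_names, name="doublet_score")
    rng = np.random.default_rng(seed)
    Xl = _lognorm_dense(adata.X)
    n_art = max(1, int(round(artificial_fraction * n)))
    pairs = rng.integers(0, n, size=(n_art, 2))
    art = 0.5 * (Xl[pairs[:, 0]] + Xl[pairs[:, 1]])
    joint = np.vstack([Xl, art])
    joint = joint - joint.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, joint.shape[0] - 1, joint.shape[1] - 1)
    emb = PCA(
        n_components=n_pcs, svd_solver="randomized", random_state=seed
    ).fit_transform(joint)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]  # drop self
    frac_art = (idx >= n).mean(axis=1)
    return pd.Series(frac_art, index=adata.obs_names, name="doublet_score")


def doublet_cutoff_from_rate(scores: pd.Series, expected_rate: float = 0.05) -> float:
    """Score threshold at the quantile matching the expected doublet rate."""
    if not 0.0 <= expected_rate <= 1.0:
        raise ValueError("expected_rate must be in [0, 1]")
    if expected_rate == 0.0:
        return float(np.inf)
    return float(np.quantile(scores.to_numpy(), 1.0 - expected_rate))


def cluster_cells(
    adata,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    resolution: float = 0.6,
    n_top_genes: int = 2000,
    hvg_genes: list[str] | None = None,
    batch_key: str | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Louvain community detection on a kNN graph of QC-passed cells.

    Pipeline: counts-per-10k + log1p normalization, top
    ``n_top_genes`` highly variable genes (or a supplied fixed list),
    per-gene z-scoring clipped at ±10, PCA, optional per-batch mean
    centering in PC space, kNN graph, then igraph multilevel (Louvain)
    modularity optimization at the given resolution. Deterministic under
    a fixed seed.
    """
    adw = adata.copy()
    sc.pp.normalize_total(adw, target_sum=1e4)
    sc.pp.log1p(adw)
    if hvg_genes is not None:
        adw = adw[:, [g for g in hvg_genes if g in adw.var_names]].copy()
    elif adw.n_vars > n_top_genes:
        sc.pp.highly_variable_genes(adw, n_top_genes=n_top_genes)
        adw = adw[:, adw.var["highly_variable"]].copy()
    sc.pp.scale(adw, max_value=10)
    if n_pcs >= adw.n_obs:
        warnings.warn(
            f"n_pcs={n_pcs} >= number of cells; reducing", UserWarning, stacklevel=2
        )
        n_pcs = max(1, adw.n_obs - 1)
    sc.pp.pca(adw, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    if batch_key is not None:
        pcs = adw.obsm["X_pca"]
        for _, idx in adw.obs.groupby(batch_key, observed=True).indices.items():
            pcs[idx] -= pcs[idx].mean(axis=0, keepdims=True)
    sc.pp.neighbors(adw, n_neighbors=k_neighbors, n_pcs=n_pcs, random_state=seed)
    conn = adw.obsp["connectivities"].tocoo()
    mask = conn.row < conn.col
    edges = list(zip(conn.row[mask].tolist(), conn.col[mask].tolist()))
    weights = conn.data[mask].tolist()
    g = igraph.Graph(n=adw.n_obs, edges=edges)
    _pyrandom.seed(seed)
    part = g.community_multilevel(weights=weights, resolution=resolution)
    clusters = pd.Series(
        np.asarray(part.membership, dtype=int), index=adw.obs_names, name="cluster"
    )
    return ClusterAssignment(clusters=clusters)


def annotate_cell_types(
    assignment: ClusterAssignment,
    adata,
    marker_sets: dict[str, list[str]],
    seed: int = 0,
) -> ClusterAssignment:
    """Label each cluster by the marker set with the highest mean module score.

    Marker genes absent from the bundle are dropped with a warning; an
    empty set after dropping is an error. Exact score ties are broken by
    the order of ``marker_sets`` and logged via warning.
    """
    usable = {}
    for label, genes in marker_sets.items():
        present = [g for g in genes if g in adata.var_names]
        missing = len(genes) - len(present)
        if missing:
            warnings.warn(
                f"{missing} marker genes for {label!r} absent from bundle",
                UserWarning,
                stacklevel=2,
            )
        if not present:
            raise ValueError(f"no marker genes left for label {label!r}")
        usable[label] = present

    cells = assignment.clusters.index
    sub = adata[cells].copy()
    scores = pd.DataFrame(
        {
            label: module_score(sub, genes, seed=seed)
            for label, genes in usable.items()
        },
        index=cells,
    )
    labels = {}
    order = list(usable)
    for cl, idx in scores.groupby(assignment.clusters).groups.items():
        means = scores.loc[idx].mean(axis=0)
        best = means.max()
        winners = [lab for lab in order if means[lab] == best]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cl}: tie between {winners}; first in fixed order wins",
                UserWarning,
                stacklevel=2,
            )
        labels[int(cl)] = winners[0]
    return ClusterAssignment(clusters=assignment.clusters, labels=labels)
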