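"""Expression-inferred copy-number profiles and malignancy calling.

Per-cell relative expression (log2 of normalized counts, centered on a
nonmalignant reference, clipped at ±3) is smoothed with a centered
101-gene moving average within each chromosome; a 3-state Gaussian HMM
(loss / neutral / gain) is Viterbi-decoded along each chromosome; and
per-chromosome altered-gene fractions feed the malignancy concordance
rule: a malignant-candidate cluster cell with > 25% of chromosome 7
inferred gain and/or > 25% of chromosome 10 inferred loss is malignant,
while discordant cells are labelled unresolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CNVProfile",
    "HMMParams",
    "build_cnv_profile",
    "viterbi_cnv_states",
    "chromosome_altered_fraction",
    "classify_malignant_cells",
    "filter_samples_by_malignant_count",
    "STATE_LOSS",
    "STATE_NEUTRAL",
    "STATE_GAIN",
]

STATE_LOSS, STATE_NEUTRAL, STATE_GAIN = 0, 1, 2


@dataclass
class CNVProfile:
    """Smoothed relative-expression tracks over genomically ordered genes."""

    smoothed: np.ndarray  # cells x ordered genes, float32
    barcodes: pd.Index
    gene_order: pd.DataFrame  # ordered: gene_id, chromosome, position
    states: np.ndarray | None = None  # cells x ordered genes, int8

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.gene_order["chromosome"]))

    def chromosome_slice(self, chrom: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_order["chromosome"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in profile")
        return idx


@dataclass(frozen=True)
class HMMParams:
    """3-state Gaussian emission HMM with a symmetric stay-probability chain."""

    means: tuple[float, float, float] = (-0.2, 0.0, 0.2)
    sigma: float = 0.1
    stay_prob: float = 0.9999

    def transition_matrix(self) -> np.ndarray:
        p = self.stay_prob
        off = (1.0 - p) / 2.0
        T = np.full((3, 3), off)
        np.fill_diagonal(T, p)
        return T

    def __post_init__(self):
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ValueError("HMM means must be ordered loss < neutral < gain")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in (0, 1)")


def _moving_average_truncated(M: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with edge-truncated windows."""
    if window == 1:
        return M.copy()
    n = M.shape[1]
    half = window // 2
    cs = np.concatenate(
        [np.zeros((M.shape[0], 1), dtype=np.float64), np.cumsum(M, axis=1)], axis=1
    )
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def build_cnv_profile(
    adata,
    reference_barcodes,
    window: int = 101,
    clip: float = 3.0,
    chunk_size: int = 2000,
) -> CNVProfile:
    """Smoothed per-cell relative-expression profile over ordered genes.

    Per gene: log2(counts-per-10k + 1), centered by the mean over the
    reference (nonmalignant) cells, clipped to ±``clip``, then
    re-centered per cell by the cell's mean (removing genome-wide
    library-depth offsets that would otherwise mimic whole-genome gain
    or loss), and finally a centered ``window``-gene moving average
    within each chromosome (window truncated at chromosome edges).
    Mitochondrial genes are excluded; genes are ordered by
    (chromosome, position).
    """
    reference_barcodes = pd.Index(reference_barcodes)
    if reference_barcodes.empty:
        raise ValueError("reference_barcodes must be non-empty")

    var = adata.var
    keep = ~var["mito"].to_numpy().astype(bool)
    chroms_in_order = pd.unique(var.loc[keep, "chromosome"])
    order_parts = []
    for chrom in chroms_in_order:
        on = np.flatnonzero((var["chromosome"].to_numpy() == chrom) & keep)
        on = on[np.argsort(var["position"].to_numpy()[on], kind="stable")]
        if on.size < window:
            warnings.warn(
                f"chromosome {chrom} has {on.size} genes < window {window}; "
                "windows truncated",
                UserWarning,
                stacklevel=2,
            )
        order_parts.append(on)
    gene_idx = np.concatenate(order_parts)
    gene_order = pd.DataFrame(
        {
            "gene_id": np.asarray(adata.var_names)[gene_idx],
            "chromosome": var["chromosome"].to_numpy()[gene_idx],
            "position": var["position"].to_numpy()[gene_idx],
        }
    )
    chrom_labels = gene_order["chromosome"].to_numpy()
    blocks = [
        np.flatnonzero(chrom_labels == c) for c in pd.unique(chrom_labels)
    ]

    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0

    def _log2norm(rows) -> np.ndarray:
        sub = X[rows][:, gene_idx].toarray().astype(np.float64)
        sub = sub / totals[rows, None] * 1e4
        return np.log2(sub + 1.0)

    ref_rows = adata.obs_names.get_indexer(reference_barcodes)
    if (ref_rows < 0).any():
        raise KeyError("some reference barcodes absent from bundle")
    ref_mean = np.zeros(gene_idx.size)
    for start in range(0, ref_rows.size, chunk_size):
        ref_mean += _log2norm(ref_rows[start : start + chunk_size]).sum(axis=0)
    ref_mean /= ref_rows.size

    n_cells = adata.n_obs
    smoothed = np.empty((n_cells, gene_idx.size), dtype=np.float32)
    for start in range(0, n_cells, chunk_size):
        rows = np.arange(start, min(start + chunk_size, n_cells))
        centered = np.clip(_log2norm(rows) - ref_mean, -clip, clip)
        centered -= centered.mean(axis=1, keepdims=True)
        for blk in blocks:
            smoothed[np.ix_(rows, blk)] = _moving_average_truncated(
                centered[:, blk], window
            )
    return CNVProfile(
        smoothed=smoothed, barcodes=adata.obs_names.copy(), gene_order=gene_order
    )


def viterbi_decode(values: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most-probable 3-state path for each row of ``values`` (vectorized).

    Gaussian emissions with shared sigma, uniform initial distribution,
    symmetric stay-probability transitions; deterministic (ties resolved
    toward the lower state index).
    """
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    T = params.transition_matrix()
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0):
        raise ValueError("transition rows must be stochastic")
    logT = np.log(T)
    mu = np.asarray(params.means)
    n_cells, L = values.shape
    ll = -((values[:, :, None] - mu[None, None, :]) ** 2) / (2 * params.sigma**2)
    delta = ll[:, 0, :] + np.log(1.0 / 3.0)
    psi = np.empty((n_cells, L, 3), dtype=np.int8)
    for t in range(1, L):
        cand = delta[:, :, None] + logT[None, :, :]  # cells x from x to
        psi[:, t, :] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + ll[:, t, :]
    path = np.empty((n_cells, L), dtype=np.int8)
    path[:, -1] = delta.argmax(axis=1)
    for t in range(L - 2, -1, -1):
        path[:, t] = np.take_along_axis(
            psi[:, t + 1, :], path[:, t + 1][:, None], axis=1
        ).ravel()
    return path


def viterbi_cnv_states(
    profile: CNVProfile, params: HMMParams | None = None
) -> CNVProfile:
    """Decode loss/neutral/gain states per cell, per chromosome.

    Each chromosome is decoded as an independent chain; the decoded
    state matrix is stored on the returned profile.
    """
    if params is None:
        params = HMMParams()
    states = np.empty_like(profile.smoothed, dtype=np.int8)
    for chrom in profile.chromosomes:
        idx = profile.chromosome_slice(chrom)
        states[:, idx] = viterbi_decode(profile.smoothed[:, idx], params)
    return CNVProfile(
        smoothed=profile.smoothed,
        barcodes=profile.barcodes,
        gene_order=profile.gene_order,
        states=states,
    )


def chromosome_altered_fraction(
    profile: CNVProfile,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell fraction of genes decoded gain / loss, per chromosome.

    fraction_gain(chr) = decoded-gain genes / genes on chr, analogously
    for loss; denominators are gene counts, not base pairs.
    """
    if profile.states is None:
        raise ValueError("profile has no decoded states; run viterbi_cnv_states")
    gain, loss = {}, {}
    for chrom in profile.chromosomes:
        idx = profile.chromosome_slice(chrom)
        st = profile.states[:, idx]
        gain[chrom] = (st == STATE_GAIN).mean(axis=1)
        loss[chrom] = (st == STATE_LOSS).mean(axis=1)
    gain_df = pd.DataFrame(gain, index=profile.barcodes)
    loss_df = pd.DataFrame(loss, index=profile.barcodes)
    return gain_df, loss_df


def classify_malignant_cells(
    cell_labels: pd.Series,
    gain_fractions: pd.DataFrame,
    loss_fractions: pd.DataFrame,
    threshold: float = 0.25,
    gain_chromosome: str = "chr7",
    loss_chromosome: str = "chr10",
    candidate_label: str = "malignant-candidate",
) -> pd.Series:
    """Concordance rule combining cluster identity and CNV evidence.

    ================================  ======================  ============
    cluster                            CNV event (>threshold)  call
    ================================  ======================  ============
    malignant-candidate                yes                     malignant
    malignant-candidate                no                      unresolved
    nonmalignant                       yes                     unresolved
    nonmalignant                       no                      nonmalignant
    ================================  ======================  ============

    The CNV event is gain(chr7) > threshold OR loss(chr10) > threshold,
    both strict.
    """
    cells = cell_labels.index
    for df, chrom in ((gain_fractions, gain_chromosome), (loss_fractions, loss_chromosome)):
        if chrom not in df.columns:
            raise KeyError(f"chromosome {chrom!r} missing from fractions")
        missing = cells.difference(df.index)
        if len(missing):
            raise KeyError(f"CNV fractions missing for {len(missing)} cells")
    gain = gain_fractions.loc[cells, gain_chromosome].to_numpy()
    loss = loss_fractions.loc[cells, loss_chromosome].to_numpy()
    if np.isnan(gain).any() or np.isnan(loss).any():
        raise ValueError("CNV fractions contain missing values")
    event = (gain > threshold) | (loss > threshold)
    candidate = (cell_labels == candidate_label).to_numpy()
    call = np.where(
        candidate & event,
        "malignant",
        np.where(~candidate & ~event, "nonmalignant", "unresolved"),
    )
    return pd.Series(call, index=cells, name="malignancy")


def filter_samples_by_malignant_count(
    calls: pd.Series, sample_labels: pd.Series, min_cells: int = 25
) -> list[str]:
    """Samples retained for malignant state analysis (>= min_cells malignant)."""
    labels = sample_labels.reindex(calls.index)
    counts = labels[calls == "malignant"].value_counts()
    all_samples = sorted(labels.dropna().unique())
    return [s for s in all_samples if counts.get(s, 0) >= min_cells]
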