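"""Signature module scoring and malignant cell-state assignment.

A module score is the mean log-normalized expression of a gene set
minus that of expression-matched control genes drawn from average-
expression bins (the AddModuleScore construction). Malignant cells are
scored separately within each tumor sample for the four Neftel
metaprograms (AC-like, MES-like, NPC-like, OPC-like) and the cell-cycle
program; the state call is the argmax over the four state scores, and
cycling status is thresholded independently of state.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "module_score",
    "assign_neftel_state",
    "assign_cycling",
    "score_states_per_sample",
    "sample_state_composition",
    "STATE_ORDER",
    "DEFAULT_CYCLING_THRESHOLD",
]

#: fixed tie-break order for state assignment
STATE_ORDER = ("AC-like", "MES-like", "NPC-like", "OPC-like")
DEFAULT_CYCLING_THRESHOLD = 0.1


def _lognorm(adata) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return np.log1p(X / total * 1e4)


def module_score(
    adata,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    return_controls: bool = False,
):
    """Expression-bin-matched module score per cell.

    Genes are binned into ``n_bins`` equal-size bins by their average
    log-normalized expression across the scored cells; for each
    signature gene, ``n_ctrl`` control genes are drawn from its bin
    (without replacement when the bin is large enough, with replacement
    otherwise). The score is mean(signature) - mean(all drawn controls).

    Parameters
    ----------
    adata
        The cell subset to score (raw counts; normalization is internal,
        so scoring is relative to exactly these cells).
    gene_set
        Signature gene ids; genes absent from the bundle are dropped
        with a warning, and an empty intersection is an error.
    return_controls
        Also return the drawn control genes per signature gene, enabling
        independent recomputation of the score for a fixed draw.
    """
    var_names = pd.Index(adata.var_names)
    present = [g for g in gene_set if g in var_names]
    missing = [g for g in gene_set if g not in var_names]
    if not present:
        raise ValueError(f"no signature genes found in bundle; missing: {missing}")
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from bundle: {missing[:5]}...",
            UserWarning,
            stacklevel=2,
        )

    Xl = _lognorm(adata)
    data_avg = Xl.mean(axis=0)
    order = np.argsort(data_avg, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    n_genes = len(order)
    bins = (rank * n_bins) // n_genes  # equal-count bins 0..n_bins-1
    bin_members = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    col = {g: i for i, g in enumerate(var_names)}
    sig_idx = np.array([col[g] for g in present])

    rng = np.random.default_rng(seed)
    ctrl_draws = {}
    ctrl_idx_all = []
    for g, gi in zip(present, sig_idx):
        members = bin_members[int(bins[gi])]
        if members.size >= n_ctrl:
            draw = rng.choice(members, size=n_ctrl, replace=False)
        else:
            draw = rng.choice(members, size=n_ctrl, replace=True)
        ctrl_draws[g] = var_names.to_numpy()[draw]
        ctrl_idx_all.append(draw)
    ctrl_idx_all = np.concatenate(ctrl_idx_all)

    scores = Xl[:, sig_idx].mean(axis=1) - Xl[:, ctrl_idx_all].mean(axis=1)
    out = pd.Series(scores, index=adata.obs_names, name="module_score")
    if return_controls:
        return out, ctrl_draws
    return out


def assign_neftel_state(
    scores: pd.DataFrame, state_order=STATE_ORDER
) -> tuple[pd.Series, int]:
    """Per-cell state call: argmax over the four state score columns.

    Exact ties are broken by the fixed ``state_order`` and counted;
    the tie count is returned alongside the calls.
    """
    missing = [s for s in state_order if s not in scores.columns]
    if missing:
        raise ValueError(f"missing score columns: {missing}")
    mat = scores[list(state_order)].to_numpy()
    best = mat.max(axis=1, keepdims=True)
    is_best = mat == best
    n_ties = int((is_best.sum(axis=1) > 1).sum())
    if n_ties:
        warnings.warn(
            f"{n_ties} cells with tied top state; fixed order applied",
            UserWarning,
            stacklevel=2,
        )
    calls = np.asarray(state_order)[is_best.argmax(axis=1)]
    return pd.Series(calls, index=scores.index, name="state"), n_ties


def assign_cycling(
    cycle_scores: pd.Series, threshold: float = DEFAULT_CYCLING_THRESHOLD
) -> pd.Series:
    """Cycling iff the cell-cycle module score exceeds the threshold."""
    return (cycle_scores > threshold).rename("cycling")


def score_states_per_sample(
    adata,
    barcodes,
    sample_labels: pd.Series,
    programs: dict[str, list[str]],
    cycle_program: list[str] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score the four state programs (and optionally cell cycle) per sample.

    Cells are scored separately within each tumor sample so scores are
    relative to the sample's own expression distribution. Returns a
    score table indexed by barcode with one column per program.
    """
    barcodes = pd.Index(barcodes)
    labels = sample_labels.reindex(barcodes)
    all_programs = dict(programs)
    if cycle_program is not None:
        all_programs["cell-cycle"] = cycle_program
    pieces = []
    for sample in labels.dropna().unique():
        cells = barcodes[labels == sample]
        sub = adata[cells].copy()
        cols = {
            name: module_score(sub, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
            for name, genes in all_programs.items()
        }
        pieces.append(pd.DataFrame(cols, index=cells))
    return pd.concat(pieces).reindex(barcodes)


def sample_state_composition(
    states: pd.Series,
    cycling: pd.Series,
    sample_labels: pd.Series,
    retained_samples=None,
) -> pd.DataFrame:
    """Per-sample malignant state fractions and cycling fraction.

    State fractions are computed over malignant cells and sum to one per
    sample; the cycling fraction is computed independently over all
    malignant cells of the sample. Samples not in ``retained_samples``
    (when given) are excluded with a warning.
    """
    labels = sample_labels.reindex(states.index)
    rows = []
    for sample in sorted(labels.dropna().unique()):
        if retained_samples is not None and sample not in set(retained_samples):
            warnings.warn(
                f"sample {sample!r} not in retention list; excluded from composition",
                UserWarning,
                stacklevel=2,
            )
            continue
        cells = labels.index[labels == sample]
        st = states.loc[cells]
        row = {"sample": sample, "n_malignant": len(cells)}
        for s in STATE_ORDER:
            row[s] = float((st == s).mean()) if len(cells) else np.nan
        row["cycling"] = float(cycling.loc[cells].mean()) if len(cells) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
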