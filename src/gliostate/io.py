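"""Readers/writers for the standard formats and the pipeline driver.

Count bundles use the 10x layout (Matrix Market ``matrix.mtx`` with
genes as rows, ``features.tsv``, ``barcodes.tsv``, optionally gzipped);
gene sets use GMT; tabular outputs are TSV/CSV. ``run_pipeline``
orchestrates simulate -> qc -> cluster -> cnv -> states -> composition
with per-stage output caching and a hash manifest for determinism
checks.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import cnv as cnv_mod
from . import qc as qc_mod
from . import scoring as scoring_mod
from . import synthetic as syn

__all__ = [
    "read_10x_bundle",
    "write_10x_bundle",
    "read_gmt",
    "write_gmt",
    "write_tables",
    "PipelineConfig",
    "run_pipeline",
]

FEATURE_COLUMNS = ["gene_id", "name", "chromosome", "position", "mito"]

#: nonmalignant cluster labels preferred as the CNV reference
REFERENCE_LABELS = ("oligodendrocytes", "neurons", "myeloid")


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path: Path, name: str) -> Path:
    for cand in (path / name, path / f"{name}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{name}(.gz) not found under {path}")


def read_10x_bundle(path) -> ad.AnnData:
    """Read a 10x-style bundle into a cells x genes AnnData.

    Expects ``matrix.mtx`` (genes x cells, coordinate integer),
    ``features.tsv`` (gene_id, name, chromosome, position, mito) and
    ``barcodes.tsv``, each optionally gzipped.
    """
    path = Path(path)
    mtx_path = _find(path, "matrix.mtx")
    try:
        with _open_maybe_gz(mtx_path, "rb") as fh:
            M = scipy.io.mmread(fh)
    except Exception as exc:  # surface the offending file/line
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    M = sp.csr_matrix(M.T)  # cells x genes

    with _open_maybe_gz(_find(path, "features.tsv")) as fh:
        features = pd.read_csv(fh, sep="\t", header=None, names=FEATURE_COLUMNS)
    with _open_maybe_gz(_find(path, "barcodes.tsv")) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None, names=["barcode"])

    if M.shape[1] != len(features) or M.shape[0] != len(barcodes):
        raise ValueError(
            f"dimension mismatch: matrix is {M.shape[1]} genes x {M.shape[0]} cells "
            f"but features has {len(features)} rows and barcodes {len(barcodes)}"
        )
    features["mito"] = features["mito"].astype(bool)
    var = features.set_index("gene_id")
    obs = barcodes.set_index("barcode")
    # sample label convention: "<sample>-<index>" barcodes
    obs["sample"] = [b.rsplit("-", 1)[0] for b in obs.index]
    return ad.AnnData(X=M.astype(np.int32), obs=obs, var=var)


def write_10x_bundle(adata, path, compress: bool = False) -> None:
    """Write a cells x genes AnnData as a 10x-style bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    with _open_maybe_gz(path / f"matrix.mtx{suffix}", "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(X.T), field="integer")
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "name": adata.var_names,
            "chromosome": adata.var["chromosome"].to_numpy(),
            "position": adata.var["position"].to_numpy(),
            "mito": adata.var["mito"].to_numpy(),
        }
    )
    with _open_maybe_gz(path / f"features.tsv{suffix}", "wt") as fh:
        feats.to_csv(fh, sep="\t", header=False, index=False)
    with _open_maybe_gz(path / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with _open_maybe_gz(Path(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_tables(objects: dict[str, pd.DataFrame], out_dir, overwrite: bool = False) -> list[Path]:
    """Write named DataFrames as CSV with deterministic column order.

    Existing files raise unless ``overwrite`` is set. Returns the paths
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in objects.items():
        p = out_dir / f"{name}.csv"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
        df.to_csv(p, float_format="%.17g")
        paths.append(p)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end run (fully serializable)."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    bundle_path: str | None = None
    truth_path: str | None = None
    sim: dict = field(default_factory=dict)
    qc: dict = field(
        default_factory=lambda: {
            "min_genes": 500,
            "max_genes": 10_000,
            "max_pct_mito": 5.0,
            "expected_doublet_rate": 0.05,
        }
    )
    cluster: dict = field(
        default_factory=lambda: {
            "n_pcs": 30,
            "k_neighbors": 20,
            "resolution": 0.6,
            "n_top_genes": 2000,
        }
    )
    cnv: dict = field(
        default_factory=lambda: {
            "window": 101,
            "means": [-0.2, 0.0, 0.2],
            "sigma": 0.1,
            "stay_prob": 0.9999,
            "threshold": 0.25,
            "min_malignant_cells": 25,
        }
    )
    scoring: dict = field(
        default_factory=lambda: {
            "n_bins": 25,
            "n_ctrl": 100,
            "cycling_threshold": scoring_mod.DEFAULT_CYCLING_THRESHOLD,
        }
    )
    marker_gmt: str | None = None
    program_gmt: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    Stages: simulate (optional) -> qc -> cluster/annotate -> cnv ->
    state scoring -> composition. Each stage's outputs are cached on
    disk; a stage reruns only when its outputs are missing or an
    upstream stage reran. The manifest records the seed, per-file
    sha256 hashes and wall time; a fixed seed yields identical hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.json")
    t0 = time.time()
    ran: list[str] = []
    upstream_changed = False

    # --- stage: simulate / load -------------------------------------------
    truth_path = out / "truth.tsv"
    if config.simulate:
        # the bundle itself stays in memory (deterministic given the seed);
        # truth and gene-set files are the stage's persisted outputs
        sim_cfg = syn.SimConfig(seed=config.seed, **config.sim)
        model = syn.build_genome_model(cnv_chromosomes=tuple(sim_cfg.cnv_spec.keys()))
        adata, truth = syn.simulate_dataset(model, sim_cfg)
        if not truth_path.exists():
            syn.write_truth(truth, truth_path)
            write_gmt(syn.marker_gene_sets(model, sim_cfg), out / "markers.gmt")
            write_gmt(syn.metaprogram_gene_sets(model, sim_cfg), out / "programs.gmt")
            ran.append("simulate")
            upstream_changed = True
        marker_gmt = out / "markers.gmt"
        program_gmt = out / "programs.gmt"
    else:
        if config.bundle_path is None:
            raise ValueError("bundle_path required when simulate is false")
        adata = read_10x_bundle(Path(config.bundle_path))
        marker_gmt = Path(config.marker_gmt)
        program_gmt = Path(config.program_gmt)

    # --- stage: qc ---------------------------------------------------------
    anno_path = out / "cell_annotation.tsv"
    comp_path = out / "composition.csv"
    stage_needed = upstream_changed or not anno_path.exists() or not comp_path.exists()
    if stage_needed:
        qc_tab = qc_mod.compute_qc_metrics(adata)
        doublet = qc_mod.score_doublets(adata, seed=config.seed)
        cutoff = qc_mod.doublet_cutoff_from_rate(
            doublet, config.qc["expected_doublet_rate"]
        )
        kept = qc_mod.apply_qc_filters(
            qc_tab,
            min_genes=config.qc["min_genes"],
            max_genes=config.qc["max_genes"],
            max_pct_mito=config.qc["max_pct_mito"],
            doublet_scores=doublet,
            doublet_cutoff=cutoff,
        )
        sub = adata[kept].copy()

        assignment = qc_mod.cluster_cells(
            sub,
            n_pcs=config.cluster["n_pcs"],
            k_neighbors=config.cluster["k_neighbors"],
            resolution=config.cluster["resolution"],
            n_top_genes=config.cluster["n_top_genes"],
            seed=config.seed,
        )
        marker_sets = read_gmt(marker_gmt)
        if "malignant" in marker_sets and "malignant-candidate" not in marker_sets:
            marker_sets["malignant-candidate"] = marker_sets.pop("malignant")
        assignment = qc_mod.annotate_cell_types(
            assignment, sub, marker_sets, seed=config.seed
        )
        labels = assignment.cell_labels()

        # CNV reference: preferred nonmalignant labels, else lowest-variance cluster
        ref_cells = labels.index[labels.isin(REFERENCE_LABELS)]
        if ref_cells.empty:
            warnings.warn(
                "no preferred reference cell types found; using lowest-variance cluster",
                UserWarning,
            )
            Xl = scoring_mod._lognorm(sub)
            var_by_cluster = {
                cl: Xl[np.flatnonzero((assignment.clusters == cl).to_numpy())].var()
                for cl in assignment.clusters.unique()
            }
            ref_cl = min(var_by_cluster, key=var_by_cluster.get)
            ref_cells = assignment.clusters.index[assignment.clusters == ref_cl]

        profile = cnv_mod.build_cnv_profile(
            sub, ref_cells, window=config.cnv["window"]
        )
        params = cnv_mod.HMMParams(
            means=tuple(config.cnv["means"]),
            sigma=config.cnv["sigma"],
            stay_prob=config.cnv["stay_prob"],
        )
        profile = cnv_mod.viterbi_cnv_states(profile, params)
        gain_df, loss_df = cnv_mod.chromosome_altered_fraction(profile)
        calls = cnv_mod.classify_malignant_cells(
            labels, gain_df, loss_df, threshold=config.cnv["threshold"]
        )
        retained = cnv_mod.filter_samples_by_malignant_count(
            calls, sub.obs["sample"], min_cells=config.cnv["min_malignant_cells"]
        )

        # --- states --------------------------------------------------------
        programs = read_gmt(program_gmt)
        cycle = programs.pop("cell-cycle", None)
        mal_cells = calls.index[calls == "malignant"]
        mal_cells = mal_cells[sub.obs.loc[mal_cells, "sample"].isin(retained)]
        scores = scoring_mod.score_states_per_sample(
            sub,
            mal_cells,
            sub.obs["sample"],
            programs,
            cycle_program=cycle,
            n_bins=config.scoring["n_bins"],
            n_ctrl=config.scoring["n_ctrl"],
            seed=config.seed,
        )
        states, _ = scoring_mod.assign_neftel_state(scores)
        cycling = scoring_mod.assign_cycling(
            scores["cell-cycle"], config.scoring["cycling_threshold"]
        )
        composition = scoring_mod.sample_state_composition(
            states, cycling, sub.obs["sample"], retained_samples=retained
        )

        anno = pd.DataFrame(
            {
                "sample": sub.obs["sample"],
                "cluster": assignment.clusters,
                "cell_type": labels,
                "malignancy": calls,
                "state": states.reindex(sub.obs_names).fillna(""),
                "cycling": cycling.reindex(sub.obs_names).fillna(False),
            },
            index=sub.obs_names,
        )
        anno.index.name = "barcode"
        anno.to_csv(anno_path, sep="\t")
        composition.to_csv(comp_path, float_format="%.12g")
        ran.append("analyze")

    manifest = {
        "seed": config.seed,
        "stages_ran": ran,
        "wall_time_s": round(time.time() - t0, 3),
        "files": {},
    }
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
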