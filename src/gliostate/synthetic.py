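"""Ground-truthed synthetic data for the glioma cell-state pipeline.

Generates (1) multi-sample snRNA-seq count bundles in which malignant cells
carry the hallmark high-grade-glioma arm-level events (chromosome 7 gain,
chromosome 10 loss), express one of the four Neftel metaprograms and may be
cycling, while nonmalignant brain cell types (neurons, oligodendrocytes,
astrocytes, myeloid) are separated by marker programs; (2) paired pre/post
immunohistochemistry percentage tables; (3) per-patient pharmacokinetic
tables for ribociclib and everolimus across CNS compartments.

Counts follow a negative-binomial hierarchy: per-cell library size x
per-gene baseline x cell-type effect x CNV multiplicative shift x
metaprogram shift, with doublets formed as sums of two parent cells'
expectations. Every emitted barcode is recorded in a truth table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeModel",
    "SimConfig",
    "build_genome_model",
    "simulate_dataset",
    "simulate_pkpd_tables",
    "simulate_pseudobulk_experiment",
    "write_truth",
    "read_truth",
    "sample_true_state_fractions",
    "NEFTEL_STATES",
    "NONMALIGNANT_TYPES",
    "DEFAULT_DOSE_ARMS",
]

NEFTEL_STATES = ("AC-like", "MES-like", "NPC-like", "OPC-like")
NONMALIGNANT_TYPES = ("neurons", "oligodendrocytes", "astrocytes", "myeloid")

#: chromosome hosting each synthetic signature block (kept off chr7/chr10 so
#: planted CNV never confounds marker or metaprogram expression)
_MARKER_CHROM = {
    "neurons": "chr1",
    "oligodendrocytes": "chr2",
    "astrocytes": "chr3",
    "myeloid": "chr4",
    "malignant": "chr5",
}
_PROGRAM_CHROM = {
    "AC-like": "chr11",
    "MES-like": "chr12",
    "NPC-like": "chr13",
    "OPC-like": "chr14",
    "cell-cycle": "chr15",
}


@dataclass(frozen=True)
class GenomeModel:
    """Synthetic genome: ordered genes with chromosome, position, mito flag.

    Positions are a uniform grid, strictly increasing within each
    chromosome; mitochondrial genes are appended on ``chrM`` with the
    mito flag set.
    """

    genes: pd.DataFrame  # columns: gene_id, chromosome, position, mito

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.genes["chromosome"]))

    def genes_on(self, chromosome: str) -> np.ndarray:
        """Integer indices of genes on one chromosome, in genomic order."""
        idx = np.flatnonzero(self.genes["chromosome"].to_numpy() == chromosome)
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome!r} absent from genome model")
        return idx


def build_genome_model(
    n_chromosomes: int = 22,
    genes_per_chromosome: int = 250,
    n_mito: int = 13,
    cnv_chromosomes: tuple[str, ...] | None = ("chr7", "chr10"),
) -> GenomeModel:
    """Construct a deterministic synthetic genome model.

    Parameters
    ----------
    n_chromosomes
        Number of autosomes, labelled ``chr1 .. chrN``.
    genes_per_chromosome
        Genes per autosome. Any chromosome named in ``cnv_chromosomes``
        must carry at least 202 genes so that a 101-gene smoothing window
        fits twice.
    n_mito
        Mitochondrial genes, appended on ``chrM`` with the mito flag set.
    cnv_chromosomes
        Chromosome labels that will host planted copy-number events;
        validated against the model.
    """
    labels = [f"chr{i}" for i in range(1, n_chromosomes + 1)]
    if cnv_chromosomes:
        missing = [c for c in cnv_chromosomes if c not in labels]
        if missing:
            raise ValueError(
                f"CNV chromosomes {missing} absent from model with {n_chromosomes} autosomes"
            )
        if genes_per_chromosome < 202:
            raise ValueError(
                "chromosomes carrying planted CNV events need >= 202 genes "
                f"(got genes_per_chromosome={genes_per_chromosome})"
            )
    rows = []
    for chrom in labels:
        for j in range(genes_per_chromosome):
            rows.append((f"{chrom}_g{j:04d}", chrom, (j + 1) * 10_000, False))
    for j in range(n_mito):
        rows.append((f"MT_g{j:02d}", "chrM", (j + 1) * 1_000, True))
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "position", "mito"])
    return GenomeModel(genes=genes)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic snRNA-seq cohort.

    Defaults emulate a six-sample cohort of ~1500 nuclei each, half
    malignant, with chr7 +0.4 / chr10 -0.5 log2 arm-level shifts planted
    in malignant cells only.
    """

    n_samples: int = 6
    cells_per_sample: int = 1500
    malignant_fraction: float = 0.5
    #: chromosome -> (log2 expression shift, fraction of chromosome affected)
    cnv_spec: dict = field(
        default_factory=lambda: {"chr7": (0.4, 1.0), "chr10": (-0.5, 1.0)}
    )
    n_program_genes: int = 100
    program_log2_shift: float = 1.2
    cycling_fraction: float = 0.2
    cycling_log2_shift: float = 1.2
    #: signature (metaprogram + cycle) genes are drawn from the
    #: moderately-to-highly expressed range, as real metaprogram genes are
    signature_baseline_multiplier: float = 4.0
    n_marker_genes: int = 120
    marker_log2_shift: float = 3.0
    doublet_rate: float = 0.05
    mito_beta: tuple[float, float] = (2.0, 60.0)
    libsize_mean: float = 6000.0
    libsize_sigma: float = 0.35
    nb_dispersion: float = 0.5
    state_dirichlet_alpha: float = 8.0
    #: per-batch gene-wise multiplicative noise (log-sd); off by default
    batch_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("malignant_fraction", "cycling_fraction", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for chrom, (_, frac) in self.cnv_spec.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"cnv_spec fraction for {chrom} must be in [0, 1], got {frac}"
                )


def marker_gene_sets(model: GenomeModel, config: SimConfig) -> dict[str, list[str]]:
    """Marker genes per cell-type label (including malignant candidates)."""
    out = {}
    gene_ids = model.genes["gene_id"].to_numpy()
    for label, chrom in _MARKER_CHROM.items():
        idx = model.genes_on(chrom)[: config.n_marker_genes]
        out[label] = list(gene_ids[idx])
    return out


def metaprogram_gene_sets(model: GenomeModel, config: SimConfig) -> dict[str, list[str]]:
    """Neftel-style metaprogram gene sets plus the cell-cycle program."""
    out = {}
    gene_ids = model.genes["gene_id"].to_numpy()
    for program, chrom in _PROGRAM_CHROM.items():
        idx = model.genes_on(chrom)[: config.n_program_genes]
        out[program] = list(gene_ids[idx])
    return out


def _cnv_multipliers(model: GenomeModel, config: SimConfig) -> np.ndarray:
    """Per-gene multiplicative shift applied to malignant cells only."""
    mult = np.ones(model.n_genes)
    for chrom, (log2_shift, frac) in config.cnv_spec.items():
        idx = model.genes_on(chrom)
        n_aff = int(np.ceil(frac * idx.size))
        mult[idx[:n_aff]] = 2.0**log2_shift
    return mult


def simulate_dataset(
    model: GenomeModel, config: SimConfig
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a multi-sample count bundle with per-barcode ground truth.

    Returns
    -------
    adata
        Cells x genes AnnData with raw integer counts (CSR), per-cell
        ``obs['sample']`` labels, and gene annotation
        (``chromosome``, ``position``, ``mito``) in ``.var``.
    truth
        One row per emitted barcode: true cell type, malignancy, Neftel
        state, cycling flag and doublet flag.
    """
    for chrom in config.cnv_spec:
        model.genes_on(chrom)  # raises KeyError if absent

    rng = np.random.default_rng(config.seed)
    n_genes = model.n_genes
    mito_mask = model.genes["mito"].to_numpy()
    gene_ids = model.genes["gene_id"].to_numpy()

    # per-gene baseline relative expression
    baseline = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    sig_idx = np.concatenate(
        [model.genes_on(ch)[: config.n_program_genes] for ch in _PROGRAM_CHROM.values()]
    )
    baseline[sig_idx] *= config.signature_baseline_multiplier
    baseline[mito_mask] = baseline[mito_mask].mean()  # mito budget set per cell

    # cell-type multiplier vectors
    type_mult = {}
    for label, chrom in _MARKER_CHROM.items():
        m = np.ones(n_genes)
        m[model.genes_on(chrom)[: config.n_marker_genes]] = 2.0**config.marker_log2_shift
        cell_type = "malignant" if label == "malignant" else label
        type_mult[cell_type] = m

    cnv_mult = _cnv_multipliers(model, config)
    program_idx = {
        s: model.genes_on(_PROGRAM_CHROM[s])[: config.n_program_genes]
        for s in NEFTEL_STATES
    }
    cycle_idx = model.genes_on(_PROGRAM_CHROM["cell-cycle"])[: config.n_program_genes]

    if config.malignant_fraction == 0.0 and config.cnv_spec:
        warnings.warn(
            "malignant fraction is 0; planted CNV spec has no carrier cells and is ignored",
            UserWarning,
            stacklevel=2,
        )

    X_blocks, obs_rows, truth_rows = [], [], []
    for s in range(config.n_samples):
        sample = f"S{s + 1:02d}"
        n_cells = config.cells_per_sample
        n_doublets = int(round(config.doublet_rate * n_cells))
        n_singlets = n_cells - n_doublets
        n_mal = int(round(config.malignant_fraction * n_singlets))
        n_nonmal = n_singlets - n_mal
        per_type = np.full(len(NONMALIGNANT_TYPES), n_nonmal // len(NONMALIGNANT_TYPES))
        per_type[: n_nonmal % len(NONMALIGNANT_TYPES)] += 1

        cell_types = ["malignant"] * n_mal
        for t, k in zip(NONMALIGNANT_TYPES, per_type):
            cell_types += [t] * int(k)

        state_props = rng.dirichlet(
            np.full(len(NEFTEL_STATES), config.state_dirichlet_alpha)
        )
        states = rng.choice(len(NEFTEL_STATES), size=n_mal, p=state_props)
        cycling = rng.random(n_mal) < config.cycling_fraction

        # expected expression per singlet
        expected = np.empty((n_singlets, n_genes))
        for i, ct in enumerate(cell_types):
            rel = baseline * type_mult[ct]
            if ct == "malignant" and n_mal > 0:
                rel = rel * cnv_mult
                rel = rel.copy()
                rel[program_idx[NEFTEL_STATES[states[i]]]] *= (
                    2.0**config.program_log2_shift
                )
                if cycling[i]:
                    rel[cycle_idx] *= 2.0**config.cycling_log2_shift
            expected[i] = rel
        if config.batch_noise_sigma > 0:
            expected = expected * np.exp(
                rng.normal(0.0, config.batch_noise_sigma, size=n_genes)
            )

        libsize = rng.lognormal(
            np.log(config.libsize_mean), config.libsize_sigma, size=n_singlets
        )
        mito_frac = rng.beta(*config.mito_beta, size=n_singlets)

        # split the per-cell budget between mito and nuclear genes
        nm = ~mito_mask
        nuc = expected[:, nm]
        nuc = nuc / nuc.sum(axis=1, keepdims=True)
        mito = expected[:, mito_mask]
        mito = mito / mito.sum(axis=1, keepdims=True)
        mu = np.empty_like(expected)
        mu[:, nm] = nuc * (libsize * (1 - mito_frac))[:, None]
        mu[:, mito_mask] = mito * (libsize * mito_frac)[:, None]

        if n_doublets > 0:
            parents = rng.integers(0, n_singlets, size=(n_doublets, 2))
            mu_doub = mu[parents[:, 0]] + mu[parents[:, 1]]
            mu = np.vstack([mu, mu_doub])

        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu * config.nb_dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(np.int32)
        X_blocks.append(sp.csr_matrix(counts))

        for i in range(n_cells):
            barcode = f"{sample}-{i:05d}"
            obs_rows.append((barcode, sample))
            if i < n_singlets:
                ct = cell_types[i]
                is_mal = ct == "malignant"
                truth_rows.append(
                    (
                        barcode,
                        sample,
                        ct,
                        is_mal,
                        NEFTEL_STATES[states[i]] if is_mal else "",
                        bool(cycling[i]) if is_mal else False,
                        False,
                    )
                )
            else:
                truth_rows.append((barcode, sample, "doublet", False, "", False, True))

    X = sp.vstack(X_blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["barcode", "sample"]).set_index("barcode")
    var = model.genes.set_index("gene_id")
    var.index = pd.Index(gene_ids, name="gene_id")
    adata = ad.AnnData(X=X, obs=obs, var=var.copy())
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "barcode",
            "sample",
            "cell_type",
            "is_malignant",
            "state",
            "cycling",
            "is_doublet",
        ],
    )
    return adata, truth


def sample_true_state_fractions(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample true Neftel state fractions (over malignant singlets).

    Rows sum to one across the four states; a separate ``cycling``
    column gives the true cycling fraction of malignant cells.
    """
    mal = truth[truth["is_malignant"]]
    rows = []
    for sample, grp in mal.groupby("sample", sort=True):
        fr = {st: float((grp["state"] == st).mean()) for st in NEFTEL_STATES}
        fr["cycling"] = float(grp["cycling"].mean())
        fr["sample"] = sample
        rows.append(fr)
    return pd.DataFrame(rows).set_index("sample")


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV with header; round-trips losslessly."""
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"state": "string"},
        keep_default_na=False,
    )
    for col in ("is_malignant", "cycling", "is_doublet"):
        if df[col].dtype == object or str(df[col].dtype) == "string":
            df[col] = df[col].map({"True": True, "False": False})
        df[col] = df[col].astype(bool)
    df["state"] = df["state"].astype(str)
    return df


# ---------------------------------------------------------------------------
# PK / IHC tables
# ---------------------------------------------------------------------------

COMPARTMENTS = ("enhancing", "non-enhancing", "CSF", "plasma")
IHC_MARKERS = ("Ki-67", "pRb", "pS6", "p4EBP1")

#: (ribociclib mg QD, everolimus mg) arms mirroring the trial design
DEFAULT_DOSE_ARMS = (
    {"ribociclib": 400, "everolimus": 2.5},
    {"ribociclib": 600, "everolimus": 5.0},
    {"ribociclib": 600, "everolimus": 10.0},
    {"ribociclib": 600, "everolimus": 50.0},
    {"ribociclib": 600, "everolimus": 60.0},
    {"ribociclib": 600, "everolimus": 70.0},
)

#: geometric-mean total concentration (nM) and fraction unbound per
#: (drug, compartment), at the reference dose; totals scale linearly in dose
_DEFAULT_PK_PARAMS = {
    # ribociclib geometric means chosen so the 400 mg arm reproduces the
    # trial's regime: unbound non-enhancing ~170 nM and Kp,uu ~ 3
    "ribociclib": {
        "ref_dose": 400.0,
        "fu": {"enhancing": 0.10, "non-enhancing": 0.10, "CSF": 1.0, "plasma": 0.05},
        "total_gm": {
            "enhancing": 4000.0,
            "non-enhancing": 1700.0,
            "CSF": 60.0,
            "plasma": 1050.0,
        },
        "cv": 0.6,
    },
    "everolimus": {
        "ref_dose": 5.0,
        "fu": {"enhancing": 0.002, "non-enhancing": 0.002, "CSF": 1.0, "plasma": 0.25},
        "total_gm": {
            "enhancing": 20.0,
            "non-enhancing": 10.0,
            "CSF": 0.5,
            "plasma": 30.0,
        },
        "cv": 0.6,
    },
}

#: planted mean fractional pre->post decrease per IHC marker (negative =
#: increase), reflecting a CDK4/6-inhibitor response with mTOR escape
_DEFAULT_IHC_DECREASE = {"Ki-67": 0.30, "pRb": 0.10, "pS6": -0.10, "p4EBP1": -0.10}
_DEFAULT_IHC_PRE = {"Ki-67": 25.0, "pRb": 40.0, "pS6": 35.0, "p4EBP1": 30.0}


def simulate_pkpd_tables(
    n_patients: int = 24,
    dose_arms: tuple[dict, ...] = DEFAULT_DOSE_ARMS,
    pk_params: dict | None = None,
    seed: int = 0,
    lloq: float = 0.1,
    force_everolimus_tumor_below_lloq: bool = True,
    ihc_decrease: dict | None = None,
    ihc_noise_sd: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-patient PK rows and a paired pre/post IHC table.

    Each patient contributes one row per drug per compartment with a
    total concentration (lognormal inter-patient variability around the
    arm geometric mean, totals scaling linearly with dose) and a fraction
    unbound. With ``force_everolimus_tumor_below_lloq`` the everolimus
    tumor rows are capped so that unbound = total x fu stays below the
    LLOQ, mirroring the undetectable-unbound-everolimus regime.
    """
    if not dose_arms:
        raise ValueError("dose_arms must be non-empty")
    params = pk_params if pk_params is not None else _DEFAULT_PK_PARAMS
    for drug, p in params.items():
        if any(v < 0 for v in p["total_gm"].values()):
            raise ValueError(f"negative geometric-mean concentration for {drug}")
    rng = np.random.default_rng(seed)

    pk_rows = []
    for i in range(n_patients):
        patient = f"P{i + 1:03d}"
        arm = dose_arms[i % len(dose_arms)]
        for drug, p in params.items():
            dose = arm[drug]
            scale = dose / p["ref_dose"]
            for comp in COMPARTMENTS:
                gm = p["total_gm"][comp] * scale
                cv = p["cv"]
                if cv > 0:
                    sigma = np.sqrt(np.log(1 + cv**2))
                    total = gm * np.exp(rng.normal(0.0, sigma))
                else:
                    total = gm
                fu = p["fu"][comp]
                if (
                    force_everolimus_tumor_below_lloq
                    and drug == "everolimus"
                    and comp in ("enhancing", "non-enhancing")
                    and total * fu >= lloq
                ):
                    total = 0.95 * lloq / fu
                if total < 0:
                    raise ValueError("negative concentration generated")
                pk_rows.append((patient, drug, dose, comp, total, fu, lloq))
    pk = pd.DataFrame(
        pk_rows,
        columns=[
            "patient",
            "drug",
            "dose",
            "compartment",
            "total_nM",
            "fraction_unbound",
            "lloq_nM",
        ],
    )

    decrease = ihc_decrease if ihc_decrease is not None else _DEFAULT_IHC_DECREASE
    ihc_rows = []
    for i in range(n_patients):
        patient = f"P{i + 1:03d}"
        for marker in IHC_MARKERS:
            pre = max(
                0.5, _DEFAULT_IHC_PRE[marker] + rng.normal(0.0, ihc_noise_sd)
            )
            post = pre * (1.0 - decrease.get(marker, 0.0)) + rng.normal(
                0.0, ihc_noise_sd
            )
            post = float(np.clip(post, 0.0, 100.0))
            ihc_rows.append((patient, marker, float(pre), post))
    ihc = pd.DataFrame(ihc_rows, columns=["patient", "marker", "pre_pct", "post_pct"])
    return pk, ihc


# ---------------------------------------------------------------------------
# pseudobulk experiment
# ---------------------------------------------------------------------------


def simulate_pseudobulk_experiment(
    n_genes: int = 2000,
    n_effect_genes: int = 100,
    n_per_arm: int = 3,
    depth: float = 1e6,
    effect_log2fc: float = 1.0,
    replicate_log2_sd: float = 0.2,
    nb_dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Simulate a paired-replicate pseudobulk treatment/control experiment.

    Replicate ``r`` contributes one treated and one control sample sharing
    a replicate-specific gene-wise log2 offset; the first
    ``n_effect_genes`` genes carry a true treatment log2 fold change of
    ±``effect_log2fc``, half up- and half down-regulated (mirroring the
    near-balanced up/down split of real treatment responses, and keeping
    the library composition stable so per-million normalization stays
    unbiased). Returns (counts gene x sample, sample metadata, per-gene
    true log2 fold change).
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    base /= base.sum()
    effect = np.zeros(n_genes)
    half = n_effect_genes // 2
    effect[:half] = effect_log2fc
    effect[half:n_effect_genes] = -effect_log2fc

    cols, meta = {}, []
    for r in range(n_per_arm):
        rep_offset = rng.normal(0.0, replicate_log2_sd, size=n_genes)
        for treat in (0, 1):
            rel = base * 2.0 ** (rep_offset + treat * effect)
            mu = depth * rel / rel.sum()
            if nb_dispersion > 0:
                lam = rng.gamma(1.0 / nb_dispersion, mu * nb_dispersion)
            else:
                lam = mu
            name = f"{'ribo' if treat else 'ctrl'}_rep{r + 1}"
            cols[name] = rng.poisson(lam).astype(np.int64)
            meta.append((name, "ribociclib" if treat else "control", f"rep{r + 1}"))
    counts = pd.DataFrame(cols, index=[f"g{i:05d}" for i in range(n_genes)])
    metadata = pd.DataFrame(meta, columns=["sample", "treatment", "replicate"]).set_index(
        "sample"
    )
    return counts, metadata, effect
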