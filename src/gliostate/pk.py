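"""CNS pharmacokinetic arithmetic and the Phase 1 qualification gate.

Unbound concentration = total x fraction unbound, flagged when the
measurement sits below the assay's lower limit of quantification
(LLOQ). Partition coefficients relate tissue to plasma: Kp on totals,
Kp,uu on unbound concentrations (Kp,uu near 1 indicates free-drug
equilibration across the blood-brain barrier). The qualification gate
requires, per patient, unbound tumor concentrations strictly greater
than 5x the biochemical IC50 for BOTH drugs (ribociclib 40 nM,
everolimus 2 nM) and a > 30% longitudinal decrease in both pRb and pS6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PKRecord",
    "PartitionCoefficients",
    "QualificationResult",
    "unbound_concentration",
    "partition_coefficients",
    "phase1_qualification",
    "summarize_unbound",
    "DEFAULT_IC50_NM",
]

DEFAULT_IC50_NM = {"ribociclib": 40.0, "everolimus": 2.0}
COMPARTMENTS = ("enhancing", "non-enhancing", "CSF", "plasma")


@dataclass(frozen=True)
class PKRecord:
    """One compartment-level measurement for one patient and drug."""

    patient: str
    drug: str
    compartment: str
    total_nM: float
    fraction_unbound: float
    lloq_nM: float = 0.1

    def __post_init__(self):
        if self.total_nM < 0:
            raise ValueError(f"negative total concentration: {self.total_nM}")
        if not 0.0 <= self.fraction_unbound <= 1.0:
            raise ValueError(
                f"fraction unbound outside [0, 1]: {self.fraction_unbound}"
            )


@dataclass(frozen=True)
class PartitionCoefficients:
    """Tissue-to-plasma ratios for total (Kp) and unbound (Kp,uu) drug."""

    kp: float | None
    kp_uu: float | None
    defined: bool


def unbound_concentration(record: PKRecord) -> tuple[float | None, bool]:
    """(unbound nM, below_lloq flag).

    The unbound concentration total x fu is reported only when both the
    total and the resulting unbound value sit at or above the LLOQ;
    otherwise the measurement is flagged below-LLOQ and no numeric value
    is returned.
    """
    unbound = record.total_nM * record.fraction_unbound
    if record.total_nM < record.lloq_nM or unbound < record.lloq_nM:
        return None, True
    return unbound, False


def partition_coefficients(
    tissue: PKRecord, plasma: PKRecord
) -> PartitionCoefficients:
    """Kp = tissue total / plasma total; Kp,uu = tissue unbound / plasma unbound.

    Undefined (flagged) when either side is below LLOQ or the plasma
    term is zero. Requires matching patient and drug, and a plasma
    record in the plasma compartment.
    """
    if plasma.compartment != "plasma":
        raise ValueError(f"plasma argument is in compartment {plasma.compartment!r}")
    if (tissue.patient, tissue.drug) != (plasma.patient, plasma.drug):
        raise ValueError("tissue and plasma records must share patient and drug")
    t_u, t_flag = unbound_concentration(tissue)
    p_u, p_flag = unbound_concentration(plasma)
    if t_flag or p_flag or plasma.total_nM == 0:
        return PartitionCoefficients(kp=None, kp_uu=None, defined=False)
    return PartitionCoefficients(
        kp=tissue.total_nM / plasma.total_nM, kp_uu=t_u / p_u, defined=True
    )


@dataclass(frozen=True)
class QualificationResult:
    """Per-patient Phase 1 gate outcome."""

    patient: str
    pk_pass: dict  # drug -> bool
    pd_pass: bool
    pd_defined: bool
    overall: bool


def _records_from_frame(pk: pd.DataFrame) -> list[PKRecord]:
    return [
        PKRecord(
            patient=row.patient,
            drug=row.drug,
            compartment=row.compartment,
            total_nM=row.total_nM,
            fraction_unbound=row.fraction_unbound,
            lloq_nM=getattr(row, "lloq_nM", 0.1),
        )
        for row in pk.itertuples(index=False)
    ]


def phase1_qualification(
    pk: pd.DataFrame,
    ihc: pd.DataFrame,
    ic50_nM: dict | None = None,
    pk_multiplier: float = 5.0,
    pd_cut_pct: float = 30.0,
    tumor_compartment: str = "non-enhancing",
    pd_markers: tuple[str, str] = ("pRb", "pS6"),
) -> list[QualificationResult]:
    """Apply the Phase 1 expansion gate to every patient.

    pk_pass(drug) iff the unbound tumor concentration is strictly
    greater than ``pk_multiplier`` x IC50 (below-LLOQ measurements
    fail); pd decrease = 100 x (pre - post) / pre per marker, and
    pd_pass iff both markers decrease by strictly more than
    ``pd_cut_pct``; overall = pk_pass for every drug AND pd_pass. A
    zero pre-treatment IHC value leaves the decrease undefined, the
    patient flagged, and overall false.
    """
    ic50 = ic50_nM if ic50_nM is not None else DEFAULT_IC50_NM
    records = _records_from_frame(pk)
    patients = sorted({r.patient for r in records})
    by_key = {(r.patient, r.drug, r.compartment): r for r in records}

    results = []
    for patient in patients:
        pk_pass = {}
        for drug, ic in ic50.items():
            rec = by_key.get((patient, drug, tumor_compartment))
            if rec is None:
                pk_pass[drug] = False
                continue
            unbound, below = unbound_concentration(rec)
            pk_pass[drug] = (not below) and unbound > pk_multiplier * ic

        sub = ihc[ihc["patient"] == patient]
        pd_defined = True
        decreases = {}
        for marker in pd_markers:
            row = sub[sub["marker"] == marker]
            if row.empty:
                pd_defined = False
                continue
            pre = float(row["pre_pct"].iloc[0])
            post = float(row["post_pct"].iloc[0])
            if pre == 0.0:
                pd_defined = False
                continue
            decreases[marker] = 100.0 * (pre - post) / pre
        pd_pass = pd_defined and all(
            decreases.get(m, -np.inf) > pd_cut_pct for m in pd_markers
        )
        overall = pd_pass and all(pk_pass.get(d, False) for d in ic50)
        results.append(
            QualificationResult(
                patient=patient,
                pk_pass=pk_pass,
                pd_pass=pd_pass,
                pd_defined=pd_defined,
                overall=overall,
            )
        )
    return results


def summarize_unbound(
    pk: pd.DataFrame, drug: str, compartment: str
) -> dict:
    """Median and range of unbound concentrations for one drug/compartment.

    Below-LLOQ measurements are excluded from the median and counted
    separately.
    """
    sub = pk[(pk["drug"] == drug) & (pk["compartment"] == compartment)]
    values, n_below = [], 0
    for rec in _records_from_frame(sub):
        unbound, below = unbound_concentration(rec)
        if below:
            n_below += 1
        else:
            values.append(unbound)
    values = np.asarray(values)
    return {
        "n": len(values),
        "n_below_lloq": n_below,
        "median_nM": float(np.median(values)) if len(values) else float("nan"),
        "min_nM": float(values.min()) if len(values) else float("nan"),
        "max_nM": float(values.max()) if len(values) else float("nan"),
    }
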