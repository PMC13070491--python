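"""CNS PK summaries and the Phase 1 qualification gate.

Simulates per-patient PK tables for ribociclib and everolimus across
the four compartments plus paired pre/post IHC, then computes unbound
concentrations, partition coefficients and the qualification gate
(unbound tumor > 5 x IC50 for both drugs AND > 30% decrease in pRb and
pS6).
"""

import numpy as np

from gliostate import pk as pkm
from gliostate import synthetic as syn

pk, ihc = syn.simulate_pkpd_tables(n_patients=24, seed=0)

for drug in ("ribociclib", "everolimus"):
    s = pkm.summarize_unbound(pk, drug, "non-enhancing")
    print(
        f"{drug:>11} unbound, non-enhancing tumor: median "
        f"{s['median_nM']:.1f} nM (n={s['n']}, below LLOQ: {s['n_below_lloq']})"
    )

kpuu = []
for patient, grp in pk[pk["drug"] == "ribociclib"].groupby("patient"):
    plasma = grp[grp["compartment"] == "plasma"].iloc[0]
    tissue = grp[grp["compartment"] == "non-enhancing"].iloc[0]
    pc = pkm.partition_coefficients(
        pkm.PKRecord(patient, "ribociclib", "non-enhancing",
                     tissue["total_nM"], tissue["fraction_unbound"]),
        pkm.PKRecord(patient, "ribociclib", "plasma",
                     plasma["total_nM"], plasma["fraction_unbound"]),
    )
    if pc.defined:
        kpuu.append(pc.kp_uu)
print(f"ribociclib non-enhancing Kp,uu median: {np.median(kpuu):.2f} "
      "(> 1 means free drug accumulates beyond the blood-brain barrier)")

results = pkm.phase1_qualification(pk, ihc)
n_qualify = sum(r.overall for r in results)
print(f"\npatients qualifying for Phase 1: {n_qualify}/{len(results)}")
print("(unbound everolimus in tumor sits below the 0.1 nM LLOQ for every "
      "patient, so the gate fails cohort-wide)")
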