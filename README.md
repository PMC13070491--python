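# gliostate

Malignant cell-state analysis for high-grade glioma single-nucleus
RNA-seq, with the surrounding pharmacology arithmetic of a presurgical
(Phase 0) drug-exposure study.

Recurrent IDH-wildtype glioblastoma is organized into four recurrent
malignant expression programs — NPC-like, OPC-like, AC-like and
MES-like (the Neftel states) — with a cycling subpopulation layered on
top. A Phase 0 design doses patients briefly before a scheduled
resection and asks, from the resected tissue: did the drug reach the
tumor in pharmacologically active (unbound) concentrations, did its
proximal markers move, and did the malignant state distribution shift?
`gliostate` implements that readout end to end and ships a
ground-truthed synthetic data generator so every step is testable
against known answers.

What it computes:

- **Malignancy calling from inferred CNV.** Per-cell relative
  expression tracks (log2 CP10K, reference-centered, clipped, 101-gene
  moving average within chromosome) are Viterbi-decoded with a 3-state
  Gaussian HMM into loss/neutral/gain; cells in a malignant-candidate
  cluster with >25% of chr7 decoded gain and/or >25% of chr10 decoded
  loss are malignant, discordant cells are `unresolved` and excluded.
- **QC and clustering.** Genes-detected bounds (>500, <10 000), ≤5%
  mitochondrial (10% in vitro preset), artificial-nearest-neighbor
  doublet scoring, Louvain clustering at resolution 0.6, marker-based
  cell-type annotation.
- **State and cycling assignment.** AddModuleScore-style
  expression-bin-matched module scores per tumor sample; state =
  argmax of the four Neftel scores; cycling = cell-cycle score > 0.1,
  independent of state; per-sample composition tables (samples with
  <25 malignant cells excluded).
- **Cohort statistics.** Pooled-variance and paired two-sided t-tests,
  Pearson correlation, and a declared-comparison dispatcher for
  treated-vs-standard composition shifts.
- **Pseudobulk DE + GSEA.** Per-sample summed counts; per-gene OLS on
  log2(CPM+1) of `expression ~ treatment + replicate`; BH adjustment;
  strict DE calls (padj < .05, |log2FC| > 1); preranked running-sum
  GSEA with NES and a seeded gene-permutation null.
- **PK/PD qualification.** Unbound = total × f_u with LLOQ flagging,
  Kp = tissue/plasma totals, Kp,uu = unbound analogue, and the Phase 1
  gate: unbound tumor > 5×IC50 for both drugs (ribociclib 40 nM,
  everolimus 2 nM) AND >30% decrease in both pRb and pS6.

## Worked example

```bash
python examples/01_simulate_and_call_malignancy.py
```

```
simulated 1000 cells x 5513 genes
775 cells pass QC (genes>500, <10000; mito<=5%; doublet filter)

call vs truth on singlets (unresolved cells are excluded downstream):
truth         False  True
call
malignant         0    361
nonmalignant    274      0
unresolved      117      3
```

Every planted malignant cell that is called at all is called
malignant, and no nonmalignant cell is: the `malignant` row contains
361 true positives and zero false positives. The 117 nonmalignant cells
in the `unresolved` row are noise-driven spurious arm events that the
concordance rule deliberately quarantines rather than mislabels.

```bash
python examples/05_pk_qualification.py
```

```
 ribociclib unbound, non-enhancing tumor: median 244.8 nM (n=24, below LLOQ: 0)
 everolimus unbound, non-enhancing tumor: median nan nM (n=0, below LLOQ: 24)
ribociclib non-enhancing Kp,uu median: 3.88 (> 1 means free drug accumulates beyond the blood-brain barrier)

patients qualifying for Phase 1: 0/24
```

Ribociclib penetrates the non-enhancing tumor well above its 40 nM
IC50; unbound everolimus is undetectable in tumor for every patient, so
no patient clears the dual-drug gate.

The other examples cover state scoring and composition (`02`), cohort
comparison (`03`), and pseudobulk DE + GSEA (`04`). A thin CLI mirrors
the library (`gliostate simulate|qc|run|compare|dge|gsea|pk`).

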