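# tnfipredict

About 30–40% of rheumatoid arthritis (RA) patients do not respond to TNF
inhibitor (TNFi) biologics, and no routine test predicts who will.  TNFi
molecules do more than neutralize soluble TNF: by binding the transmembrane
precursor tmTNF they trigger *reverse signaling* into the monocyte, which in
some individuals activates the transcription factor Nrf2 and its
anti-oxidative / anti-inflammatory gene program.  `tnfipredict` implements a
pre-treatment assay built on that observation, for rheumatology labs and
method developers: patient monocytes are stimulated ex vivo with the TNFi
about to be prescribed, seven transcripts are quantified by RT-qPCR, and a
deterministic decision rule calls the patient an **activator** (predicted
responder) or **non-activator** (predicted non-responder) before the first
dose is given.

## The method

**Quantitation.** Each gene *g* is measured in treated (T) and untreated (NT)
wells as technical duplicates. Replicates are collapsed by mean Ct over
amplified wells (Ct > 40 = non-amplified), and expression is summarized by
the standard ΔΔCt ratio normalized to GAPDH:

    ratio_g = 2^-[(Ct_g,T - Ct_GAPDH,T) - (Ct_g,NT - Ct_GAPDH,NT)]

**Decision rule.** The measurement CV of these ratios is 0.06, so ratios in
the band (1 − CV, 1 + CV) = (0.94, 1.06) are indistinguishable from "no
change":

1. `CD36 ratio < 0.94` → **non-activator**;
2. `0.94 ≤ CD36 ratio ≤ 1.06` → **uncertain** (repeat the assay);
3. `CD36 ratio > 1.06` → count the evaluable Nrf2 target genes (FBXO30,
   GABARA, HMOX1, LBR, MAFG, OSGIN1) with ratio > 1.06: at least 50% →
   **activator**, otherwise **non-activator**.

**Outcome.** At month 3 the clinical response is classified from DAS28-CRP
with the EULAR grid (Good / Moderate / None; responder = Good or Moderate),
and prediction–outcome concordance is scored per drug class (monoclonal
antibodies vs the soluble receptor etanercept).

A synthetic cohort generator produces Ct-level data with calibrated
replicate noise, amplification dropout, and ground-truth labels, so the
whole pipeline is testable without patient samples.

## Worked example

```
$ tnfipredict reproduce-table2
Concordance (uncertain policy: exclude)
  antibody: n=15 correct=14 wrong=1 uncertain=0 accuracy=93.3%
  soluble_receptor: n=10 correct=2 wrong=6 uncertain=2 accuracy=25.0%
  overall: n=25 correct=16 wrong=7 uncertain=2 accuracy=69.6%
  ...
antibody-arm baseline DAS28: mean 4.82 (IQR 4.15-5.58)
Fisher p (women 9/15 vs 5/10):  0.697
Fisher p (erosion 6/15 vs 6/10): 0.428
```

The packaged 25-patient validation cohort scores 14 of 15 correct
predictions (93.3%) among patients on monoclonal antibodies — the single
miss is a predicted activator who did not respond — while in the
etanercept arm (all of whom responded) the assay carries no predictive
information, with all three uncertain-call policies reported side by side.

A fully synthetic run:

```
$ tnfipredict simulate --n-act 5 --n-nonact 5 --nonact-effect 0.85 \
      --cv 0.06 --dropout 0 --seed 4 --out-dir sim/
$ tnfipredict quantify --ct sim/ct_table.csv --out sim/profiles.csv
$ tnfipredict classify --profiles sim/profiles.csv --out sim/calls.csv
$ tnfipredict evaluate --calls sim/calls.csv --clinical sim/clinical.csv
Concordance (uncertain policy: exclude)
  antibody: n=10 correct=10 wrong=0 uncertain=0 accuracy=100.0%
```

All ten donors recover their generating label: activators were simulated
with a 1.5-fold induction, non-activators with 0.85, both well clear of the
(0.94, 1.06) indecision band at the assay's noise level.

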