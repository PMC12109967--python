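# Methods

## Assay model

The package models a pre-treatment theranostic assay for TNF-inhibitor
(TNFi) response in rheumatoid arthritis.  Freshly purified CD14+ monocytes
are stimulated (or not) for 16 h with the TNFi to be prescribed
(10 µg/mL for the antibody class); CD36 and six Nrf2 target genes
(FBXO30, GABARA, HMOX1, LBR, MAFG, OSGIN1) plus the GAPDH normalizer are
quantified by SYBR-green RT-qPCR in technical duplicate.  The stimulation
metadata are carried as provenance annotations only; computation starts at
the Ct table.

### Relative quantitation

Fold changes use the 2^−ΔΔCt convention with 100% amplification efficiency
assumed — the field standard for SYBR-green relative quantitation.  Technical
replicates are collapsed by **mean Ct** before any ratio is formed (not by
averaging per-replicate ratios): this matches duplicate-averaging practice
and keeps dropout handling per well.  A well with Ct > 40 cycles, or with no
recorded Ct, is non-amplified; a collapsed triplet is non-amplified only
when *no* replicate amplified.  A gene is evaluable in a sample when gene
and normalizer amplified in both conditions.  A sample whose GAPDH failed
in either condition is invalid rather than imputed — without a normalizer
there is no ratio — and is excluded with an explicit reason rather than
silently dropped.

### Decision algorithm

The replicate coefficient of variation of fold-change ratios is SD/mean
(sample SD); the assay's calibrated value is **0.06**, giving the indecision
band (0.94, 1.06) around the no-change ratio 1.  The call is:

* CD36 ratio < 0.94 → non-activator;
* CD36 ratio in [0.94, 1.06] → uncertain (the algorithm's published
  branches use strict inequalities, so band edges resolve to uncertainty);
* CD36 ratio > 1.06 → activator iff ≥ 50% of the *evaluable* Nrf2 genes
  have ratio > 1.06 (a ratio exactly 1.06 is a non-hit), else
  non-activator.  Missing genes leave the denominator; with zero evaluable
  Nrf2 genes the majority rule is undefined and the call stays uncertain.

Replicate runs of the same sample are combined by majority of the decisive
calls; a tie, or all-uncertain, remains uncertain — borderline samples need
more replicates, not a forced call.

### Clinical response

DAS28-CRP at months 0 and 3 map to Good/Moderate/None through the classical
EULAR grid (attained-score cuts 3.2 / 5.1, improvement cuts 1.2 / 0.6),
with responder = Good or Moderate.  All four cut-points and the responder
set are configuration, never hard-coded, because published usage varies
(DAS28-ESR vs -CRP cut-points in particular).  When a clinician-recorded
evolution is present it is the scoring ground truth; the recomputed EULAR
category is a consistency diagnostic.  In the packaged validation cohort
the recomputed categories agree with the recorded evolution on 12 of the
15 antibody-arm rows; the discordant rows (e.g. 5.60→3.17 recorded "−")
are not reconcilable with any single standard grid and are surfaced, not
resolved.

### Concordance scoring

A prediction is correct when activator ∧ responder or non-activator ∧
non-responder.  Uncertain calls are governed by an explicit policy:
`exclude` (default — abstentions leave the denominator), `count_wrong`
(conservative), or `count_correct_if_positive` (an uncertain call leans
activator and scores correct for a responder).  The antibody arm of the
validation cohort contains no uncertain calls, so its 14/15 (93.3%) is
policy-invariant; the etanercept arm is reported under all three policies
because the assay is not informative for that class.

### Statistics

Categorical cohort comparisons use the two-sided Fisher exact test in the
point-probability convention (sum of all same-margin tables no more
probable than the observed one) — the convention that reproduces the
cohort table's printed p-values (0.697, 0.428) — delegated to
`scipy.stats.fisher_exact` and verified in the suite against a full
hypergeometric enumeration for every table with grand total ≤ 30.
Mann–Whitney U is computed from midranks, with an exact two-sided p by
enumeration of all rank assignments for pooled n ≤ 12 (valid under ties)
and a tie-corrected, continuity-corrected normal approximation otherwise;
this is implemented in the package because library exact methods decline
tied data.  Paired comparisons use the paired t-test.  Center/IQR summaries
place quartiles by the (n+1)p order-statistic rule, which reproduces the
printed antibody-arm IQR (4.15–5.58); the rule is configurable.

## Synthetic cohorts

The generator emulates exactly the structure the assay assumes:

* **Baseline expression**: per gene and donor, Ct uniform on 18–32 cycles
  (a plausible window for expressed transcripts in macrophage cDNA).
* **Treatment effect**: a Ct shift of −log2(effect) on the target genes in
  the treated condition only; GAPDH is never moved by treatment, so the
  normalizer stays a normalizer.  Defaults: activators 1.5-fold (a clear
  induction above the band), non-activators 1.0 (no modulation), with 0.85
  available to exercise the low gate.
* **Replicate noise**: independent Gaussian perturbations on the Ct scale —
  qPCR measurement error is approximately normal in cycles.  The per-well
  SD is set analytically so the propagated fold-change CV equals the
  requested `ratio_cv`: a ratio assembled from four replicate-mean Cts is
  lognormal with log-2 SD 2σ/√m (m technical replicates), hence
  σ = √(m·ln(1 + cv²)) / (2 ln 2).  At cv = 0.06 and duplicates this is
  σ ≈ 0.061 cycles; a 10,000-donor run recovers CV 0.060.  The lognormal
  noise leaves the ratio *median* at the configured effect; the mean is
  biased upward by cv²/2 ≈ 0.2%, which is negligible at assay noise levels.
  `ratio_cv = 0` switches noise off for exact zero-noise constructions.
* **Dropout**: each gene × condition pair independently fails amplification
  with probability `dropout_prob` (default 0.05, an order-of-magnitude
  convention for sporadic late-Ct failure); failed wells record a Ct drawn
  in (40, 45].  GAPDH is not exempt — its failure exercises the
  invalid-sample path downstream.
* **Clinical outcomes**: the responder label matches the activation truth
  label with probability `concordance` (default 1.0); DAS28 pairs are then
  drawn inside unambiguous EULAR cells (responders: endpoint in [1, 3],
  improvement in [1.5, 3.5]; non-responders: baseline in [3.5, 7],
  improvement in [−0.5, 0.5]) so the grid reproduces the label exactly.

Not modeled: plate effects, inter-run drift, primer-efficiency differences,
correlated gene–gene biology, or realistic DAS28 trajectories near the
EULAR cell boundaries.  Passing tests therefore demonstrate the pipeline's
correctness and the decision rule's behaviour under calibrated measurement
noise — not the assay's clinical accuracy on real patients, which only the
packaged validation cohort (n = 25) speaks to.

## Numerical and design choices

* Band edges and Nrf2 hits use strict inequalities as published; boundary
  values abstain rather than decide.
* At the assay's own conditions (non-activator center 0.85, CV 0.06) the
  0.94 cut lies ~1.7σ above the center, so a few percent of non-activators
  necessarily fall in the band and abstain.  Recovery is therefore reported
  as accuracy over decisive calls (≥ 99% at 1,000 donors per class)
  together with the wrong-label rate (< 1%); abstention is not an error.
* Problem sizes in the suite — 10,000 donors for CV calibration (tolerance
  10%), 1,000 per class for label recovery, grand total ≤ 30 for the
  Fisher enumeration sweep, a 0.05-spaced DAS28 lattice — were chosen as
  the smallest runs whose Monte-Carlo error is far below the assertion
  tolerances.
* The validation-cohort CSV ships inside the package with a SHA-256 guard
  so fixture drift fails loudly.  Gene-symbol variants (FBX030/FBXO30,
  HMOX-1/HMOX1) and drug-code variants (GOL/GOLI) are normalized on ingest.
* The analysis path contains no randomness; only the generator consumes a
  seed, and identical configs reproduce cohorts byte-for-byte.

## Known limitations

* The validation cohort is small (15 + 10) and single-center; the 93.3%
  antibody-arm concordance carries wide binomial uncertainty.
* The assay is explicitly not informative for the soluble-receptor class
  (etanercept), and the package makes no attempt to rescue it.
* The printed baseline-DAS28 Mann–Whitney p of the source cohort table
  (0.521) is not reproducible from the per-patient scores under standard
  conventions (this package computes 0.637); the statistic is reported but
  never asserted.
* DAS28 is consumed as a composite score; computing it from joint counts
  and CRP is out of scope, as are instrument-specific qPCR export formats
  and primer-efficiency correction.
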