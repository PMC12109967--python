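"""Synthetic qPCR cohorts with the statistical structure the assay assumes.

Each simulated donor gets a baseline Ct per gene (uniform over a plausible
expression window), a treatment effect applied as a Ct shift of
-log2(effect) on the target genes in the treated condition (the GAPDH
normalizer is never moved by treatment), well-level Gaussian Ct noise, and
optional per-gene amplification dropout recorded as Ct > 40.

The Ct noise SD is set analytically from the requested fold-change
coefficient of variation: a ratio assembled from four replicate-mean Cts
is lognormal with log2-scale SD 2*sigma/sqrt(m) (m technical replicates),
so sigma = sqrt(m * ln(1 + cv^2)) / (2 * ln 2) makes the ratio CV equal
``ratio_cv`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import ACTIVATOR, NON_ACTIVATOR
from .clinical import ClinicalRecord
from .config import DEFAULT_PANEL, REFERENCE_GENE, TARGET_GENES

ANTIBODY_DRUGS = ("ADA", "GOLI", "IFX")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    ``effect_size_activator`` / ``effect_size_nonactivator`` are the
    multiplicative treated/untreated fold-change centers applied to CD36
    and the six Nrf2 genes; ``ratio_cv`` the replicate-level CV of those
    ratios (0 switches noise off); ``dropout_prob`` the chance a gene
    fails to amplify in one condition of one sample; ``concordance`` the
    probability the clinical outcome matches the activation truth label.
    """

    n_activators: int = 10
    n_nonactivators: int = 10
    effect_size_activator: float = 1.5
    effect_size_nonactivator: float = 1.0
    ratio_cv: float = 0.06
    dropout_prob: float = 0.05
    n_tech_reps: int = 2
    baseline_ct_range: tuple[float, float] = (18.0, 32.0)
    concordance: float = 1.0
    seed: int = 0
    gene_panel: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.n_activators < 0 or self.n_nonactivators < 0:
            raise ValueError("donor counts must be non-negative")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
        if self.ratio_cv < 0.0:
            raise ValueError("ratio_cv must be non-negative")
        if self.n_tech_reps < 1:
            raise ValueError("need at least one technical replicate")
        if self.effect_size_activator <= 0 or self.effect_size_nonactivator <= 0:
            raise ValueError("effect sizes must be strictly positive")
        lo, hi = self.baseline_ct_range
        if not 0 < lo < hi:
            raise ValueError("baseline_ct_range must be an increasing positive interval")

    @property
    def ct_noise_sd(self) -> float:
        """Per-well Ct SD that propagates to a fold-change CV of ratio_cv."""
        if self.ratio_cv == 0.0:
            return 0.0
        return math.sqrt(self.n_tech_reps * math.log1p(self.ratio_cv**2)) / (2.0 * math.log(2.0))


@dataclass
class SimulatedCohort:
    """Ct table plus ground truth and matching synthetic clinical records."""

    ct_table: pd.DataFrame
    truth_labels: dict[str, str]
    clinical: list[ClinicalRecord] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.truth_labels), "truth_status": list(self.truth_labels.values())}
        )


def _donor_rows(
    sample_id: str, status: str, config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    if status == ACTIVATOR:
        effect = config.effect_size_activator
    elif status == NON_ACTIVATOR:
        effect = config.effect_size_nonactivator
    else:
        raise ValueError(f"status must be {ACTIVATOR!r} or {NON_ACTIVATOR!r}, got {status!r}")
    lo, hi = config.baseline_ct_range
    sd = config.ct_noise_sd
    rows = []
    for gene in config.gene_panel:
        baseline = rng.uniform(lo, hi)
        for condition in ("NT", "T"):
            true_ct = baseline
            if condition == "T" and gene in TARGET_GENES:
                true_ct -= math.log2(effect)
            dropped = rng.random() < config.dropout_prob
            for rep in range(1, config.n_tech_reps + 1):
                if dropped:
                    ct = rng.uniform(40.01, 45.0)
                else:
                    ct = true_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(
                    dict(sample_id=sample_id, condition=condition, gene=gene,
                         replicate=rep, ct=ct)
                )
    return rows


def simulate_donor(status: str, config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Simulate one donor's full Ct table (GAPDH + 7 targets x T/NT x replicates)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(_donor_rows("donor", status, config, rng))


def _synthetic_das28(responder: bool, rng: np.random.Generator) -> tuple[float, float]:
    """DAS28 (M0, M3) pair landing unambiguously in one EULAR cell.

    Responders sit in the Good cell (endpoint <= 3.2, improvement > 1.2);
    non-responders show improvement <= 0.6 from an active baseline.
    """
    if responder:
        m3 = rng.uniform(1.0, 3.0)
        m0 = m3 + rng.uniform(1.5, 3.5)
    else:
        m0 = rng.uniform(3.5, 7.0)
        m3 = m0 - rng.uniform(-0.5, 0.5)
    return round(m0, 2), round(m3, 2)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort: Ct table, truth labels, clinical records.

    Clinical responder status matches the activation truth label with
    probability ``concordance``; DAS28 pairs are drawn so the EULAR grid
    reproduces that responder status.  Deterministic for a fixed config
    (the seed lives in the config).
    """
    n_total = config.n_activators + config.n_nonactivators
    if n_total == 0:
        raise ValueError("cohort must contain at least one donor")
    rng = np.random.default_rng(config.seed)
    statuses = [ACTIVATOR] * config.n_activators + [NON_ACTIVATOR] * config.n_nonactivators
    width = max(3, len(str(n_total)))
    rows: list[dict] = []
    truth: dict[str, str] = {}
    clinical: list[ClinicalRecord] = []
    for i, status in enumerate(statuses, start=1):
        sample_id = f"S{i:0{width}d}"
        truth[sample_id] = status
        rows.extend(_donor_rows(sample_id, status, config, rng))
        concordant = rng.random() < config.concordance
        responder = (status == ACTIVATOR) == concordant
        m0, m3 = _synthetic_das28(responder, rng)
        clinical.append(
            ClinicalRecord(
                patient_id=sample_id,
                drug=ANTIBODY_DRUGS[(i - 1) % len(ANTIBODY_DRUGS)],
                das28_m0=m0,
                das28_m3=m3,
                recorded_evolution="+" if responder else "-",
            )
        )
    return SimulatedCohort(ct_table=pd.DataFrame(rows), truth_labels=truth, clinical=clinical)
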