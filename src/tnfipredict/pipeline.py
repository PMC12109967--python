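"""End-to-end composition: raw Ct wells to a prediction/outcome report.

The analysis path is deterministic — replicate collapse, fold-change
quantitation, activation calling, EULAR response mapping, concordance —
with every per-sample rule decision logged.  Randomness exists only in
the synthetic-data generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classifier import ActivationCall, classify
from .clinical import ClinicalRecord
from .config import PipelineConfig
from .evaluation import EvaluationSummary, concordance, render_summary
from .qpcr import FoldChangeProfile, build_profiles

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline produced, with skipped samples accounted for."""

    profiles: list[FoldChangeProfile]
    calls: list[ActivationCall]
    invalid_samples: dict[str, str]
    summary: EvaluationSummary | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def report(self) -> str:
        lines = [
            f"Samples quantified: {len(self.profiles)}",
            f"Samples classified: {len(self.calls)}",
            f"Samples excluded:  {len(self.invalid_samples)}",
        ]
        for sid, reason in sorted(self.invalid_samples.items()):
            lines.append(f"  excluded {sid}: {reason}")
        for call in self.calls:
            lines.append(f"  {call.sample_id}: {call.status} ({call.rationale})")
        if self.summary is not None:
            lines.append(render_summary(self.summary))
        return "\n".join(lines)


def run_pipeline(
    ct_table: pd.DataFrame,
    clinical: list[ClinicalRecord] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Quantify, classify and (when clinical records are given) score a cohort.

    Samples that cannot be normalized (GAPDH failure, missing condition)
    or classified (CD36 non-evaluable) are excluded with their reason and
    dropped from concordance scoring; the report lists them.
    """
    config = config or PipelineConfig()
    profiles = build_profiles(ct_table, config.non_amplified_ct_cutoff)
    calls: list[ActivationCall] = []
    invalid: dict[str, str] = {}
    for prof in profiles:
        if not prof.valid:
            invalid[prof.sample_id] = prof.invalid_reason or "invalid sample"
            logger.warning("sample %s excluded: %s", prof.sample_id, prof.invalid_reason)
            continue
        if not prof.cd36_evaluable:
            invalid[prof.sample_id] = "CD36 not evaluable"
            logger.warning("sample %s excluded: CD36 not evaluable", prof.sample_id)
            continue
        call = classify(prof, config.band)
        logger.info("sample %s: %s (%s)", call.sample_id, call.status, call.rationale)
        calls.append(call)
    summary = None
    if clinical is not None:
        scored = [r for r in clinical if r.patient_id not in invalid]
        call_map = {c.sample_id: c for c in calls}
        summary = concordance(
            call_map, scored, policy=config.uncertain_policy, grid=config.eular_grid
        )
    return PipelineResult(
        profiles=profiles, calls=calls, invalid_samples=invalid,
        summary=summary, config=config,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write profiles, calls and the text report under ``out_dir``."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "calls": out / "calls.csv",
        "report": out / "report.txt",
    }
    io.write_profiles(result.profiles, paths["profiles"])
    io.write_calls(result.calls, paths["calls"])
    paths["report"].write_text(result.report() + "\n", encoding="utf-8")
    return paths
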