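"""CSV schemas, the packaged validation-cohort fixture, and file round-trips.

All files are UTF-8, comma-separated, dot-decimal.  Schemas:

* Ct table:      sample_id, condition (T/NT), gene, replicate, ct
                 (blank ct = non-amplified well)
* profiles:      sample_id, gene, ratio, evaluable
* calls:         sample_id, status, cd36_ratio, nrf2_hits, n_evaluable, rule_fired
* clinical:      patient_id, drug, drug_class, das28_m0, das28_m3, evolution
                 [, prediction][, truth_status]

The 25-patient validation cohort (15 on monoclonal antibodies, 10 on
etanercept, with DAS28 at months 0 and 3, the baseline activation-status
prediction and the clinician-recorded 3-month evolution) ships as a
versioned CSV guarded by a checksum against silent drift.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .classifier import ACTIVATOR, NON_ACTIVATOR, UNCERTAIN, ActivationCall
from .clinical import ClinicalRecord
from .config import drug_class
from .qpcr import (
    CT_COLUMNS,
    FoldChangeProfile,
    frame_to_profiles,
    profiles_to_frame,
    validate_ct_table,
)

TABLE2_SHA256 = "04ca3ed68bbfe8a4cdb045e66e726049eda160727070e00aed33b9bece0b4661"

PREDICTION_CODES = {"+": ACTIVATOR, "-": NON_ACTIVATOR, "+?": UNCERTAIN, "?": UNCERTAIN}
STATUS_CODES = {v: k for k, v in PREDICTION_CODES.items() if k in ("+", "-", "+?")}


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format Ct CSV."""
    return validate_ct_table(pd.read_csv(path, dtype={"sample_id": str}))


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, CT_COLUMNS].to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[FoldChangeProfile]:
    return frame_to_profiles(pd.read_csv(path, dtype={"sample_id": str, "gene": str}, keep_default_na=False))


def write_profiles(profiles: list[FoldChangeProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def write_calls(calls: list[ActivationCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                sample_id=c.sample_id,
                status=c.status,
                cd36_ratio=c.cd36_ratio,
                nrf2_hits=c.nrf2_hits,
                n_evaluable=c.n_evaluable_nrf2,
                rule_fired=c.rationale,
            )
            for c in calls
        ]
    ).to_csv(path, index=False)


def read_calls(path: str | Path) -> dict[str, str]:
    """Read a calls CSV down to the {sample_id: status} mapping scoring needs."""
    frame = pd.read_csv(path, dtype={"sample_id": str})
    return dict(zip(frame["sample_id"], frame["status"]))


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV into records (evolution column optional)."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    return clinical_from_frame(frame)


def clinical_from_frame(frame: pd.DataFrame) -> list[ClinicalRecord]:
    records = []
    for _, row in frame.iterrows():
        evolution = row.get("evolution")
        if pd.isna(evolution) or evolution == "":
            evolution = None
        rec = ClinicalRecord(
            patient_id=str(row["patient_id"]),
            drug=str(row["drug"]),
            das28_m0=float(row["das28_m0"]),
            das28_m3=float(row["das28_m3"]),
            recorded_evolution=evolution,
        )
        if "drug_class" in frame.columns and str(row["drug_class"]) != rec.drug_class:
            raise ValueError(
                f"{rec.patient_id}: drug_class {row['drug_class']!r} inconsistent with "
                f"drug {rec.drug!r} ({rec.drug_class})"
            )
        records.append(rec)
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path, extra: dict[str, dict] | None = None) -> None:
    """Write records; ``extra`` maps column name -> {patient_id: value}."""
    rows = []
    for rec in records:
        row = dict(
            patient_id=rec.patient_id,
            drug=rec.drug,
            drug_class=rec.drug_class,
            das28_m0=rec.das28_m0,
            das28_m3=rec.das28_m3,
            evolution=rec.recorded_evolution or "",
        )
        for col, mapping in (extra or {}).items():
            row[col] = mapping.get(rec.patient_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _fixture_path() -> Path:
    return Path(str(resources.files("tnfipredict").joinpath("data", "table2.csv")))


def load_table2_fixture() -> tuple[dict[str, str], list[ClinicalRecord]]:
    """Load the packaged 25-patient validation cohort.

    Returns (predictions, records): predictions maps patient_id to an
    activation status (Activator for '+', NonActivator for '-', Uncertain
    for '+?'); records carry drug, DAS28 M0/M3 and the recorded evolution.
    Raises ``ValueError`` if the packaged file fails its checksum.
    """
    path = _fixture_path()
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != TABLE2_SHA256:
        raise ValueError(
            f"packaged validation-cohort fixture is corrupted (sha256 {digest})"
        )
    frame = pd.read_csv(path, dtype={"patient_id": str})
    predictions = {
        str(row["patient_id"]): PREDICTION_CODES[str(row["prediction"])]
        for _, row in frame.iterrows()
    }
    records = clinical_from_frame(frame)
    for rec in records:
        drug_class(rec.drug)
    return predictions, records
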