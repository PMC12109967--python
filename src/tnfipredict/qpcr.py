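"""Relative RT-qPCR quantitation: Ct tables to fold-change profiles.

Raw input is a long-format table of cycle-threshold (Ct) values, one row
per well: ``sample_id, condition (T/NT), gene, replicate, ct``.  Technical
replicates are collapsed by mean Ct over amplified wells, and per-gene
treated/untreated expression ratios are computed with the 2^-ddCt
convention normalized to GAPDH (100% amplification efficiency assumed).
Wells beyond the amplification cutoff (Ct > 40 by default) or without a
recorded Ct count as non-amplified; a gene is evaluable in a sample only
when gene and normalizer amplified in both conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CD36, NRF2_GENES, REFERENCE_GENE, canonical_gene

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame, panel: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Normalize and sanity-check a raw Ct table.

    Gene symbols are mapped to canonical panel spellings; Ct is coerced to
    float with missing/non-amplified markers becoming NaN.  Raises
    ``ValueError`` on structural problems (missing columns, unknown
    conditions, genes outside the panel, non-positive Ct).
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks required columns: {missing}")
    out = table.loc[:, CT_COLUMNS].copy()
    out["gene"] = out["gene"].map(canonical_gene)
    out["condition"] = out["condition"].astype(str).str.upper()
    bad_cond = set(out["condition"]) - {"T", "NT"}
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected T/NT")
    if panel is not None:
        extra = set(out["gene"]) - set(panel)
        if extra:
            raise ValueError(f"genes outside the assay panel: {sorted(extra)}")
    out["ct"] = pd.to_numeric(out["ct"], errors="coerce")
    if (out["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycles")
    return out


def collapse_replicates(
    table: pd.DataFrame, non_amplified_ct_cutoff: float = 40.0
) -> pd.DataFrame:
    """Collapse technical replicates to one mean Ct per sample/condition/gene.

    The mean is taken over amplified wells only (Ct present and <= cutoff);
    ``amplified`` is False when no replicate of the triplet amplified.

    Returns a frame with columns ``sample_id, condition, gene, ct, amplified``.
    """
    if table.empty:
        raise ValueError("empty Ct table")
    t = validate_ct_table(table)
    ok = t["ct"].notna() & (t["ct"] <= non_amplified_ct_cutoff)
    t = t.assign(ct=t["ct"].where(ok))
    grouped = (
        t.groupby(["sample_id", "condition", "gene"], sort=False)["ct"]
        .agg(ct="mean", n_amplified="count")
        .reset_index()
    )
    grouped["amplified"] = grouped["n_amplified"] > 0
    return grouped.drop(columns="n_amplified")


def fold_change(
    ct_gene_t: float, ct_gapdh_t: float, ct_gene_nt: float, ct_gapdh_nt: float
) -> float:
    """Treated/untreated expression ratio by 2^-ddCt, normalized to GAPDH.

    All four Ct inputs must come from amplified wells; NaN anywhere makes
    the ratio undefined and raises ``ValueError``.
    """
    cts = (ct_gene_t, ct_gapdh_t, ct_gene_nt, ct_gapdh_nt)
    if any(c is None or np.isnan(c) for c in cts):
        raise ValueError("fold change undefined: non-amplified Ct among inputs")
    ddct = (ct_gene_t - ct_gapdh_t) - (ct_gene_nt - ct_gapdh_nt)
    return float(2.0 ** (-ddct))


@dataclass
class FoldChangeProfile:
    """Per-sample fold-change ratios for the target genes.

    ``ratios`` holds a ratio only for evaluable genes; ``valid`` is False
    when the sample could not be normalized at all (GAPDH failure or a
    missing condition), with the reason recorded.
    """

    sample_id: str
    ratios: dict[str, float] = field(default_factory=dict)
    evaluable: dict[str, bool] = field(default_factory=dict)
    valid: bool = True
    invalid_reason: str | None = None

    @property
    def cd36_ratio(self) -> float | None:
        return self.ratios.get(CD36)

    @property
    def cd36_evaluable(self) -> bool:
        return self.evaluable.get(CD36, False)

    @property
    def nrf2_ratios(self) -> dict[str, float]:
        return {g: r for g, r in self.ratios.items() if g in NRF2_GENES}

    @property
    def n_evaluable_nrf2(self) -> int:
        return sum(bool(self.evaluable.get(g)) for g in NRF2_GENES)


def build_profiles(
    table: pd.DataFrame, non_amplified_ct_cutoff: float = 40.0
) -> list[FoldChangeProfile]:
    """Compute one FoldChangeProfile per sample in a raw Ct table.

    Samples whose GAPDH failed to amplify in either condition, or that lack
    a condition entirely, are returned invalid with an explicit reason so
    cohorts keep their full roster through the pipeline.
    """
    if table.empty:
        logger.warning("build_profiles called on an empty Ct table")
        return []
    collapsed = collapse_replicates(table, non_amplified_ct_cutoff)
    # wide layout (one row per sample) keeps large simulated cohorts cheap
    ct_wide = collapsed.pivot(index="sample_id", columns=["condition", "gene"], values="ct")
    amp_wide = (
        collapsed.pivot(index="sample_id", columns=["condition", "gene"], values="amplified")
        .fillna(False)
        .astype(bool)
    )
    genes = sorted({g for _, g in ct_wide.columns} - {REFERENCE_GENE})
    sample_order = collapsed["sample_id"].drop_duplicates()
    conditions_seen = collapsed.groupby("sample_id")["condition"].agg(frozenset)

    profiles: list[FoldChangeProfile] = []
    for sample_id in sample_order:
        seen = conditions_seen[sample_id]
        if seen != {"T", "NT"}:
            missing = sorted({"T", "NT"} - set(seen))
            profiles.append(
                FoldChangeProfile(
                    sample_id=str(sample_id),
                    valid=False,
                    invalid_reason=f"missing condition(s): {missing}",
                )
            )
            continue
        ct = ct_wide.loc[sample_id]
        amp = amp_wide.loc[sample_id]

        def ok(cond: str, gene: str) -> bool:
            return bool(amp.get((cond, gene), False))

        if not (ok("T", REFERENCE_GENE) and ok("NT", REFERENCE_GENE)):
            profiles.append(
                FoldChangeProfile(
                    sample_id=str(sample_id),
                    valid=False,
                    invalid_reason="GAPDH not amplified; sample cannot be normalized",
                )
            )
            continue
        gap_t = float(ct[("T", REFERENCE_GENE)])
        gap_nt = float(ct[("NT", REFERENCE_GENE)])
        prof = FoldChangeProfile(sample_id=str(sample_id))
        for gene in genes:
            if ok("T", gene) and ok("NT", gene):
                prof.ratios[gene] = fold_change(
                    float(ct[("T", gene)]), gap_t, float(ct[("NT", gene)]), gap_nt
                )
                prof.evaluable[gene] = True
            else:
                prof.evaluable[gene] = False
        profiles.append(prof)
    return profiles


def profiles_to_frame(profiles: list[FoldChangeProfile]) -> pd.DataFrame:
    """Long-format view of profiles: sample_id, gene, ratio, evaluable."""
    rows = []
    for p in profiles:
        if not p.valid:
            rows.append(
                dict(sample_id=p.sample_id, gene="", ratio=np.nan, evaluable=False)
            )
            continue
        for gene, ok in p.evaluable.items():
            rows.append(
                dict(
                    sample_id=p.sample_id,
                    gene=gene,
                    ratio=p.ratios.get(gene, np.nan),
                    evaluable=ok,
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ratio", "evaluable"])


def frame_to_profiles(frame: pd.DataFrame) -> list[FoldChangeProfile]:
    """Inverse of :func:`profiles_to_frame` (invalid samples round-trip as such)."""
    profiles = []
    for sample_id, sub in frame.groupby("sample_id", sort=False):
        genes = [g for g in sub["gene"] if g]
        if not genes:
            profiles.append(
                FoldChangeProfile(
                    sample_id=str(sample_id), valid=False, invalid_reason="invalid on write"
                )
            )
            continue
        prof = FoldChangeProfile(sample_id=str(sample_id))
        for _, row in sub.iterrows():
            gene = canonical_gene(row["gene"])
            ok = bool(row["evaluable"])
            prof.evaluable[gene] = ok
            if ok:
                prof.ratios[gene] = float(row["ratio"])
        profiles.append(prof)
    return profiles


def coefficient_of_variation(ratios) -> float:
    """Sample coefficient of variation, SD / mean (SD with n-1 denominator)."""
    values = np.asarray(list(ratios), dtype=float)
    if values.size < 2:
        raise ValueError("CV requires at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def cv_band(cv: float) -> tuple[float, float]:
    """Indecision band (1 - cv, 1 + cv) around a no-change ratio of 1."""
    if not 0.0 < cv < 1.0:
        raise ValueError("cv must lie strictly between 0 and 1")
    return (1.0 - cv, 1.0 + cv)
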