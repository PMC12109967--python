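"""Pipeline configuration: gene panel, thresholds, EULAR grid parameters.

The assay panel is GAPDH (normalizer), CD36 (scavenger receptor, the
gating gene of the decision algorithm) and six Nrf2 target genes.  All
thresholds live here so the analysis path itself is parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

REFERENCE_GENE = "GAPDH"
CD36 = "CD36"
NRF2_GENES: tuple[str, ...] = ("FBXO30", "GABARA", "HMOX1", "LBR", "MAFG", "OSGIN1")
TARGET_GENES: tuple[str, ...] = (CD36,) + NRF2_GENES
DEFAULT_PANEL: tuple[str, ...] = (REFERENCE_GENE,) + TARGET_GENES

# Published gene symbols vary in spelling across sources (zero vs letter O,
# hyphenation); normalize on ingest.
GENE_ALIASES: dict[str, str] = {
    "FBX030": "FBXO30",
    "FBX30": "FBXO30",
    "HMOX-1": "HMOX1",
    "HMOX_1": "HMOX1",
    "GABARAPL1": "GABARA",
}

DRUG_CLASSES: dict[str, str] = {
    "ADA": "antibody",          # adalimumab
    "GOLI": "antibody",         # golimumab
    "GOL": "antibody",
    "IFX": "antibody",          # infliximab
    "CZP": "antibody",          # certolizumab pegol (Fab')
    "ETA": "soluble_receptor",  # etanercept
}

CONDITIONS = ("T", "NT")  # treated / untreated


def canonical_gene(name: str) -> str:
    """Map a gene symbol (any capitalisation, known alias) to its panel symbol."""
    up = str(name).strip().upper()
    return GENE_ALIASES.get(up, up)


def drug_class(drug: str) -> str:
    """Return the TNFi class (``antibody`` or ``soluble_receptor``) for a drug code."""
    code = str(drug).strip().upper()
    try:
        return DRUG_CLASSES[code]
    except KeyError:
        raise ValueError(f"unknown TNFi drug code: {drug!r}") from None


@dataclass(frozen=True)
class EularGrid:
    """Cut-points of the EULAR DAS28 response grid.

    The classical grid: a *good* response requires an attained DAS28 <= 3.2
    together with an improvement > 1.2; *no* response is an improvement
    <= 0.6, or <= 1.2 with an attained score still > 5.1; everything else is
    *moderate*.  Responder status is membership of ``responder_set``.
    """

    good_endpoint_max: float = 3.2
    moderate_endpoint_max: float = 5.1
    major_improvement_min: float = 1.2
    minor_improvement_min: float = 0.6
    responder_set: frozenset[str] = frozenset({"Good", "Moderate"})

    def __post_init__(self) -> None:
        if not self.minor_improvement_min < self.major_improvement_min:
            raise ValueError("minor improvement cut must lie below the major cut")
        if not self.good_endpoint_max < self.moderate_endpoint_max:
            raise ValueError("good endpoint cut must lie below the moderate cut")
        if not self.responder_set <= {"Good", "Moderate"}:
            raise ValueError("responder_set may only contain 'Good' and 'Moderate'")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings.

    ``cv`` is the replicate coefficient of variation of treated/untreated
    fold-change ratios; the indecision band around a ratio of 1 is
    ``(1 - cv, 1 + cv)``.  ``stimulation`` carries assay provenance (drug,
    dose, duration) and is never consumed by computation.
    """

    cv: float = 0.06
    non_amplified_ct_cutoff: float = 40.0
    gene_panel: tuple[str, ...] = DEFAULT_PANEL
    eular_grid: EularGrid = field(default_factory=EularGrid)
    uncertain_policy: str = "exclude"
    percentile_method: str = "weibull"  # the (n+1)p order-statistic rule
    stimulation: tuple[tuple[str, str], ...] = (
        ("dose", "10 ug/mL"),
        ("duration", "16 h"),
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.cv < 1.0:
            raise ValueError("cv must lie strictly between 0 and 1")
        if self.non_amplified_ct_cutoff <= 0:
            raise ValueError("non-amplified Ct cutoff must be positive")
        panel = tuple(canonical_gene(g) for g in self.gene_panel)
        if len(set(panel)) != len(panel):
            raise ValueError("gene panel contains duplicates")
        if REFERENCE_GENE not in panel:
            raise ValueError(f"gene panel must include the normalizer {REFERENCE_GENE}")
        object.__setattr__(self, "gene_panel", panel)
        if self.uncertain_policy not in (
            "exclude",
            "count_wrong",
            "count_correct_if_positive",
        ):
            raise ValueError(f"unknown uncertain_policy: {self.uncertain_policy!r}")

    @property
    def band(self) -> tuple[float, float]:
        return (1.0 - self.cv, 1.0 + self.cv)

    def with_cv(self, cv: float) -> "PipelineConfig":
        return replace(self, cv=cv)
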