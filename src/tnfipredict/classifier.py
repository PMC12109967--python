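"""Activator / non-activator decision algorithm.

The call is a two-stage rule on GAPDH-normalized treated/untreated ratios.
Stage 1 gates on CD36: a ratio below the lower band edge (0.94 at the
default CV of 0.06) is a non-activator; a ratio inside the band is
indistinguishable from no change and stays uncertain.  Stage 2, entered
only when CD36 exceeds the upper edge, counts the evaluable Nrf2 target
genes whose ratio exceeds the upper edge: the donor is an activator when
at least half of them do, otherwise a non-activator.  Band edges resolve
to uncertainty (CD36) or to a non-hit (Nrf2 genes): the printed rules use
strict inequalities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .config import NRF2_GENES
from .qpcr import FoldChangeProfile

ACTIVATOR = "Activator"
NON_ACTIVATOR = "NonActivator"
UNCERTAIN = "Uncertain"
STATUSES = (ACTIVATOR, NON_ACTIVATOR, UNCERTAIN)


@dataclass(frozen=True)
class ActivationCall:
    """Classifier output with the evidence that produced it."""

    sample_id: str
    status: str
    cd36_ratio: float
    nrf2_hits: int
    n_evaluable_nrf2: int
    band: tuple[float, float]
    rationale: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


class UnclassifiableSampleError(ValueError):
    """Raised when a profile cannot legally enter the decision algorithm."""


def classify(profile: FoldChangeProfile, band: tuple[float, float]) -> ActivationCall:
    """Apply the CD36 gate + Nrf2 majority rule to one fold-change profile.

    Refuses profiles whose CD36 ratio is non-evaluable (the gate has
    nothing to act on) and invalid samples.  With CD36 above the band but
    zero evaluable Nrf2 genes the majority rule is undefined on an empty
    set, so the call is Uncertain.
    """
    lower, upper = band
    if not lower < 1.0 < upper:
        raise ValueError(f"band must straddle 1: {band}")
    if not profile.valid:
        raise UnclassifiableSampleError(
            f"sample {profile.sample_id}: {profile.invalid_reason}"
        )
    if not profile.cd36_evaluable:
        raise UnclassifiableSampleError(
            f"sample {profile.sample_id}: CD36 not evaluable, classification refused"
        )
    cd36 = profile.cd36_ratio
    nrf2 = {g: r for g, r in profile.ratios.items() if g in NRF2_GENES}
    n_eval = profile.n_evaluable_nrf2
    hits = sum(1 for r in nrf2.values() if r > upper)

    if cd36 < lower:
        status, why = NON_ACTIVATOR, f"CD36 ratio {cd36:.4g} < {lower:g}"
    elif cd36 <= upper:
        status, why = UNCERTAIN, f"CD36 ratio {cd36:.4g} within band [{lower:g}, {upper:g}]"
    elif n_eval == 0:
        status, why = UNCERTAIN, "CD36 above band but no evaluable Nrf2 genes"
    elif hits / n_eval >= 0.5:
        status, why = ACTIVATOR, (
            f"CD36 ratio {cd36:.4g} > {upper:g} and {hits}/{n_eval} Nrf2 genes > {upper:g}"
        )
    else:
        status, why = NON_ACTIVATOR, (
            f"CD36 ratio {cd36:.4g} > {upper:g} but only {hits}/{n_eval} Nrf2 genes > {upper:g}"
        )
    return ActivationCall(
        sample_id=profile.sample_id,
        status=status,
        cd36_ratio=float(cd36),
        nrf2_hits=hits,
        n_evaluable_nrf2=n_eval,
        band=(float(lower), float(upper)),
        rationale=why,
    )


def classify_with_replicates(calls: list[ActivationCall]) -> ActivationCall:
    """Consensus call across replicate runs of the same sample.

    Decisive (non-Uncertain) calls vote; a strict majority wins and
    resolves any Uncertain replicates.  A tie between decisive calls, or
    all replicates Uncertain, leaves the sample Uncertain — borderline
    measurements need more replicates, not a coin flip.
    """
    if not calls:
        raise ValueError("no calls to form a consensus from")
    ids = {c.sample_id for c in calls}
    if len(ids) != 1:
        raise ValueError(f"calls mix samples: {sorted(ids)}")
    decisive = [c for c in calls if c.status != UNCERTAIN]
    if not decisive:
        status, why = UNCERTAIN, f"all {len(calls)} replicate calls uncertain"
    else:
        counts = Counter(c.status for c in decisive)
        (top, n_top), *rest = counts.most_common()
        if rest and rest[0][1] == n_top:
            status, why = UNCERTAIN, f"replicates tied: {dict(counts)}"
        else:
            status, why = top, f"majority of decisive replicates: {dict(counts)}"
    template = max(decisive, default=calls[0], key=lambda c: c.status == status)
    return ActivationCall(
        sample_id=template.sample_id,
        status=status,
        cd36_ratio=template.cd36_ratio,
        nrf2_hits=template.nrf2_hits,
        n_evaluable_nrf2=template.n_evaluable_nrf2,
        band=template.band,
        rationale=f"consensus of {len(calls)} replicates: {why}",
    )
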