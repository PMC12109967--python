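"""Prediction scoring and cohort statistics.

Concordance compares the baseline activation call (the prediction) with
the 3-month clinical outcome: an Activator predicting a responder or a
NonActivator predicting a non-responder is correct.  Uncertain calls are
handled by an explicit policy because borderline assays do occur; the
default excludes them from the accuracy denominator.

The statistical helpers mirror routine two-group cohort comparisons:
two-sided Fisher exact test (point-probability method), Mann-Whitney U
with an exact small-sample branch, paired t-test, and center/IQR
summaries with the (n+1)p percentile convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifier import ACTIVATOR, NON_ACTIVATOR, UNCERTAIN, ActivationCall
from .clinical import ClinicalRecord, record_response
from .config import EularGrid

UNCERTAIN_POLICIES = ("exclude", "count_wrong", "count_correct_if_positive")


@dataclass(frozen=True)
class ClassSummary:
    """Concordance counts and accuracy for one patient group."""

    n: int
    n_correct: int
    n_wrong: int
    n_uncertain: int
    n_uncertain_responder: int
    accuracy: float | None  # percent, None when the denominator is empty

    def __post_init__(self) -> None:
        if self.n_correct + self.n_wrong + self.n_uncertain != self.n:
            raise ValueError("concordance counts do not add up")


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-drug-class and overall prediction/outcome concordance."""

    per_class: dict[str, ClassSummary]
    overall: ClassSummary
    confusion: dict[str, int]
    uncertain_policy: str


def _accuracy(
    n: int, correct: int, wrong: int, uncertain: int, uncertain_resp: int, policy: str
) -> float | None:
    if policy == "exclude":
        denom = correct + wrong
        return 100.0 * correct / denom if denom else None
    if policy == "count_wrong":
        return 100.0 * correct / n if n else None
    # count_correct_if_positive: an uncertain call leans activator ("+?"),
    # so it scores correct exactly when the patient responded
    return 100.0 * (correct + uncertain_resp) / n if n else None


def _summarize(rows: list[tuple[str, bool]], policy: str) -> ClassSummary:
    correct = sum(1 for s, r in rows if (s == ACTIVATOR and r) or (s == NON_ACTIVATOR and not r))
    uncertain = sum(1 for s, _ in rows if s == UNCERTAIN)
    uncertain_resp = sum(1 for s, r in rows if s == UNCERTAIN and r)
    n = len(rows)
    wrong = n - correct - uncertain
    return ClassSummary(
        n=n,
        n_correct=correct,
        n_wrong=wrong,
        n_uncertain=uncertain,
        n_uncertain_responder=uncertain_resp,
        accuracy=_accuracy(n, correct, wrong, uncertain, uncertain_resp, policy),
    )


def concordance(
    calls: dict[str, str | ActivationCall],
    clinical: list[ClinicalRecord],
    policy: str = "exclude",
    grid: EularGrid | None = None,
) -> EvaluationSummary:
    """Score activation-status predictions against clinical response.

    ``calls`` maps patient_id to an ActivationCall or a bare status string;
    every patient must appear in both tables.  Accuracy is reported overall
    and per drug class (antibody vs soluble receptor), as a percentage.
    """
    if policy not in UNCERTAIN_POLICIES:
        raise ValueError(f"unknown uncertain policy {policy!r}")
    statuses = {
        pid: (c.status if isinstance(c, ActivationCall) else str(c))
        for pid, c in calls.items()
    }
    record_ids = {r.patient_id for r in clinical}
    orphans = sorted(set(statuses) ^ record_ids)
    if orphans:
        raise ValueError(f"patients present in only one table: {orphans}")
    bad = {s for s in statuses.values() if s not in (ACTIVATOR, NON_ACTIVATOR, UNCERTAIN)}
    if bad:
        raise ValueError(f"unknown activation statuses: {sorted(bad)}")

    rows_by_class: dict[str, list[tuple[str, bool]]] = {}
    all_rows: list[tuple[str, bool]] = []
    conf = {
        "activator_responder": 0,
        "activator_nonresponder": 0,
        "nonactivator_responder": 0,
        "nonactivator_nonresponder": 0,
        "uncertain_responder": 0,
        "uncertain_nonresponder": 0,
    }
    for rec in sorted(clinical, key=lambda r: r.patient_id):
        status = statuses[rec.patient_id]
        responder = record_response(rec, grid)
        row = (status, responder)
        rows_by_class.setdefault(rec.drug_class, []).append(row)
        all_rows.append(row)
        key = {ACTIVATOR: "activator", NON_ACTIVATOR: "nonactivator", UNCERTAIN: "uncertain"}[status]
        conf[f"{key}_{'responder' if responder else 'nonresponder'}"] += 1

    return EvaluationSummary(
        per_class={k: _summarize(v, policy) for k, v in sorted(rows_by_class.items())},
        overall=_summarize(all_rows, policy),
        confusion=conf,
        uncertain_policy=policy,
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability convention: sum the hypergeometric probabilities of
    every table with the observed margins that is no more probable than
    the observed one.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError("counts must be non-negative integers")
    if sum(counts) == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney_u(group_a, group_b, exact_limit: int = 12) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-sided p-value.

    For pooled sizes up to ``exact_limit`` the null distribution of U is
    enumerated over every assignment of the pooled midranks, so ties are
    handled exactly; larger samples use the normal approximation with the
    usual tie-corrected variance and a 0.5 continuity correction.
    Returns (U of group_a, p).
    """
    x = np.asarray(list(group_a), dtype=float)
    y = np.asarray(list(group_b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = x.size, y.size
    n = n_a + n_b
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mu = n_a * n_b / 2.0

    if n <= exact_limit:
        obs_dev = abs(u_obs - mu)
        total = math.comb(n, n_a)
        extreme = 0
        for combo in itertools.combinations(range(n), n_a):
            u = _u_statistic(ranks[list(combo)], n_a)
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return u_obs, extreme / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 == 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return u_obs, float(2.0 * stats.norm.sf(max(z, 0.0)))


def paired_t_test(treated, untreated) -> tuple[float, float]:
    """Paired two-sided t-test on treated-minus-untreated differences."""
    x = np.asarray(list(treated), dtype=float)
    y = np.asarray(list(untreated), dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if np.allclose(x - y, (x - y)[0]):
        raise ValueError("zero variance of differences; t statistic undefined")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def group_summary(
    values, kind: str = "mean", percentile_method: str = "weibull"
) -> tuple[float, tuple[float, float]]:
    """Center and interquartile range of a cohort variable.

    ``kind`` is 'mean' or 'median'; quartiles use the (n+1)p order-statistic
    rule by default (numpy's 'weibull' method), configurable.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if kind == "mean":
        center = float(v.mean())
    elif kind == "median":
        center = float(np.median(v))
    else:
        raise ValueError(f"unknown center kind {kind!r}")
    q25, q75 = np.percentile(v, [25, 75], method=percentile_method)
    return center, (float(q25), float(q75))


@dataclass
class GroupComparison:
    """One row of a cohort characteristics table."""

    variable: str
    group_values: dict[str, str]
    statistic: float | None
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def render_summary(summary: EvaluationSummary) -> str:
    """Plain-text report of an EvaluationSummary."""
    lines = [f"Concordance (uncertain policy: {summary.uncertain_policy})"]
    for name, cls in list(summary.per_class.items()) + [("overall", summary.overall)]:
        acc = "n/a" if cls.accuracy is None else f"{cls.accuracy:.1f}%"
        lines.append(
            f"  {name}: n={cls.n} correct={cls.n_correct} wrong={cls.n_wrong} "
            f"uncertain={cls.n_uncertain} accuracy={acc}"
        )
    lines.append("  confusion: " + ", ".join(f"{k}={v}" for k, v in summary.confusion.items()))
    return "\n".join(lines)
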