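"""Concordance scoring and the cohort statistics toolbox."""

import itertools
import random

import numpy as np
import pytest
from scipy import stats

from oracles import fisher_enumeration, mann_whitney_permutation
from tnfipredict.clinical import ClinicalRecord
from tnfipredict.evaluation import (
    concordance,
    fisher_exact_two_sided,
    group_summary,
    mann_whitney_u,
    paired_t_test,
)

M0_ANTIBODY = [5.09, 4.50, 5.40, 4.58, 3.78, 4.79, 7.10, 4.15, 4.39, 6.02, 5.60, 2.62, 3.78, 4.92, 5.58]
M0_ETA = [3.72, 5.88, 4.55, 4.64, 5.12, 3.55, 4.63, 6.03, 3.97, 4.18]


# --- concordance ----------------------------------------------------------

def test_validation_cohort_antibody_concordance(table2):
    predictions, records = table2
    summary = concordance(predictions, records)
    ab = summary.per_class["antibody"]
    assert (ab.n, ab.n_correct, ab.n_wrong, ab.n_uncertain) == (15, 14, 1, 0)
    assert ab.accuracy == pytest.approx(93.3, abs=0.05)


def test_antibody_accuracy_invariant_to_uncertain_policy(table2):
    """No uncertain calls in the antibody arm, so every policy agrees."""
    predictions, records = table2
    for policy in ("exclude", "count_wrong", "count_correct_if_positive"):
        ab = concordance(predictions, records, policy).per_class["antibody"]
        assert ab.accuracy == pytest.approx(100 * 14 / 15)


def test_uncertain_policies_differ_on_eta_arm(table2):
    predictions, records = table2
    eta = {p: concordance(predictions, records, p).per_class["soluble_receptor"]
           for p in ("exclude", "count_wrong", "count_correct_if_positive")}
    # 10 ETA patients, all responders: 2 activator calls correct, 6 non-activator
    # calls wrong, 2 uncertain
    assert eta["exclude"].accuracy == pytest.approx(100 * 2 / 8)
    assert eta["count_wrong"].accuracy == pytest.approx(100 * 2 / 10)
    assert eta["count_correct_if_positive"].accuracy == pytest.approx(100 * 4 / 10)


def test_inverted_predictions_score_complement(table2):
    predictions, records = table2
    flip = {"Activator": "NonActivator", "NonActivator": "Activator", "Uncertain": "Uncertain"}
    inverted = {pid: flip[s] for pid, s in predictions.items()}
    ab = concordance(inverted, records).per_class["antibody"]
    assert (ab.n_correct, ab.n_wrong) == (1, 14)


def test_concordance_order_invariance_and_count_additivity(table2):
    predictions, records = table2
    rng = random.Random(0)
    shuffled = records[:]
    rng.shuffle(shuffled)
    a = concordance(predictions, records)
    b = concordance(predictions, shuffled)
    assert a == b
    per_class_n = sum(c.n for c in a.per_class.values())
    assert per_class_n == a.overall.n == 25
    assert a.overall.n_correct == sum(c.n_correct for c in a.per_class.values())


def test_concordance_reports_orphans():
    records = [ClinicalRecord("p1", "ADA", 4.0, 2.0, "+")]
    with pytest.raises(ValueError, match="p2"):
        concordance({"p2": "Activator"}, records)


def test_all_match_synthetic_cohort_scores_100():
    records = [
        ClinicalRecord(f"p{i}", "ADA", 5.0, 2.0 if i % 2 else 5.0, "+" if i % 2 else "-")
        for i in range(10)
    ]
    calls = {f"p{i}": "Activator" if i % 2 else "NonActivator" for i in range(10)}
    assert concordance(calls, records).overall.accuracy == 100.0


# --- Fisher exact ---------------------------------------------------------

@pytest.mark.parametrize(
    "table, expected",
    [
        ((9, 6, 5, 5), 0.697),
        ((6, 9, 6, 4), 0.428),
        ((0, 7, 0, 5), 1.0),
    ],
)
def test_fisher_published_and_degenerate_tables(table, expected):
    assert fisher_exact_two_sided(*table) == pytest.approx(expected, abs=5e-4)


def test_fisher_rejects_bad_counts():
    with pytest.raises(ValueError):
        fisher_exact_two_sided(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_exact_two_sided(0, 0, 0, 0)


def test_fisher_spot_agreement_with_enumeration():
    rng = random.Random(7)
    for _ in range(200):
        a, b, c, d = (rng.randint(0, 12) for _ in range(4))
        if a + b + c + d == 0:
            continue
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
        )


# --- Mann-Whitney ---------------------------------------------------------

def test_mann_whitney_enumerated_example():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0
    assert p == pytest.approx(1 / 3, rel=1e-12)


def test_mann_whitney_identical_groups_tie_out():
    u, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
    assert u == 3.0  # n_a * n_b / 2
    assert p == 1.0


def test_mann_whitney_exact_branch_matches_full_permutation():
    rng = random.Random(3)
    for _ in range(5):
        x = [rng.choice([1.0, 2.0, 3.5, 5.0]) for _ in range(4)]
        y = [rng.choice([1.0, 2.5, 3.5, 6.0]) for _ in range(4)]
        u_ours, p_ours = mann_whitney_u(x, y)
        u_oracle, p_oracle = mann_whitney_permutation(x, y)
        assert u_ours == pytest.approx(u_oracle)
        assert p_ours == pytest.approx(p_oracle, rel=1e-12)


def test_mann_whitney_asymptotic_matches_reference_implementation():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 12).tolist()
    y = rng.normal(0.5, 1, 14).tolist()
    u_ours, p_ours = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert u_ours == pytest.approx(float(ref.statistic))
    assert p_ours == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_mann_whitney_on_cohort_baseline_das28():
    """Baseline DAS28, antibody vs etanercept arm: U is rank-derived and the
    p-value is reported, not asserted against any printed value."""
    u, p = mann_whitney_u(M0_ANTIBODY, M0_ETA)
    assert u == 84.0
    assert 0.0 < p < 1.0


def test_mann_whitney_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# --- paired t -------------------------------------------------------------

def test_paired_t_type_one_error_calibrated():
    rng = np.random.default_rng(12)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        d = rng.normal(0, 1, 15)
        _, p = paired_t_test(d, np.zeros(15))
        rejections += p < 0.05
    assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


def test_paired_t_detects_constant_shift():
    rng = np.random.default_rng(1)
    base = rng.normal(10, 1, 200)
    _, p = paired_t_test(base + 0.5, base + rng.normal(0, 0.3, 200))
    assert p < 1e-6


def test_paired_t_degenerate_differences():
    with pytest.raises(ValueError):
        paired_t_test([1.0, 2.0], [0.0, 1.0])  # differences constant
    with pytest.raises(ValueError):
        paired_t_test([1.0, 2.0], [1.0])


# --- group summaries ------------------------------------------------------

def test_cohort_baseline_das28_summary():
    mean, (q25, q75) = group_summary(M0_ANTIBODY, kind="mean")
    assert mean == pytest.approx(4.82, abs=0.005)
    assert (q25, q75) == pytest.approx((4.15, 5.58), abs=0.005)


def test_group_summary_small_cases():
    assert group_summary([1, 2, 3], kind="mean")[0] == 2.0
    center, iqr = group_summary([5.0], kind="median")
    assert center == 5.0 and iqr == (5.0, 5.0)
    with pytest.raises(ValueError):
        group_summary([], kind="mean")
    with pytest.raises(ValueError):
        group_summary([1.0], kind="mode")
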