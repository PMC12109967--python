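"""Independent brute-force oracles the test suite checks the package against.

Everything here is written directly from first principles (decision-rule
restatement, the classic EULAR 3x3 response table, hypergeometric
enumeration, full permutation null) and never calls into tnfipredict.
"""

from __future__ import annotations

import itertools
import math

from scipy.stats import rankdata


def brute_force_activation(cd36: float, nrf2_ratios: list[float], lower: float, upper: float) -> str:
    """Literal restatement of the activation decision rules.

    Step 1: CD36 treated/untreated ratio below the lower cut -> non-activator;
    between the cuts (inclusive) -> uncertain.  Step 2: above the upper cut,
    count Nrf2 target genes whose ratio exceeds the upper cut; activator
    when they are at least half of the genes measured, non-activator
    otherwise, uncertain when no Nrf2 gene was measured at all.
    """
    if cd36 < lower:
        return "NonActivator"
    if cd36 <= upper:
        return "Uncertain"
    if len(nrf2_ratios) == 0:
        return "Uncertain"
    hits = [r for r in nrf2_ratios if r > upper]
    if 2 * len(hits) >= len(nrf2_ratios):
        return "Activator"
    return "NonActivator"


# The classic EULAR response table: rows are the attained DAS28 level,
# columns the improvement from baseline.
_EULAR_TABLE = {
    ("low", "major"): "Good",
    ("low", "minor"): "Moderate",
    ("low", "none"): "None",
    ("mid", "major"): "Moderate",
    ("mid", "minor"): "Moderate",
    ("mid", "none"): "None",
    ("high", "major"): "Moderate",
    ("high", "minor"): "None",
    ("high", "none"): "None",
}


def eular_table_oracle(m0: float, m3: float) -> str:
    improvement = m0 - m3
    if improvement > 1.2:
        col = "major"
    elif improvement > 0.6:
        col = "minor"
    else:
        col = "none"
    if m3 <= 3.2:
        row = "low"
    elif m3 <= 5.1:
        row = "mid"
    else:
        row = "high"
    return _EULAR_TABLE[(row, col)]


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf_vector(r1: int, r2: int, c1: int) -> tuple[range, list[float]]:
    """P(top-left cell = x) for every table with margins (r1, r2 | c1, .)."""
    n = r1 + r2
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    denom = _log_comb(n, c1)
    pmf = [math.exp(_log_comb(r1, x) + _log_comb(r2, c1 - x) - denom) for x in support]
    return support, pmf


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing all same-margin tables no more probable
    than the observed one (point-probability convention)."""
    r1, r2, c1 = a + b, c + d, a + c
    support, pmf = hypergeom_pmf_vector(r1, r2, c1)
    p_obs = pmf[list(support).index(a)]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + 1e-9)))


def mann_whitney_permutation(x: list[float], y: list[float]) -> tuple[float, float]:
    """U of the first group and the exact two-sided p over all n! relabelings."""
    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n_a = len(x)
    mu = n_a * len(y) / 2.0

    def u_of(index_tuple) -> float:
        return sum(ranks[i] for i in index_tuple) - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    dev = abs(u_obs - mu)
    extreme = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        total += 1
        if abs(u_of(perm[:n_a]) - mu) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total
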