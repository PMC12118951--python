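"""Nonparametric tests used throughout the pipeline.

Mann-Whitney, Wilcoxon signed-rank and Spearman delegate to SciPy (with exact
small-sample methods where available); the Steel-Dwass all-pairs post hoc,
which no common Python library ships, is implemented here against the
Studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple
    method: str
    ties_corrected: bool = False
    extra: dict = None

    def __post_init__(self):
        if self.extra is None:
            self.extra = {}
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for pooled n <= 12 without ties, tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    ties = _has_ties(x, y)
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), (x.size, y.size),
                      f"Mann-Whitney U ({method})", ties_corrected=ties)


def wilcoxon_signed_rank(d) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on differences ``d``.

    Zero differences are dropped (Wilcoxon convention); exact null for
    n <= 12 without ties in |d|.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 12 and not ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), (d.size,),
                      f"Wilcoxon signed-rank ({method})", ties_corrected=ties)


def spearman(x, y) -> TestResult:
    """Tie-aware Spearman rank correlation with two-sided p.

    Exact permutation null for n <= 7, t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires two equal-length samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance sample")
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    if n <= 7:
        ry = sps.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        rx = sps.rankdata(x)
        for perm in permutations(range(n)):
            r = float(sps.spearmanr(rx, ry[list(perm)]).statistic)
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
        method = "Spearman (exact permutation)"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "Spearman (t approximation)"
    return TestResult(rho, float(p), (n,), method, ties_corrected=_has_ties(x) or _has_ties(y))


# ---------------------------------------------------------------------------
# Steel-Dwass
# ---------------------------------------------------------------------------

def _steel_dwass_pair(a, b, k: int) -> TestResult:
    """One Steel-Dwass pairwise comparison within a family of k groups.

    Joint ranks over the two groups only; the standardized rank-sum statistic
    t is referred to the Studentized range via q = sqrt(2)*|t| with infinite
    degrees of freedom. Tie correction enters the variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    n = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(np.sum(ranks[:na]))
    e = na * (n + 1) / 2.0
    # variance of the rank sum with tie correction
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(np.nan, np.nan, (na, nb), "Steel-Dwass (degenerate)",
                          ties_corrected=True)
    t = (w - e) / np.sqrt(var)
    q = np.sqrt(2.0) * abs(t)
    p = float(sps.studentized_range.sf(q, k, np.inf))
    return TestResult(float(t), p, (na, nb), "Steel-Dwass",
                      ties_corrected=tie_term > 0, extra={"rank_sum": w, "q": q})


def kruskal_steel_dwass(groups, gate_alpha: float = 0.05, gate: bool = True):
    """Kruskal-Wallis omnibus with Steel-Dwass all-pairs post hoc.

    Returns ``(omnibus, pairwise)`` where pairwise is a dict keyed by group
    index pairs; it is empty when the omnibus p fails the gate (the gate can
    be disabled with ``gate=False``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    kw = sps.kruskal(*groups)
    omnibus = TestResult(float(kw.statistic), float(kw.pvalue),
                         tuple(g.size for g in groups), "Kruskal-Wallis",
                         ties_corrected=_has_ties(*groups))
    pairwise = {}
    if (not gate) or omnibus.p_value < gate_alpha:
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                pairwise[(i, j)] = _steel_dwass_pair(groups[i], groups[j], k)
    return omnibus, pairwise
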