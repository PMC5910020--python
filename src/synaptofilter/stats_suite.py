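"""Non-parametric statistics: tie-aware rank tests with exact small-sample modes.

The recipes are the ones standard in slice-physiology work: two-tailed
Wilcoxon matched-pairs signed rank and Mann-Whitney for two-group
comparisons, Kruskal-Wallis with Dunn's multiple-comparison post hoc for
independent multi-group designs, and Friedman's two-way ANOVA by ranks for
blocked designs, all at alpha = 0.05.

Exact modes enumerate the permutation null directly (2^n sign patterns for
the signed-rank test, all C(N, n1) group assignments for Mann-Whitney) on
the observed mid-ranks, so they remain correct under ties; the asymptotic
modes use normal/chi-square approximations with the standard tie
corrections.  Zero differences are dropped before ranking (the common
signed-rank convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .core_io import ValidationError

EXACT_MAX_N_WILCOXON = 12   # enumerate 2^n sign patterns up to here
EXACT_MAX_N_MANNWHITNEY = 14  # enumerate C(N, n1) assignments up to here


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alpha: float = 0.05
    labels: tuple[str, ...] = ()
    mode: str = "exact"
    note: str = ""
    extra: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p value outside [0, 1]")


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _two_tailed(p_low: float, p_high: float) -> float:
    return min(1.0, 2.0 * min(p_low, p_high))


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    mode: str = "auto",
    alpha: float = 0.05,
) -> StatResult:
    """Two-tailed Wilcoxon matched-pairs signed rank test.

    ``x`` is the paired differences when ``y`` is omitted.  Zero differences
    are dropped; ties in |d| receive mid-ranks.  ``mode`` is ``exact``
    (enumeration over all 2^n sign patterns; automatic for n <= 12),
    ``approx`` (normal with tie correction), or ``auto``.  When every
    difference is zero the test is defined with p = 1 and a warning note.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult(
            test="wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
            n=(0,), alpha=alpha, mode="degenerate",
            note="all differences zero; no evidence either way",
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if mode not in ("auto", "exact", "approx"):
        raise ValidationError("mode must be auto, exact or approx")
    exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_N_WILCOXON)
    if exact:
        patterns = (
            np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        ) & 1  # all sign assignments
        w_all = patterns @ ranks
        p = _two_tailed(
            float(np.mean(w_all <= w_plus)), float(np.mean(w_all >= w_plus))
        )
        used = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
        used = "approx"
    return StatResult(
        test="wilcoxon_signed_rank", statistic=w_plus, p_value=min(p, 1.0),
        n=(n,), alpha=alpha, mode=used,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alpha: float = 0.05,
) -> StatResult:
    """Two-tailed Mann-Whitney U test with mid-ranks.

    Exact by enumeration of all group assignments of the observed pooled
    ranks for combined n <= 14 (automatic), otherwise a normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if mode not in ("auto", "exact", "approx"):
        raise ValidationError("mode must be auto, exact or approx")
    exact = mode == "exact" or (
        mode == "auto" and n1 + n2 <= EXACT_MAX_N_MANNWHITNEY
    )
    if exact:
        offset = n1 * (n1 + 1) / 2.0
        u_all = np.array(
            [ranks[list(c)].sum() - offset
             for c in combinations(range(n1 + n2), n1)]
        )
        p = _two_tailed(
            float(np.mean(u_all <= u1)), float(np.mean(u_all >= u1))
        )
        used = "exact"
    else:
        N = n1 + n2
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * (N + 1 - _tie_term(pooled) / (N * (N - 1)))
        z = (u1 - mu) / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
        used = "approx"
    return StatResult(
        test="mann_whitney", statistic=u1, p_value=min(p, 1.0),
        n=(n1, n2), alpha=alpha, mode=used,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    labels: Sequence[str] | None = None,
) -> StatResult:
    """Kruskal-Wallis H test with Dunn's pairwise post hoc comparisons.

    H carries the standard tie correction; Dunn z statistics use pooled
    ranks with tie-corrected variance, two-tailed, family-wise adjusted over
    all k(k-1)/2 comparisons (Bonferroni by default, ``adjust='none'`` to
    disable).  The pairwise table is attached as ``result.extra``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValidationError("Kruskal-Wallis requires >= 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("all groups must be non-empty")
    if adjust not in ("bonferroni", "none"):
        raise ValidationError("adjust must be 'bonferroni' or 'none'")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    sizes = np.array([g.size for g in groups])
    N = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(float(ranks[start : start + n_i].mean()))
        start += n_i
    mean_ranks = np.array(mean_ranks)

    tie = _tie_term(pooled)
    h = 12.0 / (N * (N + 1)) * float(
        np.sum(sizes * (mean_ranks - (N + 1) / 2.0) ** 2)
    )
    correction = 1.0 - tie / (N**3 - N)
    if correction <= 0:  # every observation identical
        h, p = 0.0, 1.0
    else:
        h /= correction
        p = float(chi2.sf(h, k - 1))

    m = k * (k - 1) // 2
    var_pool = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_pool * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = float(2 * norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * m) if adjust == "bonferroni" else p_raw
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return StatResult(
        test="kruskal_wallis", statistic=float(h), p_value=p,
        n=tuple(int(s) for s in sizes), alpha=alpha,
        labels=tuple(labels), mode="chi2", extra=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

def friedman(data: Sequence[Sequence[float]], alpha: float = 0.05) -> StatResult:
    """Friedman's two-way ANOVA by ranks with tie correction.

    ``data`` is blocks x treatments (complete blocks required, k >= 3
    treatments).  Identical treatments yield statistic 0, p = 1.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("data must be blocks x treatments")
    if np.isnan(arr).any():
        raise ValidationError("incomplete blocks are not supported")
    n, k = arr.shape
    if k < 3:
        raise ValidationError("Friedman requires >= 3 treatments")
    ranks = np.apply_along_axis(rankdata, 1, arr)
    col_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks**2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # all treatments tied within every block
        stat, p = 0.0, 1.0
    else:
        stat = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / (a - c)
        p = float(chi2.sf(stat, k - 1))
    return StatResult(
        test="friedman", statistic=float(stat), p_value=p,
        n=(n, k), alpha=alpha, mode="chi2",
    )


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    test: str,
    n: int = 8,
    reps: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    k: int = 5,
) -> float:
    """Empirical type-I error rate under a Gaussian null.

    Simulates ``reps`` null datasets (standard normal, no group effect) and
    returns the fraction rejected at ``alpha``.  ``n`` is the per-group
    sample size (or block count for Friedman); ``k`` the number of groups
    or treatments where applicable.
    """
    if reps < 1000:
        raise ValidationError("use >= 1000 replicates for calibration")
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(reps):
        if test == "wilcoxon":
            res = wilcoxon_signed_rank(rng.normal(size=n), rng.normal(size=n))
        elif test == "mannwhitney":
            res = mann_whitney(rng.normal(size=n), rng.normal(size=n))
        elif test == "kruskal":
            res = kruskal_wallis_dunn([rng.normal(size=n) for _ in range(k)])
        elif test == "friedman":
            res = friedman(rng.normal(size=(n, k)))
        else:
            raise ValidationError(f"unknown test {test!r}")
        if res.p_value < alpha:
            rejected += 1
    return rejected / reps
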