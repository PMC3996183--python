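"""Group summaries and the rank-based tests used on the accuracy tables.

Two-sample comparisons use the Wilcoxon rank-sum test with mid-ranks for
ties, the tie-corrected normal approximation and a continuity correction —
the convention of Matlab's ``ranksum``, which reproduces the published Z
values on percentage data with heavy ties.  The magnitude |Z| is reported
(signs depend only on argument order) together with the effect size
r = |Z|/√(n_a + n_b).  Paired comparisons use the Wilcoxon signed-rank test
with zero differences dropped, exact enumeration for n ≤ 15 and the normal
approximation above that.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

__all__ = ["summarize_accuracies", "rank_sum", "signed_rank"]


def summarize_accuracies(values, groups=None) -> dict:
    """Median, mean and sample SD (n−1) per group of accuracy values.

    Without ``groups``, a single summary dict is returned; with a per-value
    group label array, a dict of summaries keyed by group.  SD on a
    singleton group raises.
    """
    if groups is not None:
        values = np.asarray(values, float)
        groups = np.asarray(groups)
        return {g: summarize_accuracies(values[groups == g])
                for g in dict.fromkeys(groups.tolist())}
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("need at least one value")
    out = {"n": int(v.size), "median": float(np.median(v)),
           "mean": float(v.mean())}
    if v.size < 2:
        raise ValueError("sample SD requires at least two values")
    out["sd"] = float(v.std(ddof=1))
    return out


def rank_sum(a, b) -> dict:
    """Two-sided Wilcoxon rank-sum: |Z|, p and effect size r = |Z|/√N."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = a.size, b.size
    N = n1 + n2
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    T = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return {"Z": 0.0, "p": 1.0, "r": 0.0}
    d = T - mu
    d -= 0.5 * np.sign(d)  # continuity correction
    z = d / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return {"Z": abs(float(z)), "p": float(min(p, 1.0)),
            "r": abs(float(z)) / math.sqrt(N)}


def signed_rank(a, b) -> dict:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped; if every difference is zero the result is
    p = 1 with ``degenerate=True``.  Exact enumeration for n ≤ 15 pairs,
    normal approximation above.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return {"p": 1.0, "degenerate": True}
    method = "exact" if d.size <= 15 else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return {"p": float(res.pvalue), "degenerate": False}
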