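"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (sums,
loops, permutations) and never calls into the package, so agreement with
the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def disk_pixel_count(center: tuple[float, float], radius: float) -> int:
    """Count integer pixels within ``radius`` of ``center`` by brute force."""
    cy, cx = center
    n = 0
    for r in range(int(math.floor(cy - radius)) - 1, int(math.ceil(cy + radius)) + 2):
        for c in range(int(math.floor(cx - radius)) - 1, int(math.ceil(cx + radius)) + 2):
            if (r - cy) ** 2 + (c - cx) ** 2 <= radius**2:
                n += 1
    return n


def anova_f(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F from the explicit between/within decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction, from the rank formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        k = len(g)
        rbar = ranks[start : start + k].mean()
        h += k * (rbar - (n + 1) / 2.0) ** 2
        start += k
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def tukey_adjusted_p(groups: list[np.ndarray], i: int, j: int) -> float:
    """Tukey HSD adjusted p for one pair via the studentized range,
    computed from the hand-built q statistic."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    ni, nj = len(groups[i]), len(groups[j])
    se = math.sqrt(msw / 2.0 * (1.0 / ni + 1.0 / nj))
    q = abs(groups[i].mean() - groups[j].mean()) / se
    return float(stats.studentized_range.sf(q, k, df))


def permutation_pvalue_kruskal(groups: list[np.ndarray], n_perm: int, rng) -> float:
    """Permutation null of the Kruskal-Wallis H (>= observed)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = kruskal_h(groups)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for s in sizes:
            parts.append(perm[start : start + s])
            start += s
        hits += kruskal_h(parts) >= h_obs - 1e-12
    return hits / n_perm


def logrank_chi2(times, events, in_a) -> float:
    """Two-group log-rank chi-square from the O-E / hypergeometric sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    in_a = np.asarray(in_a, bool)
    o_minus_e = 0.0
    var = 0.0
    for tj in np.unique(times[events]):
        at_risk = times >= tj
        n_j = at_risk.sum()
        n_aj = (at_risk & in_a).sum()
        d_j = (events & (times == tj)).sum()
        d_aj = (events & (times == tj) & in_a).sum()
        o_minus_e += d_aj - d_j * n_aj / n_j
        if n_j > 1:
            var += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)
    return 0.0 if var == 0 else o_minus_e**2 / var


def permutation_pvalue_logrank(times, events, in_a, n_perm: int, rng) -> float:
    chi_obs = logrank_chi2(times, events, in_a)
    labels = np.asarray(in_a, bool).copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        hits += logrank_chi2(times, events, labels) >= chi_obs - 1e-12
    return hits / n_perm
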