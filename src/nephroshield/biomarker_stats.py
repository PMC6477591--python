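"""Statistical toolkit used across the study's endpoints.

Four treatment arms are compared, but only three pairs are ever reported:
control vs irradiated, control vs irradiated+protein, and irradiated vs
irradiated+protein.  Continuous endpoints use one-way ANOVA with Tukey's
post hoc test, ordinal endpoints use Kruskal-Wallis with Dunn's post hoc
test, and outliers are removed beforehand with a one-sample adaptation of
the ROUT method at Q = 1%.  Relative gene expression is computed with the
delta-delta-Ct method and binned for heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ARMS",
    "RESTRICTED_PAIRS",
    "PairResult",
    "ComparisonReport",
    "significance_stars",
    "rout_outliers",
    "delta_delta_ct",
    "heatmap_bin",
    "one_way_anova",
    "tukey_hsd",
    "kruskal_dunn",
    "compare_groups",
]

#: Canonical arm identifiers (control, radioligand alone, radioligand with
#: the alpha-1-microglobulin radioprotector, protector alone).
ARMS = ("control", "lu", "lu_a1m", "a1m")

#: The three pairwise comparisons the study reports.
RESTRICTED_PAIRS = (("control", "lu"), ("control", "lu_a1m"), ("lu", "lu_a1m"))

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for thr, stars in _STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        object.__setattr__(self, "stars", significance_stars(self.p_adjusted))


@dataclass
class ComparisonReport:
    analyte: str
    method: str  # "tukey" | "dunn"
    omnibus_statistic: float
    omnibus_p: float
    pairs: list[PairResult]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": self.analyte,
                "method": self.method,
                "group_a": [p.pair[0] for p in self.pairs],
                "group_b": [p.pair[1] for p in self.pairs],
                "statistic": [p.statistic for p in self.pairs],
                "p_adjusted": [p.p_adjusted for p in self.pairs],
                "stars": [p.stars for p in self.pairs],
            }
        )


# ---------------------------------------------------------------------------
# ROUT outlier removal (one-sample adaptation)
# ---------------------------------------------------------------------------

def rout_outliers(values, q: float = 0.01) -> np.ndarray:
    """Flag outliers in a single sample, ROUT-style, at FDR rate ``q``.

    ROUT was formulated for nonlinear regression (robust fit, then
    FDR-controlled testing of residuals).  For group scatter data the fit
    degenerates to a robust location: residuals are taken from the median,
    the robust scale (RSDR) is the 68.27th percentile of the absolute
    residuals with the small-sample correction ``n / (n - 1)``, and
    residual t-ratios are referred to a t distribution with ``n - 1``
    degrees of freedom.  Outliers are then decided by the FDR step-down
    from the most extreme residual: the i-th most extreme point (and all
    points more extreme than it) is flagged when its two-sided p-value is
    below ``q * (n - i + 1) / n``; the walk stops at the first
    non-significant point.

    Returns a boolean mask (True = flagged); the input is never mutated.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    if not 0.0 < q <= 0.5:
        raise ValueError("Q must lie in (0, 0.5]")
    n = len(x)
    resid = x - np.median(x)
    adev = np.abs(resid)
    if np.all(adev == 0):
        return np.zeros(n, dtype=bool)
    rsdr = np.percentile(adev, 68.27) * n / (n - 1)
    if rsdr == 0:
        # >68% of the sample sits exactly on the median; anything off it
        # is infinitely many robust SDs away
        return adev > 0
    t_ratio = adev / rsdr
    p = 2.0 * stats.t.sf(t_ratio, df=n - 1)

    # FDR step-down: walk in from the most extreme residual
    order = np.argsort(-adev)
    mask = np.zeros(n, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] < q * (n - rank) / n:
            mask[order[: rank + 1]] = True
        else:
            break
    return mask


# ---------------------------------------------------------------------------
# Relative expression (delta-delta-Ct)
# ---------------------------------------------------------------------------

def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_arm: str = "control",
) -> pd.DataFrame:
    """Fold change relative to the control arm, normalised to a reference gene.

    ``ct_table`` is long-format with columns ``sample_id, arm, gene, ct``.
    For every target gene, ``dct = ct_target - ct_reference`` per sample,
    ``ddct = dct - mean(control-arm dct)`` (arithmetic mean), and
    ``fold_change = 2 ** (-ddct)``.  By construction the control arm's
    geometric mean fold change is exactly 1.
    """
    required = {"sample_id", "arm", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    ref = ct_table[ct_table["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = ct_table[ct_table["gene"] != reference_gene]
    if targets.empty:
        raise ValueError("no target genes in table")

    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        missing = set(sub["sample_id"]) - set(ref.index)
        if missing:
            raise ValueError(
                f"missing reference-gene Ct for sample(s) {sorted(missing)}"
            )
        dct = sub["ct"].to_numpy() - ref.loc[sub["sample_id"]].to_numpy()
        is_control = (sub["arm"] == control_arm).to_numpy()
        if not is_control.any():
            raise ValueError(f"control arm {control_arm!r} absent for gene {gene!r}")
        ddct = dct - dct[is_control].mean()
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sub["sample_id"].to_numpy(),
                    "arm": sub["arm"].to_numpy(),
                    "gene": gene,
                    "ct_target": sub["ct"].to_numpy(),
                    "ct_reference": ref.loc[sub["sample_id"]].to_numpy(),
                    "delta_ct": dct,
                    "delta_delta_ct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def heatmap_bin(fold_change: float) -> str:
    """Heat-map colour bin for a fold change.

    Green [0, 1.5), orange [1.5, 2.0), red [2.0, 5.0], black above 5.
    The published ranges overlap at the edges; they are resolved right-open
    except that black is strictly above 5.
    """
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if fold_change < 1.5:
        return "green"
    if fold_change < 2.0:
        return "orange"
    if fold_change <= 5.0:
        return "red"
    return "black"


# ---------------------------------------------------------------------------
# Omnibus tests and restricted post hoc comparisons
# ---------------------------------------------------------------------------

def _check_groups(groups: dict[str, np.ndarray], min_per_group: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two arms")
    out = {}
    for arm, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < min_per_group:
            raise ValueError(f"arm {arm!r} needs >= {min_per_group} values")
        out[arm] = v
    return out


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p over the given arms."""
    g = _check_groups(groups)
    pooled = np.concatenate(list(g.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("undefined F: all values identical")
    f, p = stats.f_oneway(*g.values())
    return float(f), float(p)


def tukey_hsd(
    groups: dict[str, np.ndarray],
    restricted_pairs: tuple[tuple[str, str], ...] = RESTRICTED_PAIRS,
    analyte: str = "",
) -> ComparisonReport:
    """Tukey's HSD over the full family of arms; only the restricted pairs
    are reported.

    The adjusted p-values come from the studentized-range distribution
    computed over all ``k`` arms, so the familywise error control reflects
    the full design even though only three comparisons are printed.
    """
    g = _check_groups(groups)
    arms = list(g.keys())
    f, p_omni = one_way_anova(g)
    res = stats.tukey_hsd(*[g[a] for a in arms])
    idx = {a: i for i, a in enumerate(arms)}
    pairs = []
    for a, b in restricted_pairs:
        if a not in idx or b not in idx:
            raise KeyError(f"arm pair ({a!r}, {b!r}) not present")
        pairs.append(
            PairResult(
                pair=(a, b),
                statistic=float(res.statistic[idx[a], idx[b]]),
                p_adjusted=float(min(1.0, res.pvalue[idx[a], idx[b]])),
            )
        )
    return ComparisonReport(analyte, "tukey", f, p_omni, pairs)


def _dunn_pairwise(
    g: dict[str, np.ndarray], pairs: tuple[tuple[str, str], ...]
) -> list[tuple[tuple[str, str], float, float]]:
    """Dunn z statistics and unadjusted two-sided p for the given pairs.

    Uses pooled mid-ranks with the tie-corrected variance
    ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` where
    ``T = sum(t^3 - t)`` over tie groups.
    """
    arms = list(g.keys())
    pooled = np.concatenate([g[a] for a in arms])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for a in arms:
        k = len(g[a])
        mean_rank[a] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    out = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / len(g[a]) + 1.0 / len(g[b])))
        if se == 0:
            out.append(((a, b), 0.0, 1.0))
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        out.append(((a, b), float(z), float(2.0 * stats.norm.sf(abs(z)))))
    return out


def _holm(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    restricted_pairs: tuple[tuple[str, str], ...] = RESTRICTED_PAIRS,
    analyte: str = "",
) -> ComparisonReport:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post hoc z-tests.

    Dunn p-values are Holm-adjusted over the restricted pairs that are
    actually reported.
    """
    g = _check_groups(groups)
    pooled = np.concatenate(list(g.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate H: all values tied across all groups")
    h, p_omni = stats.kruskal(*g.values())
    raw = _dunn_pairwise(g, restricted_pairs)
    adj = _holm([p for _, _, p in raw])
    pairs = [
        PairResult(pair=pr, statistic=z, p_adjusted=pa)
        for (pr, z, _), pa in zip(raw, adj)
    ]
    return ComparisonReport(analyte, "dunn", float(h), float(p_omni), pairs)


def compare_groups(
    groups: dict[str, np.ndarray],
    method: str = "anova",
    analyte: str = "",
    remove_outliers: bool = True,
    q: float = 0.01,
    restricted_pairs: tuple[tuple[str, str], ...] = RESTRICTED_PAIRS,
) -> ComparisonReport:
    """Fixed pipeline: per-arm ROUT outlier removal, omnibus test, post hoc.

    ``method`` is ``"anova"`` (ANOVA + Tukey) or ``"kw"`` (Kruskal-Wallis +
    Dunn).  Outlier removal is per arm; an arm shrunk below two values
    raises rather than silently dropping the comparison.
    """
    g = _check_groups(groups)
    if remove_outliers:
        cleaned = {}
        for arm, vals in g.items():
            mask = rout_outliers(vals, q=q) if len(vals) >= 3 else np.zeros(len(vals), bool)
            kept = vals[~mask]
            if len(kept) < 2:
                raise ValueError(f"arm {arm!r} has < 2 values after outlier removal")
            cleaned[arm] = kept
        g = cleaned
    if method == "anova":
        return tukey_hsd(g, restricted_pairs, analyte=analyte)
    if method == "kw":
        return kruskal_dunn(g, restricted_pairs, analyte=analyte)
    raise ValueError(f"unknown method: {method!r}")
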