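"""Nonparametric group statistics for herding measurements.

Group comparisons follow the experimental analysis: a Kruskal-Wallis
omnibus test on the group medians, Dunn's post-hoc pairwise z-tests on the
pooled ranks (with tie correction), and median summaries with seeded
percentile-bootstrap 95 % confidence intervals.  Dunn p-values are reported
raw by default (the common post-hoc-after-significant-omnibus convention);
Holm or Bonferroni adjustment is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "dunn_posthoc",
    "median_ci",
    "significance_stars",
    "compare_groups",
    "summarize_study",
]


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate input (all values identical) returns (0.0, 1.0)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        return 0.0, 1.0
    h, p = _sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: list, adjust: str = "none", labels=None) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on pooled ranks.

    For groups i, j with mean pooled ranks Ri, Rj,

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj)),
        T = sum(t^3 - t) / (12 (N - 1))  over tie groups,

    with two-sided normal p-values.  ``adjust`` is 'none', 'holm' or
    'bonferroni'.  Returns a tidy DataFrame (one row per unordered pair).
    """
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError("adjust must be 'none', 'holm' or 'bonferroni'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = _sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * _sps.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "z": float(z), "p_raw": float(min(p, 1.0))})
    df = pd.DataFrame(rows)
    if len(df) == 0:
        df["p_adj"] = []
        return df
    if adjust == "none":
        df["p_adj"] = df["p_raw"]
    else:
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=adjust)[1]
    return df


def median_ci(values, n_boot: int = 10000, seed: int | None = None,
              alpha: float = 0.05) -> tuple[float, float, float]:
    """Median with a seeded percentile-bootstrap (1 - alpha) CI.

    With fewer than 3 values the interval is undefined: the median is
    returned with NaN bounds and a warning."""
    values = np.asarray(values, dtype=float)
    med = float(np.median(values))
    if len(values) < 3:
        warnings.warn("median CI undefined for n < 3", UserWarning, stacklevel=2)
        return med, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boots = np.median(values[idx], axis=1)
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return med, float(lo), float(hi)


def significance_stars(p: float) -> str:
    """Figure-convention stars: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p <= cut:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """One grouping axis: per-group medians/CIs plus KW and Dunn results."""

    key: str
    value: str
    summary: pd.DataFrame       # group, n, median, ci_low, ci_high
    H: float | None
    p: float | None
    dunn: pd.DataFrame | None
    alpha: float = 0.05


def compare_groups(df: pd.DataFrame, group_by: str, value: str,
                   adjust: str = "none", n_boot: int = 10000,
                   seed: int = 0, alpha: float = 0.05) -> GroupComparison:
    """Group a results table by one key and compare one metric across groups."""
    if group_by not in df.columns:
        raise KeyError(f"unknown grouping key {group_by!r}")
    if value not in df.columns:
        raise KeyError(f"unknown value column {value!r}")
    sub = df[[group_by, value]].dropna()
    keys, groups = [], []
    for k, g in sub.groupby(group_by, sort=True):
        keys.append(k)
        groups.append(g[value].to_numpy(dtype=float))
    rows = []
    for i, (k, g) in enumerate(zip(keys, groups)):
        med, lo, hi = median_ci(g, n_boot=n_boot, seed=seed + i, alpha=alpha) \
            if len(g) >= 3 else (float(np.median(g)), float("nan"), float("nan"))
        rows.append({"group": k, "n": len(g), "median": med,
                     "ci_low": lo, "ci_high": hi})
    summary = pd.DataFrame(rows)
    if len(groups) >= 2:
        H, p = kruskal_wallis(groups)
        dunn = dunn_posthoc(groups, adjust=adjust, labels=[str(k) for k in keys])
    else:
        H = p = None
        dunn = None
    return GroupComparison(key=group_by, value=value, summary=summary,
                           H=H, p=p, dunn=dunn, alpha=alpha)


DEFAULT_METRICS = ("N_CNT", "N_Si", "G_CNT", "G_Si", "N", "G", "GN")
DEFAULT_AXES = ("label", "div", "W_Si", "W_CNT", "D", "m", "kind", "regime")


def summarize_study(df: pd.DataFrame, axes=None, metrics=None,
                    adjust: str = "none", n_boot: int = 2000, seed: int = 0
                    ) -> tuple[pd.DataFrame, dict]:
    """Grouped medians + CIs + KW/Dunn for every available comparison axis.

    Returns a tidy summary DataFrame (one row per axis/metric/group) and a
    dict of the underlying GroupComparison objects keyed by (axis, metric).
    """
    axes = [a for a in (axes or DEFAULT_AXES) if a in df.columns]
    metrics = [m for m in (metrics or DEFAULT_METRICS) if m in df.columns]
    records = []
    comparisons = {}
    for ax in axes:
        for metric in metrics:
            gc = compare_groups(df, ax, metric, adjust=adjust,
                                n_boot=n_boot, seed=seed)
            comparisons[(ax, metric)] = gc
            for _, row in gc.summary.iterrows():
                records.append({
                    "axis": ax, "metric": metric, "group": row["group"],
                    "n": row["n"], "median": row["median"],
                    "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "kw_H": gc.H, "kw_p": gc.p,
                    "kw_stars": significance_stars(gc.p) if gc.p is not None else "",
                })
    return pd.DataFrame(records), comparisons
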