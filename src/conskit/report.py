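"""Group summaries and rank-based comparisons of per-individual metrics.

For each metric and group the summary reports mean, sd (ddof=1) and n; for
each pair of groups a two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value,
exact when both groups have <= 25 observations and no ties, otherwise the
normal approximation with continuity correction.  No multiple-testing
correction is applied by default; Benjamini-Hochberg is available.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_MAX_N = 25


def ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p-value (exact for small untied samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def summarize_groups(
    metrics: pd.DataFrame,
    group_col: str = "group",
    metric_cols: Sequence[str] | None = None,
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean/sd/n and pairwise rank-sum comparisons.

    ``metrics`` holds one row per individual with a group label column and
    numeric metric columns.  Returns ``(summary, comparisons)``; groups of
    size 1 get NaN sd and their comparisons are flagged ``underpowered``.
    """
    if group_col not in metrics.columns:
        raise ValueError(f"missing group column {group_col!r}")
    if metric_cols is None:
        metric_cols = [c for c in metrics.columns if c != group_col and pd.api.types.is_numeric_dtype(metrics[c])]
    if not metric_cols:
        raise ValueError("no numeric metric columns found")

    rows = []
    for grp, sub in metrics.groupby(group_col, sort=True):
        for m in metric_cols:
            vals = sub[m].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "group": grp,
                    "metric": m,
                    "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals)),
                }
            )
    summary = pd.DataFrame(rows)

    comp_rows = []
    groups = sorted(metrics[group_col].unique().tolist())
    for g_a, g_b in itertools.combinations(groups, 2):
        for m in metric_cols:
            x = metrics.loc[metrics[group_col] == g_a, m].dropna().to_numpy(dtype=float)
            y = metrics.loc[metrics[group_col] == g_b, m].dropna().to_numpy(dtype=float)
            if len(x) == 0 or len(y) == 0:
                continue
            comp_rows.append(
                {
                    "group_a": g_a,
                    "group_b": g_b,
                    "metric": m,
                    "p_value": ranksum_p(x, y),
                    "underpowered": len(x) < 2 or len(y) < 2,
                }
            )
    comparisons = pd.DataFrame(comp_rows, columns=["group_a", "group_b", "metric", "p_value", "underpowered"])
    if bh_correction and len(comparisons):
        comparisons["p_adjusted"] = stats.false_discovery_control(comparisons["p_value"].to_numpy())
    return summary, comparisons


def plot_group_bars(summary: pd.DataFrame, metric: str, path: str) -> None:
    """Bar chart of group means with sd error bars (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["metric"] == metric]
    fig, ax = plt.subplots(figsize=(1.2 * len(sub) + 2, 4))
    ax.bar(sub["group"], sub["mean"], yerr=sub["sd"].fillna(0.0), capsize=4, color="#4878a8")
    ax.set_ylabel(metric)
    ax.set_xlabel("group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
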