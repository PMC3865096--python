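"""Cohort-level statistics: one-way ANOVA with Tukey HSD post-hoc tests.

Each tumor is one independent observation (the two flank tumors of a mouse are
not modeled as clustered — a deliberate simplification, see docs).  Unequal
group sizes use the Tukey-Kramer form.  Alongside the Tukey-adjusted p-values
an unadjusted pairwise t-test p (Fisher-LSD form: the same pooled all-groups
error variance the Tukey statistic studentizes with) is reported for every
pair so either convention can be inspected; the adjusted value drives the
significance flag and is never smaller than its unadjusted companion.
"""
from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05


def _as_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float).ravel()
        v = v[np.isfinite(v)]
        out[str(label)] = v
    return out


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical between/within mean-square F and its p-value.

    Degenerate inputs are resolved explicitly: zero variance everywhere (all
    observations identical) is treated as no evidence (F=0, p=1); zero within-
    group variance with distinct group means gives p=0.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError(f"need >= 2 groups; got {len(g)}")
    for label, v in g.items():
        if v.size < 2:
            raise ValueError(f"group {label!r} has {v.size} observation(s); need >= 2")
    allv = np.concatenate(list(g.values()))
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
    if within == 0:
        return np.inf, 0.0
    f, p = sps.f_oneway(*g.values())
    return float(f), float(p)


def tukey_pairwise(
    groups: dict[str, np.ndarray],
    order: list[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Tukey(-Kramer) adjusted p for every unordered pair of groups.

    Pairs are emitted in the order ``(g_i, g_j), i < j`` of ``order`` (default:
    insertion order of ``groups``), i.e. for (C, M, G, X): C-M, C-G, C-X, M-G,
    M-X, G-X.  Columns: group_a, group_b, mean_diff, p_tukey, p_unadjusted,
    significant.
    """
    g = _as_groups(groups)
    labels = list(order) if order is not None else list(g)
    if set(labels) != set(g):
        raise ValueError(f"order {labels} does not match group labels {list(g)}")
    for label in labels:
        if g[label].size < 2:
            raise ValueError(f"group {label!r} has {g[label].size} observation(s); need >= 2")
    # zero pooled within-group variance cannot be studentized; resolve those
    # cells like the ANOVA degenerate conventions (equal means: p=1, else 0)
    within = sum(((g[label] - g[label].mean()) ** 2).sum() for label in labels)
    degenerate = within == 0
    n_total = sum(g[label].size for label in labels)
    df = n_total - len(labels)
    mse = within / df if df > 0 else np.nan
    if not degenerate:
        res = sps.tukey_hsd(*[g[label] for label in labels])
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        a, b = labels[i], labels[j]
        diff = float(g[b].mean() - g[a].mean())
        if degenerate:
            p_adj = 1.0 if diff == 0 else 0.0
            p_raw = p_adj
        else:
            p_adj = float(res.pvalue[i, j])
            se = np.sqrt(mse * (1.0 / g[a].size + 1.0 / g[b].size))
            t_stat = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t_stat), df))
        rows.append({
            "group_a": a, "group_b": b, "mean_diff": diff,
            "p_tukey": p_adj, "p_unadjusted": p_raw,
            "significant": bool(p_adj < alpha),
        })
    return pd.DataFrame(rows)


def build_comparison_report(
    cohort: pd.DataFrame,
    group_order: list[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pairwise comparison grid over every (metric, day) in a long table.

    ``cohort`` needs columns group, day, metric, value (one row per tumor per
    day per metric).  Cells with fewer than 2 observations in any group, or
    fewer than 2 groups, are skipped and logged.  Returns one row per
    (metric, day, pair) with the ANOVA F/p repeated per cell.
    """
    required = {"group", "day", "metric", "value"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    if cohort.empty:
        logger.warning("build_comparison_report: empty cohort table")
        return pd.DataFrame(
            columns=["metric", "day", "group_a", "group_b", "mean_diff",
                     "anova_F", "anova_p", "p_tukey", "p_unadjusted", "significant"]
        )
    out = []
    for (metric, day), sub in cohort.groupby(["metric", "day"], sort=True):
        g = {
            label: grp["value"].to_numpy()
            for label, grp in sub.groupby("group", sort=False)
        }
        g = {k: v[np.isfinite(v)] for k, v in g.items()}
        order = [x for x in (group_order or list(g)) if x in g]
        if len(order) < 2 or any(g[k].size < 2 for k in order):
            logger.warning(
                "comparison cell (%s, day %s) skipped: insufficient observations",
                metric, day,
            )
            continue
        g = {k: g[k] for k in order}
        f, p = one_way_anova(g)
        grid = tukey_pairwise(g, order=order, alpha=alpha)
        grid.insert(0, "metric", metric)
        grid.insert(1, "day", day)
        grid["anova_F"] = f
        grid["anova_p"] = p
        out.append(grid)
    if not out:
        logger.warning("build_comparison_report: no computable cells")
        return pd.DataFrame(
            columns=["metric", "day", "group_a", "group_b", "mean_diff",
                     "anova_F", "anova_p", "p_tukey", "p_unadjusted", "significant"]
        )
    cols = ["metric", "day", "group_a", "group_b", "mean_diff",
            "anova_F", "anova_p", "p_tukey", "p_unadjusted", "significant"]
    return pd.concat(out, ignore_index=True)[cols]
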