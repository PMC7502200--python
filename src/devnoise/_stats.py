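"""Shared statistical helpers: pairwise Wilcoxon rank-sum tests with BH
correction, and small correlation utilities used across modules."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def pairwise_wilcoxon_bh(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum (Mann-Whitney U) tests between
    named groups, Benjamini-Hochberg corrected over the set of pairs.

    Returns a tidy frame: group_a, group_b, statistic, p_raw, p_bh.
    """
    names = [k for k, v in groups.items() if len(v) > 0]
    rows = []
    for a, b in combinations(names, 2):
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    if len(out):
        out["p_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_bh"] = pd.Series(dtype=float)
    return out


def pair_matrix(pairs: pd.DataFrame, names: list[str], column: str = "p_bh") -> pd.DataFrame:
    """Symmetric matrix view of a pairwise-test frame (diagonal NaN)."""
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for _, row in pairs.iterrows():
        mat.loc[row["group_a"], row["group_b"]] = row[column]
        mat.loc[row["group_b"], row["group_a"]] = row[column]
    return mat


def pearson_to_template(values: np.ndarray, template: np.ndarray) -> float:
    """Pearson correlation of one profile against a template; NaN when either
    vector is constant (correlation undefined)."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(template, dtype=float)
    if np.ptp(v) == 0 or np.ptp(t) == 0 or not np.all(np.isfinite(v)):
        return float("nan")
    return float(np.corrcoef(v, t)[0, 1])


def top_fraction(scores: pd.Series, top_frac: float) -> list[str]:
    """Ids of the floor(top_frac * n) highest-scoring entries among non-NaN
    scores; ties at the cutoff broken by id for determinism."""
    eligible = scores.dropna()
    k = int(np.floor(top_frac * len(eligible)))
    if k == 0:
        return []
    order = eligible.reset_index()
    order.columns = ["id", "score"]
    order = order.sort_values(["score", "id"], ascending=[False, True], kind="stable")
    return order["id"].head(k).tolist()
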