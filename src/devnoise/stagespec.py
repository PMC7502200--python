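"""Stage-specifically expressed genes via correlation with artificial
one-hot stage profiles: each gene's per-stage mean-expression vector is
correlated (Pearson) with each profile and the top 10% per profile kept."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import pearson_to_template, top_fraction


def make_profiles(n_stages: int, stage_labels: list[str] | None = None) -> pd.DataFrame:
    """One artificial profile per stage: 1 at the focal stage, 0 elsewhere.
    Returns a stages x stages frame (rows = profiles)."""
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    labels = stage_labels or [f"E{i + 1}" for i in range(n_stages)]
    if len(labels) != n_stages:
        raise ValueError("stage_labels length must equal n_stages")
    return pd.DataFrame(np.eye(n_stages), index=labels, columns=labels)


def stage_mean_expression(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-stage mean expression (genes x stages, stages sorted)."""
    meta = meta.loc[expr.columns]
    stages = sorted(meta["stage"].unique())
    return pd.DataFrame(
        {s: expr[meta.index[meta["stage"] == s]].mean(axis=1) for s in stages},
        index=expr.index,
    )


def stage_specific_genes(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    top_frac: float = 0.1,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-stage gene sets plus the full correlation table.

    For each gene and profile, Pearson correlation between the gene's
    per-stage mean-expression vector and the one-hot profile; per profile the
    floor(top_frac * n_eligible) highest-correlation genes are kept (ties at
    the cutoff broken by gene id).  Genes with constant mean-expression
    vectors are excluded (correlation undefined).  The method does not forbid
    a gene appearing in several sets; overlap is reported in the returned
    table, not resolved.
    """
    means = stage_mean_expression(expr, meta)
    if profiles is None:
        profiles = make_profiles(means.shape[1], list(means.columns))
    if list(profiles.columns) != list(means.columns):
        raise ValueError("profile stages do not match expression stages")

    values = means.to_numpy()
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} gene(s) with constant profiles excluded")

    corr_cols = {}
    for stage in profiles.index:
        template = profiles.loc[stage].to_numpy()
        c = np.array([pearson_to_template(v, template) for v in values])
        c[constant] = np.nan
        corr_cols[stage] = c
    corr = pd.DataFrame(corr_cols, index=means.index)

    sets = {s: top_fraction(corr[s], top_frac) for s in profiles.index}
    membership = pd.DataFrame(
        {s: corr.index.isin(g) for s, g in sets.items()}, index=corr.index
    )
    table = corr.add_suffix("_corr").join(membership.add_suffix("_selected"))
    table["n_sets"] = membership.sum(axis=1)
    return sets, table
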