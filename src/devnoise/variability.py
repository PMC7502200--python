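"""Per-gene, per-stage expression variability: CV, distance-to-median (DM)
and the adjusted SD, with stage comparisons and resampling analyses.

The adjusted SD is the ratio of a gene's observed per-stage SD to the SD
predicted from its global mean expression by a polynomial mean-variance
trend, which removes the strong mean dependence that both CV and DM retain.
All SDs use the population convention (divisor n); this is fixed and
documented here rather than configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pair_matrix, pairwise_wilcoxon_bh, pearson_to_template, top_fraction

EPSILON = 1e-6  # floor for trend-predicted SDs used as divisors


# ------------------------------------------------------------------ trend ---


@dataclass
class PolyTrend:
    """Polynomial mean->SD trend fitted on standardized mean expression."""

    coeffs: np.ndarray  # ascending powers, on standardized x
    x_center: float
    x_scale: float
    degree: int

    def predict(self, mean: np.ndarray) -> np.ndarray:
        z = (np.asarray(mean, dtype=float) - self.x_center) / self.x_scale
        return np.polynomial.polynomial.polyval(z, self.coeffs)

    def predict_floored(self, mean: np.ndarray) -> np.ndarray:
        return np.maximum(self.predict(mean), EPSILON)


def fit_sd_trend(
    global_mean: np.ndarray,
    global_sd: np.ndarray,
    alpha: float = 0.05,
    max_degree: int = 10,
) -> PolyTrend:
    """OLS polynomial fit of global SD on global mean, degree chosen by
    nested-model F-tests: degree d is accepted while the d vs d-1 ANOVA has
    p < alpha; the last accepted degree is returned.

    Means are standardized before powers are formed (conditioning only; the
    fitted values are unchanged).
    """
    x = np.asarray(global_mean, dtype=float)
    y = np.asarray(global_sd, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 genes to fit the mean-SD trend")
    center, scale = float(x.mean()), float(x.std() or 1.0)
    z = (x - center) / scale

    def rss_fit(d: int) -> tuple[np.ndarray, float]:
        design = np.vander(z, d + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return coef, float(resid @ resid)

    coeffs, rss_prev = rss_fit(0)
    degree = 0
    for d in range(1, max_degree + 1):
        cand, rss_d = rss_fit(d)
        df_resid = n - (d + 1)
        if df_resid <= 0 or rss_d <= 0:
            break
        f = (rss_prev - rss_d) / (rss_d / df_resid)
        p = stats.f.sf(f, 1, df_resid)
        if p < alpha:
            degree, coeffs, rss_prev = d, cand, rss_d
        else:
            break
    else:
        warnings.warn(
            f"trend improvement still significant at max_degree={max_degree}; "
            "accepting max_degree"
        )
    return PolyTrend(coeffs=coeffs, x_center=center, x_scale=scale, degree=degree)


# ------------------------------------------------------------ variability ---


def _stage_groups(meta: pd.DataFrame, columns: pd.Index) -> dict[str, list[str]]:
    meta = meta.loc[columns]
    stages = sorted(meta["stage"].unique())
    groups = {}
    for s in stages:
        cols = list(meta.index[meta["stage"] == s])
        if len(cols) < 2:
            warnings.warn(f"stage {s} has < 2 samples; excluded from variability")
            continue
        groups[s] = cols
    return groups


def stage_stats(
    expr: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(stage mean, stage SD) frames, genes x stages; population SD."""
    groups = _stage_groups(meta, expr.columns)
    means = pd.DataFrame(
        {s: expr[cols].mean(axis=1) for s, cols in groups.items()}, index=expr.index
    )
    sds = pd.DataFrame(
        {s: expr[cols].std(axis=1, ddof=0) for s, cols in groups.items()}, index=expr.index
    )
    return means, sds


def cv_table(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-stage CV = SD / mean; stages where a gene's mean is 0 are
    masked (undefined)."""
    means, sds = stage_stats(expr, meta)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sds / means
    return cv.where(means != 0)


def adjusted_sd(
    expr: pd.DataFrame, meta: pd.DataFrame, trend: PolyTrend | None = None
) -> pd.DataFrame:
    """Per-gene per-stage adjusted SD: stage SD divided by the (floored)
    trend-predicted global SD at the gene's global mean expression."""
    _, sds = stage_stats(expr, meta)
    gmean = expr.mean(axis=1)
    if trend is None:
        gsd = expr.std(axis=1, ddof=0)
        trend = fit_sd_trend(gmean.to_numpy(), gsd.to_numpy())
    pred = trend.predict_floored(gmean.to_numpy())
    return sds.div(pd.Series(pred, index=expr.index), axis=0)


def _window_assignments(n: int, window: int, overlap: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Sliding rank windows [0:w), [w-ov : 2w-ov), ... and the per-rank window
    assignment by nearest window centre (tie -> lower window)."""
    step = window - overlap
    if step <= 0:
        raise ValueError("window must exceed overlap")
    if n <= window:
        return [np.arange(n)], np.zeros(n, dtype=int)
    starts = list(range(0, n - window + 1, step))
    if starts[-1] + window < n:  # terminal partial window over the top ranks
        starts.append(n - window)
    windows = [np.arange(s, s + window) for s in starts]
    centres = np.array([(w[0] + w[-1]) / 2.0 for w in windows])
    ranks = np.arange(n)
    dist = np.abs(ranks[:, None] - centres[None, :])
    assign = np.argmin(dist, axis=1)  # argmin takes the lower index on ties
    return windows, assign


def distance_to_median(
    expr: pd.DataFrame, meta: pd.DataFrame, window: int = 50, overlap: int = 25
) -> pd.DataFrame:
    """DM_gs = log10(stage CV^2) - median over the gene's mean-expression
    window of log10(global CV^2).

    Genes are ordered by global mean ascending; windows of ``window`` genes
    with ``overlap`` genes shared between consecutive windows; each gene uses
    the window whose centre is nearest its rank (ties to the lower window).
    Genes with zero global CV are excluded (NaN rows).
    """
    gmean = expr.mean(axis=1)
    gsd = expr.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gcv2 = (gsd / gmean) ** 2
    valid = gmean.ne(0) & gcv2.gt(0)
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} gene(s) with zero global CV excluded from DM")

    stage_cv = cv_table(expr, meta)
    out = pd.DataFrame(np.nan, index=expr.index, columns=stage_cv.columns)

    ids = gmean[valid].sort_values(kind="stable").index
    log_gcv2 = np.log10(gcv2.loc[ids].to_numpy())
    windows, assign = _window_assignments(len(ids), window, overlap)
    win_medians = np.array([np.median(log_gcv2[w]) for w in windows])
    ref = pd.Series(win_medians[assign], index=ids)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_stage_cv2 = np.log10(stage_cv.loc[ids] ** 2)
    out.loc[ids] = log_stage_cv2.sub(ref, axis=0).to_numpy()
    return out.replace([-np.inf, np.inf], np.nan)


@dataclass
class VariabilityTable:
    """Per-gene global statistics plus per-gene x per-stage metrics."""

    gene_stats: pd.DataFrame  # global_mean, global_sd, predicted_sd
    stage_mean: pd.DataFrame
    stage_sd: pd.DataFrame
    cv: pd.DataFrame
    dm: pd.DataFrame
    adjusted_sd: pd.DataFrame
    trend: PolyTrend

    def metric(self, name: str) -> pd.DataFrame:
        try:
            return {"cv": self.cv, "dm": self.dm, "adjusted_sd": self.adjusted_sd}[name]
        except KeyError:
            raise KeyError(f"unknown variability metric: {name!r}") from None


def compute_variability(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    trend: PolyTrend | None = None,
    window: int = 50,
    overlap: int = 25,
) -> VariabilityTable:
    """All three metrics in one pass (shared trend and stage statistics)."""
    gmean = expr.mean(axis=1)
    gsd = expr.std(axis=1, ddof=0)
    if trend is None:
        trend = fit_sd_trend(gmean.to_numpy(), gsd.to_numpy())
    means, sds = stage_stats(expr, meta)
    gene_stats = pd.DataFrame(
        {
            "global_mean": gmean,
            "global_sd": gsd,
            "predicted_sd": trend.predict_floored(gmean.to_numpy()),
        }
    )
    return VariabilityTable(
        gene_stats=gene_stats,
        stage_mean=means,
        stage_sd=sds,
        cv=cv_table(expr, meta),
        dm=distance_to_median(expr, meta, window=window, overlap=overlap),
        adjusted_sd=sds.div(gene_stats["predicted_sd"], axis=0),
        trend=trend,
    )


# -------------------------------------------------------- stage comparison ---


@dataclass
class StageComparison:
    medians: pd.Series          # per-stage median over genes
    n_samples: pd.Series        # samples per stage (NaN when unknown)
    pairs: pd.DataFrame         # group_a, group_b, statistic, p_raw, p_bh

    def p_matrix(self, column: str = "p_bh") -> pd.DataFrame:
        return pair_matrix(self.pairs, list(self.medians.index), column)


def stage_summary(
    metric_df: pd.DataFrame, meta: pd.DataFrame | None = None
) -> StageComparison:
    """Per-stage medians of a per-gene metric plus all pairwise two-sided
    Wilcoxon rank-sum tests, BH-corrected over the set of stage pairs."""
    if metric_df.shape[1] < 2:
        raise ValueError("need at least 2 stages to compare")
    groups = {s: metric_df[s].dropna().to_numpy() for s in metric_df.columns}
    medians = pd.Series({s: float(np.median(v)) for s, v in groups.items()}, name="median")
    if meta is not None:
        counts = meta["stage"].value_counts()
        n = pd.Series({s: int(counts.get(s, 0)) for s in metric_df.columns}, name="n")
    else:
        n = pd.Series(np.nan, index=metric_df.columns, name="n")
    return StageComparison(medians=medians, n_samples=n, pairs=pairwise_wilcoxon_bh(groups))


# ------------------------------------------------------------- resampling ---


def bootstrap_stage_medians(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    trend: PolyTrend,
    n_boot: int = 500,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage bootstrap of the adjusted-SD median.

    Per replicate, resample ``n`` samples (the minimum stage size) with
    replacement within each stage, recompute the adjusted SD against the
    fixed full-data trend, and keep the per-stage median.  Returns
    (replicates x stages medians, pairwise Wilcoxon on the bootstrap
    medians)."""
    rng = np.random.default_rng(rng)
    groups = _stage_groups(meta, expr.columns)
    n = min(len(c) for c in groups.values())
    if n < 2:
        raise ValueError("smallest stage has < 2 samples")
    pred = trend.predict_floored(expr.mean(axis=1).to_numpy())
    values = {s: expr[cols].to_numpy() for s, cols in groups.items()}
    medians = np.empty((n_boot, len(groups)))
    for b in range(n_boot):
        for si, (s, mat) in enumerate(values.items()):
            take = rng.integers(0, mat.shape[1], size=n)
            sd = mat[:, take].std(axis=1, ddof=0)
            medians[b, si] = np.median(sd / pred)
    med_df = pd.DataFrame(medians, columns=list(groups))
    tests = pairwise_wilcoxon_bh({s: med_df[s].to_numpy() for s in med_df.columns})
    return med_df, tests


def subsample_equal(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    trend: PolyTrend,
    n: int = 8,
    reps: int = 500,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Equal-n subsampling: per repetition draw ``n`` samples per stage
    without replacement, recompute stage adjusted SDs (fixed trend) and
    record the median across genes.  Returns a reps x stages frame."""
    rng = np.random.default_rng(rng)
    groups = _stage_groups(meta, expr.columns)
    for s, cols in groups.items():
        if len(cols) < n:
            raise ValueError(f"stage {s} has only {len(cols)} samples; cannot draw {n}")
    pred = trend.predict_floored(expr.mean(axis=1).to_numpy())
    values = {s: expr[cols].to_numpy() for s, cols in groups.items()}
    out = np.empty((reps, len(groups)))
    for r in range(reps):
        for si, (s, mat) in enumerate(values.items()):
            take = rng.choice(mat.shape[1], size=n, replace=False)
            sd = mat[:, take].std(axis=1, ddof=0)
            out[r, si] = np.median(sd / pred)
    return pd.DataFrame(out, columns=list(groups))


# ------------------------------------------------------------ gene groups ---


def group_compare(
    metric_df: pd.DataFrame, groups: dict[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group per-stage medians and group-vs-complement Wilcoxon tests.

    A group equal to the whole gene universe is degenerate and skipped with
    a warning.  Returns (medians frame indexed (group, stage), tests frame).
    """
    universe = set(metric_df.index)
    med_rows, test_rows = [], []
    for name, members in groups.items():
        inside = sorted(universe & set(members))
        if not inside:
            raise ValueError(f"group {name!r} has empty intersection with the gene universe")
        outside = sorted(universe - set(members))
        if not outside:
            warnings.warn(f"group {name!r} equals the gene universe; comparison skipped")
            continue
        for s in metric_df.columns:
            x = metric_df.loc[inside, s].dropna().to_numpy()
            y = metric_df.loc[outside, s].dropna().to_numpy()
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            med_rows.append((name, s, float(np.median(x)), float(np.median(y))))
            test_rows.append((name, s, float(res.statistic), float(res.pvalue)))
    medians = pd.DataFrame(
        med_rows, columns=["group", "stage", "median_in", "median_out"]
    )
    tests = pd.DataFrame(test_rows, columns=["group", "stage", "statistic", "p_raw"])
    if len(tests):
        from statsmodels.stats.multitest import multipletests

        tests["p_bh"] = multipletests(tests["p_raw"], method="fdr_bh")[1]
    return medians, tests


def hourglass_genes(adjsd: pd.DataFrame, top_frac: float = 0.1) -> list[str]:
    """Genes whose variability profile follows the global (median) profile:
    Pearson correlation of each gene's per-stage adjusted-SD profile with the
    across-gene median profile; the floor(top_frac * n_eligible) highest
    correlations are returned (ties at the cutoff broken by gene id).
    Genes with constant or incomplete profiles are excluded."""
    complete = adjsd.dropna()
    if len(complete) < 10:
        raise ValueError("need at least 10 genes with complete variability profiles")
    template = complete.median(axis=0).to_numpy()
    corr = pd.Series(
        {g: pearson_to_template(row, template) for g, row in complete.iterrows()},
        name="profile_corr",
    )
    n_excluded = corr.isna().sum()
    if n_excluded:
        warnings.warn(f"{n_excluded} gene(s) with constant profiles excluded")
    return top_fraction(corr, top_frac)
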