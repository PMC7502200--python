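"""From raw single-embryo counts to the analysis-ready expression matrix.

Steps mirror a standard 3'-end bulk pipeline: per-sample QC on mapped reads
and expressed-gene counts, removal of lowly expressed genes by mean CPM,
quantile normalization of log2 CPM, empirical-Bayes batch correction
(ComBat) with non-negativity clipping, classical MDS on correlation
distance, and flagging of developmentally arrested (unfertilized-egg)
samples by cluster-level correlation with an egg reference profile plus a
meiosis-gene rank score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome import validate_gene_models


class QCError(RuntimeError):
    """All samples failed quality control."""


def qc_filter(
    counts: pd.DataFrame, min_reads: int = 300_000, min_genes: int = 4500
) -> list[str]:
    """Samples passing QC: total count >= min_reads AND number of expressed
    genes (count >= 1) >= min_genes.  Removal is by strict inequality, so
    samples exactly at a threshold are kept."""
    if counts.empty:
        raise ValueError("empty count matrix")
    totals = counts.sum(axis=0)
    expressed = (counts >= 1).sum(axis=0)
    keep = [s for s in counts.columns if totals[s] >= min_reads and expressed[s] >= min_genes]
    if not keep:
        report = pd.DataFrame({"total_reads": totals, "expressed_genes": expressed})
        raise QCError(f"all samples failed QC:\n{report.to_string()}")
    return keep


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(counts.columns[totals == 0])
        raise ValueError(f"zero total count in sample(s): {zero}")
    return counts / totals * 1e6


def filter_genes(counts: pd.DataFrame) -> list[str]:
    """Genes kept for analysis: mean CPM across samples > 1 (genes with mean
    CPM <= 1 are removed).  Retained genes keep their original integer
    counts."""
    mean_cpm = cpm(counts).mean(axis=1)
    return list(counts.index[mean_cpm > 1.0])


def normalize(
    counts: pd.DataFrame, pseudocount: float = 0.5, ties: str = "stable"
) -> pd.DataFrame:
    """log2(CPM + pseudocount) followed by full quantile normalization.

    With ``ties="stable"`` each column's sorted values are replaced by the
    across-column mean of sorted values (ties broken by input order), so
    every column ends with the identical multiset of values — the defining
    quantile-normalization property, held exactly.  ``ties="average"``
    instead assigns tied entries the mean of their would-be quantiles.
    """
    if counts.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    log_expr = np.log2(cpm(counts).to_numpy() + pseudocount)
    ref = np.sort(log_expr, axis=0).mean(axis=1)
    out = np.empty_like(log_expr)
    n = log_expr.shape[0]
    for j in range(log_expr.shape[1]):
        col = log_expr[:, j]
        if ties == "stable":
            order = np.argsort(col, kind="stable")
            out[order, j] = ref
        elif ties == "average":
            out[:, j] = np.interp(rankdata(col, method="average"), np.arange(1, n + 1), ref)
        else:
            raise ValueError(f"unknown ties mode: {ties!r}")
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def correct_batch(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    protect_stage: bool = True,
    zero_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """ComBat location/scale batch adjustment followed by the clipping rule.

    Parametric empirical-Bayes adjustment (per-gene batch means/variances
    shrunk toward across-gene priors, then removed), with stage kept as a
    covariate when ``protect_stage`` so stage-wise signal confounded with
    library is not erased.  Afterwards any value < 0 is set to 0, as is any
    entry flagged by ``zero_mask`` (default: entries that were exactly 0
    before correction).
    """
    meta = meta.loc[expr.columns]
    if zero_mask is None:
        zero_mask = expr == 0
    else:
        zero_mask = zero_mask.loc[expr.index, expr.columns]

    from ._combat import combat

    batches = meta["batch"].astype(str)
    if batches.nunique() < 2:
        corrected = expr.copy()
    else:
        covariates = None
        if protect_stage:
            covariates = pd.get_dummies(
                meta["stage"].astype(str), drop_first=True, dtype=float
            )
        corrected = combat(expr, batches, covariates)

    corrected[corrected < 0] = 0.0
    corrected[zero_mask] = 0.0
    return corrected


def correlation_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """d(i, j) = 1 - Pearson correlation of expression columns."""
    sds = expr.std(axis=0)
    if (sds == 0).any():
        bad = list(expr.columns[sds == 0])
        raise ValueError(f"constant expression column(s), correlation undefined: {bad}")
    return 1.0 - expr.corr(method="pearson")


def mds_embed(expr: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical MDS (principal coordinates) on 1 - Pearson correlation.

    Deterministic: each axis is sign-fixed so its largest-magnitude
    coordinate is positive.
    """
    if expr.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    d = correlation_distance(expr).to_numpy()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    for a in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return pd.DataFrame(
        coords, index=expr.columns, columns=[f"MDS{i + 1}" for i in range(coords.shape[1])]
    )


def flag_unfertilized(
    expr: pd.DataFrame,
    reference_profile: pd.Series,
    meiosis_genes: set[str] | None = None,
    embedding: pd.DataFrame | None = None,
    min_corr_gap: float = 0.05,
    min_meiosis_gap: float = 0.02,
) -> pd.DataFrame:
    """Flag developmentally arrested samples.

    Per sample: (a) Pearson correlation with the unfertilized-egg reference
    profile on shared genes; (b) a meiosis score — the difference between the
    mean expression rank (scaled to [0, 1]) of meiosis genes and of all genes.
    Samples are split by 2-means on the MDS embedding; the cluster with the
    higher mean reference correlation is flagged only when its correlation
    advantage exceeds ``min_corr_gap`` and (when a meiosis set is supplied)
    its meiosis-score advantage exceeds ``min_meiosis_gap`` — so a clean
    all-fertilized trajectory is not split into a spurious arrested cluster.
    """
    shared = expr.index.intersection(reference_profile.index)
    if len(shared) < 0.5 * expr.shape[0]:
        raise ValueError("reference profile covers < 50% of genes in the expression matrix")
    ref = reference_profile.loc[shared].to_numpy(dtype=float)
    sub = expr.loc[shared]
    ref_c = ref - ref.mean()
    mat = sub.to_numpy() - sub.to_numpy().mean(axis=0)
    corr = (mat * ref_c[:, None]).sum(axis=0) / (
        np.sqrt((mat**2).sum(axis=0)) * np.sqrt((ref_c**2).sum())
    )

    meiosis_score = np.full(expr.shape[1], np.nan)
    have_meiosis = False
    if meiosis_genes is not None:
        msel = expr.index.isin(meiosis_genes)
        if msel.sum() == 0:
            warnings.warn("empty meiosis gene set: meiosis score omitted")
        else:
            have_meiosis = True
            ranks = rankdata(expr.to_numpy(), axis=0) / expr.shape[0]
            meiosis_score = ranks[msel].mean(axis=0) - ranks.mean(axis=0)

    if embedding is None:
        embedding = mds_embed(expr, k=2)
    from sklearn.cluster import KMeans

    labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
        embedding.to_numpy()
    )
    mean_corr = np.array([corr[labels == c].mean() for c in (0, 1)])
    cand = int(np.argmax(mean_corr))
    flagged = np.zeros(expr.shape[1], dtype=bool)
    corr_gap = mean_corr[cand] - mean_corr[1 - cand]
    ok = corr_gap > min_corr_gap
    if ok and have_meiosis:
        gap = meiosis_score[labels == cand].mean() - meiosis_score[labels == 1 - cand].mean()
        ok = gap > min_meiosis_gap
    if ok:
        flagged = labels == cand

    return pd.DataFrame(
        {
            "reference_corr": corr,
            "meiosis_score": meiosis_score,
            "cluster": labels,
            "unfertilized": flagged,
        },
        index=expr.columns,
    )


def x_autosome_ratio(expr: pd.DataFrame, models: pd.DataFrame) -> pd.Series:
    """Per sample: median expression of X-linked genes over median expression
    of autosomal genes."""
    validate_gene_models(models)
    shared = expr.index.intersection(models.index)
    chroms = models.loc[shared, "chrom"].astype(str)
    x_genes = shared[chroms.str.upper().str.lstrip("CHR") == "X"]
    auto_genes = shared.difference(x_genes)
    if len(x_genes) == 0:
        raise ValueError("no X-linked genes among expressed genes")
    if len(auto_genes) == 0:
        raise ValueError("no autosomal genes among expressed genes")
    return expr.loc[x_genes].median(axis=0) / expr.loc[auto_genes].median(axis=0)
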