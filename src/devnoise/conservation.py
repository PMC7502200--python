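"""Promoter sequence conservation: strand-aware promoter regions, per-region
phastCons means, stage-set comparisons, and the expression-weighted
transcriptome conservation index (TPI) with gene-bootstrap confidence
intervals.

The core promoter follows the EPD convention: 49 bp upstream of the TSS to
10 bp downstream, TSS base included (60 bp total).  Window flavours (200 bp,
400 bp, 1 kb, proximal +/-2 kb) are centred on the TSS coordinate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import pairwise_wilcoxon_bh
from .genome import ConservationTrack, tss_coord, validate_gene_models
from .variability import StageComparison, stage_summary

logger = logging.getLogger(__name__)

#: symmetric window flavours: nominal total width in bp
WINDOW_FLAVOURS = {"win200": 200, "win400": 400, "win1000": 1000, "proximal": 4000}


@dataclass
class PromoterRegion:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    flavour: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty promoter region for {self.gene_id}")


def promoter_region(
    gene_id: str,
    model: pd.Series,
    flavour: str = "core",
    chrom_size: int | None = None,
) -> PromoterRegion:
    """Build one promoter region around a gene's TSS.

    ``core``: -49..+10 relative to the TSS base, strand-aware (60 bp; on the
    plus strand ``[tss-49, tss+11)``, mirrored on the minus strand).  The
    window flavours are strand-symmetric around the TSS coordinate.  Regions
    extending past the chromosome bounds are clipped (flagged and logged).
    """
    strand = model["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r} for gene {gene_id}")
    tss = int(model["start"] if strand == "+" else model["end"] - 1)
    if flavour == "core":
        start, end = (tss - 49, tss + 11) if strand == "+" else (tss - 10, tss + 50)
    elif flavour in WINDOW_FLAVOURS:
        half = WINDOW_FLAVOURS[flavour] // 2
        start, end = tss - half, tss + half
    else:
        raise ValueError(f"unknown promoter flavour: {flavour!r}")
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_size is not None and end > chrom_size:
        end, clipped = chrom_size, True
    if clipped:
        logger.info("promoter region for %s (%s) clipped to [%d, %d)", gene_id, flavour, start, end)
    return PromoterRegion(
        gene_id=gene_id,
        chrom=str(model["chrom"]),
        strand=strand,
        start=start,
        end=end,
        flavour=flavour,
        clipped=clipped,
    )


def mean_conservation(region: PromoterRegion, track: ConservationTrack) -> float:
    """Unweighted per-base mean conservation over the region; uncovered bases
    are excluded from both numerator and denominator (NaN if none covered)."""
    return track.region_mean(region.chrom, region.start, region.end)


def promoter_conservation(
    models: pd.DataFrame,
    track: ConservationTrack,
    flavour: str = "core",
) -> pd.Series:
    """Per-gene promoter conservation scores for one flavour."""
    validate_gene_models(models)
    sizes = track.chrom_sizes
    scores = {}
    for gene_id, model in models.iterrows():
        region = promoter_region(
            gene_id, model, flavour, chrom_size=sizes.get(str(model["chrom"]))
        )
        scores[gene_id] = mean_conservation(region, track)
    return pd.Series(scores, name=f"conservation_{flavour}")


def stage_set_conservation(
    stage_sets: dict[str, list[str]], scores: pd.Series
) -> tuple[dict[str, np.ndarray], StageComparison]:
    """Per-stage conservation-score distributions for stage-specific gene
    sets, with medians and pairwise Wilcoxon-BH tests.  Empty sets (or sets
    with no scored genes) are skipped with a warning."""
    dists = {}
    for stage, genes in stage_sets.items():
        vals = scores.reindex(genes).dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"stage {stage} has no scored genes; skipped")
            continue
        dists[stage] = vals
    medians = pd.Series({s: float(np.median(v)) for s, v in dists.items()}, name="median")
    n = pd.Series({s: len(v) for s, v in dists.items()}, name="n")
    comparison = StageComparison(medians=medians, n_samples=n, pairs=pairwise_wilcoxon_bh(dists))
    return dists, comparison


# -------------------------------------------------------------------- TPI ---


@dataclass
class TPIResult:
    """Per-stage transcriptome conservation index with optional CIs."""

    tpi: pd.Series
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None
    n_genes: int = 0


def _tpi_values(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """TPI_s = sum_i score_i * e_is / sum_i e_is for each stage column."""
    wsum = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(wsum > 0, (scores[:, None] * weights).sum(axis=0) / wsum, np.nan)


def tpi(
    expr: pd.DataFrame, meta: pd.DataFrame, scores: pd.Series
) -> TPIResult:
    """Expression-weighted mean conservation per stage.

    Weights e_is are the per-stage means of the (log-scale, non-negative)
    expression values; genes without a conservation score are excluded from
    both sums.  Stages whose weights are all zero yield NaN.
    """
    from .stagespec import stage_mean_expression

    weights = stage_mean_expression(expr, meta)
    shared = weights.index.intersection(scores.dropna().index)
    w = weights.loc[shared].to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("expression weights must be non-negative (clip before TPI)")
    s = scores.loc[shared].to_numpy(dtype=float)
    values = _tpi_values(s, w)
    return TPIResult(tpi=pd.Series(values, index=weights.columns, name="TPI"), n_genes=len(shared))


def tpi_ci(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    scores: pd.Series,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> TPIResult:
    """TPI with gene-bootstrap 95% confidence intervals: gene ids are
    resampled with replacement ``n_boot`` times and the 2.5%/97.5% empirical
    percentiles of the recomputed indices taken per stage."""
    if n_boot < 100:
        warnings.warn("n_boot < 100: confidence intervals will be unstable")
    from .stagespec import stage_mean_expression

    rng = np.random.default_rng(rng)
    weights = stage_mean_expression(expr, meta)
    shared = weights.index.intersection(scores.dropna().index)
    if len(shared) < 10:
        raise ValueError("need at least 10 scored genes for a bootstrap CI")
    w = weights.loc[shared].to_numpy(dtype=float)
    s = scores.loc[shared].to_numpy(dtype=float)
    point = _tpi_values(s, w)

    n = len(shared)
    boots = np.empty((n_boot, w.shape[1]))
    sw = s[:, None] * w
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = sw[idx].sum(axis=0) / w[idx].sum(axis=0)
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)
    stages = weights.columns
    return TPIResult(
        tpi=pd.Series(point, index=stages, name="TPI"),
        ci_lower=pd.Series(lo, index=stages, name="ci_lower"),
        ci_upper=pd.Series(hi, index=stages, name="ci_upper"),
        n_genes=n,
    )
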