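"""Promoter histone-modification signal: proximal-promoter window means,
intergenic Z-score normalization (so marks are comparable across stages and
libraries), and (partial) Spearman correlations of promoter signal against
expression variability, promoter conservation and promoter shape."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from ._stats import pairwise_wilcoxon_bh
from .genome import SignalTrack, tes_coord, tss_coord, validate_gene_models
from .variability import StageComparison

logger = logging.getLogger(__name__)


def promoter_signal(
    models: pd.DataFrame, track: SignalTrack, half_width: int = 2000
) -> pd.Series:
    """Per-gene mean signal over the proximal promoter [TSS-hw, TSS+hw).

    Interval-map "mean" semantics: every window overlapping the promoter
    counts once, regardless of overlap length.  Promoters at chromosome
    edges use the remaining windows; genes with no overlapping window get
    NaN.
    """
    validate_gene_models(models)
    tss = tss_coord(models)
    out = {}
    for gene_id, model in models.iterrows():
        t = int(tss[gene_id])
        out[gene_id] = track.overlapping_mean(
            str(model["chrom"]), t - half_width, t + half_width
        )
    return pd.Series(out, name=f"{track.mark}_{track.stage}")


def intergenic_regions(
    models: pd.DataFrame, chrom_sizes: dict[str, int], half_width: int = 2000
) -> dict[str, list[tuple[int, int]]]:
    """Genome complement of the union of proximal promoters (+/-hw around
    the TSS) and gene bodies (TSS..TES), as merged half-open intervals.

    Overlapping genes are merged before complementing, so nothing is
    double-subtracted.  An empty complement on every chromosome is an error.
    """
    validate_gene_models(models)
    tss = tss_coord(models)
    tes = tes_coord(models)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for gene_id, model in models.iterrows():
        chrom = str(model["chrom"])
        if chrom not in occupied:
            continue
        t, e = int(tss[gene_id]), int(tes[gene_id])
        body = (min(t, e), max(t, e) + 1)
        prom = (t - half_width, t + half_width)
        start = max(0, min(body[0], prom[0]))
        end = min(chrom_sizes[chrom], max(body[1], prom[1]))
        occupied[chrom].append((start, end))

    complement: dict[str, list[tuple[int, int]]] = {}
    total = 0
    for chrom, size in chrom_sizes.items():
        merged: list[list[int]] = []
        for start, end in sorted(occupied[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        gaps, pos = [], 0
        for start, end in merged:
            if start > pos:
                gaps.append((pos, start))
            pos = max(pos, end)
        if pos < size:
            gaps.append((pos, size))
        complement[chrom] = gaps
        total += sum(e - s for s, e in gaps)
    if total == 0:
        raise ValueError("genes and promoters tile the whole genome: no intergenic region left")
    return complement


def zscore_track(
    track: SignalTrack, intergenic: dict[str, list[tuple[int, int]]]
) -> SignalTrack:
    """Z-score every window against the intergenic background.

    The mean and SD (population convention) are computed over windows fully
    contained in an intergenic interval; windows straddling a boundary are
    excluded (their count is logged).  Every window is then mapped to
    (x - mu) / sigma.
    """
    values, n_straddling = [], 0
    for chrom, regions in intergenic.items():
        if chrom not in track.scores or not regions:
            continue
        starts, ends = track.window_bounds(chrom)
        rs = np.array([r[0] for r in regions])
        re_ = np.array([r[1] for r in regions])
        # regions are sorted and disjoint: the only candidate region for a
        # window is the last one starting at or before the window start
        idx = np.searchsorted(rs, starts, side="right") - 1
        valid = idx >= 0
        i = np.clip(idx, 0, None)
        inside = valid & (ends <= re_[i])
        touch_left = valid & (starts < re_[i])
        nxt = np.clip(idx + 1, 0, len(rs) - 1)
        touch_right = (idx + 1 < len(rs)) & (ends > rs[nxt])
        touching = touch_left | touch_right
        n_straddling += int((touching & ~inside).sum())
        values.append(track.scores[chrom][inside])
    if n_straddling:
        logger.info("%d window(s) straddling an intergenic boundary excluded", n_straddling)
    pooled = np.concatenate(values) if values else np.empty(0)
    if len(pooled) < 2:
        raise ValueError("fewer than 2 fully intergenic windows")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=0))
    if sigma == 0:
        raise ValueError("intergenic signal has zero standard deviation")
    return track.transformed(mu, sigma)


def signal_feature_correlation(
    signal: pd.Series, feature: pd.Series
) -> tuple[float, float]:
    """Spearman correlation (rho, two-sided p) between a per-gene signal
    summary and a per-gene feature, on genes with both values."""
    df = pd.concat([signal, feature], axis=1).dropna()
    if len(df) < 10:
        raise ValueError("fewer than 10 genes with both signal and feature values")
    rho, p = stats.spearmanr(df.iloc[:, 0], df.iloc[:, 1])
    return float(rho), float(p)


def partial_spearman(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Spearman partial correlation of x and y controlling for one variable.

    All three vectors are rank-transformed, then
    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))
    on the ranks.  Complete cases only; undefined when either variable is a
    perfect monotone function of the control.
    """
    arr = np.column_stack([x, y, control]).astype(float)
    arr = arr[np.isfinite(arr).all(axis=1)]
    r = np.corrcoef(rankdata(arr, axis=0), rowvar=False)
    r_xy, r_xz, r_yz = r[0, 1], r[0, 2], r[1, 2]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("partial correlation undefined: a variable is rank-degenerate "
                         "with the control")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


@dataclass
class GeneSignal:
    """Per-gene promoter signal for one mark across stages (genes x stages),
    raw and Z-scored."""

    mark: str
    raw: pd.DataFrame
    zscored: pd.DataFrame

    def stage_mean(self, zscored: bool = True) -> pd.Series:
        table = self.zscored if zscored else self.raw
        return table.mean(axis=1)


def promoter_signal_by_stage(
    models: pd.DataFrame,
    tracks: dict[tuple[str, str], SignalTrack],
    mark: str,
    intergenic: dict[str, list[tuple[int, int]]] | None = None,
    half_width: int = 2000,
) -> GeneSignal:
    """Promoter signal table for one mark over all stages present in
    ``tracks``, both raw and intergenic-Z-scored."""
    stages = sorted(stage for (m, stage) in tracks if m == mark)
    if not stages:
        raise ValueError(f"no tracks for mark {mark!r}")
    raw, z = {}, {}
    for stage in stages:
        track = tracks[(mark, stage)]
        raw[stage] = promoter_signal(models, track, half_width)
        if intergenic is not None:
            z[stage] = promoter_signal(models, zscore_track(track, intergenic), half_width)
    raw_df = pd.DataFrame(raw)
    z_df = pd.DataFrame(z) if z else raw_df * np.nan
    return GeneSignal(mark=mark, raw=raw_df, zscored=z_df)


def stage_signal_summary(gene_signal: GeneSignal, zscored: bool = True) -> StageComparison:
    """Per-stage distributions of per-gene promoter signal (Z-scored by
    default) with pairwise Wilcoxon-BH tests; stages whose column is all-NaN
    are omitted."""
    table = gene_signal.zscored if zscored else gene_signal.raw
    groups = {}
    for stage in table.columns:
        vals = table[stage].dropna().to_numpy()
        if len(vals) == 0:
            logger.info("stage %s has no promoter signal values; omitted", stage)
            continue
        groups[stage] = vals
    medians = pd.Series({s: float(np.median(v)) for s, v in groups.items()}, name="median")
    n = pd.Series({s: len(v) for s, v in groups.items()}, name="n")
    pairs = (
        pairwise_wilcoxon_bh(groups)
        if len(groups) > 1
        else pd.DataFrame(columns=["group_a", "group_b", "statistic", "p_raw", "p_bh"])
    )
    return StageComparison(medians=medians, n_samples=n, pairs=pairs)
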