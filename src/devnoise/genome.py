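"""Genomic containers: gene models, conservation tracks, windowed signal tracks.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open ``[start, end)`` (BED-native).  A gene
model stores its transcribed interval plus strand; the transcription start
site (TSS) is the coordinate of the first transcribed base: ``start`` on the
plus strand, ``end - 1`` on the minus strand.  Promoter windows are built
around the TSS coordinate.

Conservation is a piecewise-constant per-base track (scores in [0, 1]);
signal tracks hold fixed 35-bp windows of background-subtracted tag density,
one track per histone mark per developmental stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fixed window width of the histone signal tracks (bp)
SIGNAL_WINDOW = 35

GENE_MODEL_COLUMNS = ["chrom", "start", "end", "strand"]


def validate_gene_models(models: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-model table (indexed by gene id) and return it.

    Requires columns chrom/start/end/strand, strand in {+,-}, end > start,
    unique gene ids.
    """
    missing = [c for c in GENE_MODEL_COLUMNS if c not in models.columns]
    if missing:
        raise ValueError(f"gene models missing columns: {missing}")
    if models.index.duplicated().any():
        raise ValueError("duplicate gene ids in gene models")
    bad_strand = set(models["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"unknown strand value(s): {sorted(bad_strand)}")
    if (models["end"] <= models["start"]).any():
        raise ValueError("gene models must satisfy end > start")
    return models


def tss_coord(models: pd.DataFrame) -> pd.Series:
    """0-based coordinate of the TSS base for every gene."""
    plus = models["strand"] == "+"
    return pd.Series(
        np.where(plus, models["start"], models["end"] - 1),
        index=models.index,
        name="tss",
    )


def tes_coord(models: pd.DataFrame) -> pd.Series:
    """0-based coordinate of the last transcribed base (TES) for every gene."""
    plus = models["strand"] == "+"
    return pd.Series(
        np.where(plus, models["end"] - 1, models["start"]),
        index=models.index,
        name="tes",
    )


@dataclass
class ConservationTrack:
    """Piecewise-constant per-base conservation scores (phastCons-like).

    ``intervals`` maps chromosome -> DataFrame(start, end, value) with sorted,
    non-overlapping rows.  Bases not covered by any interval are *uncovered*
    and are excluded from means.
    """

    intervals: dict[str, pd.DataFrame]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, df in self.intervals.items():
            arr = df["value"].to_numpy()
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"conservation scores outside [0,1] on {chrom}")
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            if (ends <= starts).any() or (starts[1:] < ends[:-1]).any():
                raise ValueError(f"intervals not sorted/non-overlapping on {chrom}")

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Unweighted per-base mean over [start, end); uncovered bases are
        excluded from numerator and denominator.  NaN if fully uncovered."""
        if chrom not in self.intervals:
            return float("nan")
        df = self.intervals[chrom]
        s = df["start"].to_numpy()
        e = df["end"].to_numpy()
        v = df["value"].to_numpy()
        ov = np.minimum(e, end) - np.maximum(s, start)
        mask = ov > 0
        covered = ov[mask].sum()
        if covered == 0:
            return float("nan")
        return float((v[mask] * ov[mask]).sum() / covered)

    def to_per_base(self, chrom: str) -> np.ndarray:
        """Expand one chromosome to a per-base array (NaN where uncovered).

        Intended for small (test-sized) genomes only.
        """
        size = self.chrom_sizes.get(chrom)
        if size is None:
            size = int(self.intervals[chrom]["end"].max())
        out = np.full(size, np.nan)
        for start, end, value in self.intervals[chrom].itertuples(index=False):
            out[start:end] = value
        return out


@dataclass
class SignalTrack:
    """Histone-modification signal in fixed 35-bp windows.

    ``scores`` maps chromosome -> 1-D array; window ``i`` covers
    ``[i*width, min((i+1)*width, chrom_size))``.  The terminal window may be
    truncated at the chromosome end.
    """

    mark: str
    stage: str
    scores: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    width: int = SIGNAL_WINDOW

    def n_windows(self, chrom: str) -> int:
        return len(self.scores[chrom])

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of all windows on a chromosome."""
        n = self.n_windows(chrom)
        starts = np.arange(n, dtype=np.int64) * self.width
        ends = np.minimum(starts + self.width, self.chrom_sizes[chrom])
        return starts, ends

    def overlapping_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean score of all windows overlapping [start, end) — interval-map
        'mean' semantics: a window counts once regardless of overlap length.
        NaN if no window overlaps."""
        if chrom not in self.scores:
            return float("nan")
        arr = self.scores[chrom]
        lo = max(0, int(start) // self.width)
        hi = min(len(arr), -(-int(end) // self.width))  # ceil division
        if hi <= lo:
            return float("nan")
        return float(arr[lo:hi].mean())

    def transformed(self, mu: float, sigma: float) -> "SignalTrack":
        """Affine transform (x - mu) / sigma applied to every window."""
        return SignalTrack(
            mark=self.mark,
            stage=self.stage,
            scores={c: (a - mu) / sigma for c, a in self.scores.items()},
            chrom_sizes=dict(self.chrom_sizes),
            width=self.width,
        )
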