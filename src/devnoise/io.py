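"""Readers and writers for the plain-text formats the pipeline consumes:
count matrices (TSV / MatrixMarket), sample metadata TSV, gene models (BED12),
conservation (fixedStep wig), histone signal (bedGraph) and small per-gene
tables.  All genomic output is 0-based half-open except wig, which is 1-based
per the format."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .genome import ConservationTrack, SignalTrack, validate_gene_models

# ---------------------------------------------------------------- counts ---


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    return counts.astype(np.int64)


def write_counts_mtx(counts: pd.DataFrame, path: str) -> None:
    """MatrixMarket integer matrix plus `<path>.genes.tsv` / `<path>.samples.tsv`
    sidecars carrying the row/column ids."""
    spio.mmwrite(path, sp.csr_matrix(counts.to_numpy(dtype=np.int64)), field="integer")
    pd.Series(counts.index).to_csv(path + ".genes.tsv", sep="\t", index=False, header=["gene_id"])
    pd.Series(counts.columns).to_csv(
        path + ".samples.tsv", sep="\t", index=False, header=["sample_id"]
    )


def read_counts_mtx(path: str) -> pd.DataFrame:
    if not os.path.exists(path) and os.path.exists(path + ".mtx"):
        path = path + ".mtx"
    mat = spio.mmread(path).toarray().astype(np.int64)
    genes = pd.read_csv(path + ".genes.tsv", sep="\t")["gene_id"]
    samples = pd.read_csv(path + ".samples.tsv", sep="\t")["sample_id"]
    return pd.DataFrame(mat, index=genes.to_numpy(), columns=samples.to_numpy())


# -------------------------------------------------------------- metadata ---


def write_meta_tsv(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_meta_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ------------------------------------------------------------ gene models ---


def write_bed12(models: pd.DataFrame, path: str) -> None:
    """One BED12 record per gene (single block spanning the gene)."""
    validate_gene_models(models)
    with open(path, "w") as fh:
        for gene_id, row in models.iterrows():
            start, end = int(row["start"]), int(row["end"])
            size = end - start
            fh.write(
                f"{row['chrom']}\t{start}\t{end}\t{gene_id}\t0\t{row['strand']}"
                f"\t{start}\t{end}\t0\t1\t{size},\t0,\n"
            )


def read_bed(path: str) -> pd.DataFrame:
    """Gene models from BED (first six columns used)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
    models = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    models = models.set_index("gene_id")
    return validate_gene_models(models)


# ----------------------------------------------------------- conservation ---


def write_wig(track: ConservationTrack, path: str) -> None:
    """fixedStep wig, step=1 span=1 (per-base); 1-based starts per the format.

    Piecewise intervals are expanded to per-base lines: intended for the
    test-sized genomes the fixture writer produces.
    """
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            df = track.intervals[chrom]
            prev_end = None
            for start, end, value in df.itertuples(index=False):
                if start != prev_end:
                    fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
                for _ in range(int(end - start)):
                    fh.write(f"{value:g}\n")
                prev_end = end


def read_wig(path: str, chrom_sizes: dict[str, int] | None = None) -> ConservationTrack:
    """Parse a fixedStep (step=1) wig back into a piecewise track, merging
    runs of equal consecutive values."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    chrom, pos = None, 0
    for line in open(path):
        line = line.strip()
        if not line or line.startswith(("track", "browser", "#")):
            continue
        if line.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in line.split()[1:])
            chrom = fields["chrom"]
            pos = int(fields["start"]) - 1
            if int(fields.get("step", 1)) != 1:
                raise ValueError("only step=1 fixedStep wig supported")
            intervals.setdefault(chrom, [])
            continue
        value = float(line)
        runs = intervals[chrom]
        if runs and runs[-1][1] == pos and runs[-1][2] == value:
            runs[-1] = (runs[-1][0], pos + 1, value)
        else:
            runs.append((pos, pos + 1, value))
        pos += 1
    frames = {
        c: pd.DataFrame(v, columns=["start", "end", "value"]) for c, v in intervals.items()
    }
    return ConservationTrack(frames, chrom_sizes or {})


# --------------------------------------------------------------- bedGraph ---


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.scores):
            starts, ends = track.window_bounds(chrom)
            for s, e, v in zip(starts, ends, track.scores[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(
    path: str, mark: str, stage: str, chrom_sizes: dict[str, int], width: int = 35
) -> SignalTrack:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "score"], comment="t")
    scores = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        if (np.diff(starts) != width).any() or (starts % width != 0).any():
            raise ValueError(f"bedGraph windows on {chrom} are not a fixed {width}-bp grid")
        scores[str(chrom)] = sub["score"].to_numpy(dtype=float)
    return SignalTrack(mark=mark, stage=stage, scores=scores, chrom_sizes=chrom_sizes, width=width)


# ------------------------------------------------------------ small tables ---


def write_gene_table(table: pd.Series | pd.DataFrame, path: str, value_name: str = "value") -> None:
    if isinstance(table, pd.Series):
        table = table.rename(value_name).to_frame()
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
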