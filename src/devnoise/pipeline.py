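"""End-to-end orchestration: simulate (or load) -> preprocess -> variability
-> stage-specific sets -> promoter conservation -> chromatin, writing every
intermediate table and a reproducibility manifest.

Each stage draws its randomness from a child seed derived by stable hashing
of the stage name, so adding a stage does not shift the streams of the
others, and a rerun with the same config reproduces all outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chromatin, conservation, preprocess, stagespec, synthdata, variability
from .synthdata import GenomeBundle, SimConfig, SimTruth


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed (input digest {digest}): {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run.

    Either ``sim`` (a synthetic-study config) or ``counts_path``/``meta_path``
    must be given.
    """

    outdir: str
    sim: SimConfig | None = None
    counts_path: str | None = None
    meta_path: str | None = None
    min_reads: int = 300_000
    min_genes: int = 4500
    top_frac: float = 0.1
    alpha: float = 0.05
    boot_reps: int = 500
    subsample_n: int = 8
    subsample_reps: int = 500
    tpi_boot: int = 10_000
    protect_stage: bool = True
    write_fixture_files: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and (self.counts_path is None or self.meta_path is None):
            raise ValueError("RunConfig needs either a SimConfig or counts+meta paths")


@dataclass
class RunResult:
    counts: pd.DataFrame
    meta: pd.DataFrame
    expr: pd.DataFrame
    embedding: pd.DataFrame
    flags: pd.DataFrame | None
    vtab: variability.VariabilityTable
    adjsd_summary: variability.StageComparison
    hourglass: list[str]
    stage_sets: dict[str, list[str]]
    tpi: conservation.TPIResult | None
    signal_correlations: pd.DataFrame | None
    truth: SimTruth | None = None
    bundle: GenomeBundle | None = None
    manifest: dict = field(default_factory=dict)


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def _write(df: pd.DataFrame, outdir: str, name: str, manifest: dict) -> None:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t")
    with open(path, "rb") as fh:
        sha = hashlib.sha256(fh.read()).hexdigest()
    manifest["outputs"][name] = sha


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis; see module docstring."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "min_reads": config.min_reads,
            "min_genes": config.min_genes,
            "top_frac": config.top_frac,
            "alpha": config.alpha,
        },
        "stages": [],
        "counts": {},
        "outputs": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append(stage)
        manifest["counts"].update(info)

    # ------------------------------------------------------------- inputs --
    truth = bundle = None
    if config.sim is not None:
        counts, meta, truth = synthdata.simulate_counts(config.sim)
        bundle = synthdata.simulate_genome(config.sim, truth)
        if config.write_fixture_files:
            synthdata.write_fixtures(
                bundle, counts, meta, truth, os.path.join(config.outdir, "fixtures")
            )
        record("simulate", n_genes_simulated=counts.shape[0], n_samples_simulated=counts.shape[1])
    else:
        from . import io

        counts = io.read_counts_tsv(config.counts_path)
        meta = io.read_meta_tsv(config.meta_path)
        record("load", n_genes_loaded=counts.shape[0], n_samples_loaded=counts.shape[1])
    digest = _digest(counts)

    # ----------------------------------------------------------- preprocess --
    try:
        keep_samples = preprocess.qc_filter(counts, config.min_reads, config.min_genes)
        counts_qc = counts[keep_samples]
        keep_genes = preprocess.filter_genes(counts_qc)
        counts_f = counts_qc.loc[keep_genes]
        meta = meta.loc[counts_f.columns]
        record("filter", n_samples_qc=len(keep_samples), n_genes_kept=len(keep_genes))

        norm = preprocess.normalize(counts_f)
        expr = preprocess.correct_batch(
            norm, meta, protect_stage=config.protect_stage, zero_mask=counts_f == 0
        )
        record("normalize", n_batches=int(meta["batch"].nunique()))

        embedding = preprocess.mds_embed(expr)
        flags = None
        reference = truth.arrested_profile if truth is not None else None
        meiosis = (
            set(truth.genes.index[truth.genes["meiosis"]]) if truth is not None else None
        )
        if reference is not None:
            flags = preprocess.flag_unfertilized(
                expr, reference, meiosis_genes=meiosis, embedding=embedding
            )
            fertilized_cols = list(flags.index[~flags["unfertilized"]])
        else:
            fertilized_cols = list(expr.columns)
        expr_f = expr[fertilized_cols]
        meta_f = meta.loc[fertilized_cols]
        record("flag_unfertilized", n_fertilized=len(fertilized_cols))
    except Exception as err:  # noqa: BLE001 - annotate with stage context
        raise PipelineError("preprocess", digest, err) from err

    # ----------------------------------------------------------- variability --
    try:
        vtab = variability.compute_variability(expr_f, meta_f)
        adjsd_summary = variability.stage_summary(vtab.adjusted_sd, meta_f)
        hourglass = variability.hourglass_genes(vtab.adjusted_sd, config.top_frac)
        rng_boot = child_seed(config.seed, "bootstrap")
        boot_medians, boot_tests = variability.bootstrap_stage_medians(
            expr_f, meta_f, vtab.trend, n_boot=config.boot_reps, rng=rng_boot
        )
        min_stage_n = meta_f["stage"].value_counts().min()
        sub_medians = None
        if min_stage_n >= config.subsample_n and config.subsample_reps > 0:
            sub_medians = variability.subsample_equal(
                expr_f,
                meta_f,
                vtab.trend,
                n=config.subsample_n,
                reps=config.subsample_reps,
                rng=child_seed(config.seed, "subsample"),
            )
        record("variability", trend_degree=vtab.trend.degree, n_hourglass=len(hourglass))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("variability", digest, err) from err

    # ------------------------------------------------------------ stagespec --
    try:
        stage_sets, stage_table = stagespec.stage_specific_genes(
            expr_f, meta_f, top_frac=config.top_frac
        )
        record("stagespec", set_size=len(next(iter(stage_sets.values()), [])))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("stagespec", digest, err) from err

    # --------------------------------------------------------- conservation --
    tpi_result = None
    cons_scores = None
    if bundle is not None:
        try:
            models = bundle.models.loc[bundle.models.index.intersection(expr_f.index)]
            cons_scores = conservation.promoter_conservation(
                models, bundle.conservation, flavour="core"
            )
            _, cons_summary = conservation.stage_set_conservation(stage_sets, cons_scores)
            tpi_result = conservation.tpi_ci(
                expr_f,
                meta_f,
                cons_scores,
                n_boot=config.tpi_boot,
                rng=child_seed(config.seed, "tpi"),
            )
            record("conservation", n_scored_genes=int(cons_scores.notna().sum()))
        except Exception as err:  # noqa: BLE001
            raise PipelineError("conservation", digest, err) from err

    # ------------------------------------------------------------ chromatin --
    signal_corr = None
    if bundle is not None and bundle.signal:
        try:
            models = bundle.models.loc[bundle.models.index.intersection(expr_f.index)]
            intergenic = chromatin.intergenic_regions(bundle.models, bundle.chrom_sizes)
            mean_adjsd = vtab.adjusted_sd.mean(axis=1)
            rows = []
            for mark in sorted({m for (m, _) in bundle.signal}):
                gsig = chromatin.promoter_signal_by_stage(
                    models, bundle.signal, mark, intergenic=intergenic
                )
                mean_sig = gsig.stage_mean()
                rho_v, p_v = chromatin.signal_feature_correlation(mean_sig, mean_adjsd)
                rho_c, p_c = (np.nan, np.nan)
                if cons_scores is not None:
                    rho_c, p_c = chromatin.signal_feature_correlation(mean_sig, cons_scores)
                shared = mean_sig.dropna().index.intersection(mean_adjsd.dropna().index)
                shared = shared.intersection(bundle.shape_index.index)
                partial = chromatin.partial_spearman(
                    mean_sig.loc[shared].to_numpy(),
                    mean_adjsd.loc[shared].to_numpy(),
                    bundle.shape_index.loc[shared].to_numpy(),
                )
                rows.append((mark, rho_v, p_v, rho_c, p_c, partial))
            signal_corr = pd.DataFrame(
                rows,
                columns=[
                    "mark",
                    "rho_variability",
                    "p_variability",
                    "rho_conservation",
                    "p_conservation",
                    "partial_rho_variability",
                ],
            ).set_index("mark")
            record("chromatin", n_marks=len(signal_corr))
        except Exception as err:  # noqa: BLE001
            raise PipelineError("chromatin", digest, err) from err

    # --------------------------------------------------------------- outputs --
    _write(expr, config.outdir, "expression.tsv", manifest)
    _write(embedding, config.outdir, "mds.tsv", manifest)
    if flags is not None:
        _write(flags, config.outdir, "unfertilized_flags.tsv", manifest)
    _write(vtab.adjusted_sd, config.outdir, "adjusted_sd.tsv", manifest)
    _write(vtab.cv, config.outdir, "cv.tsv", manifest)
    _write(vtab.dm, config.outdir, "dm.tsv", manifest)
    _write(adjsd_summary.pairs, config.outdir, "adjusted_sd_stage_tests.tsv", manifest)
    _write(boot_medians, config.outdir, "bootstrap_medians.tsv", manifest)
    if sub_medians is not None:
        _write(sub_medians, config.outdir, "subsample_medians.tsv", manifest)
    _write(stage_table, config.outdir, "stage_specific_genes.tsv", manifest)
    pd.Series(hourglass, name="gene_id").to_csv(
        os.path.join(config.outdir, "hourglass_genes.tsv"), sep="\t", index=False
    )
    if tpi_result is not None:
        tpi_df = pd.DataFrame(
            {
                "TPI": tpi_result.tpi,
                "ci_lower": tpi_result.ci_lower,
                "ci_upper": tpi_result.ci_upper,
            }
        )
        _write(tpi_df, config.outdir, "tpi.tsv", manifest)
    if signal_corr is not None:
        _write(signal_corr, config.outdir, "signal_correlations.tsv", manifest)

    manifest["versions"] = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(
        counts=counts_f,
        meta=meta_f,
        expr=expr,
        embedding=embedding,
        flags=flags,
        vtab=vtab,
        adjsd_summary=adjsd_summary,
        hourglass=hourglass,
        stage_sets=stage_sets,
        tpi=tpi_result,
        signal_correlations=signal_corr,
        truth=truth,
        bundle=bundle,
        manifest=manifest,
    )
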