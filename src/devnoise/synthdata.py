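"""Synthetic single-embryo expression data with known ground truth.

Emulates the design of a single-embryo 3'-end RNA-seq study of fly
embryogenesis: 8 developmental stages, ~18 isogenic embryos per stage
collected across 4 sequencing libraries, negative-binomial counts with a
log-normal embryo-level biological factor whose log-SD is ``sigma_g * k_s``
(a per-gene noise scale times a stage noise multiplier, hourglass-shaped by
default with its minimum at stage E3), an admixture of developmentally
arrested (unfertilized-egg) samples that express one stage-independent
profile, and genome tracks in which promoter histone signal and promoter
conservation are rank-coupled (negatively, by a Gaussian copula) to the
per-gene noise scale.

Every latent quantity is recorded in :class:`SimTruth` so downstream
analyses can be tested as parameter-recovery problems.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from . import io
from .genome import ConservationTrack, SignalTrack, validate_gene_models

#: default stage noise multipliers: hourglass-shaped, minimum at stage E3
DEFAULT_K = (1.6, 1.3, 1.0, 1.05, 1.2, 1.1, 1.3, 1.5)

DEFAULT_MARKS = ("H3K4me3", "H3K9ac", "H3K27ac")
MARK_SCALES = {"H3K4me3": 1.0, "H3K9ac": 0.8, "H3K27ac": 0.9}


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults are the study conditions the analysis is tested under:
    8 stages x 18 embryos, 4 libraries, hourglass noise multipliers with the
    minimum at E3, BRB-seq-like library depth (~2e6 reads) and moderate NB
    over-dispersion.
    """

    n_genes: int
    n_stages: int = 8
    embryos_per_stage: int | tuple[int, ...] = 18
    n_batches: int = 4
    stage_noise_multipliers: tuple[float, ...] | None = None
    unfertilized_fraction: float = 0.0
    maternal_fraction: float = 0.2
    meiosis_fraction: float = 0.01
    essential_fraction: float = 0.15
    hub_fraction: float = 0.10
    essential_noise_factor: float = 0.5
    hub_noise_factor: float = 0.6
    nb_dispersion: float = 0.01
    library_size_log_mean: float = 14.5  # exp(14.5) ~ 2e6 reads
    library_size_log_sd: float = 0.3
    batch_effect_sd: float = 0.1
    noise_scale_median: float = 0.4
    noise_scale_log_sd: float = 0.35
    traj_amplitude: float = 1.0
    arrested_noise_multiplier: float = 0.5
    coupling_signal_noise: float = -0.4
    coupling_signal_cons: float = -0.4
    marks: tuple[str, ...] = DEFAULT_MARKS
    signal_stage_profile: tuple[float, ...] | None = None
    chroms: tuple[str, ...] = ("2L", "2R", "3L", "3R", "X")
    gene_slot_bp: int = 9000
    cons_background: float = 0.1
    cons_halfwidth: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or self.n_genes <= 0:
            raise SimConfigError("n_genes must be a positive integer")
        if not isinstance(self.n_stages, (int, np.integer)) or self.n_stages < 2:
            raise SimConfigError("n_stages must be an integer >= 2")
        if isinstance(self.embryos_per_stage, (int, np.integer)):
            self.embryos_per_stage = (int(self.embryos_per_stage),) * self.n_stages
        else:
            self.embryos_per_stage = tuple(int(x) for x in self.embryos_per_stage)
        if len(self.embryos_per_stage) != self.n_stages:
            raise SimConfigError("embryos_per_stage length must equal n_stages")
        if any(n < 2 for n in self.embryos_per_stage):
            raise SimConfigError("embryos_per_stage entries must all be >= 2")
        if self.n_batches < 1:
            raise SimConfigError("n_batches must be >= 1")
        if self.stage_noise_multipliers is None:
            self.stage_noise_multipliers = default_noise_multipliers(self.n_stages)
        self.stage_noise_multipliers = tuple(float(k) for k in self.stage_noise_multipliers)
        if len(self.stage_noise_multipliers) != self.n_stages:
            raise SimConfigError("stage_noise_multipliers length must equal n_stages")
        if any(k <= 0 for k in self.stage_noise_multipliers):
            raise SimConfigError("stage noise multipliers must all be > 0")
        for name in ("unfertilized_fraction", "maternal_fraction", "meiosis_fraction",
                     "essential_fraction", "hub_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SimConfigError(f"{name} must be in [0, 1)")
        if self.maternal_fraction + self.meiosis_fraction > 1.0:
            raise SimConfigError("gene-set fractions must sum to <= 1")
        if self.essential_fraction + self.hub_fraction > 1.0:
            raise SimConfigError("gene-set fractions must sum to <= 1")
        for name in ("coupling_signal_noise", "coupling_signal_cons"):
            v = getattr(self, name)
            if not -1.0 <= v <= 0.0:
                raise SimConfigError(f"{name} must lie in [-1, 0]")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if self.batch_effect_sd < 0:
            raise SimConfigError("batch_effect_sd must be >= 0")
        if self.signal_stage_profile is not None:
            self.signal_stage_profile = tuple(float(x) for x in self.signal_stage_profile)
            if len(self.signal_stage_profile) != self.n_stages:
                raise SimConfigError("signal_stage_profile length must equal n_stages")

    @property
    def stage_labels(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_stages)]


def default_noise_multipliers(n_stages: int) -> tuple[float, ...]:
    """Hourglass-shaped noise multipliers; the canonical 8-stage vector, or a
    linear interpolation of it for other stage counts."""
    if n_stages == len(DEFAULT_K):
        return DEFAULT_K
    x = np.linspace(0, len(DEFAULT_K) - 1, n_stages)
    return tuple(np.interp(x, np.arange(len(DEFAULT_K)), DEFAULT_K))


@dataclass
class SimTruth:
    """Ground truth of one simulation: the recovery-test oracle."""

    genes: pd.DataFrame            # base_mean, sigma, cons_level, signal_level, shape_index, flags
    stage_means: pd.DataFrame      # genes x stages expression means (mu_gs)
    signal_level_stage: pd.DataFrame  # genes x stages promoter histone level
    samples: pd.DataFrame          # stage, batch, fertilized, library_size
    arrested_profile: pd.Series    # stage-independent profile of unfertilized samples
    k: np.ndarray                  # stage noise multipliers used
    config: SimConfig

    def __post_init__(self) -> None:
        n = self.config.n_genes
        if not (len(self.genes) == len(self.stage_means) == len(self.arrested_profile) == n):
            raise ValueError("truth tables inconsistent with config dimensions")


@dataclass
class GenomeBundle:
    """Gene models plus the regulatory-feature tracks built around them."""

    models: pd.DataFrame                       # gene_id -> chrom, start, end, strand
    conservation: ConservationTrack
    signal: dict[tuple[str, str], SignalTrack]  # (mark, stage) -> track
    shape_index: pd.Series                      # lower = broader promoter
    chrom_sizes: dict[str, int] = field(default_factory=dict)


def _coupled_latent(
    rng: np.random.Generator, anchor: np.ndarray, target_spearman: float
) -> np.ndarray:
    """Gaussian-copula latent normal with a target Spearman correlation
    against ``anchor``'s ranks.  Uses the exact Gaussian-copula relation
    rho_latent = 2 sin(pi * rho_spearman / 6)."""
    n = len(anchor)
    z = ndtri((rankdata(anchor) - 0.5) / n)
    r = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    return r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw a full synthetic count matrix with metadata and ground truth.

    Fertilized embryo j at stage s: gene g receives an NB draw with mean
    ``L_j * p_gjs`` where p is the normalized expression fraction of
    ``mu_gs * exp(N(0, (sigma_g k_s)^2)) * exp(batch_gb)``.  Unfertilized
    samples draw from one stage-independent arrested profile regardless of
    their nominal collection stage.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    stages = config.stage_labels
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    k = np.asarray(config.stage_noise_multipliers)

    # --- per-gene latent state -------------------------------------------
    base_mean = np.exp(1.2 * rng.standard_normal(n))

    def _flag(frac: float) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=int(round(frac * n)), replace=False)] = True
        return m

    maternal = _flag(config.maternal_fraction)
    meiosis = _flag(config.meiosis_fraction)
    essential = _flag(config.essential_fraction)
    hub = _flag(config.hub_fraction)

    sigma = config.noise_scale_median * np.exp(
        config.noise_scale_log_sd * rng.standard_normal(n)
    )
    sigma = sigma * np.where(essential, config.essential_noise_factor, 1.0)
    sigma = sigma * np.where(hub, config.hub_noise_factor, 1.0)

    # smooth per-gene stage trajectories (Gaussian bump in log space) so the
    # sample embedding recovers an ordered developmental trajectory
    s_grid = np.arange(1, config.n_stages + 1, dtype=float)
    centre = rng.uniform(1.0, config.n_stages, size=n)[:, None]
    width = rng.uniform(1.5, 4.0, size=n)[:, None]
    amp = config.traj_amplitude * rng.standard_normal(n)[:, None]
    log_traj = amp * np.exp(-((s_grid[None, :] - centre) ** 2) / (2.0 * width**2))
    mat_amp = np.where(maternal, rng.uniform(1.0, 2.5, size=n), 0.0)[:, None]
    log_traj += mat_amp * np.exp(-(s_grid[None, :] - 1.0) / 1.5)
    stage_means = base_mean[:, None] * np.exp(log_traj)

    # arrested (unfertilized-egg) profile: partly maternal-like, partly its
    # own axis, with a strong completion-of-meiosis signature
    log_arr = 0.4 * np.log(stage_means[:, 0]) + 0.6 * (1.2 * rng.standard_normal(n))
    arrested = np.exp(log_arr) * np.where(meiosis, 8.0, 1.0)

    # regulatory features rank-coupled to the final noise scale
    latent_signal = _coupled_latent(rng, sigma, config.coupling_signal_noise)
    latent_cons = _coupled_latent(rng, sigma, config.coupling_signal_cons)
    signal_level = np.exp(1.0 + 0.8 * latent_signal)
    cons_level = 0.1 + 0.8 * ndtr(latent_cons)
    shape_index = 0.6 * latent_signal + 0.8 * rng.standard_normal(n)

    stage_profile = (
        np.ones(config.n_stages)
        if config.signal_stage_profile is None
        else np.asarray(config.signal_stage_profile)
    )
    signal_level_stage = signal_level[:, None] * stage_profile[None, :]

    # --- samples ----------------------------------------------------------
    sample_rows = []
    for si, stage in enumerate(stages):
        n_emb = config.embryos_per_stage[si]
        # libraries are balanced across stages, as in a designed multiplexed
        # experiment: within-stage round-robin assignment, randomly permuted
        batch_ids = rng.permuted(
            np.tile(np.arange(config.n_batches), -(-n_emb // config.n_batches))[:n_emb]
        )
        for j in range(n_emb):
            sample_rows.append(
                (
                    f"{stage}_r{j + 1:02d}",
                    stage,
                    int(batch_ids[j]),
                    bool(rng.random() >= config.unfertilized_fraction),
                    float(np.exp(rng.normal(config.library_size_log_mean,
                                            config.library_size_log_sd))),
                )
            )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "stage", "batch", "fertilized", "library_size"]
    ).set_index("sample_id")

    batch_offsets = rng.normal(0.0, config.batch_effect_sd, size=(n, config.n_batches))

    # --- counts -----------------------------------------------------------
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        si = stages.index(row["stage"])
        if row["fertilized"]:
            log_e = np.log(stage_means[:, si]) + rng.normal(0.0, sigma * k[si])
        else:
            log_e = np.log(arrested) + rng.normal(
                0.0, sigma * config.arrested_noise_multiplier
            )
        log_e += batch_offsets[:, int(row["batch"])]
        e = np.exp(log_e)
        mean = row["library_size"] * e / e.sum()
        if config.nb_dispersion > 0:
            nb_n = 1.0 / config.nb_dispersion
            counts[:, j] = rng.negative_binomial(nb_n, nb_n / (nb_n + mean))
        else:
            counts[:, j] = rng.poisson(mean)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)
    meta = samples[["stage", "batch"]].copy()

    genes = pd.DataFrame(
        {
            "base_mean": base_mean,
            "sigma": sigma,
            "cons_level": cons_level,
            "signal_level": signal_level,
            "shape_index": shape_index,
            "essential": essential,
            "hub": hub,
            "maternal": maternal,
            "meiosis": meiosis,
        },
        index=gene_ids,
    )
    truth = SimTruth(
        genes=genes,
        stage_means=pd.DataFrame(stage_means, index=gene_ids, columns=stages),
        signal_level_stage=pd.DataFrame(signal_level_stage, index=gene_ids, columns=stages),
        samples=samples,
        arrested_profile=pd.Series(arrested, index=gene_ids, name="arrested"),
        k=k,
        config=config,
    )
    return counts_df, meta, truth


def simulate_genome(config: SimConfig, truth: SimTruth) -> GenomeBundle:
    """Lay the genes out on chromosomes and build the coupled genome tracks.

    Each gene occupies a fixed slot; its conservation level forms a plateau
    around the TSS over a constant background, and its histone level is added
    to all 35-bp signal windows within +/-2 kb of the TSS over a low-mean
    intergenic background.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = truth.genes.index
    n = len(gene_ids)
    slot = config.gene_slot_bp

    chrom_of = np.array([config.chroms[i % len(config.chroms)] for i in range(n)])
    slot_idx = np.array([i // len(config.chroms) for i in range(n)])
    strand = rng.choice(["+", "-"], size=n)
    length = rng.integers(1000, 3000, size=n)
    slot_start = slot_idx * slot
    start = np.where(strand == "+", slot_start + 3000, slot_start + 6000 - length)
    end = start + length
    models = pd.DataFrame(
        {"chrom": chrom_of, "start": start, "end": end, "strand": strand}, index=gene_ids
    )
    validate_gene_models(models)
    chrom_sizes = {
        c: int((slot_idx[chrom_of == c].max() + 1) * slot) for c in np.unique(chrom_of)
    }

    tss = np.where(strand == "+", start, end - 1)

    # conservation: plateau of width 2*cons_halfwidth centred on the TSS
    cons_intervals: dict[str, pd.DataFrame] = {}
    for chrom in chrom_sizes:
        mask = chrom_of == chrom
        order = np.argsort(tss[mask])
        t = tss[mask][order]
        level = truth.genes["cons_level"].to_numpy()[mask][order]
        rows, pos = [], 0
        for ti, li in zip(t, level):
            lo = max(0, int(ti) - config.cons_halfwidth)
            hi = min(chrom_sizes[chrom], int(ti) + config.cons_halfwidth)
            if lo > pos:
                rows.append((pos, lo, config.cons_background))
            rows.append((lo, hi, float(li)))
            pos = hi
        if pos < chrom_sizes[chrom]:
            rows.append((pos, chrom_sizes[chrom], config.cons_background))
        cons_intervals[chrom] = pd.DataFrame(rows, columns=["start", "end", "value"])
    conservation = ConservationTrack(cons_intervals, chrom_sizes)

    # histone signal: exponential background + per-gene level on promoter windows
    width = 35
    signal: dict[tuple[str, str], SignalTrack] = {}
    for mark in config.marks:
        mark_scale = MARK_SCALES.get(mark, 1.0)
        for stage in config.stage_labels:
            level_gs = truth.signal_level_stage[stage].to_numpy()
            jitter = np.exp(rng.normal(0.0, 0.1, size=n))
            scores = {}
            for chrom, size in chrom_sizes.items():
                n_win = -(-size // width)
                arr = rng.exponential(0.5, size=n_win)
                mask = chrom_of == chrom
                for ti, li, ji in zip(tss[mask], level_gs[mask], jitter[mask]):
                    lo = max(0, (int(ti) - 2000) // width)
                    hi = min(n_win, -(-(int(ti) + 2000) // width))
                    arr[lo:hi] += li * mark_scale * ji
                scores[chrom] = arr
            signal[(mark, stage)] = SignalTrack(
                mark=mark, stage=stage, scores=scores, chrom_sizes=chrom_sizes, width=width
            )

    shape = truth.genes["shape_index"].rename("shape_index")
    return GenomeBundle(
        models=models,
        conservation=conservation,
        signal=signal,
        shape_index=shape,
        chrom_sizes=chrom_sizes,
    )


def write_fixtures(
    bundle: GenomeBundle,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: SimTruth,
    outdir: str,
) -> dict[str, str]:
    """Write every fixture file (plain-text formats); returns name -> path.

    Files round-trip through :mod:`devnoise.io` readers.  The per-base wig
    writer is intended for the small genomes used in tests and examples.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    io.write_counts_tsv(counts, p("counts.tsv"))
    io.write_counts_mtx(counts, p("counts.mtx"))
    io.write_meta_tsv(meta, p("meta.tsv"))
    io.write_bed12(bundle.models, p("genes.bed"))
    io.write_wig(bundle.conservation, p("conservation.wig"))
    for (mark, stage), track in bundle.signal.items():
        io.write_bedgraph(track, p(f"signal_{mark}_{stage}.bedgraph"))
    io.write_gene_table(bundle.shape_index, p("shape_index.tsv"), "shape_index")
    io.write_gene_table(truth.genes, p("gene_truth.tsv"))
    io.write_gene_table(truth.stage_means, p("stage_means_truth.tsv"))
    io.write_gene_table(truth.arrested_profile, p("arrested_profile.tsv"), "arrested")
    io.write_meta_tsv(truth.samples, p("sample_truth.tsv"))
    return paths
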