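# Methods

## Data model and pipeline overview

The analysis consumes a genes × samples integer count matrix from
single-embryo 3′-end RNA-seq (one library barcode per embryo), sample
metadata (ordered developmental stage E1…E8, sequencing library/batch), and
a genome side: gene models, a per-base conservation track in [0, 1], and
histone-modification signal tracks in fixed 35-bp windows, one per mark per
stage. All genomic coordinates are 0-based half-open internally (BED
native; wig converted on I/O); the TSS coordinate of a minus-strand gene is
`end − 1`.

Processing order: sample QC → gene filter → quantile normalization →
ComBat batch correction with clipping → MDS and arrested-sample flagging →
variability metrics and stage tests → stage-specific sets → promoter
conservation / TPI → chromatin signal analyses.

## Preprocessing

* **Sample QC** keeps samples with ≥ 300,000 total reads and ≥ 4,500
  expressed genes (count ≥ 1); removal is by strict inequality. "Expressed"
  is defined as count ≥ 1 — the defensible minimal reading, fixed here.
* **Gene filter** keeps genes with mean CPM across retained samples > 1;
  retained genes keep their original integer counts.
* **Normalization** is log2(CPM + 0.5) followed by full quantile
  normalization: each column's sorted values are replaced by the
  across-column mean of sorted values, ties broken by input order. This
  makes the post-normalization sorted column vectors identical as an exact
  invariant. (Assigning tied entries the mean of their would-be quantiles
  is available as `ties="average"`, but it breaks the exact shared-multiset
  property whenever zeros tie, so it is not the default.)
* **Batch correction** is parametric empirical-Bayes ComBat, implemented in
  `devnoise/_combat.py`: per-gene batch locations and scales estimated on
  standardized data, shrunk toward across-gene normal / inverse-gamma
  priors (method-of-moments hyperparameters, iterative conditional
  solution to 1e-4), and removed. Developmental stage is protected as a
  covariate by default (drop-first dummies in the design); without
  protection, stage signal partially confounded with library could be
  erased. A design in which a library serves a single stage is singular and
  rejected with an explicit error. After correction, negative values are
  clipped to 0, as are entries whose original counts were 0 (the pipeline
  passes `zero_mask = counts == 0`; the function's default masks entries
  that are exactly 0 on input).
* **Embedding** is classical MDS (principal coordinates) on
  d(i, j) = 1 − Pearson correlation of expression columns, sign-fixed per
  axis, so it is deterministic.
* **Arrested-sample flagging.** Unfertilized eggs complete meiosis and
  arrest, forming a dense cluster off the developmental trajectory. Samples
  are split by 2-means on the embedding; the cluster with the higher mean
  Pearson correlation to the unfertilized-egg reference profile is flagged
  only if its correlation advantage exceeds 0.05 and, when a meiosis gene
  set is supplied, its meiosis rank-score advantage (mean normalized
  expression rank of meiosis genes minus all genes) exceeds 0.02. The two
  margins are there so that a clean all-fertilized trajectory, which
  2-means will still split somewhere, produces no flags; 0.02 is roughly
  3× the null standard error of the score gap for a 50-gene meiosis set.

## Variability metrics

All SDs use the population convention (divisor n); this is fixed, not
configurable, and matters only as a constant factor within any one
comparison.

* **Mean–SD trend.** OLS of global SD on powers of global mean expression
  (standardized before powers for conditioning; predictions unchanged).
  Degree selection is greedy: accept degree d while the nested F-test of d
  vs d−1 has p < 0.05, stop at the first non-significant degree, cap at 10
  with a warning. Fitted values are floored at 1e-6 when used as divisors.
* **Adjusted SD** = per-stage SD / trend-predicted global SD. On null data
  (all stages identically distributed) its per-stage Spearman correlation
  with mean expression is ≈ 0.02–0.03 in magnitude at 5,000 genes — not
  exactly zero, because OLS estimates the conditional mean of SD while rank
  correlations respond to the conditional median, and the skew of the SD
  distribution varies along the expression axis. This residual is an
  order of magnitude below CV's dependence (|ρ| ≈ 0.6) on the same data.
* **DM.** Genes ordered by global mean ascending; windows of 50 genes
  stepping 25 ([1..50], [26..75], …), plus, when the count is not an exact
  fit, a terminal 50-gene window ending at the top rank. Each gene uses the
  window whose centre is nearest its rank (ties to the lower window);
  DM<sub>gs</sub> = log₁₀ CV²<sub>gs</sub> − median window log₁₀ CV²
  (global). Genes with zero global CV are excluded; zero stage-CVs yield
  missing values rather than −∞.
* **Stage tests.** Pairwise two-sided Wilcoxon rank-sum
  (`scipy.stats.mannwhitneyu`, asymptotic with tie correction, matching R's
  default at these sizes), BH-corrected over the set of stage pairs.
* **Bootstrap** (500 replicates): within each stage, resample n = smallest
  stage size with replacement, recompute adjusted SDs against the fixed
  full-data trend, keep per-stage medians; Wilcoxon between stages' median
  vectors. Refitting the trend per replicate is deliberately excluded: the
  predicted global SD is defined on the full data. **Equal-n subsampling**
  (default 8 embryos × 500 repetitions) is the same without replacement.
* **Hourglass genes**: Pearson correlation of each gene's 8-stage adjusted
  SD profile with the across-gene median profile; top ⌊0.1·n⌋, ties at the
  cutoff broken by gene id.

## Stage-specific genes

One-hot artificial profiles, one per stage; per gene, Pearson correlation
between the per-stage **mean** expression vector (aggregation is forced by
the profile length; mean chosen) and each profile; top ⌊0.1·n⌋ per profile.
Genes may appear in several sets; the output table reports, and does not
resolve, the overlap.

## Promoter conservation and TPI

* **Core promoter**: −49 to +10 around the TSS base (TSS included; 60 bp),
  strand-aware, following the experimentally validated promoter convention.
  Window flavours (200 bp, 400 bp, 1 kb, ±2 kb proximal) are
  strand-symmetric around the TSS coordinate. Regions are clipped at
  chromosome bounds and flagged.
* **Scores**: unweighted per-base mean of the conservation track over the
  region; uncovered bases excluded from both numerator and denominator.
* **TPI**: per stage, Σ scoreᵢ·e<sub>is</sub> / Σ e<sub>is</sub> with
  e<sub>is</sub> = per-stage mean of the log-scale, non-negative expression
  (per-stage mean chosen as the aggregation); genes without scores excluded
  from both sums. CIs: resample gene ids with replacement (default 10,000),
  take stage-wise 2.5/97.5 percentiles.

## Chromatin signal

Promoter signal is the unweighted mean of all 35-bp windows overlapping
[TSS − 2 kb, TSS + 2 kb) — interval-map "mean" semantics, so a window
counts once regardless of overlap length and a promoter can absorb up to
34 bp of slop per side. Intergenic regions are the genome complement of the
merged union of proximal promoters and gene bodies (TSS..TES). Z-scoring
subtracts the mean and divides by the population SD of windows **fully
contained** in intergenic regions (straddling windows excluded, counted in
the log), per mark per stage; since the transform is affine, rank
correlations are unchanged, and the intergenic windows themselves have mean
0 and SD 1 exactly. Partial Spearman uses the closed form on ranked data,
r<sub>xy·z</sub> = (r<sub>xy</sub> − r<sub>xz</sub>r<sub>yz</sub>) /
√((1−r<sub>xz</sub>²)(1−r<sub>yz</sub>²)), rejecting inputs rank-degenerate
with the control; it equals the residual-of-rank-regressions estimator.

## The synthetic study

The generator emulates the study design the pipeline targets: 8 stages ×
18 embryos across 4 multiplexed libraries.

For fertilized embryo j at stage s, gene g's count is negative-binomial
with mean L<sub>j</sub>·p<sub>gjs</sub>, where p is the normalized fraction
of μ<sub>gs</sub> · exp(ε), ε ~ N(0, (σ<sub>g</sub>k<sub>s</sub>)²), times
a gene-specific log-normal library factor. Defaults, chosen once:

| parameter | default | meaning |
|---|---|---|
| library size | exp(N(14.5, 0.3)) ≈ 2·10⁶ | 3′-end depth per embryo |
| NB dispersion φ | 0.01 | residual technical overdispersion |
| σ<sub>g</sub> | 0.4 · exp(0.35·N(0,1)) | per-gene biological noise scale (natural-log SD) |
| k<sub>s</sub> | (1.6, 1.3, 1.0, 1.05, 1.2, 1.1, 1.3, 1.5) | stage noise multipliers, minimum at E3 |
| batch effect | gene×batch log-normal, SD 0.1 | removed by ComBat |
| trajectories | per-gene Gaussian bump in log space | gives MDS an ordered trajectory |

Two calibration notes. The NB dispersion covers only residual technical
noise because biological embryo-to-embryo variation is carried explicitly
by σ<sub>g</sub>k<sub>s</sub>; folding biological-scale dispersion into φ
would double-count it and drown the 5% adjacent-stage contrast between E3
and E4 that the analysis must resolve — the study this emulates separates
every stage pair decisively, which pins the technical-to-biological and
spread-to-contrast ratios to roughly these values. Libraries are balanced
across stages (stratified round-robin), as in a designed multiplexed
experiment; unbalanced assignment injects a stage-level shared batch
variance that no gene-wise averaging removes.

Unfertilized samples (fraction configurable, 0 by default) ignore their
nominal collection stage and express one arrested profile: 40% stage-1-like
and 60% an independent axis in log space, with meiosis-annotated genes
8-fold enriched and a reduced noise multiplier (0.5). Essential and hub
gene flags multiply σ<sub>g</sub> by 0.5 / 0.6 — variability analyses
should find them quieter.

Promoter histone level and promoter conservation are generated by a
Gaussian copula against the **final** σ<sub>g</sub> ranks (latent
correlation 2·sin(π·ρ_S/6) for a target Spearman ρ_S, default −0.4 each),
so the realized rank couplings hit their targets within ±0.05 at ≥ 2,000
genes. Genomically, each gene occupies a 9-kb slot on one of five
chromosomes (2L, 2R, 3L, 3R, X): the conservation level forms a ±500 bp
plateau around the TSS over a 0.1 background, and the histone level is
added to all 35-bp windows within ±2 kb of the TSS over an Exponential(0.5)
background. The promoter shape index loads 0.6 on the signal latent plus
independent noise (lower = broader).

### What the generator does not emulate

Real read-level artifacts (mapping bias, barcode collisions, gene-length
effects), correlated gene modules, genuinely mean-dependent biological
noise, multiple TSSs per gene, overlapping gene structures, and any
sequence-level signal. Passing recovery tests therefore demonstrates that
the implementation measures what it claims under the declared generative
model — not that the biological conclusions transfer to any real dataset.
Notably, DM appears nearly mean-independent on these fixtures even though
it retains mean-dependence on real data; the generator's noise model is
exactly the multiplicative regime DM handles well.

## Numerical choices and degenerate inputs

Trend predictions floored at 1e-6 before division; genes with constant
profiles are excluded from profile correlations with a warning; stages with
fewer than 2 samples are dropped from variability with a warning; a stage
whose expression weights are all zero yields a missing TPI; Z-scoring with
zero intergenic variance, QC removing every sample, empty gene groups, and
rank-degenerate partial correlations are hard errors. All randomness flows
from explicit seeds; the pipeline derives per-stage child seeds by CRC-32
of the stage name XOR the run seed, so adding a stage leaves other streams
unchanged. Problem sizes used by the test suite and the acceptance script
(5,000 genes × 144 embryos, 20 seeds for the recovery scan, 200
replications × 2,000 bootstrap draws for CI coverage) keep a full run
within a couple of minutes on one CPU.

## Known limitations

* The adjusted SD's residual mean-dependence (above) is intrinsic to
  trend-ratio detrending with an OLS conditional-mean fit.
* ComBat shrinkage removes most, not all, of a per-gene batch offset; the
  residual is the price of variance pooling and shrinks with batch size.
* The arrested-sample detector assumes the arrested cluster is separable in
  two MDS dimensions; heavily admixed or tiny clusters (< a handful of
  samples) will not form a k-means cluster of their own.
* With a single TSS per gene in fixtures, multi-TSS averaging conventions
  (representative vs mean coordinate) are accepted as an input column but
  not exercised.
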