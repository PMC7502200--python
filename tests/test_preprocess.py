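import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

import devnoise as dn
from devnoise import preprocess as pp


def _matrix(data, genes=None, samples=None):
    data = np.asarray(data)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=samples)


class TestQCFilter:
    def test_toy_matrix_both_rules(self):
        """Totals (1e6, 2e5, 5e5, 1e5) with expressed-gene counts
        (5000, 5000, 4000, 5000): only the first sample passes both rules."""
        n = 5000
        counts = np.zeros((n, 4), dtype=int)
        counts[:, 0] = 200          # 5000 expressed, 1e6 reads
        counts[:, 1] = 40           # 5000 expressed, 2e5 reads
        counts[:4000, 2] = 125      # 4000 expressed, 5e5 reads
        counts[:, 3] = 20           # 5000 expressed, 1e5 reads
        keep = pp.qc_filter(_matrix(counts))
        assert keep == ["s0"]

    def test_thresholds_are_inclusive(self):
        n = 4500
        good = np.zeros((n + 1, 2), dtype=int)
        # sample 0: exactly 300000 reads over exactly 4500 expressed genes
        good[: n - 1, 0] = 66
        good[n - 1, 0] = 300_000 - 66 * (n - 1)
        # sample 1: one read short
        good[: n - 1, 1] = 66
        good[n - 1, 1] = 300_000 - 66 * (n - 1) - 1
        counts = _matrix(good)
        assert pp.qc_filter(counts) == ["s0"]

    def test_all_removed_raises_with_report(self):
        counts = _matrix([[1, 2], [3, 4]])
        with pytest.raises(pp.QCError, match="total_reads"):
            pp.qc_filter(counts)

    def test_idempotent(self, hourglass_sim):
        counts = hourglass_sim["counts"]
        keep = pp.qc_filter(counts, min_reads=1000, min_genes=100)
        assert pp.qc_filter(counts[keep], min_reads=1000, min_genes=100) == keep


class TestFilterGenes:
    def test_rules_and_boundary(self):
        # totals 1e6 each via a filler gene; g0 all-zero, g1 mean cpm exactly 1,
        # g2 mean cpm 1.5 (counts (3, 0))
        counts = _matrix(
            [
                [0, 0],
                [1, 1],
                [3, 0],
                [10**6 - 4, 10**6 - 1],
            ],
            genes=["zero", "at_one", "kept", "filler"],
        )
        keep = pp.filter_genes(counts)
        assert "zero" not in keep and "at_one" not in keep
        assert "kept" in keep and "filler" in keep

    def test_idempotent(self, hourglass_sim):
        counts = hourglass_sim["counts"]
        keep = pp.filter_genes(counts)
        assert pp.filter_genes(counts.loc[keep]) == keep


class TestNormalize:
    def test_permuted_samples_fixed_point(self, rng):
        base = rng.integers(1, 1000, size=50)
        counts = _matrix(np.column_stack([base, rng.permutation(base)]))
        out = pp.normalize(counts)
        assert sorted(out["s0"]) == pytest.approx(sorted(out["s1"]))

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(
            np.int64,
            (20, 5),
            elements=st.integers(0, 5000),
        ).filter(lambda a: (a.sum(axis=0) > 0).all())
    )
    def test_sorted_columns_identical_exact(self, data):
        out = pp.normalize(_matrix(data)).to_numpy()
        srt = np.sort(out, axis=0)
        assert (srt == srt[:, [0]]).all()

    def test_three_by_three_matches_reference(self):
        counts = _matrix([[10, 0, 4], [20, 5, 4], [30, 10, 2]])
        out = pp.normalize(counts)
        # independent reference: explicit sort/mean/reassign on log2(cpm + .5)
        log = np.log2(counts.to_numpy() / counts.to_numpy().sum(axis=0) * 1e6 + 0.5)
        ref = np.sort(log, axis=0).mean(axis=1)
        expected = np.empty_like(log)
        for j in range(3):
            expected[np.argsort(log[:, j]), j] = ref
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pp.normalize(_matrix([[1], [2]]))


class TestCorrectBatch:
    def _meta(self, samples, batches, stages=None):
        return pd.DataFrame(
            {
                "batch": batches,
                "stage": stages or ["E1"] * len(samples),
            },
            index=samples,
        )

    def test_single_batch_is_identity_plus_clipping(self, rng):
        expr = _matrix(rng.uniform(0, 5, size=(30, 6)))
        meta = self._meta(expr.columns, [0] * 6)
        out = pp.correct_batch(expr, meta, zero_mask=expr != expr)  # no zeros masked
        pd.testing.assert_frame_equal(out, expr)

    def test_zero_entries_stay_zero(self, rng):
        data = rng.uniform(1, 5, size=(40, 8))
        data[0, 0] = 0.0
        expr = _matrix(data)
        meta = self._meta(expr.columns, [0, 0, 0, 0, 1, 1, 1, 1])
        out = pp.correct_batch(expr, meta)
        assert out.iloc[0, 0] == 0.0
        assert (out.to_numpy() >= 0).all()

    def test_additive_offset_removed(self, rng):
        genes, per_batch = 200, 12
        base = rng.normal(5, 1, size=(genes, 2 * per_batch))
        delta = rng.normal(0, 1, size=genes)
        base[:, per_batch:] += delta[:, None]
        expr = _matrix(base)
        meta = self._meta(expr.columns, [0] * per_batch + [1] * per_batch)
        out = pp.correct_batch(expr, meta, protect_stage=False)
        gap_before = np.abs(delta).mean()
        gap_after = (
            (out.iloc[:, :per_batch].mean(axis=1) - out.iloc[:, per_batch:].mean(axis=1))
            .abs()
            .mean()
        )
        # EB shrinkage removes most (not all) of the per-gene offset
        assert gap_after < 0.3 * gap_before

    def test_protect_stage_preserves_stage_signal(self, rng):
        """With no real batch effect, stage-mean differences survive
        correction when stage is protected."""
        genes = 150
        stages = ["E1"] * 10 + ["E2"] * 10
        shift = rng.normal(0, 2, size=genes)
        data = rng.normal(5, 0.3, size=(genes, 20))
        data[:, 10:] += shift[:, None]
        expr = _matrix(data)
        batches = ([0, 1] * 10)[:20]
        meta = self._meta(expr.columns, batches, stages)
        out = pp.correct_batch(expr, meta, protect_stage=True)
        observed = out.iloc[:, 10:].mean(axis=1) - out.iloc[:, :10].mean(axis=1)
        assert np.corrcoef(observed, shift)[0, 1] > 0.99

    def test_confounded_design_raises(self, rng):
        expr = _matrix(rng.uniform(1, 5, size=(30, 8)))
        meta = self._meta(
            expr.columns, [0, 0, 0, 0, 1, 1, 1, 1], ["E1"] * 4 + ["E2"] * 4
        )
        with pytest.raises(ValueError, match="singular|confounded"):
            pp.correct_batch(expr, meta, protect_stage=True)

    def test_matches_scanpy_combat_without_covariates(self, hourglass_sim):
        """Independent cross-check of the EB adjustment against scanpy's
        ComBat on its full-rank (no-covariate) path."""
        import warnings

        import anndata as ad
        import scanpy as sc

        expr = pp.normalize(hourglass_sim["counts"].iloc[:300])
        meta = hourglass_sim["meta"]
        obs = pd.DataFrame(
            {"batch": meta.loc[expr.columns, "batch"].astype(str).to_numpy()},
            index=expr.columns,
        )
        adata = ad.AnnData(X=expr.T.to_numpy(float), obs=obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(adata, key="batch")
        from devnoise._combat import combat

        mine = combat(expr, meta["batch"])
        # scanpy uses a population-variance location prior; agreement is
        # near-exact up to that ddof convention
        assert np.abs(mine.to_numpy() - adata.X.T).max() < 5e-3


class TestMDS:
    def test_duplicate_sample_embeds_at_zero_distance(self, rng):
        data = rng.normal(size=(50, 5))
        data[:, 4] = data[:, 0]
        emb = pp.mds_embed(_matrix(data))
        d = np.linalg.norm(emb.iloc[0] - emb.iloc[4])
        span = np.linalg.norm(emb.iloc[0] - emb.iloc[2])
        assert d < 1e-8 * max(span, 1.0)

    def test_equidistant_triple_is_equilateral(self, rng):
        # three mutually orthogonal deviations => equal pairwise correlations
        x = np.eye(3)
        expr = _matrix(np.vstack([x, np.zeros((3, 3))]) + rng.normal(0, 1e-9, (6, 3)))
        emb = pp.mds_embed(expr)
        d01 = np.linalg.norm(emb.iloc[0] - emb.iloc[1])
        d02 = np.linalg.norm(emb.iloc[0] - emb.iloc[2])
        d12 = np.linalg.norm(emb.iloc[1] - emb.iloc[2])
        assert d01 == pytest.approx(d02, rel=1e-6)
        assert d01 == pytest.approx(d12, rel=1e-6)

    def test_constant_column_raises_with_name(self, rng):
        data = rng.normal(size=(20, 4))
        data[:, 2] = 3.0
        with pytest.raises(ValueError, match="s2"):
            pp.mds_embed(_matrix(data))

    def test_developmental_trajectory_recovered(self, hourglass_sim):
        emb = pp.mds_embed(hourglass_sim["expr"])
        stage_rank = (
            hourglass_sim["meta"].loc[emb.index, "stage"].str.lstrip("E").astype(int)
        )
        rho = abs(spearmanr(emb["MDS1"], stage_rank).statistic)
        assert rho > 0.9


class TestFlagUnfertilized:
    def _run(self, fraction, seed=10):
        cfg = dn.SimConfig(
            n_genes=800, embryos_per_stage=12, unfertilized_fraction=fraction, seed=seed
        )
        counts, meta, truth = dn.simulate_counts(cfg)
        expr = pp.correct_batch(pp.normalize(counts), meta, zero_mask=counts == 0)
        flags = pp.flag_unfertilized(
            expr,
            truth.arrested_profile,
            meiosis_genes=set(truth.genes.index[truth.genes["meiosis"]]),
        )
        return flags, truth

    def test_recovery_at_thirty_percent(self):
        flags, truth = self._run(0.3)
        agreement = (
            flags["unfertilized"] == ~truth.samples.loc[flags.index, "fertilized"]
        ).mean()
        assert agreement >= 0.95

    def test_no_flags_when_all_fertilized(self):
        flags, _ = self._run(0.0)
        assert not flags["unfertilized"].any()

    def test_sample_identical_to_reference_is_flagged(self):
        flags, truth = self._run(0.3)
        arrested = ~truth.samples.loc[flags.index, "fertilized"]
        top = flags.loc[arrested, "reference_corr"].idxmax()
        assert flags.loc[top, "unfertilized"]
        assert flags.loc[top, "reference_corr"] > flags.loc[~arrested, "reference_corr"].mean()

    def test_sparse_reference_coverage_rejected(self, hourglass_sim):
        expr = hourglass_sim["expr"]
        ref = hourglass_sim["truth"].arrested_profile.iloc[: expr.shape[0] // 4]
        with pytest.raises(ValueError, match="50%"):
            pp.flag_unfertilized(expr, ref)


class TestXAutosomeRatio:
    def _models(self, genes, chroms):
        return pd.DataFrame(
            {
                "chrom": chroms,
                "start": np.arange(len(genes)) * 1000 + 100,
                "end": np.arange(len(genes)) * 1000 + 600,
                "strand": ["+"] * len(genes),
            },
            index=genes,
        )

    def test_matched_distributions_give_ratio_near_one(self, rng):
        genes = [f"g{i}" for i in range(400)]
        expr = _matrix(rng.uniform(2, 8, size=(400, 6)), genes=genes)
        models = self._models(genes, ["X"] * 200 + ["2L"] * 200)
        ratios = pp.x_autosome_ratio(expr, models)
        assert np.allclose(ratios, 1.0, atol=0.15)

    def test_shifted_x_expression_moves_ratio(self, rng):
        genes = [f"g{i}" for i in range(400)]
        data = rng.uniform(2, 8, size=(400, 2))
        data[:200, 1] += 1.0  # +1 on log2 scale for X genes in sample 2
        expr = _matrix(data, genes=genes)
        models = self._models(genes, ["X"] * 200 + ["3R"] * 200)
        ratios = pp.x_autosome_ratio(expr, models)
        assert ratios["s1"] > ratios["s0"] * 1.1

    def test_no_autosomes_is_an_error(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = _matrix(rng.uniform(1, 5, size=(10, 3)), genes=genes)
        models = self._models(genes, ["X"] * 10)
        with pytest.raises(ValueError, match="autosomal"):
            pp.x_autosome_ratio(expr, models)
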