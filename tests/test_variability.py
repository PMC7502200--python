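import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import devnoise as dn
from devnoise import preprocess as pp
from devnoise import variability as vb


def _expr(data, genes=None, samples=None):
    data = np.asarray(data, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=samples)


def _meta(samples, stages):
    return pd.DataFrame({"stage": stages, "batch": 0}, index=samples)


class TestFitSdTrend:
    def test_linear_truth_selects_degree_one(self, rng):
        mean = rng.uniform(0, 10, size=500)
        sd = 2 + 0.5 * mean
        trend = vb.fit_sd_trend(mean, sd)
        assert trend.degree == 1
        np.testing.assert_allclose(trend.predict(mean), sd, atol=1e-8)

    def test_quadratic_truth_selects_degree_two(self, rng):
        mean = rng.uniform(0, 10, size=2000)
        sd = 1 + 0.3 * mean - 0.02 * mean**2 + rng.normal(0, 0.02, size=2000)
        trend = vb.fit_sd_trend(mean, sd)
        assert trend.degree == 2

    def test_constant_sd_keeps_intercept_only(self, rng):
        mean = rng.uniform(0, 10, size=800)
        sd = np.full(800, 1.7) + rng.normal(0, 0.05, size=800)
        trend = vb.fit_sd_trend(mean, sd)
        assert trend.degree == 0
        assert trend.predict(np.array([5.0]))[0] == pytest.approx(1.7, abs=0.02)

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="20 genes"):
            vb.fit_sd_trend(np.arange(10.0), np.arange(10.0))


class TestAdjustedSD:
    def test_definition_on_toy_with_given_trend(self, rng):
        """10-gene toy against brute-force ratios for a fixed linear trend."""
        data = rng.uniform(1, 9, size=(10, 8))
        expr = _expr(data)
        meta = _meta(expr.columns, ["E1"] * 4 + ["E2"] * 4)
        trend = vb.PolyTrend(
            coeffs=np.array([2.0, 0.5]), x_center=0.0, x_scale=1.0, degree=1
        )
        out = vb.adjusted_sd(expr, meta, trend)
        for g in expr.index:
            gmean = data[expr.index.get_loc(g)].mean()
            pred = 2.0 + 0.5 * gmean
            for si, stage in enumerate(["E1", "E2"]):
                block = data[expr.index.get_loc(g), si * 4 : si * 4 + 4]
                expected = block.std() / pred  # population SD
                assert out.loc[g, stage] == pytest.approx(expected, rel=1e-12)

    def test_gene_matching_trend_prediction_scores_one(self):
        values = np.array([1.0, 3.0])  # population SD 1, mean 2
        expr = _expr(np.tile(values, (25, 1)))
        expr += np.linspace(0, 4, 25)[:, None]  # means 2..6, SD 1 everywhere
        meta = _meta(expr.columns, ["E1", "E1"])
        trend = vb.PolyTrend(coeffs=np.array([1.0]), x_center=0.0, x_scale=1.0, degree=0)
        out = vb.adjusted_sd(expr, meta, trend)
        np.testing.assert_allclose(out["E1"], 1.0)

    def test_small_stage_excluded_with_warning(self, rng):
        expr = _expr(rng.uniform(1, 5, size=(30, 5)))
        meta = _meta(expr.columns, ["E1"] * 4 + ["E2"])
        trend = vb.PolyTrend(coeffs=np.array([1.0]), x_center=0.0, x_scale=1.0, degree=0)
        with pytest.warns(UserWarning, match="E2"):
            out = vb.adjusted_sd(expr, meta, trend)
        assert list(out.columns) == ["E1"]


class TestCV:
    def test_hand_values(self):
        expr = _expr([[2.0, 4.0], [3.0, 3.0], [0.0, 0.0]])
        meta = _meta(expr.columns, ["E1", "E1"])
        out = vb.cv_table(expr, meta)
        assert out.loc["g000", "E1"] == pytest.approx(1 / 3)  # population SD 1, mean 3
        assert out.loc["g001", "E1"] == 0.0
        assert np.isnan(out.loc["g002", "E1"])  # zero-mean stage masked


def brute_force_dm(expr, meta, window=50, overlap=25):
    """Independent implementation straight from the definition."""
    gmean = expr.mean(axis=1)
    gsd = expr.std(axis=1, ddof=0)
    gcv2 = (gsd / gmean) ** 2
    keep = [g for g in expr.index if gmean[g] != 0 and gcv2[g] > 0]
    order = sorted(keep, key=lambda g: (gmean[g], keep.index(g)))
    n = len(order)
    step = window - overlap
    if n <= window:
        windows = [list(range(n))]
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] + window < n:
            starts.append(n - window)
        windows = [list(range(s, s + window)) for s in starts]
    centres = [(w[0] + w[-1]) / 2 for w in windows]
    stages = sorted(meta["stage"].unique())
    out = pd.DataFrame(np.nan, index=expr.index, columns=stages)
    for rank, g in enumerate(order):
        dists = [abs(rank - c) for c in centres]
        wi = dists.index(min(dists))
        med = np.median([np.log10(gcv2[order[r]]) for r in windows[wi]])
        for s in stages:
            cols = meta.index[meta["stage"] == s]
            m = expr.loc[g, cols].mean()
            sd = expr.loc[g, cols].std(ddof=0)
            cv2 = (sd / m) ** 2
            if cv2 > 0:
                out.loc[g, s] = np.log10(cv2) - med
    return out


class TestDistanceToMedian:
    def test_window_assignment_rule_75_genes(self):
        windows, assign = vb._window_assignments(75, 50, 25)
        assert [list(w[:2]) for w in windows] == [[0, 1], [25, 26]]
        assert len(windows) == 2
        # gene ranked 30 (1-based) is 4.5 ranks from centre 24.5 and 20.5
        # from centre 49.5: window 1
        assert assign[29] == 0

    def test_zero_dm_when_gene_sits_on_its_window_median(self):
        # 3 genes, all with identical CV-squared: every DM is exactly 0
        base = np.array([[1.0, 3.0], [2.0, 6.0], [4.0, 12.0]])
        expr = _expr(np.hstack([base, base]))
        meta = _meta(expr.columns, ["E1", "E1", "E2", "E2"])
        out = vb.distance_to_median(expr, meta)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        expr = _expr(rng.uniform(0.5, 20, size=(200, 12)))
        meta = _meta(expr.columns, ["E1"] * 4 + ["E2"] * 4 + ["E3"] * 4)
        mine = vb.distance_to_median(expr, meta)
        oracle = brute_force_dm(expr, meta)
        np.testing.assert_allclose(
            mine.to_numpy(), oracle.to_numpy(), rtol=1e-10, atol=1e-12
        )


class TestStageSummary:
    def test_single_pair_bh_equals_raw(self, rng):
        metric = pd.DataFrame(
            {"E1": rng.normal(0, 1, 100), "E2": rng.normal(1, 1, 100)}
        )
        comp = vb.stage_summary(metric)
        assert comp.pairs.loc[0, "p_bh"] == comp.pairs.loc[0, "p_raw"]

    def test_hourglass_fixture_minimum_at_e3(self, hourglass_sim):
        vtab = vb.compute_variability(hourglass_sim["expr"], hourglass_sim["meta"])
        comp = vb.stage_summary(vtab.adjusted_sd, hourglass_sim["meta"])
        assert comp.medians.idxmin() == "E3"

    def test_null_type_one_error_controlled(self, rng):
        """Identically distributed stages: few BH-significant pairs."""
        sig = 0
        for _ in range(10):
            metric = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("ABCD"))
            comp = vb.stage_summary(metric)
            sig += (comp.pairs["p_bh"] < 0.05).sum()
        assert sig <= 6  # 60 tests at alpha .05 under the null


@pytest.fixture(scope="module")
def small(hourglass_sim):
    expr = hourglass_sim["expr"].iloc[:400]
    meta = hourglass_sim["meta"]
    trend = vb.compute_variability(expr, meta).trend
    return expr, meta, trend


class TestResampling:

    def test_bootstrap_shapes_and_range(self, small):
        expr, meta, trend = small
        med, tests = vb.bootstrap_stage_medians(expr, meta, trend, n_boot=30, rng=0)
        assert med.shape == (30, 8)
        assert (med.to_numpy() > 0).all()
        assert len(tests) == 28

    def test_bootstrap_separates_extreme_stages(self, small):
        expr, meta, trend = small
        med, _ = vb.bootstrap_stage_medians(expr, meta, trend, n_boot=100, rng=1)
        assert (med["E3"] < med["E1"]).mean() >= 0.95

    def test_subsample_full_size_is_identity(self, small):
        expr, meta, trend = small
        n = int(meta["stage"].value_counts().min())
        out = vb.subsample_equal(expr, meta, trend, n=n, reps=3, rng=2)
        full = vb.adjusted_sd(expr, meta, trend)
        expected = full.median(axis=0)
        for _, row in out.iterrows():
            np.testing.assert_allclose(row.to_numpy(), expected.to_numpy(), rtol=1e-12)

    def test_subsample_zero_reps_empty(self, small):
        expr, meta, trend = small
        out = vb.subsample_equal(expr, meta, trend, n=4, reps=0, rng=3)
        assert out.shape == (0, 8)

    def test_subsample_too_small_stage_named(self, small):
        expr, meta, trend = small
        with pytest.raises(ValueError, match="E1"):
            vb.subsample_equal(expr, meta, trend, n=1000, reps=2, rng=4)


class TestGroupCompare:
    def test_essential_genes_less_variable(self, hourglass_sim):
        vtab = vb.compute_variability(hourglass_sim["expr"], hourglass_sim["meta"])
        truth = hourglass_sim["truth"]
        essential = set(truth.genes.index[truth.genes["essential"]])
        medians, tests = vb.group_compare(vtab.adjusted_sd, {"essential": essential})
        assert (medians["median_in"] < medians["median_out"]).all()
        assert (tests["p_raw"] < 0.05).all()

    def test_universe_group_skipped(self, hourglass_sim, rng):
        metric = pd.DataFrame(rng.normal(size=(50, 2)), columns=["E1", "E2"])
        with pytest.warns(UserWarning, match="universe"):
            medians, tests = vb.group_compare(metric, {"all": set(metric.index)})
        assert medians.empty and tests.empty

    def test_stage_minimum_preserved_in_always_expressed_subset(self, hourglass_sim):
        """Restricting to genes expressed at every stage keeps E3 minimal."""
        expr, meta = hourglass_sim["expr"], hourglass_sim["meta"]
        vtab = vb.compute_variability(expr, meta)
        always = vtab.stage_mean.index[(vtab.stage_mean > 0).all(axis=1)]
        comp = vb.stage_summary(vtab.adjusted_sd.loc[always], meta)
        assert comp.medians.idxmin() == "E3"


class TestHourglassGenes:
    def test_exact_count_rule(self, rng):
        adjsd = pd.DataFrame(
            rng.uniform(0.5, 2, size=(1000, 8)), columns=[f"E{i}" for i in range(1, 9)]
        )
        assert len(vb.hourglass_genes(adjsd)) == 100

    def test_gene_equal_to_median_profile_selected(self, rng):
        adjsd = pd.DataFrame(
            rng.uniform(0.5, 2, size=(199, 8)),
            index=[f"g{i:03d}" for i in range(199)],
            columns=[f"E{i}" for i in range(1, 9)],
        )
        adjsd.loc["match"] = adjsd.median(axis=0)
        assert "match" in vb.hourglass_genes(adjsd)

    def test_matches_brute_force_ranking(self, rng):
        adjsd = pd.DataFrame(
            rng.uniform(0.5, 2, size=(50, 8)),
            index=[f"g{i:03d}" for i in range(50)],
            columns=[f"E{i}" for i in range(1, 9)],
        )
        got = vb.hourglass_genes(adjsd, top_frac=0.2)
        med = adjsd.median(axis=0)
        corrs = {
            g: np.corrcoef(adjsd.loc[g], med)[0, 1] for g in adjsd.index
        }
        expected = sorted(sorted(corrs), key=lambda g: -corrs[g])[:10]
        assert sorted(got) == sorted(expected)
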