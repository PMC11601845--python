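import numpy as np
import pandas as pd
import pytest

from codexspatial import (
    build_knn_graph,
    compare_cn_proportions,
    compare_distance,
    interaction_enrichment,
    min_distance,
)

from oracles import brute_force_min_distance, permutation_t_pvalue, welch_t


def cell_frame(xy, roi="R0"):
    xy = np.asarray(xy, dtype=float)
    rois = [roi] * len(xy) if isinstance(roi, str) else list(roi)
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(xy))],
                         "roi_id": rois, "x_um": xy[:, 0], "y_um": xy[:, 1]})


def phen_series(cells, labels):
    return pd.Series(list(labels), index=pd.Index(cells["cell_id"], name="cell_id"))


class TestMinDistance:
    def test_single_pair_is_euclidean(self):
        cells = cell_frame([(0, 0), (3, 4)])
        phen = phen_series(cells, ["A", "B"])
        out = min_distance(cells, phen, "A", "B")
        assert out["mean_min_dist"].iloc[0] == pytest.approx(5.0)
        assert out["n_source"].iloc[0] == 1

    def test_coincident_cells_give_zero(self):
        cells = cell_frame([(1, 1), (1, 1), (9, 9)])
        phen = phen_series(cells, ["A", "B", "B"])
        out = min_distance(cells, phen, "A", "B")
        assert out["mean_min_dist"].iloc[0] == 0.0

    def test_same_type_excludes_self(self):
        cells = cell_frame([(0, 0), (2, 0), (5, 0)])
        phen = phen_series(cells, ["A", "A", "A"])
        out = min_distance(cells, phen, "A", "A")
        assert out["mean_min_dist"].iloc[0] == pytest.approx((2 + 2 + 3) / 3)

    def test_absent_type_flagged_not_zero(self):
        cells = cell_frame([(0, 0), (1, 1)])
        phen = phen_series(cells, ["A", "A"])
        out = min_distance(cells, phen, "A", "B")
        assert np.isnan(out["mean_min_dist"].iloc[0])

    def test_matches_brute_force(self, rng):
        a = rng.uniform(0, 500, (200, 2))
        b = rng.uniform(0, 500, (200, 2))
        cells = cell_frame(np.vstack([a, b]))
        phen = phen_series(cells, ["A"] * 200 + ["B"] * 200)
        out = min_distance(cells, phen, "A", "B")
        assert out["mean_min_dist"].iloc[0] == pytest.approx(
            brute_force_min_distance(a, b), abs=1e-12)

    def test_directional_asymmetry_on_3v2_fixture(self):
        a = [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0)]
        b = [(1.0, 0.0), (19.0, 0.0)]
        cells = cell_frame(a + b)
        phen = phen_series(cells, ["A"] * 3 + ["B"] * 2)
        ab = min_distance(cells, phen, "A", "B")["mean_min_dist"].iloc[0]
        ba = min_distance(cells, phen, "B", "A")["mean_min_dist"].iloc[0]
        assert ab == pytest.approx(brute_force_min_distance(a, b))
        assert ba == pytest.approx(brute_force_min_distance(b, a))
        assert ab != ba


class TestCompareDistance:
    @staticmethod
    def as_results(values_by_roi):
        return pd.DataFrame([{"roi_id": r, "type_a": "A", "type_b": "B",
                              "mean_min_dist": v, "n_source": 10}
                             for r, v in values_by_roi.items()])

    def test_identical_groups_t0_p1(self):
        res = self.as_results({"r1": 5.0, "r2": 7.0, "r3": 5.0, "r4": 7.0})
        out = compare_distance(res, {"r1": "x", "r2": "x", "r3": "y", "r4": "y"})
        assert out.statistic == pytest.approx(0.0)
        assert out.p_raw == pytest.approx(1.0)

    def test_matches_closed_form_welch(self, rng):
        vals = dict(enumerate(rng.normal(10, 2, 12)))
        res = self.as_results({f"r{i}": v for i, v in vals.items()})
        cohorts = {f"r{i}": ("x" if i < 6 else "y") for i in range(12)}
        out = compare_distance(res, cohorts)
        x = [vals[i] for i in range(6)]
        y = [vals[i] for i in range(6, 12)]
        t, df, p = welch_t(x, y)
        assert out.statistic == pytest.approx(t)
        assert out.df == pytest.approx(df)
        assert out.p_raw == pytest.approx(p)

    def test_equal_variance_welch_equals_pooled_student(self):
        # equal n and equal sample variances make Welch and pooled t coincide
        from scipy.stats import ttest_ind

        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.5, 3.5, 4.5, 5.5])  # same spread, shifted
        res = self.as_results({f"r{i}": v for i, v in enumerate(np.r_[x, y])})
        cohorts = {f"r{i}": ("x" if i < 4 else "y") for i in range(8)}
        out = compare_distance(res, cohorts)
        pooled = ttest_ind(x, y, equal_var=True)
        assert out.statistic == pytest.approx(pooled.statistic)
        assert out.p_raw == pytest.approx(pooled.pvalue)

    def test_agrees_with_permutation_reference(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        res = self.as_results({f"r{i}": v for i, v in enumerate(np.r_[x, y])})
        cohorts = {f"r{i}": ("x" if i < 8 else "y") for i in range(16)}
        out = compare_distance(res, cohorts)
        p_perm = permutation_t_pvalue(x, y, n_draws=20_000, seed=0)
        # equal n, similar spread: Welch p ~ permutation p within MC error
        assert out.p_raw == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / 20_000) + 0.01)

    def test_too_few_usable_rois_rejected(self):
        res = self.as_results({"r1": 5.0, "r2": np.nan, "r3": 6.0, "r4": 7.0})
        with pytest.raises(ValueError, match="usable"):
            compare_distance(res, {"r1": "x", "r2": "x", "r3": "y", "r4": "y"})


class TestCompareCnProportions:
    @staticmethod
    def props(rows, cns=("CN0", "CN1")):
        return pd.DataFrame(rows, columns=list(cns))

    def test_asinh_of_zero_proportion_is_zero(self):
        assert np.arcsinh(0.0) == 0.0

    def test_bonferroni_multiplication(self, rng):
        # m = 6 CN columns: adjusted p must be exactly min(1, 6 * raw p)
        vals = rng.dirichlet(np.ones(6), size=8)
        props = pd.DataFrame(vals, columns=[f"CN{i}" for i in range(6)],
                             index=[f"r{i}" for i in range(8)])
        cohorts = {f"r{i}": ("x" if i < 4 else "y") for i in range(8)}
        out = compare_cn_proportions(props, cohorts)
        ok = out["p_raw"].notna()
        assert np.allclose(out.loc[ok, "p_bonferroni"],
                           np.minimum(1.0, 6 * out.loc[ok, "p_raw"]))
        assert (out.loc[ok, "p_bonferroni"] >= out.loc[ok, "p_raw"]).all()

    def test_transform_applied_before_test(self, rng):
        vals = rng.dirichlet(np.ones(2), size=10)
        props = pd.DataFrame(vals, columns=["CN0", "CN1"],
                             index=[f"r{i}" for i in range(10)])
        cohorts = {f"r{i}": ("x" if i < 5 else "y") for i in range(10)}
        out = compare_cn_proportions(props, cohorts, transform="asinh")
        t, _, p = welch_t(np.arcsinh(vals[:5, 0]), np.arcsinh(vals[5:, 0]))
        row = out[out["cn"] == "CN0"].iloc[0]
        assert row["statistic"] == pytest.approx(t)
        assert row["p_raw"] == pytest.approx(p)

    def test_atanh_mode_clamps_at_one(self):
        props = pd.DataFrame({"CN0": [1.0, 0.9, 0.2, 0.1],
                              "CN1": [0.0, 0.1, 0.8, 0.9]},
                             index=[f"r{i}" for i in range(4)])
        cohorts = {f"r{i}": ("x" if i < 2 else "y") for i in range(4)}
        out = compare_cn_proportions(props, cohorts, transform="atanh")
        assert np.isfinite(out["statistic"]).all()

    def test_degenerate_cn_flagged_but_counted(self):
        props = pd.DataFrame({"CN0": [0.0, 0.0, 0.0, 0.0],
                              "CN1": [1.0, 0.8, 0.6, 0.7],
                              "CN2": [0.0, 0.2, 0.4, 0.3]},
                             index=[f"r{i}" for i in range(4)])
        cohorts = {f"r{i}": ("x" if i < 2 else "y") for i in range(4)}
        out = compare_cn_proportions(props, cohorts)
        assert out.loc[out["cn"] == "CN0", "degenerate"].iloc[0]
        ok = out["p_raw"].notna()
        # the correction denominator stays m=3 despite the flagged CN
        assert np.allclose(out.loc[ok, "p_bonferroni"],
                           np.minimum(1.0, 3 * out.loc[ok, "p_raw"]))


class TestInteractionEnrichment:
    def test_single_phenotype_degenerate_null(self, rng):
        cells = cell_frame(rng.uniform(0, 200, (60, 2)))
        phen = phen_series(cells, ["A"] * 60)
        out = interaction_enrichment(build_knn_graph(cells, k=5), phen,
                                     n_perm=100, seed=0)
        row = out.iloc[0]
        assert row["degenerate"]
        assert np.isnan(row["z"])
        assert 0 < row["p_emp"] <= 1.0

    def test_p_never_zero(self, rng):
        cells = cell_frame(rng.uniform(0, 300, (80, 2)))
        phen = phen_series(cells, rng.choice(["A", "B"], 80))
        out = interaction_enrichment(build_knn_graph(cells, k=5), phen,
                                     n_perm=100, seed=1)
        assert (out["p_emp"] > 0).all()
        assert (out["p_emp"] <= 1).all()

    def test_band_filters_edges(self, rng):
        # neighbours at distance 1 are outside a (3, 100) band
        cells = cell_frame([(float(i), 0.0) for i in range(30)])
        phen = phen_series(cells, ["A", "B"] * 15)
        out = interaction_enrichment(build_knn_graph(cells, k=2), phen,
                                     n_perm=100, seed=0, band=(3.0, 100.0))
        assert (out["observed"] == 0).all()

    def test_planted_attraction_positive_z(self):
        # B cells generated adjacent to CD8 cells: (B, CD8) must enrich
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cd8 = rng.uniform(0, 600, (80, 2))
            b = cd8 + rng.normal(0, 6, cd8.shape)  # clings to CD8
            tumor = rng.uniform(0, 600, (160, 2))
            cells = cell_frame(np.vstack([cd8, b, tumor]))
            phen = phen_series(cells, ["CD8"] * 80 + ["B"] * 80 + ["Tumor"] * 160)
            out = interaction_enrichment(build_knn_graph(cells, k=10), phen,
                                         n_perm=150, seed=seed)
            z = out.set_index(["type_a", "type_b"]).loc[("B", "CD8"), "z"]
            hits += z > 0
        assert hits >= 9

    def test_permutation_reproducible_per_seed(self, rng):
        cells = cell_frame(rng.uniform(0, 300, (60, 2)))
        phen = phen_series(cells, rng.choice(["A", "B"], 60))
        g = build_knn_graph(cells, k=5)
        a = interaction_enrichment(g, phen, n_perm=120, seed=9)
        b = interaction_enrichment(g, phen, n_perm=120, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_n_perm_floor(self, rng):
        cells = cell_frame(rng.uniform(0, 100, (20, 2)))
        phen = phen_series(cells, ["A"] * 20)
        with pytest.raises(ValueError, match="n_perm"):
            interaction_enrichment(build_knn_graph(cells, k=3), phen, n_perm=10)
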