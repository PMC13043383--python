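"""Bulk and single-cell differential expression operations."""

import numpy as np
import pandas as pd
import pytest

from coelomyx import diffexpr, qc, simdata
from tests.conftest import make_adata


class TestPoverA:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([10, 10, 10, 0, 0, 0], True),  # exactly 3 samples at the threshold
            ([9, 50, 50, 0, 0, 0], False),  # only 2 samples >= 10
            ([0, 0, 0, 0, 0, 0], False),  # all-zero rows removed first
        ],
    )
    def test_boundaries(self, row, kept):
        counts = pd.DataFrame([row, [100] * 6], index=["g0", "ref"])
        out = diffexpr.pover_a_filter(counts)
        assert ("g0" in out.index) == kept

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(200, 8)), index=[f"g{i}" for i in range(200)]
        )
        out = diffexpr.pover_a_filter(counts)
        expected = []
        for g in counts.index:
            row = counts.loc[g]
            if row.sum() > 0 and sum(1 for v in row if v >= 10) >= 3:
                expected.append(g)
        assert list(out.index) == expected


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = diffexpr.median_of_ratios_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = diffexpr.median_of_ratios_size_factors(counts)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_recovers_simulated_depth_multipliers(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(4, 1, size=2000)
        depths = np.array([0.5, 1.0, 1.5, 2.0])
        counts = pd.DataFrame(
            rng.poisson(base[:, None] * depths[None, :]),
            columns=["s1", "s2", "s3", "s4"],
        )
        sf = diffexpr.median_of_ratios_size_factors(counts)
        norm = sf / np.exp(np.log(sf).mean())
        truth = depths / np.exp(np.log(depths).mean())
        assert np.all(np.abs(norm.to_numpy() / truth - 1.0) < 0.05)

    def test_no_common_nonzero_gene_is_an_error(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError, match="nonzero"):
            diffexpr.median_of_ratios_size_factors(counts)


class TestNBWald:
    def _fixture(self, seed=0, lfc=0.0):
        design = simdata.BulkDesign(
            n_genes=400, timepoints=(6,), de_fraction=0.2 if lfc else 0.0,
            de_log2fc=lfc, dispersion=0.05, seed=seed,
        )
        counts, truth = simdata.simulate_bulk_experiment(design)
        sf = diffexpr.median_of_ratios_size_factors(counts)
        cols_t = [c for c in counts.columns if c.startswith("uvb")]
        cols_c = [c for c in counts.columns if c.startswith("control")]
        return counts, truth, sf, cols_t, cols_c

    def test_identical_groups_give_null_results(self):
        counts = pd.DataFrame(
            np.tile(np.arange(10, 110, 10), (6, 1)).T,
            columns=[f"{g}_{i}" for g in ("a", "b") for i in range(3)],
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = diffexpr.nb_wald_test(
            counts, sf, ([c for c in counts if c.startswith("a")],
                         [c for c in counts if c.startswith("b")])
        )
        assert np.allclose(res["log2FC"], 0.0)
        assert np.all(res["p"] > 0.99)

    def test_planted_effect_detected(self):
        counts, truth, sf, cols_t, cols_c = self._fixture(seed=3, lfc=2.0)
        res = diffexpr.nb_wald_test(counts, sf, (cols_t, cols_c))
        de = truth["is_de"]
        assert (res.loc[de, "call"] == 1).mean() > 0.9
        assert (res.loc[~de, "call"] != 0).mean() < 0.05

    def test_invariance_to_joint_count_and_factor_scaling(self):
        counts, truth, sf, cols_t, cols_c = self._fixture(seed=4)
        res1 = diffexpr.nb_wald_test(counts, sf, (cols_t, cols_c))
        scaled = counts.copy()
        scaled[cols_t[0]] *= 3
        sf2 = sf.copy()
        sf2[cols_t[0]] *= 3
        res2 = diffexpr.nb_wald_test(scaled, sf2, (cols_t, cols_c))
        pd.testing.assert_frame_equal(res1, res2)

    def test_bh_monotone_in_rank(self):
        counts, truth, sf, cols_t, cols_c = self._fixture(seed=5, lfc=2.0)
        res = diffexpr.nb_wald_test(counts, sf, (cols_t, cols_c)).sort_values("p")
        assert res["q"].is_monotonic_increasing


class TestKMeansClusters:
    def _profiles(self, seed):
        rng = np.random.default_rng(seed)
        cols = [f"{c}_T{t}_R{r}" for c in ("control", "uvb") for t in range(5) for r in range(3)]
        up = np.array([0.0] * 15 + [2.0] * 15)
        rows = []
        for i in range(30):
            sign = 1.0 if i < 15 else -1.0
            rows.append(sign * up + 0.1 * rng.standard_normal(30))
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(30)], columns=cols)

    def test_planted_antiphase_groups_recovered(self):
        cond = None
        for seed in range(10):
            profiles = self._profiles(seed)
            cond = pd.Series(
                ["uvb" if c.startswith("uvb") else "control" for c in profiles.columns],
                index=profiles.columns,
            )
            result = diffexpr.kmeans_gene_clusters(profiles, cond, seed=seed)
            up_genes = set(result.labels[result.labels == 1].index)
            assert up_genes == {f"g{i}" for i in range(15)}, f"seed {seed}"

    def test_centroid_member_has_unit_correlation(self):
        profiles = self._profiles(0)
        cond = pd.Series(
            ["uvb" if c.startswith("uvb") else "control" for c in profiles.columns],
            index=profiles.columns,
        )
        result = diffexpr.kmeans_gene_clusters(profiles, cond, seed=0)
        # append a synthetic gene exactly equal to its cluster centroid
        centroid = result.centroids.loc[1]
        profiles2 = pd.concat([profiles, centroid.to_frame("gc").T])
        result2 = diffexpr.kmeans_gene_clusters(profiles2, cond, seed=0)
        assert result2.centroid_corr["gc"] > 0.999

    def test_degenerate_profiles_rejected(self):
        profiles = pd.DataFrame(np.ones((5, 6)), columns=[f"s{i}" for i in range(6)])
        cond = pd.Series(["control"] * 3 + ["uvb"] * 3, index=profiles.columns)
        with pytest.raises(ValueError, match="degenerate"):
            diffexpr.kmeans_gene_clusters(profiles, cond)


class TestClusterMeanAnova:
    def _long(self, effect_trt=0.0, effect_time=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for trt in ("control", "uvb"):
            for time in range(5):
                for rep in range(3):
                    val = (
                        (effect_trt if trt == "uvb" else 0.0)
                        + effect_time * time
                        + noise * rng.standard_normal()
                    )
                    rows.append({"treatment": trt, "time": time, "value": val})
        return pd.DataFrame(rows)

    def test_pure_treatment_shift(self):
        table = diffexpr.cluster_mean_anova(self._long(effect_trt=2.0, noise=0.3, seed=4))
        assert table.loc["C(treatment)", "PR(>F)"] < 0.01
        assert table.loc["C(treatment):C(time)", "PR(>F)"] > 0.5

    def test_all_equal_reports_zero_f(self):
        table = diffexpr.cluster_mean_anova(self._long())
        assert table.loc["C(treatment)", "F"] == 0.0
        assert table.loc["C(treatment)", "PR(>F)"] == 1.0

    def test_exact_additivity_has_zero_interaction_ss(self):
        table = diffexpr.cluster_mean_anova(self._long(effect_trt=1.0, effect_time=0.5))
        assert table.loc["C(treatment):C(time)", "sum_sq"] < 1e-18

    def test_matches_hand_ss_decomposition_when_balanced(self):
        table_df = self._long(effect_trt=2.0, effect_time=0.4, noise=0.5, seed=1)
        out = diffexpr.cluster_mean_anova(table_df)
        # balanced two-way layout: Type-II equals the textbook decomposition
        grand = table_df["value"].mean()
        ss_trt = sum(
            len(sub) * (sub["value"].mean() - grand) ** 2
            for _, sub in table_df.groupby("treatment")
        )
        assert np.isclose(out.loc["C(treatment)", "sum_sq"], ss_trt)


class TestSingleCellDE:
    def _cohort(self, fold=1.0, seed=0, n=400):
        rng = np.random.default_rng(seed)
        X = rng.poisson(2.0, size=(2 * n, 50)).astype(float)
        cond = np.array(["control"] * n + ["uvb"] * n)
        X[cond == "uvb", 0] = rng.poisson(2.0 * fold, size=n)
        adata = make_adata(X, conditions=cond)
        adata.obs["cell_type"] = "phagocyte"
        return qc.normalize_log(adata)

    def test_planted_fourfold_gene_called_up(self):
        table = diffexpr.sc_condition_de(self._cohort(fold=4.0, seed=1))
        row = table.query("gene == 'g0'").iloc[0]
        assert row["call"] == 1

    def test_null_calibration_on_permuted_labels(self):
        table = diffexpr.sc_condition_de(self._cohort(fold=1.0, seed=2, n=500))
        frac = (table["p"] < 0.05).mean()
        assert 0.01 <= frac <= 0.09

    def test_volcano_thresholds_are_strict(self):
        call = diffexpr.volcano_call(
            q=[0.01, 0.01, 0.05, 0.01, 0.01],
            log2fc=[1.0, 1.001, 2.0, -1.0, -1.001],
        )
        assert list(call) == [0, 1, 0, 0, -1]

    def test_undersized_group_skipped(self):
        adata = self._cohort(n=10)
        with pytest.warns(UserWarning, match="skipped"):
            table = diffexpr.sc_condition_de(adata, min_cells=20)
        assert table.empty
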