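"""NB differential expression: size factors, dispersion, Wald test, BH."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from coldsrna import diffexpr
from coldsrna.simulate import SimulationConfig, draw_nb_counts


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert diffexpr.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        # min over k >= i of p(k) * m / k collapses all four to 0.04
        out = diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_statsmodels_and_is_monotone(self, p):
        ours = diffexpr.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(ours[order]) >= -1e-12).all()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5],
                               "c": [10, 20, 5]})
        np.testing.assert_allclose(diffexpr.size_factors(counts), 1.0)

    def test_doubled_column_factor_ratio_two(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5],
                               "c": [20, 40, 10]})
        sf = diffexpr.size_factors(counts)
        # factors are defined up to a common rescaling (geometric mean 1)
        assert sf["c"] / sf["a"] == pytest.approx(2.0)
        assert sf["b"] / sf["a"] == pytest.approx(1.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 500, size=(80, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = diffexpr.size_factors(counts)
        mat = counts.to_numpy(float)
        geo = np.exp(np.log(mat).mean(axis=1))
        brute = np.array([np.median(mat[:, j] / geo) for j in range(6)])
        brute /= np.exp(np.log(brute).mean())
        np.testing.assert_allclose(sf.to_numpy(), brute, rtol=1e-12)

    def test_fallback_to_total_count(self, caplog):
        counts = pd.DataFrame({"a": [0, 10], "b": [10, 0]})
        with caplog.at_level("WARNING"):
            sf = diffexpr.size_factors(counts)
        assert "total-count" in caplog.text
        assert sf["a"] == pytest.approx(sf["b"])


class TestEstimateDispersion:
    def _design_groups(self, n=3):
        cols = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        groups = pd.Series(["control"] * n + ["cold"] * n, index=cols)
        return cols, groups

    def test_poisson_data_gives_near_zero_alpha(self):
        rng = np.random.default_rng(10)
        cols, groups = self._design_groups()
        counts = pd.DataFrame(rng.poisson(100.0, size=(2000, 6)), columns=cols)
        disp = diffexpr.estimate_dispersion(counts, groups)
        assert disp.median() < 0.02

    def test_underdispersed_feature_clamped_to_zero_raw(self):
        cols, groups = self._design_groups()
        # constant counts: sample variance 0 < mean, so raw alpha clamps at 0
        counts = pd.DataFrame([[50] * 6] * 20, columns=cols)
        disp = diffexpr.estimate_dispersion(counts, groups)
        assert (disp <= 1e-6).all()

    def test_planted_alpha_recovered_in_median(self):
        config = SimulationConfig(seed=13, nb_dispersion=0.2, de_fraction=0.0)
        design = config.samples()
        tp = design[design["time"] == "2d"]
        ids = [f"F{i:04d}" for i in range(2000)]
        counts = draw_nb_counts(ids, design, config, base_means=200.0)
        sub = counts[list(tp["sample"])]
        disp = diffexpr.estimate_dispersion(sub, tp.set_index("sample")["condition"])
        assert 0.1 <= disp.median() <= 0.3

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"c0": [10], "t0": [12]})
        groups = pd.Series({"c0": "control", "t0": "cold"})
        with pytest.raises(ValueError, match="replicates"):
            diffexpr.estimate_dispersion(counts, groups)


def _one_tp_design(n=3, tp="3h"):
    rows = []
    for cond in ("control", "cold"):
        for i in range(n):
            rows.append({"sample": f"{cond}_{tp}_r{i}", "condition": cond,
                         "time": tp, "replicate": str(i)})
    return pd.DataFrame(rows)


class TestNbWaldTest:
    def test_matches_statsmodels_glm(self):
        """The vectorized IRLS agrees with statsmodels' NB GLM coefficient
        and standard error, feature by feature."""
        rng = np.random.default_rng(3)
        design = _one_tp_design()
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.05, size=(20, 6)),
            index=[f"F{i}" for i in range(20)], columns=design["sample"])
        disp = pd.Series(0.1, index=counts.index)
        res = diffexpr.nb_wald_test(counts, design, "3h", dispersions=disp)

        sf = diffexpr.size_factors(counts)
        offset = np.log(sf.to_numpy())
        x = sm.add_constant((design["condition"] == "cold").astype(float).to_numpy())
        for i, fid in enumerate(counts.index):
            fit = sm.GLM(counts.loc[fid].to_numpy(), x,
                         family=sm.families.NegativeBinomial(alpha=0.1),
                         offset=offset).fit()
            row = res[res["feature"] == fid].iloc[0]
            assert row["log2fc"] == pytest.approx(fit.params[1] / np.log(2),
                                                  abs=1e-5)
            se_log2 = None  # our z uses natural-log scale; compare z instead
            z_ours = row["log2fc"] * np.log(2) / (fit.bse[1])
            assert abs(z_ours) == pytest.approx(abs(fit.tvalues[1]), rel=1e-3)

    def test_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(4)
        design = _one_tp_design()
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.1, size=(50, 6)),
            index=[f"F{i}" for i in range(50)], columns=design["sample"])
        swapped = design.copy()
        swapped["condition"] = swapped["condition"].map(
            {"control": "cold", "cold": "control"})
        a = diffexpr.nb_wald_test(counts, design, "3h")
        b = diffexpr.nb_wald_test(counts, swapped, "3h")
        keep = a["p"].notna() & b["p"].notna() & (a["base_mean"] > 5)
        np.testing.assert_allclose(a.loc[keep, "log2fc"],
                                   -b.loc[keep, "log2fc"], atol=1e-6)
        np.testing.assert_allclose(a.loc[keep, "p"], b.loc[keep, "p"], atol=1e-8)

    def test_low_expression_is_undetected_regardless_of_ratio(self):
        design = _one_tp_design()
        counts = pd.DataFrame(
            [[1, 0, 1, 9, 8, 9],  # huge ratio but base mean ~ 3
             [300, 310, 290, 300, 305, 295]],
            index=["low", "high"], columns=design["sample"])
        res = diffexpr.nb_wald_test(counts, design, "3h").set_index("feature")
        assert res.loc["low", "base_mean"] < 5
        assert res.loc["low", "status"] == "undetected"

    def test_all_zero_feature(self):
        design = _one_tp_design()
        counts = pd.DataFrame([[0] * 6, [50, 60, 55, 52, 58, 61]],
                              index=["zero", "ok"], columns=design["sample"])
        res = diffexpr.nb_wald_test(counts, design, "3h").set_index("feature")
        assert res.loc["zero", "p"] == 1.0
        assert res.loc["zero", "status"] == "undetected"
        assert res.loc["zero", "log2fc"] == 0.0

    def test_p_adj_never_below_p(self, small_counts, small_config):
        srna, _, _ = small_counts
        res = diffexpr.run_de(srna, small_config.samples())
        ok = res["p"].notna()
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p"] - 1e-12).all()

    def test_missing_condition_rejected(self):
        design = _one_tp_design()
        only_cold = design[design["condition"] == "cold"]
        counts = pd.DataFrame([[1] * 3], index=["f"],
                              columns=only_cold["sample"])
        with pytest.raises(ValueError, match="control"):
            diffexpr.nb_wald_test(counts, only_cold, "3h")

    def test_batchwise_bh(self):
        rng = np.random.default_rng(6)
        design = _one_tp_design()
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.1, size=(40, 6)),
            index=[f"F{i}" for i in range(40)], columns=design["sample"])
        batch = pd.Series(["A"] * 20 + ["B"] * 20, index=counts.index)
        res = diffexpr.nb_wald_test(counts, design, "3h", batch=batch)
        merged = res.set_index("feature")
        for label in ("A", "B"):
            members = batch[batch == label].index
            sub = merged.loc[members]
            np.testing.assert_allclose(
                sub["p_adj"].to_numpy(),
                diffexpr.bh_adjust(sub["p"].to_numpy()), atol=1e-12)
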