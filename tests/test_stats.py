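"""Atlas scores and the statistical validation battery."""

import numpy as np
import pandas as pd
import pytest

from amcpipe.stats import (
    correlation_tables,
    differential_concentration,
    median_equality_battery,
    permutation_battery,
    specificity_index,
    top_percentile_proteins,
    two_group_battery,
    variability_score,
)


class TestVariabilityScore:
    def test_constant_values_score_zero(self):
        s = variability_score([5, 5, 5, 5])
        assert s.score == 0.0 and s.n == 4

    def test_two_point_hand_arithmetic(self):
        # mean 2, sample sd sqrt(2), CV ~0.7071, n=2 -> ~0.3536
        s = variability_score([1, 3])
        assert s.score == pytest.approx(0.35355, abs=1e-4)

    def test_undefined_cases_skipped(self):
        assert variability_score([1]) is None
        assert variability_score([-1, 1]) is None  # zero mean


class TestSpecificityIndex:
    def test_equal_everywhere_is_zero(self):
        idx = specificity_index({"ctx": [2.0, 2.0], "cb": [2.0], "th": [2.0]}, "ctx")
        assert idx.index == pytest.approx(0.0)

    def test_e_fold_enrichment_is_one(self):
        c = 3.0
        idx = specificity_index({"ctx": [np.e * c], "cb": [c], "th": [c]}, "ctx")
        assert idx.index == pytest.approx(1.0)

    def test_antisymmetry_under_target_swap(self):
        by_loc = {"a": [1.0, 2.0, 4.0], "b": [8.0, 16.0]}
        ia = specificity_index(by_loc, "a").index
        ib = specificity_index(by_loc, "b").index
        assert ia == pytest.approx(-ib)

    def test_nonpositive_dropped(self):
        idx = specificity_index({"a": [0.0, np.e], "b": [1.0]}, "a")
        assert idx.index == pytest.approx(1.0)


class TestTopPercentile:
    def _entries(self, values, locs):
        return pd.DataFrame({
            "canonical_gene": [f"G{i}" for i in range(len(values))],
            "concentration_uM": values,
            "cell_type": locs,
        })

    def test_top_cell_of_100_distinct(self):
        e = self._entries(list(range(1, 101)), ["n"] * 100)
        out = top_percentile_proteins(e, "cell_type", q=0.99)
        assert out["n"] == {"G99"}  # only the maximum exceeds the 99% quantile

    def test_all_equal_selects_nothing(self):
        e = self._entries([5.0] * 50, ["n"] * 50)
        assert top_percentile_proteins(e, "cell_type", q=0.99)["n"] == set()

    def test_degenerate_quantile_selects_all(self):
        e = self._entries([1.0, 2.0], ["n", "a"])
        out = top_percentile_proteins(e, "cell_type", q=0.0)
        assert out["n"] | out["a"] == {"G0", "G1"}


class TestCorrelationTables:
    def _atlas(self, groups):
        rows = []
        for study, genes_vals in groups.items():
            for g, v in genes_vals.items():
                rows.append((g, v, study))
        return pd.DataFrame(rows, columns=["canonical_gene", "concentration_uM", "study_id"])

    def test_identical_copies_give_unit_correlation(self):
        vals = {f"G{i}": float(np.exp(i % 7) + i) for i in range(30)}
        atlas = self._atlas({"s1": vals, "s2": dict(vals), "s3": dict(vals)})
        r, n = correlation_tables(atlas, "study_id")
        assert np.allclose(r.to_numpy(), 1.0)
        assert (n.loc["s1", "s2"] == 30) and (n.loc["s2", "s3"] == 30)

    def test_disjoint_gene_sets_undefined(self):
        atlas = self._atlas({"s1": {"A": 1.0, "B": 2.0}, "s2": {"C": 1.0, "D": 2.0}})
        r, n = correlation_tables(atlas, "study_id")
        assert n.loc["s1", "s2"] == 0
        assert np.isnan(r.loc["s1", "s2"])

    def test_latent_correlation_recovered(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, 500)
        x = np.exp(0.8 * z + 0.6 * rng.normal(0, 1, 500))
        y = np.exp(0.8 * z + 0.6 * rng.normal(0, 1, 500))
        atlas = self._atlas({
            "s1": {f"G{i}": float(x[i]) for i in range(500)},
            "s2": {f"G{i}": float(y[i]) for i in range(500)},
        })
        r, _ = correlation_tables(atlas, "study_id")
        # latent log-scale correlation 0.64/(0.64+0.36) = 0.64
        assert r.loc["s1", "s2"] == pytest.approx(0.64, abs=0.1)


class TestMedianEqualityBattery:
    def test_identical_groups_no_rejection(self):
        g = {f"s{i}": list(range(1, 11)) for i in range(3)}
        res = median_equality_battery(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert not res.rejected and res.posthoc_holm is None

    def test_shifted_group_flagged_only(self):
        g = {"a": list(range(1, 11)), "b": list(range(1, 11)),
             "c": list(range(101, 111))}
        res = median_equality_battery(g)
        assert res.rejected
        ph = res.posthoc_holm
        assert ph.loc["a", "c"] < 0.05 and ph.loc["b", "c"] < 0.05
        assert ph.loc["a", "b"] > 0.05

    def test_holm_adjustment_monotone_and_above_raw(self):
        rng = np.random.default_rng(9)
        g = {"a": rng.normal(0, 1, 20), "b": rng.normal(1, 1, 20),
             "c": rng.normal(2, 1, 20), "d": rng.normal(0.2, 1, 20)}
        res = median_equality_battery(g)
        if res.posthoc_holm is not None:
            from amcpipe.stats import conover_posthoc

            raw = conover_posthoc([np.asarray(g[k], float) for k in sorted(g)],
                                  res.h_statistic)
            adj = res.posthoc_holm.loc[sorted(g), sorted(g)].to_numpy()
            iu = np.triu_indices(4, 1)
            raw_u, adj_u = raw[iu], adj[iu]
            assert (adj_u >= raw_u - 1e-12).all()
            order = np.argsort(raw_u)
            assert (np.diff(adj_u[order]) >= -1e-12).all()

    def test_two_groups_directed_to_two_sample_test(self):
        with pytest.raises(ValueError, match="two-sample"):
            median_equality_battery({"a": [1, 2], "b": [3, 4]})


class TestTwoGroupBattery:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = two_group_battery(a, list(a))
        assert res.dbm_ovs == 0.0
        assert res.mwu_p == pytest.approx(1.0)
        for p in res.p_values().values():
            assert p >= 0.99

    def test_pure_location_shift(self):
        rng = np.random.default_rng(4)
        b = rng.normal(0, 1, 80)
        a = b + 10.0
        res = two_group_battery(a, b)
        assert res.dbm_ovs > 0.5
        assert res.mwu_p < 1e-6 and res.ks_p < 1e-6
        assert res.brown_forsythe_p > 0.9 and res.fligner_killeen_p > 0.9

    def test_pure_scale_change(self):
        rng = np.random.default_rng(4)
        b = rng.normal(5, 1, 80)
        a = 3 * (b - b.mean()) + b.mean()
        res = two_group_battery(a, b)
        assert res.brown_forsythe_p < 1e-4 and res.fligner_killeen_p < 1e-4
        assert res.dbm_ovs < 0.1  # medians comparable

    def test_zero_spread_flagged(self):
        res = two_group_battery([2.0] * 6, [2.0] * 6)
        assert np.isnan(res.dbm_ovs)


class TestPermutationBattery:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 300), rng.normal(0.3, 1, 300)
        r1 = permutation_battery(a, b, n=50, reps=30, seed=123)
        r2 = permutation_battery(a, b, n=50, reps=30, seed=123)
        assert r1 == r2

    def test_power_for_two_sd_shift(self):
        rng = np.random.default_rng(7)
        b = rng.normal(0, 1, 400)
        a = rng.normal(2.0, 1, 400)  # 2 pooled-SD location shift
        rates = permutation_battery(a, b, n=100, reps=100, seed=11)
        assert rates["mwu"] > 0.99

    def test_control_mode_calibrates_near_alpha(self):
        # ln-scale concentrations, as the pipeline feeds the battery
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 400), rng.normal(0.8, 1.3, 400)
        rates = permutation_battery(a, b, n=100, reps=200, seed=21, control=True)
        for test, rate in rates.items():
            assert 0.0 <= rate <= 0.12, (test, rate)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            permutation_battery([1] * 10, [1] * 10, n=2)


class TestDifferentialConcentration:
    def _groups(self, fc, base=10.0, n=3, jitter=1e-3):
        rng = np.random.default_rng(0)
        b = {"G": base * (1 + jitter * rng.standard_normal(n))}
        a = {"G": fc * base * (1 + jitter * rng.standard_normal(n))}
        return a, b

    def test_identical_groups_nothing_selected(self):
        a = {"G1": [1.0, 1.0, 1.0], "G2": [2.0, 2.0, 2.0]}
        out = differential_concentration(a, {k: list(v) for k, v in a.items()})
        assert (out["direction"] == "ns").all()

    def test_twofold_up_linear_but_not_log2(self):
        a, b = self._groups(2.0)
        lin = differential_concentration(a, b, mode="linear")
        log2 = differential_concentration(a, b, mode="log2")
        assert lin.loc[0, "direction"] == "up"
        assert log2.loc[0, "direction"] == "ns"  # log2 FC = 1 < 2

    def test_fivefold_up_in_both_modes(self):
        a, b = self._groups(5.0)
        assert differential_concentration(a, b, "linear").loc[0, "direction"] == "up"
        assert differential_concentration(a, b, "log2").loc[0, "direction"] == "up"

    def test_label_antisymmetry(self):
        rng = np.random.default_rng(10)
        a = {f"G{i}": rng.lognormal(1, 0.05, 4) for i in range(20)}
        b = {f"G{i}": a[f"G{i}"] * rng.choice([0.5, 1.0, 2.0]) for i in range(20)}
        fwd = differential_concentration(a, b).set_index("gene")
        rev = differential_concentration(b, a).set_index("gene")
        for g in fwd.index:
            assert fwd.loc[g, "fold_change"] == pytest.approx(1 / rev.loc[g, "fold_change"])
            pair = {fwd.loc[g, "direction"], rev.loc[g, "direction"]}
            assert pair in ({"ns"}, {"up", "down"})

    def test_genes_with_too_few_replicates_skipped(self):
        out = differential_concentration({"G": [1.0]}, {"G": [1.0, 1.0]})
        assert out.empty

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="intersection"):
            differential_concentration({"A": [1, 1]}, {"B": [1, 1]})
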