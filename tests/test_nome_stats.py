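"""Region summaries, condition comparison, footprints, profile export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import matrix_from_calls
from epilocus import build_matrix, nome_stats
from epilocus.profiles import ConditionProfile
from epilocus.simulate import simulate_clones


class TestRegionMean:
    def test_pooled_ratio_small_example(self, site_map_i):
        m = matrix_from_calls(site_map_i, [[1, 0], [0, 0]])
        assert nome_stats.region_mean(m, "endogenous").region_mean_percent == 25.0

    def test_all_methylated_is_100(self, site_map_i):
        m = matrix_from_calls(site_map_i, np.ones((3, 4)))
        assert nome_stats.region_mean(m, "endogenous").region_mean_percent == 100.0

    def test_partial_clones_pool_over_informative_calls(self, site_map_i):
        m = matrix_from_calls(site_map_i, [[1, np.nan], [0, 0]])
        assert nome_stats.region_mean(m, "endogenous").region_mean_percent == pytest.approx(100 / 3)

    def test_zero_informative_calls_raises(self, site_map_i):
        m = matrix_from_calls(site_map_i, [[np.nan, np.nan]])
        with pytest.raises(ValueError, match="zero informative"):
            nome_stats.region_mean(m, "endogenous")

    def test_monotone_in_generator_probability(self, region_i, site_map_i):
        """Raising every sitewise methylation probability raises the mean."""
        means = []
        for p in (0.1, 0.3, 0.6):
            prof = ConditionProfile("m", cpg_meth_prob=p)
            sim = simulate_clones(region_i, prof, treated=False, seed=31, n_clones=200)
            m = build_matrix(sim.records, site_map_i, treated=False)
            means.append(nome_stats.region_mean(m, "endogenous").region_mean_percent)
        assert means[0] < means[1] < means[2]

    def test_estimator_bias_below_half_point_at_2000_clones(self, region_i, site_map_i):
        """The raw pooled estimate converges to p + (1-p)(1-c_bis)."""
        p, c = 0.3, 0.99
        prof = ConditionProfile("bias", cpg_meth_prob=p, c_bis=c)
        sim = simulate_clones(region_i, prof, treated=False, seed=32, n_clones=2000)
        m = build_matrix(sim.records, site_map_i, treated=False)
        expected = 100 * (p + (1 - p) * (1 - c))
        got = nome_stats.region_mean(m, "endogenous").region_mean_percent
        assert got == pytest.approx(expected, abs=0.5)


class TestPerPositionFrequency:
    def test_half_methylated_site(self, site_map_i):
        m = matrix_from_calls(site_map_i, [[1], [1], [0], [0]])
        freq = nome_stats.per_position_frequency(m, "endogenous")
        assert freq["frequency"].iloc[0] == 0.5
        assert not freq["low_coverage"].iloc[0]

    def test_all_missing_site_flagged(self, site_map_i):
        m = matrix_from_calls(site_map_i, [[1, np.nan], [0, np.nan], [1, np.nan]])
        freq = nome_stats.per_position_frequency(m, "endogenous")
        assert freq["low_coverage"].iloc[1] and np.isnan(freq["frequency"].iloc[1])

    def test_frequencies_within_binomial_ci_of_truth(self, region_i, site_map_i):
        prof = ConditionProfile("freq", cpg_meth_prob=0.3, c_bis=1.0)
        sim = simulate_clones(region_i, prof, treated=False, seed=33, n_clones=500)
        m = build_matrix(sim.records, site_map_i, treated=False)
        freq = nome_stats.per_position_frequency(m, "endogenous")["frequency"]
        ci = 4 * np.sqrt(0.3 * 0.7 / 500)  # ~4 sigma, joint over ~50 sites
        assert (np.abs(freq - 0.3) < ci).all()


class TestCompareConditions:
    def test_type_one_error_controlled(self, site_map_i):
        """Under the null (identical groups) the per-position rejection rate
        stays at or below alpha + Monte-Carlo slack."""
        rng = np.random.default_rng(123)
        n_sites, reps = 4, 250  # 1000 site-level null tests
        rejections = total = 0
        for _ in range(reps):
            a = matrix_from_calls(site_map_i, rng.integers(0, 2, (15, n_sites)).astype(float))
            b = matrix_from_calls(site_map_i, rng.integers(0, 2, (15, n_sites)).astype(float))
            res = nome_stats.compare_conditions({"a": a, "b": b})
            rejections += int(res["significant"].sum())
            total += int(res["p_value"].notna().sum())
        assert rejections / total <= 0.07

    def test_power_on_large_shift(self, site_map_i):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = matrix_from_calls(site_map_i, (rng.random((15, 1)) < 0.9).astype(float))
            b = matrix_from_calls(site_map_i, (rng.random((15, 1)) < 0.1).astype(float))
            res = nome_stats.compare_conditions({"a": a, "b": b})
            hits += int(res["significant"].iloc[0])
        assert hits / 100 > 0.95

    def test_two_groups_match_mann_whitney(self, site_map_i):
        """With two groups the Kruskal-Wallis p equals the tie-corrected
        two-sided Mann-Whitney normal-approximation p."""
        rng = np.random.default_rng(5)
        a_vals = rng.integers(0, 2, (12, 1)).astype(float)
        b_vals = (rng.random((12, 1)) < 0.8).astype(float)
        res = nome_stats.compare_conditions(
            {"a": matrix_from_calls(site_map_i, a_vals),
             "b": matrix_from_calls(site_map_i, b_vals)}
        )
        _, p_mw = stats.mannwhitneyu(a_vals[:, 0], b_vals[:, 0], alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
        assert res["p_value"].iloc[0] == pytest.approx(p_mw, rel=1e-9)

    def test_identical_constant_groups_not_significant(self, site_map_i):
        a = matrix_from_calls(site_map_i, np.ones((5, 2)))
        b = matrix_from_calls(site_map_i, np.ones((5, 2)))
        res = nome_stats.compare_conditions({"a": a, "b": b})
        assert (res["p_value"] == 1.0).all() and not res["significant"].any()

    def test_requires_two_groups_of_three_clones(self, site_map_i):
        a = matrix_from_calls(site_map_i, np.ones((2, 2)))
        with pytest.raises(ValueError):
            nome_stats.compare_conditions({"a": a, "b": a})


class TestFootprints:
    def test_fully_accessible_clone_yields_no_footprints(self, site_map_i):
        m = matrix_from_calls(site_map_i, np.ones((5, 1)),
                              access=np.ones((5, len(site_map_i.gch))))
        assert nome_stats.call_footprints(m) == []

    def test_short_protected_run_not_called(self, site_map_i):
        """A protected run spanning under the minimum width is ignored."""
        offsets = np.asarray(list(site_map_i.offsets(site_map_i.gch)))
        access = np.ones((5, len(offsets)))
        short = (offsets >= -100) & (offsets < -20)  # ~80 bp
        access[:, short] = 0.0
        m = matrix_from_calls(site_map_i, np.ones((5, 1)), access=access)
        assert nome_stats.call_footprints(m, min_span_bp=140) == []

    def test_recovers_generator_footprint(self, region_i, site_map_i):
        """A 90%-occupied nucleosome footprint at (-200, +1) is recovered as a
        consensus interval with Jaccard >= 0.8 against the truth."""
        prof = ConditionProfile("fp", cpg_meth_prob=0.2, open_gpc_prob=0.9,
                                footprint_model=((-200, 1, 0.9),))
        sim = simulate_clones(region_i, prof, treated=True, seed=34, n_clones=500)
        m = build_matrix(sim.records, site_map_i, treated=True)
        calls = nome_stats.call_footprints(m)
        assert calls, "no footprint recovered"
        best = max(calls, key=lambda c: min(c.end, 1) - max(c.start, -200))
        inter = max(0, min(best.end, 1) - max(best.start, -200))
        union = max(best.end, 1) - min(best.start, -200)
        assert inter / union >= 0.8


class TestExportProfile:
    def test_round_trip_reproduces_frequencies(self, site_map_i, tmp_path):
        rng = np.random.default_rng(2)
        m = matrix_from_calls(site_map_i, rng.integers(0, 2, (15, 20)).astype(float))
        path = tmp_path / "profile.tsv"
        nome_stats.export_profile(m, "endogenous", path)
        clones, mean = nome_stats.read_profile(path)
        assert clones.shape == (15, 20)
        pd.testing.assert_series_equal(
            mean, m.endogenous.mean(axis=0), check_names=False, check_index_type=False
        )
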