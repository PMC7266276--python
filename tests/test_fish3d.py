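"""3D-FISH distances, pairing, classification, condition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from epilocus import FISH_PROFILES, fish3d
from epilocus.fish3d import THRESHOLDS, Thresholds
from epilocus.simulate import simulate_fish


def spot(nid, channel, x, y, z, homolog=0):
    return {"nucleus_id": nid, "channel": channel, "x_um": x, "y_um": y,
            "z_um": z, "homolog_id": homolog}


class TestDistance:
    def test_identical_spots_zero(self):
        s = spot("n", fish3d.RED, 1.0, 2.0, 3.0)
        assert fish3d.distance_3d(s, s) == 0.0

    def test_3_4_5_triangle(self):
        a = spot("n", fish3d.RED, 0, 0, 0)
        b = spot("n", fish3d.GREEN, 0.3, 0.4, 0)
        assert fish3d.distance_3d(a, b) == pytest.approx(500.0)

    def test_single_z_section_step(self):
        a = spot("n", fish3d.RED, 0, 0, 0)
        b = spot("n", fish3d.GREEN, 0, 0, 0.37)
        assert fish3d.distance_3d(a, b) == pytest.approx(370.0)


class TestClassify:
    @pytest.mark.parametrize(
        "d,cell_line,expected",
        [
            (250, "NB4-LR1", "adjacent"),
            (700, "NB4-LR1", "separated"),
            (300, "NB4-LR1", "intermediate"),   # boundary excluded: strict '<'
            (665, "NB4-LR1", "intermediate"),   # boundary excluded: strict '>'
            (335, "NB4-LR1-SFD", "adjacent"),
            (740, "NB4-LR1-SFD", "separated"),
        ],
    )
    def test_threshold_semantics(self, d, cell_line, expected):
        assert fish3d.classify_pair(d, THRESHOLDS[cell_line]) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds("x", 700, 300)


class TestPairSpots:
    def test_single_pair_is_cis(self):
        spots = pd.DataFrame([spot("n1", fish3d.RED, 0, 0, 0),
                              spot("n1", fish3d.GREEN, 0.1, 0, 0)])
        pairs = fish3d.pair_spots(spots)
        assert len(pairs) == 1 and pairs["cis"].all()

    def test_two_tight_clusters_match_by_cluster(self):
        """Mutual-NN assignment equals the minimum-total-distance matching,
        checked by enumerating both 2x2 matchings."""
        spots = pd.DataFrame([
            spot("n1", fish3d.RED, 0, 0, 0, 0), spot("n1", fish3d.GREEN, 0.2, 0, 0, 0),
            spot("n1", fish3d.RED, 5, 5, 0, 1), spot("n1", fish3d.GREEN, 5.1, 5, 0, 1),
        ])
        pairs = fish3d.pair_spots(spots)
        cis = pairs[pairs["cis"]]
        assert len(cis) == 2
        d = lambda i, j: fish3d.distance_3d(spots.loc[i], spots.loc[j])
        matchings = [d(0, 1) + d(2, 3), d(0, 3) + d(2, 1)]
        assert cis["distance_nm"].sum() == pytest.approx(min(matchings))
        trans = pairs[~pairs["cis"]]
        assert len(trans) == 2 and (trans["distance_nm"] > 5000).all()

    def test_extra_spots_exclude_nucleus(self):
        spots = pd.DataFrame(
            [spot("n1", fish3d.RED, x, 0, 0) for x in (0, 1, 2)]
            + [spot("n1", fish3d.GREEN, 0.5, 0, 0)]
        )
        assert len(fish3d.pair_spots(spots)) == 0

    def test_cis_recovery_against_generator_truth(self):
        """Mutual pairs fall on the same homolog in >= 95% of nuclei."""
        spots = simulate_fish(FISH_PROFILES["LR1_untreated_fish"], seed=13, n_nuclei=300)
        pairs = fish3d.pair_spots(spots)
        cis = pairs[pairs["cis"]]
        same = (spots.loc[cis["red_index"], "homolog_id"].to_numpy()
                == spots.loc[cis["green_index"], "homolog_id"].to_numpy())
        assert same.mean() >= 0.95
        trans = pairs[~pairs["cis"]]
        if len(trans):
            diff = (spots.loc[trans["red_index"], "homolog_id"].to_numpy()
                    != spots.loc[trans["green_index"], "homolog_id"].to_numpy())
            assert diff.mean() >= 0.95

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_isometry_invariance(self, seed):
        """Rigid rotation+translation of a nucleus leaves distances and
        classes unchanged."""
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-2, 2, (4, 3))
        spots = pd.DataFrame([
            spot("n1", fish3d.RED, *coords[0], 0), spot("n1", fish3d.GREEN, *coords[1], 0),
            spot("n1", fish3d.RED, *coords[2], 1), spot("n1", fish3d.GREEN, *coords[3], 1),
        ])
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        shifted = coords @ rot.T + rng.uniform(-5, 5, 3)
        spots2 = spots.copy()
        spots2[["x_um", "y_um", "z_um"]] = shifted
        thr = THRESHOLDS["NB4-LR1"]
        p1 = fish3d.pair_spots(spots, thr).sort_values(["red_index", "green_index"])
        p2 = fish3d.pair_spots(spots2, thr).sort_values(["red_index", "green_index"])
        np.testing.assert_allclose(p1["distance_nm"], p2["distance_nm"], rtol=1e-9, atol=1e-6)
        assert list(p1["cis"]) == list(p2["cis"])


class TestSummaries:
    def make_pairs(self, distances, cis=True):
        return pd.DataFrame({
            "nucleus_id": [f"n{i}" for i in range(len(distances))],
            "red_index": range(len(distances)),
            "green_index": range(len(distances)),
            "cis": cis,
            "distance_nm": distances,
        })

    def test_all_adjacent_partition(self):
        pairs = self.make_pairs([100.0] * 40)
        pct = fish3d.class_percentages(pairs, THRESHOLDS["NB4-LR1"])
        assert pct.tolist() == [100.0, 0.0, 0.0]

    def test_percentages_sum_to_100_exactly(self):
        rng = np.random.default_rng(3)
        pairs = self.make_pairs(rng.uniform(50, 1200, 137))
        pct = fish3d.class_percentages(pairs, THRESHOLDS["NB4-LR1"])
        assert pct.sum() == 100.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        pairs = self.make_pairs(rng.uniform(50, 1200, 200))
        pcts = [
            fish3d.class_percentages(pairs, Thresholds("x", amax, 1250))["adjacent"]
            for amax in (200, 400, 600)
        ]
        assert pcts[0] <= pcts[1] <= pcts[2]

    def test_zero_cis_pairs_raises(self):
        pairs = self.make_pairs([100.0] * 5, cis=False)
        with pytest.raises(ValueError, match="zero cis"):
            fish3d.summarize_condition({"a": pairs}, THRESHOLDS["NB4-LR1"])

    def test_mann_whitney_type_one_error(self):
        """Identical distance distributions: rejection rate stays near alpha."""
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = self.make_pairs(rng.uniform(100, 1000, 200))
            b = self.make_pairs(rng.uniform(100, 1000, 200))
            _, tests = fish3d.summarize_condition(
                {"a": a, "b": b}, THRESHOLDS["NB4-LR1"]
            )
            rejections += int(tests["significant"].iloc[0])
        assert rejections / reps <= 0.07

    def test_empty_nuclei_table_gives_empty_pairs(self):
        spots = simulate_fish(FISH_PROFILES["LR1_untreated_fish"], seed=1, n_nuclei=0)
        assert len(spots) == 0
        assert len(fish3d.pair_spots(spots)) == 0


class TestSimulateFish:
    def test_degenerate_mixture_all_adjacent(self):
        prof = FISH_PROFILES["LR1_untreated_fish"].with_(
            p_adjacent=1.0, p_intermediate=0.0, p_separated=0.0
        )
        spots = simulate_fish(prof, seed=17, n_nuclei=100)
        pairs = fish3d.pair_spots(spots)
        pct = fish3d.class_percentages(pairs, prof.thresholds)
        assert pct["adjacent"] == 100.0

    def test_class_proportions_recovered(self):
        prof = FISH_PROFILES["SFD_untreated_fish"]
        spots = simulate_fish(prof, seed=11, n_nuclei=200)
        pairs = fish3d.pair_spots(spots)
        pct = fish3d.class_percentages(pairs, prof.thresholds)
        assert pct["adjacent"] == pytest.approx(43, abs=5)
        assert pct["intermediate"] == pytest.approx(12, abs=5)

    def test_z_on_section_grid(self):
        spots = simulate_fish(FISH_PROFILES["LR1_untreated_fish"], seed=2, n_nuclei=20)
        steps = spots["z_um"] / 0.37
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_determinism(self):
        a = simulate_fish(FISH_PROFILES["LR1_ATRA_fish"], seed=5, n_nuclei=30)
        b = simulate_fish(FISH_PROFILES["LR1_ATRA_fish"], seed=5, n_nuclei=30)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_distance_params_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            FISH_PROFILES["LR1_untreated_fish"].with_(
                class_distance_params={"adjacent": (-5, 100), "intermediate": (310, 600),
                                       "separated": (700, 1400)}
            )
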