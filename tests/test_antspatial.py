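"""Arena statistics: occupancy, clustering, antennation and comparisons."""

import numpy as np
import pandas as pd
import pytest

from ethotrace import antspatial as asp
from ethotrace.containers import ArenaGeometry, TrajectoryTable
from ethotrace.errors import (
    AlignmentError,
    DesignError,
    ParameterError,
    StatisticsError,
)
from ethotrace.simulate import (
    ArenaSimParams,
    simulate_ant_arena,
    simulate_antennation_dyad,
)


def make_traj(positions: dict[str, list[tuple[float, float]]], dt=0.5):
    """Trajectory from per-ant position lists (one entry per frame)."""
    rows = []
    for ind, pts in positions.items():
        for k, (x, y) in enumerate(pts):
            rows.append({"frame": k, "id": ind, "time_s": k * dt,
                         "x_cm": x, "y_cm": y})
    return TrajectoryTable.from_dataframe(pd.DataFrame(rows))


class TestOccupancy:
    def test_ant_parked_in_zone_has_fraction_one(self, arena):
        tr = make_traj({"a": [(0.0, 0.0)] * 10})
        occ = asp.zone_occupancy(tr, arena)
        assert occ.trial_mean == 1.0

    def test_ant_never_in_zone_has_fraction_zero(self, arena):
        tr = make_traj({"a": [(6.0, 6.0)] * 10})
        assert asp.zone_occupancy(tr, arena).trial_mean == 0.0

    def test_boundary_counts_as_inside(self, arena):
        tr = make_traj({"a": [(4.0, 0.0)] * 3})
        assert asp.zone_occupancy(tr, arena).trial_mean == 1.0

    def test_uniform_positions_match_area_ratio(self, arena, rng):
        """10,000 uniform points in the 9 cm disc: occupancy ~ 16/81."""
        n = 10_000
        pts = np.empty((0, 2))
        while len(pts) < n:
            c = rng.uniform(-9, 9, size=(2 * n, 2))
            pts = np.vstack([pts, c[np.hypot(c[:, 0], c[:, 1]) <= 9.0]])
        pts = pts[:n]
        tr = make_traj({"a": [tuple(p) for p in pts]})
        occ = asp.zone_occupancy(tr, arena)
        p0 = 16 / 81
        sd = np.sqrt(p0 * (1 - p0) / n)
        assert abs(occ.trial_mean - p0) < 3 * sd

    def test_trial_mean_bounded_by_per_ant_range(self, arena, rng):
        tr = simulate_ant_arena(ArenaSimParams(n_ants=6, duration_s=60.0, seed=1))
        occ = asp.zone_occupancy(tr, arena)
        f = occ.per_ant["fraction"]
        assert f.min() - 1e-12 <= occ.trial_mean <= f.max() + 1e-12


class TestWindowedOccupancy:
    def test_full_window_equals_plain_occupancy(self, arena):
        tr = simulate_ant_arena(ArenaSimParams(n_ants=4, duration_s=60.0, seed=2))
        full = asp.zone_occupancy(tr, arena)
        win = asp.windowed_occupancy(tr, arena, (0.0, 1e9))
        assert win.trial_mean == pytest.approx(full.trial_mean)

    def test_partition_in_then_out(self, arena):
        # in zone for t < 240 s, then far outside
        pts = [(0.0, 0.0)] * 480 + [(7.0, 0.0)] * 480
        tr = make_traj({"a": pts})
        assert asp.windowed_occupancy(tr, arena, (0.0, 240.0)).trial_mean == 1.0
        assert asp.windowed_occupancy(tr, arena, (240.0, 480.0)).trial_mean == 0.0

    def test_empty_window_is_statistics_error(self, arena):
        tr = make_traj({"a": [(0.0, 0.0)] * 4})
        with pytest.raises(StatisticsError):
            asp.windowed_occupancy(tr, arena, (100.0, 200.0))

    def test_decaying_avoidance_larger_early_difference(self, arena):
        """Avoidance that decays after 240 s shows up in the early window."""
        def sim(lam_early):
            a = simulate_ant_arena(ArenaSimParams(
                n_ants=8, duration_s=240.0, lambda_repel=lam_early, seed=5))
            b = simulate_ant_arena(ArenaSimParams(
                n_ants=8, duration_s=240.0, lambda_repel=0.0, seed=6))
            b.data["time_s"] += 240.0
            b.data["frame"] += a.n_frames
            merged = pd.concat([a.data, b.data], ignore_index=True)
            return TrajectoryTable(data=merged, dt=a.dt)

        treated, control = sim(0.5), sim(0.0)
        d_early = (asp.windowed_occupancy(control, arena, (0, 240)).trial_mean
                   - asp.windowed_occupancy(treated, arena, (0, 240)).trial_mean)
        d_late = (asp.windowed_occupancy(control, arena, (240, 480)).trial_mean
                  - asp.windowed_occupancy(treated, arena, (240, 480)).trial_mean)
        assert d_early > d_late


class TestMeanNN:
    def test_hand_case_three_colinear_ants(self):
        tr = make_traj({"a": [(0.0, 0.0)], "b": [(3.0, 0.0)], "c": [(7.0, 0.0)]})
        cs = asp.mean_nn_series(tr)
        assert cs.data["mean_nn_cm"].iloc[0] == pytest.approx(10 / 3)

    def test_two_ants_mean_is_their_distance(self):
        tr = make_traj({"a": [(0.0, 0.0)] * 3, "b": [(0.0, 2.5)] * 3})
        np.testing.assert_allclose(asp.mean_nn_series(tr).data["mean_nn_cm"], 2.5)

    def test_coincident_ants_give_zero(self):
        tr = make_traj({"a": [(1.0, 1.0)], "b": [(1.0, 1.0)]})
        assert asp.mean_nn_series(tr).data["mean_nn_cm"].iloc[0] == 0.0

    def test_single_ant_frames_are_missing_not_zero(self):
        rows = [
            {"frame": 0, "id": "a", "time_s": 0.0, "x_cm": 0.0, "y_cm": 0.0},
            {"frame": 0, "id": "b", "time_s": 0.0, "x_cm": 1.0, "y_cm": 0.0},
            {"frame": 1, "id": "a", "time_s": 0.5, "x_cm": 0.0, "y_cm": 0.0},
        ]
        tr = TrajectoryTable.from_dataframe(pd.DataFrame(rows), allow_gaps=True)
        cs = asp.mean_nn_series(tr)
        assert cs.data["mean_nn_cm"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(cs.data["mean_nn_cm"].iloc[1])

    def test_never_two_ants_is_statistics_error(self):
        tr = make_traj({"a": [(0.0, 0.0)] * 5})
        with pytest.raises(StatisticsError):
            asp.mean_nn_series(tr)

    def test_matches_brute_force_enumeration(self, rng):
        """Frame means equal O(n^2) enumeration exactly, n <= 10."""
        for _ in range(50):
            n = int(rng.integers(2, 11))
            xy = rng.uniform(-5, 5, size=(n, 2))
            tr = make_traj({f"a{i}": [tuple(xy[i])] for i in range(n)})
            got = asp.mean_nn_series(tr).data["mean_nn_cm"].iloc[0]
            nn = [min(np.sqrt((xy[i, 0] - xy[j, 0]) ** 2
                              + (xy[i, 1] - xy[j, 1]) ** 2)
                      for j in range(n) if j != i)
                  for i in range(n)]
            assert got == np.mean(nn)


class TestRolling:
    def test_constant_series_preserved_exactly(self):
        cs = asp.ClusterSeries(
            data=pd.DataFrame({"time_s": np.arange(9) * 0.5,
                               "mean_nn_cm": np.full(9, 3.25), "n_ants": 4}),
            dt=0.5)
        out = asp.rolling_average(cs, 5)
        np.testing.assert_array_equal(out.data["mean_nn_cm"], 3.25)

    def test_center_value_arithmetic(self):
        cs = asp.ClusterSeries(
            data=pd.DataFrame({"time_s": np.arange(5) * 0.5,
                               "mean_nn_cm": [0.0, 0.0, 5.0, 0.0, 0.0],
                               "n_ants": 2}),
            dt=0.5)
        assert asp.rolling_average(cs, 5).data["mean_nn_cm"].iloc[2] == 1.0

    def test_interior_matches_convolution_oracle(self, rng):
        y = rng.normal(size=40)
        cs = asp.ClusterSeries(
            data=pd.DataFrame({"time_s": np.arange(40) * 0.5,
                               "mean_nn_cm": y, "n_ants": 2}), dt=0.5)
        out = asp.rolling_average(cs, 5).data["mean_nn_cm"].to_numpy()
        oracle = np.convolve(y, np.ones(5) / 5, mode="valid")
        np.testing.assert_allclose(out[2:-2], oracle, atol=1e-12)

    def test_strict_edges_are_nan(self, rng):
        y = rng.normal(size=10)
        cs = asp.ClusterSeries(
            data=pd.DataFrame({"time_s": np.arange(10.0),
                               "mean_nn_cm": y, "n_ants": 2}), dt=1.0)
        out = asp.rolling_average(cs, 5, edge_policy="strict").data["mean_nn_cm"]
        assert out.iloc[:2].isna().all() and out.iloc[-2:].isna().all()
        assert out.notna().sum() == 6

    def test_missing_values_skipped(self):
        y = [1.0, np.nan, 3.0, np.nan, 5.0]
        cs = asp.ClusterSeries(
            data=pd.DataFrame({"time_s": np.arange(5.0),
                               "mean_nn_cm": y, "n_ants": 2}), dt=1.0)
        out = asp.rolling_average(cs, 3).data["mean_nn_cm"]
        assert out.iloc[1] == pytest.approx(2.0)   # mean of 1 and 3

    def test_even_k_rejected(self):
        cs = asp.ClusterSeries(
            data=pd.DataFrame({"time_s": [0.0], "mean_nn_cm": [1.0],
                               "n_ants": 2}), dt=1.0)
        with pytest.raises(ParameterError):
            asp.rolling_average(cs, 4)


class TestDifferenceSeries:
    def _pair(self, rng):
        def cs(y):
            return asp.ClusterSeries(
                data=pd.DataFrame({"time_s": np.arange(len(y)) * 0.5,
                                   "mean_nn_cm": y, "n_ants": 4}), dt=0.5)
        return cs(rng.normal(3, 0.5, 30)), cs(rng.normal(3, 0.5, 30))

    def test_identical_series_give_zero(self, rng):
        a, _ = self._pair(rng)
        d = asp.difference_series(a, a, k=5)
        np.testing.assert_allclose(d.data["mean_nn_cm"], 0.0, atol=1e-14)

    def test_antisymmetry_under_group_swap(self, rng):
        a, b = self._pair(rng)
        d1 = asp.difference_series(a, b, k=5).data["mean_nn_cm"].to_numpy()
        d2 = asp.difference_series(b, a, k=5).data["mean_nn_cm"].to_numpy()
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_no_overlap_is_alignment_error(self, rng):
        a, b = self._pair(rng)
        b.data["time_s"] += 1000.0
        with pytest.raises(AlignmentError):
            asp.difference_series(a, b)

    def test_simulated_social_ordering(self):
        """Less social attraction in treated -> positive mean difference."""
        def series(g, seed):
            tr = simulate_ant_arena(ArenaSimParams(n_ants=8, duration_s=120.0,
                                                   g_social=g, seed=seed))
            return asp.mean_nn_series(tr)

        d = asp.difference_series(series(0.0, 3), series(0.3, 3), k=5)
        assert np.nanmean(d.data["mean_nn_cm"]) > 0


class TestAntennation:
    def test_never_in_contact_zero_events(self):
        tr = make_traj({"a": [(0.0, 0.0)] * 20, "b": [(1.0, 0.0)] * 20})
        ev = asp.detect_antennation(tr, contact_distance_cm=0.5,
                                    min_duration_s=1.0, gap_s=0.5)
        assert ev.count == 0

    def test_single_long_dip_is_one_event(self):
        xs = [1.0] * 5 + [0.2] * 6 + [1.0] * 5
        tr = make_traj({"a": [(0.0, 0.0)] * 16, "b": [(x, 0.0) for x in xs]})
        ev = asp.detect_antennation(tr, 0.5, 1.0, 0.5)
        assert ev.count == 1
        assert ev.events["duration_s"].iloc[0] == pytest.approx(3.0)
        assert ev.events["min_distance_cm"].iloc[0] == pytest.approx(0.2)

    def test_short_dip_below_min_duration_ignored(self):
        xs = [1.0] * 5 + [0.2] + [1.0] * 5
        tr = make_traj({"a": [(0.0, 0.0)] * 11, "b": [(x, 0.0) for x in xs]})
        assert asp.detect_antennation(tr, 0.5, 1.0, 0.5).count == 0

    def test_nearby_runs_merged_by_refractory_gap(self):
        # two 1.5 s runs separated by one 0.5 s off-contact frame (< 1 s gap)
        xs = [0.2] * 3 + [1.0] + [0.2] * 3
        tr = make_traj({"a": [(0.0, 0.0)] * 7, "b": [(x, 0.0) for x in xs]})
        assert asp.detect_antennation(tr, 0.5, 1.0, gap_s=1.0).count == 1
        assert asp.detect_antennation(tr, 0.5, 1.0, gap_s=0.5).count == 2

    def test_programmed_bouts_counted_exactly(self):
        tr = simulate_antennation_dyad(7, bout_duration_s=2.0, gap_s=8.0)
        ev = asp.detect_antennation(tr, 0.5, 1.0, 0.5)
        assert ev.count == 7

    def test_count_invariant_under_time_reversal(self):
        tr = simulate_antennation_dyad(5, bout_duration_s=1.5, gap_s=6.0, seed=3)
        fwd = asp.detect_antennation(tr, 0.5, 1.0, 0.5).count
        rev = tr.data.copy()
        tmax = rev["time_s"].max()
        rev["time_s"] = tmax - rev["time_s"]
        rev["frame"] = rev["frame"].max() - rev["frame"]
        rev_tr = TrajectoryTable.from_dataframe(rev)
        assert asp.detect_antennation(rev_tr, 0.5, 1.0, 0.5).count == fwd

    def test_nonpositive_thresholds_rejected(self):
        tr = simulate_antennation_dyad(1)
        with pytest.raises(ParameterError):
            asp.detect_antennation(tr, -1.0, 1.0, 0.5)


def null_trials(n_trials=10, seed=0, g=0.05, duration=30.0):
    rng = np.random.default_rng(seed)
    series, groups = {}, {}
    for i in range(n_trials):
        tr = simulate_ant_arena(ArenaSimParams(
            n_ants=4, duration_s=duration, g_social=g,
            seed=int(rng.integers(2**31))))
        series[f"t{i}"] = asp.mean_nn_series(tr)
        groups[f"t{i}"] = "T" if i < n_trials // 2 else "C"
    return series, groups


class TestGroupComparisons:
    def test_paired_degenerate_differences_flagged(self):
        res = asp.compare_groups("paired_t", x=[2.0, 3.0, 4.0, 5.0, 6.0],
                                 y=[1.0, 2.0, 3.0, 4.0, 5.0], sided="greater")
        assert res.p_value == 0.0
        assert any("zero-variance" in n for n in res.notes)

    def test_independent_closed_form(self):
        res = asp.compare_groups("independent_t", x=[1.0, 2.0, 3.0],
                                 y=[2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.p_value == pytest.approx(0.2879, abs=1e-3)

    def test_lmm_detects_strong_group_by_time_effect(self):
        """Trials whose separation grows only in the treated group."""
        rng = np.random.default_rng(4)
        series, groups = {}, {}
        for i in range(8):
            t = np.arange(80) * 0.5
            slope = 0.05 if i < 4 else 0.0
            y = 2.0 + slope * t + rng.normal(0, 0.1, 80)
            series[f"t{i}"] = asp.ClusterSeries(
                data=pd.DataFrame({"time_s": t, "mean_nn_cm": y, "n_ants": 4}),
                dt=0.5)
            groups[f"t{i}"] = "T" if i < 4 else "C"
        res = asp.fit_clustering_lmm(series, groups, "T")
        assert res.p_value < 1e-6
        assert res.estimates["interaction"] > 0

    def test_permutation_detects_effect_and_is_exact_on_null(self):
        series, groups = null_trials(seed=1)
        res = asp.permutation_slope_test(series, groups, "T")
        assert 0.0 <= res.p_value <= 1.0
        # strong effect: treated trials get a dominant slope; the exact
        # two-sided p then bottoms out at 2/252 < 0.01
        for name, cs in series.items():
            if groups[name] == "T":
                cs.data["mean_nn_cm"] += 0.5 * cs.data["time_s"]
        res2 = asp.permutation_slope_test(series, groups, "T")
        assert res2.p_value < 0.01

    def test_one_sided_trial_labels_rejected(self):
        series, groups = null_trials(n_trials=4, seed=2)
        groups = {k: "T" for k in groups}
        with pytest.raises(DesignError):
            asp.permutation_slope_test(series, groups, "T")
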