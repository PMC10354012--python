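"""Exclusion filtering, occupancy histograms, site assignment and first passage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chisquare

from treskit import permeation as pa
from treskit.simulate import simulate_sf_permeation, wt_config


def _series(distances, ion_id="K4", rep=0, dt=1.0, species="K"):
    d = np.asarray(distances, dtype=float)
    return pa.IonDistanceSeries(
        replicate_id=rep,
        ion_id=ion_id,
        species=species,
        times=np.arange(1, d.size + 1) * dt,
        distances=d,
    )


class TestReader:
    @pytest.fixture
    def table(self, tmp_path):
        run = simulate_sf_permeation(wt_config(duration_ns=3.0, n_replicates=3, seed=0))
        path = tmp_path / "traj.csv"
        run.write_csv(path)
        return path

    def test_three_replicates_give_twelve_series(self, table):
        series = pa.read_ion_distance_table(table)
        assert len(series) == 12
        assert {s.ion_id for s in series} == {"K1", "K2", "K3", "K4"}

    def test_row_order_is_irrelevant(self, table, tmp_path, rng):
        header, *body = table.read_text().splitlines()
        rng.shuffle(body)
        shuffled = tmp_path / "shuffled.csv"
        shuffled.write_text("\n".join([header, *body]) + "\n")
        a = pa.read_ion_distance_table(table)
        b = pa.read_ion_distance_table(shuffled)
        for sa, sb in zip(a, b):
            assert sa.ion_id == sb.ion_id
            np.testing.assert_array_equal(sa.distances, sb.distances)

    def test_duplicate_row_rejected_with_line_number(self, table, tmp_path):
        df = pd.read_csv(table)
        dup = pd.concat([df, df.iloc[[5]]], ignore_index=True)
        path = tmp_path / "dup.csv"
        dup.to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"duplicate .* lines \[7"):
            pa.read_ion_distance_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"replicate": [0], "time_ns": [0.1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            pa.read_ion_distance_table(path)

    def test_non_uniform_sampling_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "replicate": 0,
                "time_ns": [0.1, 0.2, 0.5],
                "ion_id": "K1",
                "species": "K",
                "distance_A": [1.5, 1.5, 1.5],
            }
        )
        path = tmp_path / "jagged.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-uniform sampling"):
            pa.read_ion_distance_table(path)


class TestExclusion:
    def test_outer_ion_leave_rule(self):
        series = [_series([4.0, 6.0, 3.0], ion_id="K1")]
        retained, report = pa.apply_sf_exclusion(series, threshold=5.0)
        np.testing.assert_array_equal(retained["distance_A"], [4.0, 3.0])
        assert report.n_excluded == 1

    def test_all_within_threshold_is_identity(self):
        series = [_series([1.0, 2.0, 3.0], ion_id="K1"), _series([10.0, 11.0], ion_id="K4")]
        retained, report = pa.apply_sf_exclusion(series)
        assert report.n_excluded == 0
        assert len(retained) == 5

    def test_inner_ion_judged_against_s4_reference(self):
        # distance-to-S4 is |d - 10.5|; 17 A is a cavity-bulk departure
        series = [_series([10.5, 17.0, 9.0], ion_id="K4")]
        retained, report = pa.apply_sf_exclusion(series)
        np.testing.assert_array_equal(retained["distance_A"], [10.5, 9.0])
        assert report.n_excluded == 1

    def test_intermediate_ions_never_excluded(self):
        series = [
            _series([4.5, 30.0], ion_id="K2"),
            _series([10.5, 10.5], ion_id="K4"),
        ]
        _, report = pa.apply_sf_exclusion(series)
        assert report.n_excluded == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            pa.apply_sf_exclusion([_series([1.0], ion_id="K1")], threshold=0.0)

    def test_counts_conserved(self):
        run = simulate_sf_permeation(wt_config(duration_ns=10.0, n_replicates=2, seed=5))
        retained, report = pa.apply_sf_exclusion(run.series)
        assert report.n_retained + report.n_excluded == sum(len(s) for s in run.series)
        assert len(retained) == report.n_retained


class TestOccupancyHistogram:
    def test_point_mass_lands_in_hand_computed_bin(self):
        hist = pa.compute_occupancy_histogram(np.full(1500, 4.50))
        # bin width 0.32 A; floor(4.50 / 0.32) = 14, i.e. [4.48, 4.80)
        assert hist.counts[14] == 1500
        assert hist.relative[14] == 1.0
        assert hist.bin_edges[14] == pytest.approx(4.48)

    def test_right_edge_is_closed(self):
        hist = pa.compute_occupancy_histogram(np.array([16.0]))
        assert hist.counts[-1] == 1
        assert hist.overflow == 0

    def test_out_of_range_goes_to_overflow(self):
        hist = pa.compute_occupancy_histogram(np.array([4.0, 16.5, 18.0]))
        assert hist.overflow == 2
        assert hist.n_binned == 1

    def test_uniform_records_fill_bins_uniformly(self, rng):
        d = rng.uniform(0.0, 16.0, size=100_000)
        hist = pa.compute_occupancy_histogram(d)
        assert chisquare(hist.counts).pvalue > 0.01
        assert hist.relative.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pa.compute_occupancy_histogram(np.array([]))

    def test_record_conservation_through_pipeline(self):
        run = simulate_sf_permeation(wt_config(duration_ns=20.0, n_replicates=1, seed=2))
        retained, report = pa.apply_sf_exclusion(run.series)
        hist = pa.compute_occupancy_histogram(retained)
        assert hist.n_binned + hist.overflow == report.n_retained


class TestDeltaHistogram:
    def test_self_comparison_is_zero(self, rng):
        hist = pa.compute_occupancy_histogram(rng.uniform(0, 16, 500))
        delta = pa.compare_occupancy(hist, hist)
        np.testing.assert_array_equal(delta.delta, np.zeros(50))

    def test_moved_mass_shows_as_signed_pair(self):
        a = pa.compute_occupancy_histogram(np.repeat([3.36, 6.56], [100, 900]))
        b = pa.compute_occupancy_histogram(np.repeat([3.36, 6.56], [200, 800]))
        delta = pa.compare_occupancy(a, b)
        assert delta.delta[10] == pytest.approx(0.1)
        assert delta.delta[20] == pytest.approx(-0.1)
        assert np.count_nonzero(np.abs(delta.delta) > 1e-15) == 2

    def test_mismatched_edges_rejected(self, rng):
        a = pa.compute_occupancy_histogram(rng.uniform(0, 16, 100))
        b = pa.compute_occupancy_histogram(rng.uniform(0, 16, 100), value_range=(0, 8))
        with pytest.raises(ValueError, match="mismatched"):
            pa.compare_occupancy(a, b)

    @given(st.integers(0, 10_000))
    def test_antisymmetry_and_zero_sum(self, seed):
        rng = np.random.default_rng(seed)
        a = pa.compute_occupancy_histogram(rng.uniform(0, 16, 200))
        b = pa.compute_occupancy_histogram(rng.uniform(0, 16, 300))
        ab = pa.compare_occupancy(a, b).delta
        ba = pa.compare_occupancy(b, a).delta
        np.testing.assert_allclose(ab, -ba, atol=1e-15)
        assert abs(ab.sum()) < 1e-12


class TestSiteAssignment:
    def test_canonical_distance_maps_to_its_site(self):
        assert pa.assign_sites(4.5) == "S2"

    def test_flicker_around_midpoint_is_suppressed(self):
        mid = 3.0  # between S1 (1.5) and S2 (4.5)
        h = 0.5
        wobble = np.array([1.5] + [mid + (h / 2) * (-1) ** k for k in range(20)])
        sites = pa.assign_sites(wobble, hysteresis=h)
        assert set(sites[1:]) == {"S1"}

    def test_monotone_sweep_visits_ladder_in_order(self):
        sweep = np.linspace(14.0, 0.0, 300)
        sites = pa.assign_sites(sweep)
        seen = list(dict.fromkeys(sites))
        assert seen == ["cavity", "S4", "S3", "S2", "S1"]

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pa.assign_sites(np.array([1.0]), {"A": 0.0, "B": 0.3}, hysteresis=0.5)


def _staircase(levels, n_per=10, dt=1.0):
    return _series(np.repeat(levels, n_per), dt=dt)


class TestTransitions:
    def test_staircase_times(self):
        s = _staircase([10.5, 7.5, 4.5, 1.5, 16.5])
        table = pa.detect_transitions(s)
        assert table.times_ns == (11.0, 21.0, 31.0, 41.0)
        assert table.censored == (False, False, False, False)

    def test_run_ending_mid_filter_censors_remaining(self):
        s = _staircase([10.5, 7.5, 4.5])
        table = pa.detect_transitions(s)
        assert table.times_ns[:2] == (11.0, 21.0)
        assert table.censored == (False, False, True, True)

    def test_back_step_keeps_first_passage(self):
        s = _staircase([10.5, 7.5, 10.5, 7.5, 4.5])
        table = pa.detect_transitions(s)
        assert table.times_ns[0] == 11.0  # first S3 arrival
        assert table.times_ns[1] == 41.0

    def test_inward_departure_is_not_an_exit(self):
        # ion tumbles back into the intracellular bulk (sentinel 18 A)
        s = _staircase([10.5, 14.0, 18.0])
        table = pa.detect_transitions(s)
        assert table.censored == (True, True, True, True)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pa.detect_transitions(_series([10.5]))

    @given(st.integers(0, 500))
    def test_matches_bruteforce_first_passage_scan(self, seed):
        rng = np.random.default_rng(seed)
        # random walk over the ladder with occasional pool excursions
        levels = [1.5, 4.5, 7.5, 10.5, 14.0, 16.5, 18.0]
        idx = 3
        path = []
        for _ in range(rng.integers(5, 400)):
            idx = int(np.clip(idx + rng.integers(-2, 3), 0, len(levels) - 1))
            path.append(levels[idx] + rng.normal(0, 0.3))
        d = np.clip(np.array(path), 0.0, None)
        s = _series(d)
        got = pa.detect_transitions(s)
        assert got.times_ns == _bruteforce_transitions(s)


def _bruteforce_transitions(series, hysteresis=0.5):
    """Independent per-frame scan of the first-passage definition."""
    full = dict(pa.DEFAULT_SITE_MAP)
    full["out"] = 16.5
    sites = pa.assign_sites(series.distances, full, hysteresis)
    rank = {"cavity": 0, "S4": 1, "S3": 2, "S2": 3, "S1": 4, "out": 5}
    stations = ["S3", "S2", "S1"]
    times = [None, None, None, None]
    prev = None
    for t, lab in zip(series.times, sites):
        if lab == "out":
            if prev in ("S1", "S2", "S3"):
                for k in range(4):
                    if times[k] is None:
                        times[k] = float(t)
        else:
            for k, st_ in enumerate(stations):
                if times[k] is None and (k == 0 or times[k - 1] is not None):
                    if rank[lab] >= rank[st_]:
                        times[k] = float(t)
            prev = lab
        if times[3] is not None:
            break
    return tuple(times)


class TestSummary:
    def test_mean_and_sem_hand_arithmetic(self):
        tables = [
            pa.TransitionTable(r, "K4", (t, t, t, t), (False,) * 4)
            for r, t in enumerate([30.0, 30.0, 40.0])
        ]
        summary = pa.summarize_permeation(tables).table
        assert summary.loc[3, "mean_ns"] == pytest.approx(33.3333, abs=1e-3)
        assert summary.loc[3, "sem_ns"] == pytest.approx(3.3333, abs=1e-3)

    def test_single_replicate_has_undefined_sem(self):
        tables = [pa.TransitionTable(0, "K4", (25.0, 25.0, 25.0, 25.0), (False,) * 4)]
        summary = pa.summarize_permeation(tables).table
        assert summary.loc[0, "mean_ns"] == 25.0
        assert np.isnan(summary.loc[0, "sem_ns"])

    def test_censored_replicates_counted_not_imputed(self):
        tables = [
            pa.TransitionTable(0, "K4", (10.0, None, None, None), (False, True, True, True)),
            pa.TransitionTable(1, "K4", (20.0, None, None, None), (False, True, True, True)),
            pa.TransitionTable(2, "K4", (None, None, None, None), (True,) * 4),
        ]
        summary = pa.summarize_permeation(tables).table
        assert summary.loc[0, "n_achieved"] == 2
        assert summary.loc[0, "n_censored"] == 1
        assert summary.loc[0, "mean_ns"] == 15.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pa.summarize_permeation([])
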