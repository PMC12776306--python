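"""Binding-event detection, gap merging and residence statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidsite.core import AtomGroup, min_image_distance
from lipidsite.events import (
    BindingEvent,
    DistanceSeries,
    EventConfig,
    compute_distance_series,
    detect_events,
    events_from_mask,
    events_to_frame,
    export_events,
    merge_runs,
    residence_stats,
    stats_to_frame,
)

from conftest import make_trajectory, point_topology, rle_merge_oracle


def series_from_mask(mask, cutoff=5.0, dt=1.0):
    d = np.where(np.asarray(mask, bool), cutoff - 1.0, cutoff + 1.0)
    return DistanceSeries("DHA1", ("A", 63), d, dt)


class TestDistanceSeries:
    def test_minimum_over_pairs(self):
        top = point_topology(3)
        coords = [[[0, 0, 0], [3, 0, 0], [6, 0, 0]]] * 10
        traj = make_trajectory(top, coords)
        lip = {"L": AtomGroup(top, np.array([0]), "L")}
        res = {("A", 63): AtomGroup(top, np.array([1, 2]), "R63")}
        series = compute_distance_series(traj, lip, res)
        assert len(series) == 1
        np.testing.assert_allclose(series[0].distances_A, 3.0)  # min(3, 6), constant

    def test_brute_force_oracle_random_fixture(self):
        rng = np.random.default_rng(5)
        n_lip, n_res, n_frames = 3, 4, 50
        top = point_topology(n_lip + n_res)
        box = (15.0, 15.0, 15.0)
        coords = rng.uniform(0, 15, size=(n_frames, n_lip + n_res, 3))
        traj = make_trajectory(top, coords, box=box)
        lip = {"L": AtomGroup(top, np.arange(n_lip), "L")}
        res = {("A", 63): AtomGroup(top, np.arange(n_lip, n_lip + n_res), "R")}
        series = compute_distance_series(traj, lip, res)[0]
        for fi in range(n_frames):
            expect = min(
                min_image_distance(coords[fi, i], coords[fi, j], box)
                for i in range(n_lip)
                for j in range(n_lip, n_lip + n_res)
            )
            assert series.distances_A[fi] == pytest.approx(expect, abs=1e-10)

    def test_empty_residue_group_skipped(self):
        top = point_topology(2)
        traj = make_trajectory(top, [[[0, 0, 0], [1, 0, 0]]])
        lip = {"L": AtomGroup(top, np.array([0]))}
        res = {("A", 64): AtomGroup(top, np.array([], dtype=int))}
        with pytest.warns(UserWarning, match="empty"):
            out = compute_distance_series(traj, lip, res)
        assert out == []


class TestDetectEvents:
    def test_short_gap_merges(self):
        events = detect_events(series_from_mask([1, 1, 0, 1, 1]),
                               EventConfig(merge_gap_frames=10))
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (0, 4)
        assert events[0].duration_ns == 5.0  # gap frames join the span

    def test_gap_of_exactly_merge_gap_splits(self):
        mask = [1] * 3 + [0] * 10 + [1] * 3
        events = detect_events(series_from_mask(mask), EventConfig(merge_gap_frames=10))
        assert len(events) == 2  # "fewer than 10" excludes exactly 10

    def test_gap_of_nine_merges(self):
        mask = [1] * 3 + [0] * 9 + [1] * 3
        events = detect_events(series_from_mask(mask), EventConfig(merge_gap_frames=10))
        assert len(events) == 1

    def test_all_unbound(self):
        assert detect_events(series_from_mask([0] * 20), EventConfig()) == []

    def test_boundary_inclusive_cutoff(self):
        d = np.array([5.0, 5.000001, 4.999999])
        s = DistanceSeries("L", ("A", 63), d, 1.0)
        events = detect_events(s, EventConfig(cutoff_A=5.0, merge_gap_frames=0))
        covered = {f for e in events for f in range(e.start_frame, e.end_frame + 1)}
        assert covered == {0, 2}

    def test_censoring_flags(self):
        events = detect_events(series_from_mask([1, 1, 0] * 5 + [1]),
                               EventConfig(merge_gap_frames=0))
        assert events[0].censored_start and not events[0].censored_end
        assert events[-1].censored_end

    def test_min_event_frames_filter(self):
        mask = [1, 0] * 10 + [1, 1, 1]
        events = detect_events(series_from_mask(mask),
                               EventConfig(merge_gap_frames=0, min_event_frames=2))
        assert len(events) == 1 and events[-1].n_frames == 3

    def test_large_random_mask_matches_oracle(self):
        rng = np.random.default_rng(17)
        mask = rng.random(10_000) < 0.4
        for gap in (0, 1, 5, 10):
            got = [
                (e.start_frame, e.end_frame)
                for e in events_from_mask(mask, EventConfig(merge_gap_frames=gap))
            ]
            assert got == rle_merge_oracle(mask, gap)


class TestEventProperties:
    @given(st.integers(0, 2**31 - 1), st.integers(0, 15))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_random(self, seed, gap):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        mask = rng.random(n) < rng.random()
        got = [
            (e.start_frame, e.end_frame)
            for e in events_from_mask(mask, EventConfig(merge_gap_frames=gap))
        ]
        assert got == rle_merge_oracle(mask, gap)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bound_frames_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 10, 200)
        s = DistanceSeries("L", ("A", 63), d, 1.0)
        prev: set = set()
        for cutoff in (2.0, 4.0, 6.0, 8.0):
            events = detect_events(s, EventConfig(cutoff_A=cutoff, merge_gap_frames=0))
            bound = {f for e in events for f in range(e.start_frame, e.end_frame + 1)}
            assert bound >= prev
            prev = bound

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_merge_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random(300) < 0.3
        if not mask.any():
            return
        prev_n = np.inf
        prev_covered = -1
        for gap in range(0, 12):
            events = events_from_mask(mask, EventConfig(merge_gap_frames=gap))
            n = len(events)
            covered = sum(e.n_frames for e in events)
            assert n <= prev_n
            assert covered >= prev_covered
            prev_n, prev_covered = n, covered

    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    @settings(max_examples=100, deadline=None)
    def test_merge_idempotent(self, seed, gap):
        rng = np.random.default_rng(seed)
        mask = rng.random(200) < 0.4
        events = events_from_mask(mask, EventConfig(merge_gap_frames=gap))
        runs = [(e.start_frame, e.end_frame) for e in events]
        assert merge_runs(runs, gap) == runs


class TestResidenceStats:
    @staticmethod
    def _events(durations, residue=("A", 63), dt=1.0):
        out, start = [], 10
        for d in durations:
            frames = int(d / dt)
            out.append(
                BindingEvent("DHA1", residue, start, start + frames - 1, d)
            )
            start += frames + 50
        return out

    def test_basic_aggregation(self):
        stats = residence_stats(self._events([10.0, 20.0, 30.0]), state_label="open")
        assert len(stats) == 1
        s = stats[0]
        assert (s.n_events, s.mean_duration_ns, s.longest_duration_ns) == (3, 20.0, 30.0)

    def test_no_events_prints_absent(self):
        stats = residence_stats([], state_label="resting", residue_keys=[("A", 63)])
        df = stats_to_frame(stats)
        assert list(df.columns) == [
            "residue", "state", "total_events", "mean_duration_ns", "longest_event_ns",
        ]
        assert df.iloc[0].tolist() == ["63", "resting", "--", "--", "--"]

    def test_pools_lipids_and_chains(self):
        events = (
            self._events([10.0], residue=("A", 63))
            + self._events([30.0], residue=("B", 63))
        )
        stats = residence_stats(events, pool_chains=True)
        assert len(stats) == 1 and stats[0].n_events == 2
        per_chain = residence_stats(events, pool_chains=False)
        assert len(per_chain) == 2

    def test_geometric_dwell_mean(self):
        rng = np.random.default_rng(99)
        durations = rng.geometric(0.01, size=500).astype(float)  # dt = 1 ns
        stats = residence_stats(self._events(list(durations)))
        assert stats[0].mean_duration_ns == pytest.approx(100.0, rel=0.10)

    def test_censored_exclusion_flag(self):
        events = self._events([10.0, 20.0])
        events.append(BindingEvent("DHA2", ("A", 63), 0, 4, 5.0, censored_start=True))
        incl = residence_stats(events, include_censored=True)
        excl = residence_stats(events, include_censored=False)
        assert incl[0].n_events == 3 and excl[0].n_events == 2


class TestExport:
    def test_round_trip_and_column_order(self, tmp_path):
        import pandas as pd

        events = TestResidenceStats._events([10.0, 20.0, 30.0])
        stats = residence_stats(events, state_label="open",
                                residue_keys=[("A", 63), ("A", 65)])
        export_events(events, stats, tmp_path / "e.tsv", tmp_path / "s.tsv")
        e = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(e) == 3
        assert e["duration_ns"].tolist() == [10.0, 20.0, 30.0]
        s = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        assert len(s) == 2
        assert list(s.columns)[:3] == ["residue", "state", "total_events"]
        back = events_to_frame(events)
        assert back["start_frame"].tolist() == e["start_frame"].tolist()
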