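"""Survey-data handling: event collapsing, histories, filters, covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gardenhunt.survey import (
    Deployment,
    DetectionEvent,
    build_histories,
    collapse_events,
    filter_sites,
    frequency_of_detection,
    standardize,
    subset_history,
    tabulate_detections,
    track_density,
    visit_windows,
)

T0 = pd.Timestamp("2015-09-21 08:00")


def photos_at(minutes, camera="C1", species="paca"):
    return pd.DataFrame(
        {
            "camera_id": camera,
            "species": species,
            "timestamp": [T0 + pd.Timedelta(minutes=m) for m in minutes],
        }
    )


def brute_force_events(rows, gap_minutes=5.0):
    """Independent oracle: pairwise transitive grouping per camera+species."""
    groups = {}
    for cam, sp, t in rows:
        groups.setdefault((cam, sp), []).append(t)
    n_events = 0
    starts = []
    for (cam, sp), times in groups.items():
        times = sorted(times)
        clusters = [[times[0]]]
        for t in times[1:]:
            if (t - clusters[-1][-1]).total_seconds() < gap_minutes * 60:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        n_events += len(clusters)
        starts += [c[0] for c in clusters]
    return n_events, sorted(starts)


class TestCollapseEvents:
    @pytest.mark.parametrize(
        "minutes,expected",
        [
            ([0, 2, 4], 1),        # all gaps < 5 merge
            ([0, 6], 2),           # gap >= 5 splits
            ([0, 5], 2),           # exactly 5 min starts a new event (strict <)
            ([0, 4.9], 1),
            ([0], 1),
        ],
    )
    def test_gap_rule(self, minutes, expected):
        events = collapse_events(photos_at(minutes))
        assert len(events) == expected
        assert sum(e.n_photos for e in events) == len(minutes)

    def test_interleaved_species_split_by_stream(self):
        df = pd.concat(
            [photos_at([0, 2], species="A"), photos_at([1], species="B")]
        )
        events = collapse_events(df)
        assert sorted((e.species, e.n_photos) for e in events) == [("A", 2), ("B", 1)]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["C1", "C2"]),
                st.sampled_from(["A", "B"]),
                st.integers(0, 60),
            ),
            min_size=1,
            max_size=20,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_order_invariance_matches_brute_force(self, rows, rnd):
        rows = [(c, s, T0 + pd.Timedelta(minutes=m)) for c, s, m in rows]
        shuffled = list(rows)
        rnd.shuffle(shuffled)
        df = pd.DataFrame(shuffled, columns=["camera_id", "species", "timestamp"])
        events = collapse_events(df)
        n_expected, starts_expected = brute_force_events(rows)
        assert len(events) == n_expected
        assert sorted(e.start_time for e in events) == starts_expected

    def test_bad_timestamp_reports_row(self):
        df = pd.DataFrame(
            {"camera_id": ["C1", "C1"], "species": ["A", "A"],
             "timestamp": ["2015-09-21 08:00", "not a time"]}
        )
        with pytest.raises(ValueError, match=r"row\(s\) \[1\]"):
            collapse_events(df)


class TestTabulateAndFD:
    def test_counts_and_class_totals(self):
        events = [DetectionEvent("C1", sp, T0) for sp in ["a", "a", "b", "x"]]
        D, totals = tabulate_detections(
            events, species_class={"a": "mammal", "b": "bird"}
        )
        assert D["a"] == 2 and D["b"] == 1
        assert totals == {"mammal": 2, "bird": 1, "unidentified": 1}

    def test_unknown_species_warns(self):
        with pytest.warns(UserWarning, match="unidentified"):
            tabulate_detections([DetectionEvent("C1", "zz", T0)], species_class={})

    def test_empty_events(self):
        D, totals = tabulate_detections([], species_class={})
        assert len(D) == 0 and totals == {}

    @pytest.mark.parametrize(
        "D,days,expected",
        [(265, 4548, 5.83), (48, 4548, 1.06), (0, 4548, 0.0), (5, 4000, 0.13)],
    )
    def test_fd_examples(self, D, days, expected):
        assert frequency_of_detection(D, days) == pytest.approx(expected, abs=1e-9)

    def test_fd_rejects_nonpositive_effort(self):
        with pytest.raises(ValueError):
            frequency_of_detection(10, 0)


class TestVisitWindows:
    def test_21_day_visits_truncate_at_period_boundaries(self):
        w = visit_windows(21, 180, 60)
        assert len(w) == 9
        assert [b - a for a, b in w] == [21, 21, 18] * 3
        assert w[0] == (0, 21) and w[-1] == (162, 180)

    def test_60_day_visits_give_three(self):
        assert len(visit_windows(60, 180, 60)) == 3


def deployment(camera="C1", intervals=((0, 60),)):
    return Deployment(
        camera_id=camera,
        x=0.0,
        y=0.0,
        activity_intervals=[
            (T0.normalize() + pd.Timedelta(days=a), T0.normalize() + pd.Timedelta(days=b))
            for a, b in intervals
        ],
    )


class TestBuildHistories:
    season = T0.normalize()

    def test_detection_and_full_effort(self):
        dep = deployment(intervals=[(0, 21)])
        ev = [DetectionEvent("C1", "paca", self.season + pd.Timedelta(days=3))]
        h = build_histories(ev, [dep], self.season)["paca"]
        assert h.y[0, 0] == 1.0 and h.effort[0, 0] == 1.0
        assert np.isnan(h.y[0, 1]) and np.isnan(h.effort[0, 1])

    def test_partial_effort_no_events(self):
        dep = deployment(intervals=[(0, 7)])
        h = build_histories(
            [DetectionEvent("C1", "paca", self.season + pd.Timedelta(days=2))],
            [dep], self.season,
        )["paca"]
        assert h.effort[0, 0] == pytest.approx(7 / 21)
        # y missing exactly where effort missing
        assert np.array_equal(np.isnan(h.y), np.isnan(h.effort))

    def test_event_outside_deployment_errors(self):
        dep = deployment(intervals=[(0, 21)])
        ev = [DetectionEvent("C1", "paca", self.season + pd.Timedelta(days=30))]
        with pytest.raises(ValueError, match="C1"):
            build_histories(ev, [dep], self.season)

    def test_total_detections_bounded_by_events(self):
        rng = np.random.default_rng(4)
        dep = deployment(intervals=[(0, 180)])
        evs = [
            DetectionEvent("C1", "paca",
                           self.season + pd.Timedelta(days=float(d)))
            for d in rng.uniform(0, 180, 40)
        ]
        h = build_histories(evs, [dep], self.season)["paca"]
        assert h.total_detections <= len(evs)
        assert h.n_visits == 9

    def test_date_covariate_standardized(self):
        dep = deployment(intervals=[(0, 180)])
        h = build_histories(
            [DetectionEvent("C1", "paca", self.season)], [dep], self.season
        )["paca"]
        assert h.date[0].mean() == pytest.approx(0, abs=1e-12)
        assert h.date[0].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_subset_history(self):
        deps = [deployment("C1", [(0, 60)]), deployment("C2", [(0, 60)])]
        ev = [DetectionEvent("C2", "paca", self.season + pd.Timedelta(days=1))]
        h = build_histories(ev, deps, self.season)["paca"]
        sub = subset_history(h, ["C2"])
        assert sub.sites == ["C2"] and sub.y[0, 0] == 1.0


class TestFilterSites:
    def covs(self):
        return pd.DataFrame(
            {"camera_id": ["C1", "C2", "C3"],
             "dist_conuco": [2000.0, 8000.0, 2000.0]}
        )

    def test_rules_and_log(self):
        deps = [
            deployment("C1", [(0, 10)]),   # retained
            deployment("C2", [(0, 10)]),   # too far from conuco
            deployment("C3", [(0, 6)]),    # too few active days
        ]
        retained, log = filter_sites(self.covs(), deps)
        assert retained == ["C1"]
        reasons = dict(zip(log["camera_id"], log["reason"]))
        assert reasons == {"C2": "distance", "C3": "min_active_days"}

    def test_empty_result_warns(self):
        deps = [deployment("C1", [(0, 1)])]
        with pytest.warns(UserWarning, match="no sites"):
            retained, _ = filter_sites(self.covs(), deps)
        assert retained == []


class TestTrackDensity:
    def test_power_law_values(self):
        assert track_density((0, 0), [(0, 1)]) == pytest.approx(1.0)
        assert track_density((0, 0), [(0, 16)]) == pytest.approx(0.5)
        assert track_density((0, 0), [(0, 1), (0, 16)]) == pytest.approx(1.5)

    def test_floor_guards_coincident_record(self):
        assert track_density((5, 5), [(5, 5)]) == pytest.approx(1.0)

    def test_additive_and_monotone(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-100, 100, (12, 2))
        total = track_density((0, 0), pts)
        assert total == pytest.approx(
            track_density((0, 0), pts[:5]) + track_density((0, 0), pts[5:])
        )
        # brute-force loop oracle
        oracle = sum(
            1.0 / max(np.hypot(x, y), 1.0) ** 0.25 for x, y in pts
        )
        assert total == pytest.approx(oracle, rel=1e-12)
        # pushing a record farther away can only lower the sum
        farther = pts * 2.0
        assert track_density((0, 0), farther) <= total

    def test_no_records_warns_zero(self):
        with pytest.warns(UserWarning):
            assert track_density((0, 0), []) == 0.0


class TestStandardize:
    def test_simple_vector(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize([5, 5, 5])

    def test_idempotent_and_nan_preserving(self):
        v = np.array([1.0, np.nan, 4.0, 9.0, 2.5])
        z = standardize(v)
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2, 3, 4]]).any()
        np.testing.assert_allclose(standardize(z)[~np.isnan(z)], z[~np.isnan(z)],
                                   atol=1e-12)
        zz = z[~np.isnan(z)]
        assert zz.mean() == pytest.approx(0, abs=1e-12)
        assert zz.std(ddof=1) == pytest.approx(1, abs=1e-12)
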