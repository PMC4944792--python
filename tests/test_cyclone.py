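"""Track parsing, landfall detection and the incidence footprint."""

import random

import pandas as pd
import pytest

from coastvuln.classify import classify_cyclone
from coastvuln.cyclone import (
    CycloneTrack,
    LandfallEvent,
    TrackPoint,
    count_incidence,
    detect_landfall,
    filter_category,
    read_tracks,
)
from coastvuln.grid import build_grid, great_circle_deg
from conftest import make_cell


def _track(storm_id, fixes):
    """fixes: list of (hours, lon, lat, category)."""
    base = pd.Timestamp("1970-06-01")
    return CycloneTrack(
        storm_id=storm_id,
        points=tuple(
            TrackPoint(time=base + pd.Timedelta(hours=h), lon=lon, lat=lat, category=cat)
            for h, lon, lat, cat in fixes
        ),
    )


class TestReadTracks:
    def test_grouping_and_sorting(self, tmp_path):
        csv = tmp_path / "tracks.csv"
        csv.write_text(
            "storm_id,timestamp,lon,lat,category\n"
            "A,1970-06-01 12:00,88.0,20.0,2\n"
            "A,1970-06-01 00:00,87.0,20.0,1\n"
            "A,1970-06-01 06:00,87.5,20.0,1\n"
            "B,1980-07-01 00:00,90.0,10.0,\n"
            "B,1980-07-01 06:00,90.5,10.0,3\n"
            "B,1980-07-01 12:00,91.0,10.0,3\n"
        )
        tracks = read_tracks(csv)
        assert len(tracks) == 2
        assert all(len(t.points) == 3 for t in tracks)
        a = next(t for t in tracks if t.storm_id == "A")
        assert [p.lon for p in a.points] == [87.0, 87.5, 88.0]  # time-sorted
        b = next(t for t in tracks if t.storm_id == "B")
        assert b.points[0].category is None  # blank category kept as missing

    def test_unparseable_rows_rejected(self, tmp_path):
        csv = tmp_path / "tracks.csv"
        csv.write_text(
            "storm_id,timestamp,lon,lat,category\n"
            "A,1970-06-01 00:00,87.0,20.0,1\n"
            "A,1970-06-01 06:00,not-a-lon,20.0,1\n"
            "A,1970-06-01 12:00,88.0,20.0,1\n"
        )
        tracks = read_tracks(csv)
        assert len(tracks) == 1
        assert len(tracks[0].points) == 2

    def test_missing_column_is_an_error(self, tmp_path):
        csv = tmp_path / "tracks.csv"
        csv.write_text("storm_id,timestamp,lon,lat\nA,1970-06-01,87.0,20.0\n")
        with pytest.raises(ValueError, match="category"):
            read_tracks(csv)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        csv = tmp_path / "tracks.csv"
        csv.write_text("storm_id,timestamp,lon,lat,category\n")
        assert read_tracks(csv) == []


class TestFilterCategory:
    def test_peak_category_rules(self):
        strong = _track("S", [(0, 87, 20, 1), (6, 88, 20, 3), (12, 89, 20, 2)])
        weak = _track("W", [(0, 87, 20, 0), (6, 88, 20, 0)])
        uncategorised = _track("U", [(0, 87, 20, None), (6, 88, 20, None)])
        kept = filter_category([strong, weak, uncategorised])
        assert [t.storm_id for t in kept] == ["S"]

    def test_min_category_threshold(self):
        cat3 = _track("S", [(0, 87, 20, 3), (6, 88, 20, 3)])
        assert filter_category([cat3], min_category=4) == []
        assert len(filter_category([cat3], min_category=3)) == 1


class TestDetectLandfall:
    def test_track_wholly_at_sea(self, meridian_coastline):
        track = _track("S", [(0, 85.0, 21.0, 2), (6, 86.0, 21.0, 2)])
        assert detect_landfall(track, meridian_coastline) == []

    def test_crossing_straight_meridian_coast(self, meridian_coastline):
        # two-point track crossing lon 90 at lat 21; oracle: the segment
        # from (89.5, 21) to (90.5, 21) crosses x=90 at exactly (90, 21)
        track = _track("S", [(0, 89.5, 21.0, 2), (6, 90.5, 21.0, 2)])
        events = detect_landfall(track, meridian_coastline)
        assert len(events) == 1
        ev = events[0]
        assert ev.lon == pytest.approx(90.0, abs=1e-9)
        assert ev.lat == pytest.approx(21.0, abs=1e-9)
        assert ev.category == 2  # category of the last at-sea fix

    def test_two_separate_landfalls(self):
        # land ring with a 2-degree-wide sea gap between two land blocks
        from coastvuln.grid import Coastline

        line1 = ((90.0, 20.0), (90.0, 21.0))
        line2 = ((90.0, 23.0), (90.0, 24.0))
        ring1 = line1 + ((92.0, 21.0), (92.0, 20.0), line1[0])
        ring2 = line2 + ((92.0, 24.0), (92.0, 23.0), line2[0])
        coast1 = Coastline(polylines=(line1,), land_polygon=(ring1,))
        coast2 = Coastline(polylines=(line2,), land_polygon=(ring2,))
        # storm hits the first block, re-emerges northward at sea, hits the second
        track = _track(
            "S",
            [(0, 89.0, 20.5, 3), (6, 91.0, 20.5, 3), (12, 89.0, 22.0, 3),
             (18, 89.0, 23.5, 3), (24, 91.0, 23.5, 3)],
        )
        ev1 = detect_landfall(track, coast1)
        ev2 = detect_landfall(track, coast2)
        assert len(ev1) == 1 and ev1[0].lat == pytest.approx(20.5)
        assert len(ev2) == 1 and ev2[0].lat == pytest.approx(23.5)

    def test_nearby_repeat_landfalls_merged(self, meridian_coastline):
        # skims out and back within 1 degree: second crossing merged away
        track = _track(
            "S",
            [(0, 89.5, 21.0, 2), (6, 90.2, 21.0, 2), (12, 89.8, 21.2, 2),
             (18, 90.3, 21.2, 2)],
        )
        events = detect_landfall(track, meridian_coastline)
        assert len(events) == 1

    def test_category_zero_transitions_ignored(self, meridian_coastline):
        track = _track("S", [(0, 89.5, 21.0, 0), (6, 90.5, 21.0, 0)])
        assert detect_landfall(track, meridian_coastline) == []


class TestCountIncidence:
    def _events_at(self, lon, lat, n, category=2):
        base = pd.Timestamp("1970-06-01")
        return [
            LandfallEvent(storm_id=f"S{i}", lon=lon, lat=lat, category=category,
                          time=base + pd.Timedelta(days=i))
            for i in range(n)
        ]

    def test_footprint_touches_about_four_cells_on_straight_coast(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        # extend the coast so the footprint is not clipped by the domain edge
        lon_c, lat_c = cells[1].center
        counts = count_incidence(self._events_at(lon_c, lat_c, 1), cells)
        touched = sum(1 for v in counts.values() if v > 0)
        assert 3 <= touched <= 5  # ~2-degree footprint = 4 +/- 1 half-degree cells
        assert counts[cells[1].cell_id] == 1

    def test_no_events_no_counts(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        counts = count_incidence([], cells)
        assert all(v == 0 for v in counts.values())

    def test_repeat_strikes_accumulate_to_high_class(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        lon_c, lat_c = cells[0].center
        counts = count_incidence(self._events_at(lon_c, lat_c, 12), cells)
        assert counts[cells[0].cell_id] == 12
        assert classify_cyclone(counts[cells[0].cell_id]) == 3

    def test_storm_counted_once_per_cell(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        lon_c, lat_c = cells[0].center
        base = pd.Timestamp("1970-06-01")
        twice = [
            LandfallEvent(storm_id="S", lon=lon_c, lat=lat_c, category=2, time=base),
            LandfallEvent(storm_id="S", lon=lon_c, lat=lat_c + 1.4, category=2,
                          time=base + pd.Timedelta(days=1)),
        ]
        counts = count_incidence(twice, cells)
        assert max(counts.values()) == 1

    def test_agrees_with_brute_force_oracle(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        rng = random.Random(42)
        events = [
            LandfallEvent(
                storm_id=f"S{i}",
                lon=90.0 + rng.uniform(-0.3, 0.3),
                lat=rng.uniform(19.5, 22.5),
                category=rng.randint(1, 5),
                time=pd.Timestamp("1970-06-01") + pd.Timedelta(days=i),
            )
            for i in range(100)
        ]
        counts = count_incidence(events, cells)
        oracle = {c.cell_id: 0 for c in cells}
        for ev in events:
            for c in cells:
                if great_circle_deg(ev.lon, ev.lat, *c.center) <= 1.0:
                    oracle[c.cell_id] += 1
        assert counts == oracle

    def test_permutation_invariance(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        events = self._events_at(90.0, 21.2, 7)
        shuffled = list(events)
        random.Random(7).shuffle(shuffled)
        assert count_incidence(events, cells) == count_incidence(shuffled, cells)

    def test_adding_an_event_never_decreases_counts(self, meridian_coastline):
        cells = build_grid(meridian_coastline)
        events = self._events_at(90.0, 21.2, 5)
        before = count_incidence(events, cells)
        after = count_incidence(events + self._events_at(90.0, 20.3, 1, category=4), cells)
        assert all(after[k] >= before[k] for k in before)


def test_landfall_event_requires_category_one_or_above():
    with pytest.raises(ValueError):
        LandfallEvent(storm_id="S", lon=90, lat=20, category=0,
                      time=pd.Timestamp("1970-06-01"))
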