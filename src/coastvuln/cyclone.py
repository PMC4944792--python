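"""Cyclone track parsing, landfall detection and per-cell incidence.

A landfall is the first crossing of a track from sea to land.  Only
storms reaching Saffir-Simpson Category 1 (wind speed > 119 km/h) or
above are retained; uncategorised storms are excluded.  Because a
tropical cyclone is much wider than one half-degree cell, each landfall
increments every coastal cell whose centre lies within an impact
half-width (default 1 degree of great-circle arc, i.e. a ~2 degree
footprint touching ~4 elements along a straight coast).  A storm
increments a given cell at most once: the statistic is landfall
frequency, not fix frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import LineString, Point

from coastvuln.grid import Coastline, CoastalCell, great_circle_deg

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("storm_id", "timestamp", "lon", "lat", "category")

#: successive landfalls of one storm closer than this are merged (degrees of arc)
MERGE_RADIUS_DEG = 1.0


@dataclass(frozen=True)
class TrackPoint:
    time: pd.Timestamp
    lon: float
    lat: float
    category: int | None  # Saffir-Simpson 0-5, None = not recorded


@dataclass(frozen=True)
class CycloneTrack:
    """Time-ordered fixes for one storm."""

    storm_id: str
    points: tuple[TrackPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"track {self.storm_id!r} needs >= 2 points")
        times = [p.time for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times[:-1], times[1:])):
            raise ValueError(f"track {self.storm_id!r} times must be strictly increasing")

    @property
    def max_category(self) -> int | None:
        cats = [p.category for p in self.points if p.category is not None]
        return max(cats) if cats else None


@dataclass(frozen=True)
class LandfallEvent:
    """One sea-to-land crossing of a categorised storm."""

    storm_id: str
    lon: float
    lat: float
    category: int
    time: pd.Timestamp

    def __post_init__(self) -> None:
        if self.category < 1:
            raise ValueError("landfall events are only retained for category >= 1")


def read_tracks(path) -> list[CycloneTrack]:
    """Read a tracks CSV (storm_id, timestamp, lon, lat, category).

    Rows with unparseable coordinates or timestamps are dropped with a
    logged count; blank categories are kept as missing.  Storms with a
    single usable fix cannot form a track segment and are dropped.
    """
    df = pd.read_csv(path, dtype={"storm_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks CSV missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("tracks CSV %s contains no rows", path)
        return []

    n_raw = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    df["category"] = pd.to_numeric(df["category"], errors="coerce")
    bad = df["lon"].isna() | df["lat"].isna() | df["timestamp"].isna()
    if bad.any():
        logger.info("rejected %d unparseable track row(s)", int(bad.sum()))
    df = df[~bad]

    tracks: list[CycloneTrack] = []
    for storm_id, group in df.groupby("storm_id", sort=True):
        group = group.sort_values("timestamp")
        points = tuple(
            TrackPoint(
                time=row.timestamp,
                lon=float(row.lon),
                lat=float(row.lat),
                category=None if pd.isna(row.category) else int(row.category),
            )
            for row in group.itertuples()
        )
        if len(points) < 2:
            logger.info("dropping storm %s with < 2 usable fixes", storm_id)
            continue
        tracks.append(CycloneTrack(storm_id=str(storm_id), points=points))
    logger.info("read %d track(s) from %d row(s)", len(tracks), n_raw)
    return tracks


def filter_category(tracks: Iterable[CycloneTrack], min_category: int = 1) -> list[CycloneTrack]:
    """Keep storms whose maximum recorded category >= min_category.

    Storms whose category was never recorded are excluded, as are
    storms that peak below the threshold (e.g. tropical storms at
    category 0 when min_category is 1).
    """
    kept = []
    for track in tracks:
        max_cat = track.max_category
        if max_cat is not None and max_cat >= min_category:
            kept.append(track)
    return kept


def _point_category(track: CycloneTrack, idx: int) -> int:
    """Category at the last at-sea fix, falling back to the storm maximum."""
    cat = track.points[idx].category
    if cat is None or cat < 1:
        cat = track.max_category
    return cat if cat is not None else 0


def detect_landfall(track: CycloneTrack, coastline: Coastline) -> list[LandfallEvent]:
    """Locate the sea-to-land crossings of one track.

    Each transition from an at-sea fix to an on-land fix yields one
    event at the first intersection of that track segment with the land
    polygon boundary, placed by linear interpolation in lon/lat between
    the bracketing fixes (6-hourly archive spacing makes anything
    fancier spurious).  The category at landfall is taken from the last
    at-sea fix (fallback: storm maximum).  Successive landfalls of the
    same storm closer than 1 degree of arc are merged into the first,
    so a track skimming the coast is not double counted.  Events below
    category 1 are discarded.
    """
    land = coastline.shapely_land
    if land is None:
        raise ValueError("landfall detection needs a coastline land polygon")

    on_land = [land.covers(Point(p.lon, p.lat)) for p in track.points]
    events: list[LandfallEvent] = []
    for i in range(len(track.points) - 1):
        if on_land[i] or not on_land[i + 1]:
            continue  # not a sea -> land transition
        p1, p2 = track.points[i], track.points[i + 1]
        seg = LineString([(p1.lon, p1.lat), (p2.lon, p2.lat)])
        hit = seg.intersection(land.boundary)
        if hit.is_empty:
            # endpoint just inside: take the landward fix itself
            lf_lon, lf_lat = p2.lon, p2.lat
        else:
            pts = [hit] if hit.geom_type == "Point" else [
                g for g in getattr(hit, "geoms", [hit]) if g.geom_type == "Point"
            ]
            if not pts:  # collinear overlap with the boundary
                pts = [Point(hit.coords[0])] if hasattr(hit, "coords") else [Point(p2.lon, p2.lat)]
            # first crossing along the direction of travel
            start = Point(p1.lon, p1.lat)
            first = min(pts, key=start.distance)
            lf_lon, lf_lat = first.x, first.y
        category = _point_category(track, i)
        if category < 1:
            continue
        # interpolate the time of crossing along the segment
        seg_len = seg.length
        frac = 0.0 if seg_len == 0 else start.distance(Point(lf_lon, lf_lat)) / seg_len
        time = p1.time + (p2.time - p1.time) * frac
        if events and great_circle_deg(events[-1].lon, events[-1].lat, lf_lon, lf_lat) < MERGE_RADIUS_DEG:
            continue  # near-duplicate of the previous landfall
        events.append(
            LandfallEvent(storm_id=track.storm_id, lon=lf_lon, lat=lf_lat,
                          category=category, time=time)
        )
    return events


def count_incidence(
    events: Sequence[LandfallEvent],
    cells: Sequence[CoastalCell],
    impact_halfwidth_deg: float = 1.0,
) -> dict[str, int]:
    """Accumulate landfall incidence per coastal cell.

    Each event increments every coastal cell whose centre lies within
    ``impact_halfwidth_deg`` degrees of great-circle arc of the
    landfall point; a storm increments a given cell at most once even
    if it makes several landfalls near it.

    Returns
    -------
    dict
        cell_id -> count, with an entry (possibly 0) for every cell.
    """
    counts: dict[str, int] = {cell.cell_id: 0 for cell in cells}
    seen: set[tuple[str, str]] = set()  # (storm_id, cell_id) pairs already counted
    for event in events:
        for cell in cells:
            if not cell.is_coastal:
                continue
            lon_c, lat_c = cell.center
            if great_circle_deg(event.lon, event.lat, lon_c, lat_c) <= impact_halfwidth_deg:
                key = (event.storm_id, cell.cell_id)
                if key not in seen:
                    seen.add(key)
                    counts[cell.cell_id] += 1
    return counts
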