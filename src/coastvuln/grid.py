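"""Half-degree coastal grid: coastline geometry and the cell data model.

The coastal zone is divided into a fixed half-degree lon/lat lattice
(cells of roughly 50 x 50 km^2 at these latitudes).  A cell is *coastal*
when a positive length of the coastline polyline falls inside its
bounds.  The lattice is anchored at (0 deg, 0 deg) with half-open cells
[min, min + cell_size), so a point on a shared edge belongs to exactly
one cell and coastline length is never double counted.

Lengths are great-circle lengths on a spherical Earth of radius
6371 km (~111.19 km per degree of arc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, MultiLineString, Polygon, box

EARTH_RADIUS_KM = 6371.0
#: km per degree of great-circle arc on the R = 6371 km sphere.
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0


class Geomorphology(str, Enum):
    """Coastal landform category, ordered by vulnerability."""

    BEACH_CLIFF = "BEACH_CLIFF"
    BEACH_RIVER_MOUTH = "BEACH_RIVER_MOUTH"
    DELTA_PLAIN_RIVER_MOUTH = "DELTA_PLAIN_RIVER_MOUTH"


class Groundwater(str, Enum):
    """Fresh-groundwater availability category, ordered by vulnerability."""

    FRESH_SHALLOW = "FRESH_SHALLOW"
    SALINE_SHALLOW_FRESH_DEEP = "SALINE_SHALLOW_FRESH_DEEP"
    SALINE_SHALLOW_AND_DEEP = "SALINE_SHALLOW_AND_DEEP"


@dataclass(frozen=True)
class Coastline:
    """One or more coastline polylines plus the land polygon.

    Parameters
    ----------
    polylines
        Sequence of polylines; each polyline is a sequence of
        (lon, lat) vertices in degrees, WGS84, with >= 2 vertices.
    land_polygon
        Closed (lon, lat) ring(s) distinguishing land from sea.  The
        first ring is the exterior; the coastline normally lies on or
        near its boundary.
    """

    polylines: tuple[tuple[tuple[float, float], ...], ...]
    land_polygon: tuple[tuple[tuple[float, float], ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.polylines:
            raise ValueError("coastline needs at least one polyline")
        for line in self.polylines:
            if len(line) < 2:
                raise ValueError("every coastline polyline needs >= 2 vertices")
            for lon, lat in line:
                if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                    raise ValueError(f"vertex ({lon}, {lat}) outside lon/lat bounds")

    @property
    def shapely_lines(self) -> MultiLineString:
        return MultiLineString([LineString(line) for line in self.polylines])

    @property
    def shapely_land(self) -> Polygon | None:
        if not self.land_polygon:
            return None
        return Polygon(self.land_polygon[0], list(self.land_polygon[1:]))

    def total_length_km(self) -> float:
        """Great-circle length of all polylines, in km."""
        return sum(_polyline_length_km(line) for line in self.polylines)

    @classmethod
    def from_geojson(cls, obj: dict) -> "Coastline":
        """Build from a GeoJSON Feature/FeatureCollection or geometry.

        LineString/MultiLineString geometries become polylines and
        Polygon geometries become the land polygon.
        """
        lines: list[tuple[tuple[float, float], ...]] = []
        land: tuple[tuple[tuple[float, float], ...], ...] = ()

        def eat_geometry(geom: dict) -> None:
            nonlocal land
            gtype = geom["type"]
            if gtype == "LineString":
                lines.append(tuple((float(x), float(y)) for x, y in geom["coordinates"]))
            elif gtype == "MultiLineString":
                for part in geom["coordinates"]:
                    lines.append(tuple((float(x), float(y)) for x, y in part))
            elif gtype == "Polygon":
                land = tuple(
                    tuple((float(x), float(y)) for x, y in ring)
                    for ring in geom["coordinates"]
                )
            elif gtype == "GeometryCollection":
                for sub in geom["geometries"]:
                    eat_geometry(sub)
            else:
                raise ValueError(f"unsupported coastline geometry type {gtype!r}")

        if obj.get("type") == "FeatureCollection":
            for feat in obj["features"]:
                eat_geometry(feat["geometry"])
        elif obj.get("type") == "Feature":
            eat_geometry(obj["geometry"])
        else:
            eat_geometry(obj)
        return cls(polylines=tuple(lines), land_polygon=land)


@dataclass(frozen=True)
class CellAttributes:
    """Raw values of the six vulnerability variables for one cell."""

    elevation_m: float
    geomorph: Geomorphology
    pop_density: float
    sept_rainfall_mm: float
    groundwater: Groundwater
    cyclone_count: int

    def __post_init__(self) -> None:
        if self.pop_density < 0:
            raise ValueError("pop_density must be >= 0")
        if self.sept_rainfall_mm < 0:
            raise ValueError("sept_rainfall_mm must be >= 0")
        if int(self.cyclone_count) != self.cyclone_count or self.cyclone_count < 0:
            raise ValueError("cyclone_count must be a non-negative integer")


@dataclass
class CoastalCell:
    """One half-degree grid element intersecting the coastline."""

    row: int
    col: int
    bounds: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max
    coastline_length_km: float = 0.0
    land_fraction: float = 0.0
    attributes: CellAttributes | None = None

    @property
    def cell_id(self) -> str:
        return f"r{self.row}c{self.col}"

    @property
    def is_coastal(self) -> bool:
        return self.coastline_length_km > 0.0

    @property
    def center(self) -> tuple[float, float]:
        lon_min, lat_min, lon_max, lat_max = self.bounds
        return ((lon_min + lon_max) / 2.0, (lat_min + lat_max) / 2.0)

    def area_km2(self) -> float:
        """Spherical area of the cell bounds in km^2."""
        lon_min, lat_min, lon_max, lat_max = self.bounds
        dlon = math.radians(lon_max - lon_min)
        return (
            EARTH_RADIUS_KM**2
            * dlon
            * (math.sin(math.radians(lat_max)) - math.sin(math.radians(lat_min)))
        )

    def with_attributes(self, attrs: CellAttributes) -> "CoastalCell":
        return replace(self, attributes=attrs)


def great_circle_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Haversine great-circle distance in km (sphere, R = 6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def great_circle_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle separation expressed in degrees of arc."""
    return great_circle_km(lon1, lat1, lon2, lat2) / KM_PER_DEG


def _polyline_length_km(coords: Sequence[tuple[float, float]]) -> float:
    return sum(
        great_circle_km(coords[i][0], coords[i][1], coords[i + 1][0], coords[i + 1][1])
        for i in range(len(coords) - 1)
    )


def _geom_length_km(geom) -> float:
    """Great-circle length of a shapely (Multi)LineString in lon/lat."""
    if geom.is_empty:
        return 0.0
    if geom.geom_type == "LineString":
        return _polyline_length_km(list(geom.coords))
    if geom.geom_type in ("MultiLineString", "GeometryCollection"):
        return sum(_geom_length_km(g) for g in geom.geoms if g.geom_type == "LineString")
    return 0.0  # points from tangent contact carry no length


def _clip_to_cell(lines: MultiLineString, bounds: tuple[float, float, float, float]):
    """Clip coastline to a cell with half-open [min, max) semantics.

    The closed-box intersection is computed first; any piece lying
    entirely on the lon_max or lat_max edge is discarded, because under
    the half-open convention it belongs to the neighbouring cell.
    """
    lon_min, lat_min, lon_max, lat_max = bounds
    clipped = lines.intersection(box(lon_min, lat_min, lon_max, lat_max))
    if clipped.is_empty:
        return clipped
    parts = [clipped] if clipped.geom_type == "LineString" else [
        g for g in getattr(clipped, "geoms", []) if g.geom_type == "LineString"
    ]
    kept = []
    for part in parts:
        xs, ys = zip(*part.coords)
        on_lon_max = all(abs(x - lon_max) < 1e-12 for x in xs)
        on_lat_max = all(abs(y - lat_max) < 1e-12 for y in ys)
        if not (on_lon_max or on_lat_max):
            kept.append(part)
    return MultiLineString(kept)


def _land_fraction(cell_bounds, land: Polygon | None) -> float:
    if land is None:
        return 0.0
    cell_box = box(*cell_bounds)
    inter = cell_box.intersection(land)
    if inter.is_empty:
        return 0.0
    # planar ratio in lon/lat: adequate within a single half-degree cell
    return min(1.0, inter.area / cell_box.area)


def build_grid(coastline: Coastline, cell_size_deg: float = 0.5) -> list[CoastalCell]:
    """Lay the half-degree lattice over the coastline and keep coastal cells.

    Cells follow the lattice row = floor(lat / cell_size),
    col = floor(lon / cell_size) with half-open bounds
    [min, min + cell_size).  Each returned cell carries the great-circle
    length of the coastline clipped to its bounds and the land fraction
    from the land polygon (0 when no land polygon is given).

    Raises
    ------
    ValueError
        If the coastline yields no coastal cells.
    """
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    lines = coastline.shapely_lines
    land = coastline.shapely_land

    # candidate lattice cells from per-segment bounding boxes
    candidates: set[tuple[int, int]] = set()
    for line in coastline.polylines:
        for (lon1, lat1), (lon2, lat2) in zip(line[:-1], line[1:]):
            col_lo = math.floor(min(lon1, lon2) / cell_size_deg)
            col_hi = math.floor(max(lon1, lon2) / cell_size_deg)
            row_lo = math.floor(min(lat1, lat2) / cell_size_deg)
            row_hi = math.floor(max(lat1, lat2) / cell_size_deg)
            for row in range(row_lo, row_hi + 1):
                for col in range(col_lo, col_hi + 1):
                    candidates.add((row, col))

    cells: list[CoastalCell] = []
    for row, col in sorted(candidates):
        bounds = (
            col * cell_size_deg,
            row * cell_size_deg,
            (col + 1) * cell_size_deg,
            (row + 1) * cell_size_deg,
        )
        clipped = _clip_to_cell(lines, bounds)
        length_km = _geom_length_km(clipped)
        if length_km <= 0.0:
            continue
        cells.append(
            CoastalCell(
                row=row,
                col=col,
                bounds=bounds,
                coastline_length_km=length_km,
                land_fraction=_land_fraction(bounds, land),
            )
        )
    if not cells:
        raise ValueError("no coastal cells")
    return cells


def coastline_length_in_cell(coastline: Coastline, cell: CoastalCell) -> float:
    """Great-circle km of coastline inside one cell's (half-open) bounds."""
    clipped = _clip_to_cell(coastline.shapely_lines, cell.bounds)
    return _geom_length_km(clipped)
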