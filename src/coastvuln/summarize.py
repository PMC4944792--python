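"""Exposure summaries: coastline length and population per vulnerability class.

``coast_length_by_class`` sums per-cell coastline length by CVI class;
because each coastline piece belongs to exactly one (half-open) cell
the class totals conserve the full coastline length.

``exposed_population`` estimates the population living within a buffer
distance of the coast inside cells of each class.  The land area of a
cell inside the buffer is approximated on a sub-grid (default 0.05
degrees): each sub-cell contributes its spherical area when its centre
is on land and within ``buffer_km`` of the coastline; population is
then density x buffered land area.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Point

from coastvuln.cvi import CviResult, VulnClass
from coastvuln.grid import (
    EARTH_RADIUS_KM,
    Coastline,
    CoastalCell,
    KM_PER_DEG,
)

_CLASSES = (VulnClass.LOW, VulnClass.MODERATE, VulnClass.HIGH)


def coast_length_by_class(
    cells: Sequence[CoastalCell], results: Mapping[str, CviResult]
) -> dict[str, float]:
    """Total coastline km in cells of each vulnerability class."""
    totals = {c.value: 0.0 for c in _CLASSES}
    for cell in cells:
        res = results.get(cell.cell_id)
        if res is None:
            continue
        totals[res.cvi_class.value] += cell.coastline_length_km
    return totals


def _subcell_area_km2(lat_lo: float, lat_hi: float, dlon_deg: float) -> float:
    return (
        EARTH_RADIUS_KM**2
        * math.radians(dlon_deg)
        * (math.sin(math.radians(lat_hi)) - math.sin(math.radians(lat_lo)))
    )


def buffered_land_area_km2(
    cell: CoastalCell,
    coastline: Coastline,
    buffer_km: float,
    resolution_deg: float = 0.05,
) -> float:
    """Land area of a cell within ``buffer_km`` of the coastline (km^2).

    Sampled on a ``resolution_deg`` sub-grid; distance to the coastline
    is measured on a local equirectangular plane (longitude scaled by
    cos(latitude)), adequate at the <=30 km buffers used here.
    """
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    if buffer_km == 0:
        return 0.0
    land = coastline.shapely_land
    lines = coastline.shapely_lines
    lon_min, lat_min, lon_max, lat_max = cell.bounds
    n_lon = max(1, round((lon_max - lon_min) / resolution_deg))
    n_lat = max(1, round((lat_max - lat_min) / resolution_deg))
    lon_edges = np.linspace(lon_min, lon_max, n_lon + 1)
    lat_edges = np.linspace(lat_min, lat_max, n_lat + 1)

    area = 0.0
    for i in range(n_lat):
        lat_c = 0.5 * (lat_edges[i] + lat_edges[i + 1])
        coslat = math.cos(math.radians(lat_c))
        for j in range(n_lon):
            lon_c = 0.5 * (lon_edges[j] + lon_edges[j + 1])
            if land is not None and not land.covers(Point(lon_c, lat_c)):
                continue
            # local-plane distance to the coastline, in km
            d_deg = _planar_distance_deg(lines, lon_c, lat_c, coslat)
            if d_deg * KM_PER_DEG <= buffer_km:
                area += _subcell_area_km2(lat_edges[i], lat_edges[i + 1], lon_edges[j + 1] - lon_edges[j])
    return area


def _planar_distance_deg(lines, lon: float, lat: float, coslat: float) -> float:
    from shapely.affinity import scale
    from shapely.geometry import Point as _P

    # scale longitudes about the sample point so planar distance ~ arc degrees
    scaled = scale(lines, xfact=coslat, yfact=1.0, origin=(lon, lat))
    return _P(lon, lat).distance(scaled)


def exposed_population(
    cells: Sequence[CoastalCell],
    results: Mapping[str, CviResult],
    coastline: Coastline,
    buffer_km: float = 30.0,
    resolution_deg: float = 0.05,
) -> dict[str, float]:
    """People within ``buffer_km`` of the coast, per vulnerability class.

    For each assessed cell: population density x land area inside the
    buffer (see :func:`buffered_land_area_km2`).  When the cell has no
    land polygon the land fraction is applied uniformly instead.
    """
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    totals = {c.value: 0.0 for c in _CLASSES}
    for cell in cells:
        res = results.get(cell.cell_id)
        if res is None or cell.attributes is None:
            continue
        if coastline.land_polygon:
            area = buffered_land_area_km2(cell, coastline, buffer_km, resolution_deg)
        else:
            area = cell.area_km2() * cell.land_fraction * (1.0 if buffer_km > 0 else 0.0)
        totals[res.cvi_class.value] += cell.attributes.pop_density * area
    return totals


def summary_report(
    cells: Sequence[CoastalCell],
    results: Mapping[str, CviResult],
    coastline: Coastline,
    buffer_km: float = 30.0,
) -> dict:
    """Assemble the per-class exposure summary as one JSON-ready dict."""
    lengths = coast_length_by_class(cells, results)
    people = exposed_population(cells, results, coastline, buffer_km=buffer_km)
    counts = {c.value: 0 for c in _CLASSES}
    for res in results.values():
        counts[res.cvi_class.value] += 1
    return {
        "n_cells": len(results),
        "cell_counts": counts,
        "coastline_km_by_class": {k: round(v, 1) for k, v in lengths.items()},
        "coastline_km_total": round(sum(lengths.values()), 1),
        "buffer_km": buffer_km,
        "population_by_class": {k: round(v, 0) for k, v in people.items()},
        "population_total": round(sum(people.values()), 0),
    }


def format_summary(report: dict) -> str:
    """Human-readable text block for a summary report."""
    lines = [
        f"Assessed coastal cells: {report['n_cells']}",
        f"Coastline length by class (km, total {report['coastline_km_total']}):",
    ]
    for cls in ("LOW", "MODERATE", "HIGH"):
        lines.append(
            f"  {cls:<9} {report['coastline_km_by_class'][cls]:>10.1f} km"
            f"   cells: {report['cell_counts'][cls]:>4d}"
            f"   people within {report['buffer_km']:.0f} km of coast:"
            f" {report['population_by_class'][cls]:>12,.0f}"
        )
    lines.append(f"Total exposed population: {report['population_total']:,.0f}")
    return "\n".join(lines)
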