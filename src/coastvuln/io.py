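"""Readers and writers for the cell and coastline formats.

Cells travel as flat CSV (one row per cell, attribute columns) or as a
GeoJSON FeatureCollection with one Polygon feature per cell; the
coastline as GeoJSON LineString/MultiLineString plus a land Polygon.
All numeric output uses a fixed column order so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from shapely.geometry import mapping

from coastvuln.cvi import CviResult
from coastvuln.grid import (
    CellAttributes,
    Coastline,
    CoastalCell,
    Geomorphology,
    Groundwater,
)

CELL_CSV_COLUMNS = [
    "cell_id", "row", "col", "lon_min", "lat_min", "lon_max", "lat_max",
    "coastline_length_km", "land_fraction",
    "elevation_m", "geomorph", "pop_density", "sept_rainfall_mm",
    "groundwater", "cyclone_count",
]


def cells_to_frame(cells: Sequence[CoastalCell]) -> pd.DataFrame:
    rows = []
    for cell in cells:
        a = cell.attributes
        rows.append(
            {
                "cell_id": cell.cell_id,
                "row": cell.row,
                "col": cell.col,
                "lon_min": cell.bounds[0],
                "lat_min": cell.bounds[1],
                "lon_max": cell.bounds[2],
                "lat_max": cell.bounds[3],
                "coastline_length_km": round(cell.coastline_length_km, 6),
                "land_fraction": round(cell.land_fraction, 6),
                "elevation_m": None if a is None else round(a.elevation_m, 6),
                "geomorph": None if a is None else a.geomorph.value,
                "pop_density": None if a is None else round(a.pop_density, 6),
                "sept_rainfall_mm": None if a is None else round(a.sept_rainfall_mm, 6),
                "groundwater": None if a is None else a.groundwater.value,
                "cyclone_count": None if a is None else a.cyclone_count,
            }
        )
    return pd.DataFrame(rows, columns=CELL_CSV_COLUMNS)


def write_cells_csv(cells: Sequence[CoastalCell], path) -> None:
    cells_to_frame(cells).to_csv(path, index=False)


def read_cells_csv(path) -> list[CoastalCell]:
    df = pd.read_csv(path)
    cells = []
    for row in df.itertuples():
        attrs = None
        if not pd.isna(getattr(row, "elevation_m", float("nan"))):
            attrs = CellAttributes(
                elevation_m=float(row.elevation_m),
                geomorph=Geomorphology(row.geomorph),
                pop_density=float(row.pop_density),
                sept_rainfall_mm=float(row.sept_rainfall_mm),
                groundwater=Groundwater(row.groundwater),
                cyclone_count=int(row.cyclone_count),
            )
        cells.append(
            CoastalCell(
                row=int(row.row),
                col=int(row.col),
                bounds=(float(row.lon_min), float(row.lat_min),
                        float(row.lon_max), float(row.lat_max)),
                coastline_length_km=float(row.coastline_length_km),
                land_fraction=float(row.land_fraction),
                attributes=attrs,
            )
        )
    return cells


def _cell_feature(cell: CoastalCell, results: Mapping[str, CviResult] | None) -> dict:
    lon_min, lat_min, lon_max, lat_max = cell.bounds
    props: dict = {
        "cell_id": cell.cell_id,
        "row": cell.row,
        "col": cell.col,
        "coastline_length_km": round(cell.coastline_length_km, 6),
        "land_fraction": round(cell.land_fraction, 6),
    }
    if cell.attributes is not None:
        a = cell.attributes
        props.update(
            elevation_m=round(a.elevation_m, 6),
            geomorph=a.geomorph.value,
            pop_density=round(a.pop_density, 6),
            sept_rainfall_mm=round(a.sept_rainfall_mm, 6),
            groundwater=a.groundwater.value,
            cyclone_count=a.cyclone_count,
        )
    if results is not None and cell.cell_id in results:
        res = results[cell.cell_id]
        props.update(
            scores=dict(zip("abcdef", res.score_vector.as_tuple())),
            product=res.product,
            cvi=round(res.cvi, 2),
            cvi_class=res.cvi_class.value,
        )
    ring = [
        [lon_min, lat_min], [lon_max, lat_min],
        [lon_max, lat_max], [lon_min, lat_max], [lon_min, lat_min],
    ]
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": props,
    }


def write_cells_geojson(
    cells: Sequence[CoastalCell],
    path,
    results: Mapping[str, CviResult] | None = None,
) -> None:
    collection = {
        "type": "FeatureCollection",
        "features": [_cell_feature(cell, results) for cell in cells],
    }
    Path(path).write_text(json.dumps(collection, indent=1, sort_keys=True) + "\n")


def write_coastline_geojson(coastline: Coastline, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(coastline.shapely_lines),
            "properties": {"kind": "coastline"},
        }
    ]
    land = coastline.shapely_land
    if land is not None:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(land),
                "properties": {"kind": "land"},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n"
    )


def read_coastline_geojson(path) -> Coastline:
    return Coastline.from_geojson(json.loads(Path(path).read_text()))
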