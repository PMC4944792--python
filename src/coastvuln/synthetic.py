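"""Seeded synthetic coastal worlds with known ground truth.

The generator emulates the statistical structure of the real input
stack — an elevation model, a gridded population model, gridded
long-term September rainfall, a groundwater-salinity map and a
cyclone-track archive — without downloading any of them.  A near-
meridional coastline alternates *deltaic* segments (low, flat, densely
populated delta plain with saline groundwater, frequent cyclone
landfalls) with *beach/cliff* segments (steep, sparse, fresher
groundwater, rare landfalls), echoing the contrast between the large
Asian mega-deltas and the coasts between them.

Every attribute draw lands strictly inside one classifier band, with a
margin away from every class boundary, so the intended ordinal score
of each variable in each cell is known exactly ("ground truth") and a
pipeline run over the generated world must recover 100 % of the
scores.  Boundary behaviour of the classifiers is the business of
dedicated unit tests, not of the generator.

Cyclone ground truth is computed by the generator's own brute-force
loop over (aimed landfall point, cell centre) distances, independent
of the track parsing / landfall detection / counting path it is used
to validate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coastvuln.grid import (
    CellAttributes,
    Coastline,
    CoastalCell,
    Geomorphology,
    Groundwater,
    build_grid,
    great_circle_deg,
)
from coastvuln.classify import ScoreVector
from coastvuln.cvi import compute_cvi

#: attribute draw ranges per intended score, strictly inside the class
#: bands with a margin of at least one output-precision unit
ELEVATION_RANGES = {3: (-0.5, 1.9), 2: (2.1, 4.9), 1: (5.1, 45.0)}
POPULATION_RANGES = {1: (2.0, 95.0), 2: (105.0, 495.0), 3: (505.0, 2500.0)}
RAINFALL_RANGES = {3: (10.0, 145.0), 2: (155.0, 295.0), 1: (305.0, 600.0)}

_GEOMORPH_BY_SCORE = {
    1: Geomorphology.BEACH_CLIFF,
    2: Geomorphology.BEACH_RIVER_MOUTH,
    3: Geomorphology.DELTA_PLAIN_RIVER_MOUTH,
}
_GROUNDWATER_BY_SCORE = {
    1: Groundwater.FRESH_SHALLOW,
    2: Groundwater.SALINE_SHALLOW_FRESH_DEEP,
    3: Groundwater.SALINE_SHALLOW_AND_DEEP,
}


@dataclass(frozen=True)
class SegmentClassMix:
    """Score probabilities (index 0 -> score 1) for one segment class."""

    elevation: tuple[float, float, float]
    population: tuple[float, float, float]
    rainfall: tuple[float, float, float]
    geomorph: tuple[float, float, float]
    groundwater: tuple[float, float, float]
    cyclone_rate: float  # mean category >=1 landfalls aimed per cell over the record


#: delta plains: low and flat, densely settled, saline groundwater,
#: monsoon-fed rainfall, frequent landfalls over a 162-year record
DELTAIC_MIX = SegmentClassMix(
    elevation=(0.0, 0.2, 0.8),
    population=(0.0, 0.3, 0.7),
    rainfall=(0.3, 0.5, 0.2),
    geomorph=(0.0, 0.0, 1.0),
    groundwater=(0.15, 0.35, 0.5),
    cyclone_rate=8.0,
)

#: beach/cliff coasts: steep, sparse, fresher shallow groundwater
BEACH_MIX = SegmentClassMix(
    elevation=(0.8, 0.2, 0.0),
    population=(0.6, 0.35, 0.05),
    rainfall=(0.5, 0.4, 0.1),
    geomorph=(0.6, 0.4, 0.0),
    groundwater=(0.6, 0.3, 0.1),
    cyclone_rate=1.5,
)


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Parameters of one synthetic coastal world.

    The same seed and spec always reproduce the identical world.
    """

    seed: int = 0
    n_coast_segments: int = 8
    segment_length_deg: float = 1.0  # latitude extent per segment (2 half-degree cells)
    deltaic_fraction: float = 0.5
    lat_start: float = 10.0
    base_lon: float = 90.1
    wiggle_amplitude_deg: float = 0.05
    land_extent_deg: float = 3.0  # land stretches this far east of the coastline
    deltaic_mix: SegmentClassMix = DELTAIC_MIX
    beach_mix: SegmentClassMix = BEACH_MIX
    uncategorised_storm_rate: float = 0.3  # per cell, exercise the exclusion rule
    sub_threshold_storm_rate: float = 0.5  # category-0 storms per cell

    def __post_init__(self) -> None:
        if self.n_coast_segments < 1:
            raise ValueError("need at least one coastal segment")
        if not (0.0 <= self.deltaic_fraction <= 1.0):
            raise ValueError("deltaic_fraction must be in [0, 1]")

    def segment_is_deltaic(self, index: int) -> bool:
        """Bresenham-spread deltaic flags: evenly interleaved along the coast."""
        f = self.deltaic_fraction
        return math.floor((index + 1) * f) - math.floor(index * f) >= 1

    def lat_end(self) -> float:
        return self.lat_start + self.n_coast_segments * self.segment_length_deg


def make_coastline(spec: SyntheticWorldSpec) -> Coastline:
    """Gently sinuous near-meridional coastline with land to the east."""
    lats = np.round(np.arange(spec.lat_start, spec.lat_end() + 1e-9, 0.1), 10)
    lons = spec.base_lon + spec.wiggle_amplitude_deg * np.sin(2 * np.pi * lats / 2.0)
    line = tuple((float(lon), float(lat)) for lon, lat in zip(lons, lats))
    east = spec.base_lon + spec.land_extent_deg
    ring = line + ((east, float(lats[-1])), (east, float(lats[0])), line[0])
    return Coastline(polylines=(line,), land_polygon=(ring,))


def coastline_lon_at(spec: SyntheticWorldSpec, lat: float) -> float:
    """Longitude of the coastline at a given latitude (piecewise-linear)."""
    lats = np.round(np.arange(spec.lat_start, spec.lat_end() + 1e-9, 0.1), 10)
    lons = spec.base_lon + spec.wiggle_amplitude_deg * np.sin(2 * np.pi * lats / 2.0)
    return float(np.interp(lat, lats, lons))


def _segment_index(spec: SyntheticWorldSpec, lat: float) -> int:
    idx = int((lat - spec.lat_start) // spec.segment_length_deg)
    return min(max(idx, 0), spec.n_coast_segments - 1)


def _draw_score(rng: np.random.Generator, probs: tuple[float, float, float]) -> int:
    return int(rng.choice((1, 2, 3), p=np.asarray(probs) / sum(probs)))


def generate_world(
    spec: SyntheticWorldSpec,
) -> tuple[Coastline, list[CoastalCell], pd.DataFrame, pd.DataFrame]:
    """Generate a complete synthetic world.

    Returns
    -------
    coastline : Coastline
    cells : list of CoastalCell
        Fully attributed coastal cells (cyclone counts are the
        generator's ground-truth incidence).
    tracks : pandas.DataFrame
        Cyclone track records (storm_id, timestamp, lon, lat, category)
        in the same dialect the track reader consumes.
    ground_truth : pandas.DataFrame
        Per cell: the intended score of each variable, the implied CVI
        and class, and the ground-truth cyclone count.
    """
    coastline = make_coastline(spec)
    cells = build_grid(coastline)

    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    attr_rng = np.random.default_rng(seeds[0])

    tracks, aimed = _generate_storms(spec, cells, np.random.default_rng(seeds[1]))
    truth_counts = _brute_force_counts(aimed, cells)

    gt_rows = []
    attributed: list[CoastalCell] = []
    for cell in cells:
        mix = (
            spec.deltaic_mix
            if spec.segment_is_deltaic(_segment_index(spec, cell.center[1]))
            else spec.beach_mix
        )
        elev_score = _draw_score(attr_rng, mix.elevation)
        pop_score = _draw_score(attr_rng, mix.population)
        rain_score = _draw_score(attr_rng, mix.rainfall)
        geo_score = _draw_score(attr_rng, mix.geomorph)
        gw_score = _draw_score(attr_rng, mix.groundwater)

        count = truth_counts[cell.cell_id]
        cyc_score = 1 if count < 5 else (2 if count <= 10 else 3)

        attrs = CellAttributes(
            elevation_m=float(attr_rng.uniform(*ELEVATION_RANGES[elev_score])),
            geomorph=_GEOMORPH_BY_SCORE[geo_score],
            pop_density=float(attr_rng.uniform(*POPULATION_RANGES[pop_score])),
            sept_rainfall_mm=float(attr_rng.uniform(*RAINFALL_RANGES[rain_score])),
            groundwater=_GROUNDWATER_BY_SCORE[gw_score],
            cyclone_count=count,
        )
        attributed.append(cell.with_attributes(attrs))

        expected = compute_cvi(
            ScoreVector(a=elev_score, b=geo_score, c=cyc_score,
                        d=rain_score, e=gw_score, f=pop_score)
        )
        gt_rows.append(
            {
                "cell_id": cell.cell_id,
                "a": elev_score, "b": geo_score, "c": cyc_score,
                "d": rain_score, "e": gw_score, "f": pop_score,
                "cyclone_count": count,
                "cvi": round(expected.cvi, 2),
                "cvi_class": expected.cvi_class.value,
            }
        )
    return coastline, attributed, tracks, pd.DataFrame(gt_rows)


def generate_tracks(spec: SyntheticWorldSpec, coastline: Coastline) -> pd.DataFrame:
    """Synthetic cyclone-track records aimed at the given coastline."""
    cells = build_grid(coastline)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    tracks, _ = _generate_storms(spec, cells, rng)
    return tracks


def _generate_storms(
    spec: SyntheticWorldSpec, cells: list[CoastalCell], rng: np.random.Generator
) -> tuple[pd.DataFrame, list[tuple[str, float, float, int]]]:
    """Draw storms aimed at each cell's stretch of coastline.

    Per cell the number of category >=1 landfalls is Poisson with the
    segment-class rate; category-0 and uncategorised storms are added
    at their own rates to exercise the filtering rules.  Each storm is
    a straight west-to-east 6-hourly track whose sea-to-land crossing
    is the aimed landfall point.

    Returns the track table plus the aimed (storm_id, lon, lat,
    category) list for the counting oracle (category >=1 only).
    """
    rows: list[dict] = []
    aimed: list[tuple[str, float, float, int]] = []
    storm_no = 0
    base_time = pd.Timestamp("1851-06-01 00:00")

    for cell in cells:
        lat_c = cell.center[1]
        mix = (
            spec.deltaic_mix
            if spec.segment_is_deltaic(_segment_index(spec, lat_c))
            else spec.beach_mix
        )
        n_hit = rng.poisson(mix.cyclone_rate)
        n_weak = rng.poisson(spec.sub_threshold_storm_rate)
        n_uncat = rng.poisson(spec.uncategorised_storm_rate)

        for kind, n in (("hit", n_hit), ("weak", n_weak), ("uncat", n_uncat)):
            for _ in range(n):
                storm_no += 1
                storm_id = f"S{storm_no:05d}"
                # rounded before use so the CSV and the counting oracle
                # see the identical landfall coordinates
                lf_lat = round(lat_c + float(rng.uniform(-0.05, 0.05)), 6)
                lf_lon = round(coastline_lon_at(spec, lf_lat), 6)
                if kind == "hit":
                    category: int | None = int(rng.integers(1, 6))
                    aimed.append((storm_id, lf_lon, lf_lat, category))
                elif kind == "weak":
                    category = 0
                else:
                    category = None
                start = base_time + pd.Timedelta(days=float(storm_no % 3650))
                # straight 6-hourly track: three fixes at sea, one inland
                fix_lons = (lf_lon - 2.4, lf_lon - 1.6, lf_lon - 0.8, lf_lon + 0.8)
                for k, lon in enumerate(fix_lons):
                    rows.append(
                        {
                            "storm_id": storm_id,
                            "timestamp": start + pd.Timedelta(hours=6 * k),
                            "lon": round(lon, 6),
                            "lat": round(lf_lat, 6),
                            "category": "" if category is None else category,
                        }
                    )
    tracks = pd.DataFrame(
        rows, columns=["storm_id", "timestamp", "lon", "lat", "category"]
    )
    return tracks, aimed


def _brute_force_counts(
    aimed: list[tuple[str, float, float, int]],
    cells: list[CoastalCell],
    impact_halfwidth_deg: float = 1.0,
) -> dict[str, int]:
    """Ground-truth incidence: plain double loop over events and cells."""
    counts = {cell.cell_id: 0 for cell in cells}
    for _storm_id, lon, lat, _cat in aimed:
        for cell in cells:
            lon_c, lat_c = cell.center
            if great_circle_deg(lon, lat, lon_c, lat_c) <= impact_halfwidth_deg:
                counts[cell.cell_id] += 1
    return counts
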