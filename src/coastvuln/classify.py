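"""Ordinal vulnerability classifiers for the six index variables.

Each classifier maps a raw cell attribute to a score in {1, 2, 3}
(1 = low, 2 = moderate, 3 = high vulnerability).  The default class
boundaries:

==================  ===============  ==================  ==================
variable            low (1)          moderate (2)        high (3)
==================  ===============  ==================  ==================
cyclone landfalls   < 5              5 - 10 (inclusive)  > 10
elevation (m amsl)  >= 5             > 2 and < 5         <= 2
geomorphology       beach w/ cliff   beach w/ river      delta plain w/
                                     mouth               river mouth
population /km^2    < 100            100 - 500 (incl.)   > 500
Sept rainfall (mm)  > 300            150 - 300 (incl.)   < 150
groundwater         fresh shallow    saline shallow,     saline shallow
                                     fresh deep          and deep
==================  ===============  ==================  ==================

Elevation and rainfall score *decreasing* vulnerability with increasing
value (height protects against inundation, rainfall supports rainwater
harvesting); cyclone incidence and population density score increasing
vulnerability.  All thresholds live in :class:`ClassifierThresholds` so
a run manifest can record exactly which boundaries were applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from coastvuln.grid import CellAttributes, Geomorphology, Groundwater


@dataclass(frozen=True)
class ScoreVector:
    """The six ordinal scores feeding the index.

    a = elevation, b = geomorphology, c = cyclone incidence,
    d = rainfall, e = groundwater availability, f = population density;
    each component in {1, 2, 3}.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value not in (1, 2, 3):
                raise ValueError(f"score component {name}={value!r} not in {{1,2,3}}")

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    def as_dict(self) -> dict[str, int]:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d, "e": self.e, "f": self.f}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Class boundaries for the four numeric classifiers.

    Defaults reproduce the standard boundary table; the moderate band is
    closed for cyclones, population and rainfall, while elevation is
    high at <= 2 m and low at >= 5 m.
    """

    cyclone_moderate_min: int = 5
    cyclone_moderate_max: int = 10
    elevation_high_max_m: float = 2.0
    elevation_low_min_m: float = 5.0
    population_moderate_min: float = 100.0
    population_moderate_max: float = 500.0
    rainfall_moderate_min_mm: float = 150.0
    rainfall_moderate_max_mm: float = 300.0

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


DEFAULT_THRESHOLDS = ClassifierThresholds()

_GEOMORPH_SCORE = {
    Geomorphology.BEACH_CLIFF: 1,
    Geomorphology.BEACH_RIVER_MOUTH: 2,
    Geomorphology.DELTA_PLAIN_RIVER_MOUTH: 3,
}

_GROUNDWATER_SCORE = {
    Groundwater.FRESH_SHALLOW: 1,
    Groundwater.SALINE_SHALLOW_FRESH_DEEP: 2,
    Groundwater.SALINE_SHALLOW_AND_DEEP: 3,
}


def classify_cyclone(count: int, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> int:
    """Score cyclone landfall incidence: <5 low, 5-10 moderate, >10 high."""
    if count < 0:
        raise ValueError("cyclone count must be >= 0")
    if count < thresholds.cyclone_moderate_min:
        return 1
    if count <= thresholds.cyclone_moderate_max:
        return 2
    return 3


def classify_elevation(elev_m: float, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> int:
    """Score representative elevation: <=2 m high, >2-<5 m moderate, >=5 m low.

    Negative elevations (subsided land) are valid and score high.
    """
    if not math.isfinite(elev_m):
        raise ValueError("elevation must be finite")
    if elev_m <= thresholds.elevation_high_max_m:
        return 3
    if elev_m < thresholds.elevation_low_min_m:
        return 2
    return 1


def classify_geomorphology(geo: Geomorphology) -> int:
    """Score the landform category: cliffed beach 1, beach with river mouth 2, delta plain 3."""
    try:
        return _GEOMORPH_SCORE[Geomorphology(geo)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown geomorphology category {geo!r}") from exc


def classify_population(density: float, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> int:
    """Score population density: <100 low, 100-500 moderate, >500 people/km^2 high."""
    if density < 0:
        raise ValueError("population density must be >= 0")
    if density < thresholds.population_moderate_min:
        return 1
    if density <= thresholds.population_moderate_max:
        return 2
    return 3


def classify_rainfall(sept_mm: float, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> int:
    """Score mean September rainfall: >300 mm low, 150-300 moderate, <150 high."""
    if sept_mm < 0:
        raise ValueError("rainfall must be >= 0")
    if sept_mm > thresholds.rainfall_moderate_max_mm:
        return 1
    if sept_mm >= thresholds.rainfall_moderate_min_mm:
        return 2
    return 3


def classify_groundwater(gw: Groundwater) -> int:
    """Score groundwater: fresh shallow 1, saline over fresh deep 2, saline throughout 3."""
    try:
        return _GROUNDWATER_SCORE[Groundwater(gw)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown groundwater category {gw!r}") from exc


def score_cell(
    attrs: CellAttributes, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
) -> ScoreVector:
    """Apply all six classifiers to one cell's attributes."""
    missing = [
        name
        for name in (
            "elevation_m", "geomorph", "pop_density",
            "sept_rainfall_mm", "groundwater", "cyclone_count",
        )
        if getattr(attrs, name, None) is None
    ]
    if missing:
        raise ValueError(f"missing cell attribute(s): {', '.join(missing)}")
    return ScoreVector(
        a=classify_elevation(attrs.elevation_m, thresholds),
        b=classify_geomorphology(attrs.geomorph),
        c=classify_cyclone(attrs.cyclone_count, thresholds),
        d=classify_rainfall(attrs.sept_rainfall_mm, thresholds),
        e=classify_groundwater(attrs.groundwater),
        f=classify_population(attrs.pop_density, thresholds),
    )


def harvest_volume(rain_mm: float, roof_area_m2: float, runoff_coeff: float = 1.0) -> float:
    """Rooftop rainwater harvest in litres: rain_mm x roof_area_m2 x runoff_coeff.

    1 mm of rain on 1 m^2 yields 1 litre.  The default runoff
    coefficient of 1.0 gives the loss-free upper bound (300 mm on a
    20 m^2 roof -> 6000 l, about 4-6 months of drinking water for a
    five-person household); real collection systems lose some water, so
    pass a coefficient < 1 for net yield.
    """
    if rain_mm <= 0 or roof_area_m2 <= 0:
        raise ValueError("rain_mm and roof_area_m2 must be positive")
    if not (0.0 < runoff_coeff <= 1.0):
        raise ValueError("runoff_coeff must be in (0, 1]")
    return rain_mm * roof_area_m2 * runoff_coeff
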