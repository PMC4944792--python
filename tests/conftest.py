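import pytest

from coastvuln.grid import CellAttributes, CoastalCell, Coastline, Geomorphology, Groundwater
from coastvuln.synthetic import SyntheticWorldSpec, generate_world


@pytest.fixture(scope="session")
def meridian_coastline() -> Coastline:
    """Straight coastline along lon 90 from lat 20 to 22, land to the east."""
    line = tuple((90.0, round(20.0 + 0.1 * i, 10)) for i in range(21))
    ring = line + ((93.0, 22.0), (93.0, 20.0), line[0])
    return Coastline(polylines=(line,), land_polygon=(ring,))


@pytest.fixture(scope="session")
def synthetic_world():
    """One fixed synthetic world shared by read-only tests."""
    return generate_world(SyntheticWorldSpec(seed=1))


def make_cell(row=40, col=180, length_km=50.0, land_fraction=0.5, attrs=None) -> CoastalCell:
    return CoastalCell(
        row=row,
        col=col,
        bounds=(col * 0.5, row * 0.5, (col + 1) * 0.5, (row + 1) * 0.5),
        coastline_length_km=length_km,
        land_fraction=land_fraction,
        attributes=attrs,
    )


def make_attrs(
    elevation_m=1.0,
    geomorph=Geomorphology.DELTA_PLAIN_RIVER_MOUTH,
    pop_density=1200.0,
    sept_rainfall_mm=140.0,
    groundwater=Groundwater.SALINE_SHALLOW_AND_DEEP,
    cyclone_count=12,
) -> CellAttributes:
    return CellAttributes(
        elevation_m=elevation_m,
        geomorph=geomorph,
        pop_density=pop_density,
        sept_rainfall_mm=sept_rainfall_mm,
        groundwater=groundwater,
        cyclone_count=cyclone_count,
    )
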