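"""Climate-change scenario projection of cell attributes to 2050/2100.

A scenario is a small set of attribute adjustments: a population
multiplier, an elevation offset (negative = effective land-height loss
through sea-level rise) and a rainfall multiplier.  The built-in
scenarios encode the mid- and end-century projections — population
40 % (2050) and 35 % (2100) above 2010, sea-level rise lowering
effective elevation by 0.2 m and 0.6 m, and rainfall up 5 % and 10 %.
Both multipliers are relative to the 2010 baseline, not compounded.
Cyclone incidence, geomorphology and groundwater category are expected
not to change at this scale and are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from coastvuln.classify import ClassifierThresholds, DEFAULT_THRESHOLDS
from coastvuln.cvi import CviResult, assess_cells
from coastvuln.grid import CellAttributes, CoastalCell


@dataclass(frozen=True)
class ScenarioSpec:
    """Multiplicative/additive attribute adjustments for one projection year."""

    label: str
    pop_multiplier: float = 1.0
    elevation_offset_m: float = 0.0
    rainfall_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.pop_multiplier <= 0:
            raise ValueError("pop_multiplier must be > 0")
        if self.rainfall_multiplier <= 0:
            raise ValueError("rainfall_multiplier must be > 0")

    def inverted(self) -> "ScenarioSpec":
        """The adjustment that undoes this one (for round-trip checks)."""
        return ScenarioSpec(
            label=f"{self.label}-inverse",
            pop_multiplier=1.0 / self.pop_multiplier,
            elevation_offset_m=-self.elevation_offset_m,
            rainfall_multiplier=1.0 / self.rainfall_multiplier,
        )


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """The 2050 and 2100 projections, both relative to the 2010 baseline."""
    return {
        "2050": ScenarioSpec("2050", pop_multiplier=1.40, elevation_offset_m=-0.2,
                             rainfall_multiplier=1.05),
        "2100": ScenarioSpec("2100", pop_multiplier=1.35, elevation_offset_m=-0.6,
                             rainfall_multiplier=1.10),
    }


def apply_scenario(attrs: CellAttributes, spec: ScenarioSpec) -> CellAttributes:
    """Project one cell's attributes; the input is not mutated.

    elevation += offset, population *= multiplier, rainfall *= multiplier;
    geomorphology, groundwater and cyclone count are copied unchanged.
    """
    return replace(
        attrs,
        elevation_m=attrs.elevation_m + spec.elevation_offset_m,
        pop_density=attrs.pop_density * spec.pop_multiplier,
        sept_rainfall_mm=attrs.sept_rainfall_mm * spec.rainfall_multiplier,
    )


def project_assessment(
    cells: Sequence[CoastalCell],
    spec: ScenarioSpec,
    baseline: Mapping[str, CviResult] | None = None,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> tuple[dict[str, CviResult], pd.DataFrame]:
    """Re-assess all cells under a scenario and tabulate class transitions.

    Returns the projected per-cell results and a delta table with one
    row per assessed cell: baseline and scenario class, the transition
    direction (``unchanged`` / ``up`` / ``down``) and the names of the
    score components that changed.
    """
    if baseline is None:
        baseline = assess_cells(cells, thresholds)
    projected_cells = [
        cell.with_attributes(apply_scenario(cell.attributes, spec))
        if cell.attributes is not None
        else cell
        for cell in cells
    ]
    projected = assess_cells(projected_cells, thresholds)

    order = {"LOW": 0, "MODERATE": 1, "HIGH": 2}
    rows = []
    for cell_id, base in baseline.items():
        proj = projected[cell_id]
        delta = order[proj.cvi_class.value] - order[base.cvi_class.value]
        changed = [
            name
            for name, (b, p) in zip(
                "abcdef", zip(base.score_vector.as_tuple(), proj.score_vector.as_tuple())
            )
            if b != p
        ]
        rows.append(
            {
                "cell_id": cell_id,
                "baseline_class": base.cvi_class.value,
                "scenario_class": proj.cvi_class.value,
                "baseline_cvi": round(base.cvi, 2),
                "scenario_cvi": round(proj.cvi, 2),
                "transition": "unchanged" if delta == 0 else ("up" if delta > 0 else "down"),
                "changed_components": "".join(changed),
            }
        )
    return projected, pd.DataFrame(rows)
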