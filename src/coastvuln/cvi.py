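"""The Coastal Vulnerability Index and its score-space analyses.

The six ordinal scores a..f (elevation, geomorphology, cyclone
frequency, rainfall, groundwater availability, population density; each
1-3) are combined as

    CVI = sqrt(a * b * c * d * e * f / 6)

the square root of the mean of the product (after Gornitz-style
sensitivity indexing).  Over the full 3^6 = 729 score space the index
ranges from sqrt(1/6) ~ 0.41 to sqrt(729/6) ~ 11.02.  Cells are placed
in three classes using the CVI of two pivotal combinations as upper
limits: 1.73 (three lows, one moderate, two highs: product 18) closes
the LOW class and 3.27 (all moderate: product 2^6 = 64) closes the
MODERATE class.  Classification is implemented on the exact integer
product (<= 18, <= 64) so no floating-point edge case can move a cell
across a class limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import product as iter_product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coastvuln.classify import ClassifierThresholds, DEFAULT_THRESHOLDS, ScoreVector, score_cell
from coastvuln.grid import CoastalCell

#: integer products whose CVI values (1.73 and 3.27) close the LOW and MODERATE classes
LOW_PRODUCT_LIMIT = 18
MODERATE_PRODUCT_LIMIT = 64


class VulnClass(str, Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class CviResult:
    score_vector: ScoreVector
    product: int
    cvi: float
    cvi_class: VulnClass


def compute_cvi(s: ScoreVector) -> CviResult:
    """Evaluate the index for one score vector and classify it."""
    prod = 1
    for component in s.as_tuple():
        prod *= component
    cvi = math.sqrt(prod / 6.0)
    return CviResult(score_vector=s, product=prod, cvi=cvi, cvi_class=_class_of_product(prod))


def _class_of_product(prod: int) -> VulnClass:
    if prod <= LOW_PRODUCT_LIMIT:
        return VulnClass.LOW
    if prod <= MODERATE_PRODUCT_LIMIT:
        return VulnClass.MODERATE
    return VulnClass.HIGH


def classify_cvi(r: CviResult) -> VulnClass:
    """Class of a result: LOW for product <= 18, MODERATE <= 64, else HIGH.

    The limits are the products behind CVI 1.73 and 3.27; both limit
    combinations fall on the lower side of their boundary.
    """
    return _class_of_product(r.product)


def enumerate_score_space() -> pd.DataFrame:
    """Tabulate the index over all 3^6 = 729 score combinations.

    Returns a DataFrame with columns a..f, product, cvi and cvi_class,
    one row per combination in lexicographic order.
    """
    rows = []
    for combo in iter_product((1, 2, 3), repeat=6):
        res = compute_cvi(ScoreVector(*combo))
        rows.append(combo + (res.product, res.cvi, res.cvi_class.value))
    return pd.DataFrame(rows, columns=["a", "b", "c", "d", "e", "f", "product", "cvi", "cvi_class"])


def score_space_summary(table: pd.DataFrame | None = None) -> dict:
    """Class counts and the distinct-CVI histogram of the enumeration."""
    if table is None:
        table = enumerate_score_space()
    hist = table.round({"cvi": 2}).groupby("cvi").size()
    return {
        "n_combinations": int(len(table)),
        "cvi_min": round(float(table["cvi"].min()), 2),
        "cvi_max": round(float(table["cvi"].max()), 2),
        "class_counts": table["cvi_class"].value_counts().to_dict(),
        "distinct_cvi_histogram": {f"{k:.2f}": int(v) for k, v in hist.items()},
    }


def compare_aggregators(table: pd.DataFrame) -> dict:
    """Contrast the multiplicative index with the arithmetic mean.

    Adds a ``mean`` column ((a+..+f)/6) to a copy of the enumeration
    table and reports the Spearman rank correlation between the two
    aggregators and the number of combination pairs they order
    differently (one strictly larger under CVI but strictly smaller
    under the mean, or vice versa).
    """
    table = table.copy()
    table["mean"] = table[["a", "b", "c", "d", "e", "f"]].mean(axis=1)
    cvi = table["cvi"].to_numpy()
    mean = table["mean"].to_numpy()
    rho = float(stats.spearmanr(cvi, mean).statistic)
    dc = np.sign(cvi[:, None] - cvi[None, :])
    dm = np.sign(mean[:, None] - mean[None, :])
    discordant = int(np.count_nonzero((dc * dm) < 0) // 2)
    return {"table": table, "spearman_rho": rho, "n_discordant_pairs": discordant}


def assess_cells(
    cells: Sequence[CoastalCell],
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, CviResult]:
    """Score and index every coastal cell.

    Applies the six classifiers followed by the index to each coastal
    cell; non-coastal cells are skipped.  Raises if any coastal cell
    lacks attributes, listing the offending cell ids.
    """
    coastal = [c for c in cells if c.is_coastal]
    unattributed = [c.cell_id for c in coastal if c.attributes is None]
    if unattributed:
        raise ValueError(f"unattributed coastal cell(s): {', '.join(unattributed)}")
    return {
        cell.cell_id: compute_cvi(score_cell(cell.attributes, thresholds))
        for cell in coastal
    }


def results_frame(cells: Sequence[CoastalCell], results: Mapping[str, CviResult]) -> pd.DataFrame:
    """Flatten per-cell results into the standard output table."""
    rows = []
    for cell in cells:
        res = results.get(cell.cell_id)
        if res is None:
            continue
        s = res.score_vector
        rows.append(
            {
                "cell_id": cell.cell_id,
                "row": cell.row,
                "col": cell.col,
                "lon_min": cell.bounds[0],
                "lat_min": cell.bounds[1],
                "lon_max": cell.bounds[2],
                "lat_max": cell.bounds[3],
                "coastline_length_km": cell.coastline_length_km,
                "a": s.a, "b": s.b, "c": s.c, "d": s.d, "e": s.e, "f": s.f,
                "product": res.product,
                "cvi": round(res.cvi, 2),
                "cvi_class": res.cvi_class.value,
            }
        )
    return pd.DataFrame(rows)
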