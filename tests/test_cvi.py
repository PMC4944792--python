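"""The index, its classification limits and the 729-combination analyses."""

import math
from itertools import product

import numpy as np
import pytest

from coastvuln.classify import ScoreVector
from coastvuln.cvi import (
    LOW_PRODUCT_LIMIT,
    MODERATE_PRODUCT_LIMIT,
    VulnClass,
    assess_cells,
    classify_cvi,
    compare_aggregators,
    compute_cvi,
    enumerate_score_space,
    score_space_summary,
)
from coastvuln.grid import Geomorphology, Groundwater
from conftest import make_attrs, make_cell


class TestComputeCvi:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ((1, 1, 1, 1, 1, 1), 0.41),
            ((3, 3, 3, 3, 3, 3), 11.02),
            ((1, 1, 1, 2, 3, 3), 1.73),
            ((2, 2, 2, 2, 2, 2), 3.27),
        ],
    )
    def test_known_index_values(self, scores, expected):
        assert round(compute_cvi(ScoreVector(*scores)).cvi, 2) == expected

    def test_cvi_equals_sqrt_product_mean(self):
        res = compute_cvi(ScoreVector(1, 2, 3, 1, 2, 3))
        assert res.product == 36
        assert res.cvi == pytest.approx(math.sqrt(36 / 6), abs=1e-12)

    def test_permutation_symmetry(self):
        base = (1, 2, 3, 3, 2, 1)
        reference = compute_cvi(ScoreVector(*base)).cvi
        for perm in [(3, 3, 2, 2, 1, 1), (2, 1, 3, 1, 2, 3), (1, 1, 2, 2, 3, 3)]:
            assert compute_cvi(ScoreVector(*perm)).cvi == pytest.approx(reference, abs=0)


class TestClassification:
    def test_limit_products_close_their_classes(self):
        low_limit = compute_cvi(ScoreVector(1, 1, 1, 2, 3, 3))  # product 18, CVI 1.73
        assert low_limit.product == LOW_PRODUCT_LIMIT
        assert classify_cvi(low_limit) is VulnClass.LOW
        mod_limit = compute_cvi(ScoreVector(2, 2, 2, 2, 2, 2))  # product 64, CVI 3.27
        assert mod_limit.product == MODERATE_PRODUCT_LIMIT
        assert classify_cvi(mod_limit) is VulnClass.MODERATE

    def test_smallest_product_above_moderate_limit_is_high(self):
        # enumeration oracle: smallest attainable product > 64
        products = sorted({np.prod(c) for c in product((1, 2, 3), repeat=6)})
        smallest_above = min(p for p in products if p > MODERATE_PRODUCT_LIMIT)
        assert smallest_above == 72
        assert classify_cvi(compute_cvi(ScoreVector(2, 2, 2, 3, 3, 1))) is VulnClass.HIGH

    def test_integer_product_rule_matches_float_thresholds_everywhere(self):
        low_edge = math.sqrt(LOW_PRODUCT_LIMIT / 6)
        mod_edge = math.sqrt(MODERATE_PRODUCT_LIMIT / 6)
        for combo in product((1, 2, 3), repeat=6):
            res = compute_cvi(ScoreVector(*combo))
            if res.cvi <= low_edge + 1e-12:
                expected = VulnClass.LOW
            elif res.cvi <= mod_edge + 1e-12:
                expected = VulnClass.MODERATE
            else:
                expected = VulnClass.HIGH
            assert res.cvi_class is expected, combo


class TestEnumeration:
    def test_full_score_space(self):
        table = enumerate_score_space()
        assert len(table) == 3**6 == 729
        assert round(table["cvi"].min(), 2) == 0.41
        assert round(table["cvi"].max(), 2) == 11.02

    def test_all_values_inside_theoretical_range(self):
        table = enumerate_score_space()
        assert (table["cvi"] >= 0.408).all()
        assert (table["cvi"] <= 11.023).all()

    def test_monotone_in_every_component(self):
        table = enumerate_score_space().set_index(["a", "b", "c", "d", "e", "f"])
        order = {"LOW": 0, "MODERATE": 1, "HIGH": 2}
        for combo in product((1, 2, 3), repeat=6):
            for k in range(6):
                if combo[k] == 3:
                    continue
                bumped = combo[:k] + (combo[k] + 1,) + combo[k + 1:]
                assert table.loc[bumped, "cvi"] >= table.loc[combo, "cvi"]
                assert (
                    order[table.loc[bumped, "cvi_class"]]
                    >= order[table.loc[combo, "cvi_class"]]
                )

    def test_summary_counts(self):
        summary = score_space_summary()
        assert summary["n_combinations"] == 729
        assert summary["cvi_min"] == 0.41
        assert summary["cvi_max"] == 11.02
        assert sum(summary["class_counts"].values()) == 729
        # class counts agree with a direct count on the product rule
        table = enumerate_score_space()
        assert summary["class_counts"]["LOW"] == int((table["product"] <= 18).sum())
        assert summary["class_counts"]["HIGH"] == int((table["product"] > 64).sum())
        # the index distribution is right-skewed: few combinations reach
        # the top of the range
        assert (table["cvi"] > 5.0).mean() < 0.25


class TestCompareAggregators:
    def test_closed_form_rows(self):
        comp = compare_aggregators(enumerate_score_space())
        table = comp["table"]
        all_low = table[(table[list("abcdef")] == 1).all(axis=1)].iloc[0]
        assert all_low["mean"] == pytest.approx(1.0)
        assert round(all_low["cvi"], 2) == 0.41
        all_high = table[(table[list("abcdef")] == 3).all(axis=1)].iloc[0]
        assert all_high["mean"] == pytest.approx(3.0)
        assert round(all_high["cvi"], 2) == 11.02

    def test_both_aggregators_increase_on_single_bump(self):
        comp = compare_aggregators(enumerate_score_space())
        t = comp["table"].set_index(["a", "b", "c", "d", "e", "f"])
        base, bumped = (1, 1, 1, 1, 1, 1), (1, 1, 1, 1, 1, 2)
        assert t.loc[bumped, "cvi"] > t.loc[base, "cvi"]
        assert t.loc[bumped, "mean"] > t.loc[base, "mean"]

    def test_rank_correlation_strong_but_imperfect(self):
        comp = compare_aggregators(enumerate_score_space())
        assert 0.9 < comp["spearman_rho"] < 1.0
        assert comp["n_discordant_pairs"] > 0  # product and mean do disagree


class TestAssessCells:
    def test_three_cell_low_mid_high(self):
        low = make_attrs(elevation_m=10, geomorph=Geomorphology.BEACH_CLIFF,
                         pop_density=10, sept_rainfall_mm=400,
                         groundwater=Groundwater.FRESH_SHALLOW, cyclone_count=0)
        mid = make_attrs(elevation_m=2.5, geomorph=Geomorphology.BEACH_RIVER_MOUTH,
                         pop_density=300, sept_rainfall_mm=200,
                         groundwater=Groundwater.SALINE_SHALLOW_FRESH_DEEP, cyclone_count=6)
        high = make_attrs()
        cells = [
            make_cell(row=40, attrs=low),
            make_cell(row=41, attrs=mid),
            make_cell(row=42, attrs=high),
        ]
        results = assess_cells(cells)
        assert results[cells[0].cell_id].cvi_class is VulnClass.LOW
        assert results[cells[1].cell_id].cvi_class is VulnClass.MODERATE
        assert results[cells[2].cell_id].cvi_class is VulnClass.HIGH

    def test_empty_and_noncoastal_cells(self):
        assert assess_cells([]) == {}
        inland = make_cell(length_km=0.0, attrs=None)  # not coastal -> skipped
        assert assess_cells([inland]) == {}

    def test_unattributed_coastal_cell_reported_by_id(self):
        bare = make_cell(row=44)
        with pytest.raises(ValueError, match=bare.cell_id):
            assess_cells([bare])
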