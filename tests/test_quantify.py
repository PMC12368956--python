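"""Areas, percentages, cross-case means and site bookkeeping, including the
published-table arithmetic they must reproduce."""

import numpy as np
import pytest
from shapely.geometry import box

from cortimap import datasets
from cortimap.quantify import (
    QuantifyError,
    area_table,
    area_table_from_measurements,
    cross_case_summary,
    movement_area,
    round_half_away,
    site_count_summary,
)
from cortimap.tessellation import CaseMap, Cell
from cortimap.taxonomy import MovementLabel

from conftest import make_site


def toy_map(cell_specs, case_id="K1", region=None):
    """CaseMap from (area-rectangle, labels) specs laid out side by side."""
    cells = []
    x = 0.0
    for i, (width, parts) in enumerate(cell_specs):
        poly = box(x, 0, x + width, 1)  # area == width
        labels = frozenset(MovementLabel(p) for p in parts)
        cells.append(Cell(f"s{i}", poly, labels, (x + width / 2, 0.5)))
        x += width
    region = region or box(0, 0, x, 1)
    return CaseMap(case_id, (), None, region, tuple(cells))


class TestMovementArea:
    def test_absent_movement_is_zero(self):
        cm = toy_map([(1.0, ("tongue",))])
        assert movement_area(cm, "digit") == 0.0

    def test_multi_label_cell_fully_attributed_to_each(self):
        cm = toy_map([(4.0, ("shoulder", "digit"))])
        assert movement_area(cm, "shoulder") == pytest.approx(4.0)
        assert movement_area(cm, "digit") == pytest.approx(4.0)

    def test_direction_ignored_by_body_part_selector(self):
        cells = toy_map([(2.0, ())]).cells
        cm = CaseMap(
            "K1",
            (),
            None,
            box(0, 0, 2, 1),
            (Cell("s0", box(0, 0, 2, 1), frozenset({MovementLabel("tongue", "retraction")})),),
        )
        assert movement_area(cm, "tongue") == pytest.approx(2.0)

    def test_unknown_body_part_rejected_with_taxonomy(self, taxonomy):
        cm = toy_map([(1.0, ("tongue",))])
        with pytest.raises(QuantifyError, match="unknown body part"):
            movement_area(cm, "tail", taxonomy)

    def test_planted_area_recovered(self):
        cm = toy_map([(2.5, ("tongue",)), (1.5, ("tongue",)), (3.0, ("lips",)), (1.0, ())])
        assert movement_area(cm, "tongue") == pytest.approx(4.0, rel=1e-9)


class TestAreaTable:
    def test_percent_against_union_denominator(self):
        cm = toy_map([(3.0, ("tongue",)), (1.0, ("tongue", "lips")), (4.0, ()), (2.0, ("lips",))])
        table = area_table([cm], ["tongue", "lips"])
        # denominator is the union of labelled cells (6), not the region (10)
        assert table.all_mm2["K1"] == pytest.approx(6.0)
        assert table.percent.loc["K1", "tongue"] == pytest.approx(100 * 4 / 6)

    def test_area_equal_to_denominator_is_100(self):
        cm = toy_map([(5.0, ("tongue",))])
        table = area_table([cm], ["tongue"])
        assert table.reported_percent().loc["K1", "tongue"] == 100.0

    def test_zero_responsive_area_flagged(self):
        cm = toy_map([(1.0, ()), (2.0, ())])
        table = area_table([cm], ["tongue"])
        assert "K1" in table.flags
        assert np.isnan(table.percent.loc["K1", "tongue"])

    @pytest.mark.parametrize(
        "case, movement, expected_pct",
        [
            ("K22-03", "shoulder", 32.2),
            ("K22-03", "digit", 9.3),
            ("K22-05", "shoulder", 26.9),
            ("K22-05", "digit", 4.7),
            ("K22-05", "tongue", 24.5),
        ],
    )
    def test_published_percent_cells(self, case, movement, expected_pct):
        """Reported percents reproduce the internally consistent printed
        cells of the study's magnification table."""
        table = datasets.representation_area_table()
        assert table.reported_percent().loc[case, movement] == expected_pct

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(5.25) == 5.3
        assert round_half_away(0.05) == 0.1
        assert round_half_away(-0.05) == -0.1
        assert round_half_away(32.2061) == 32.2


class TestCrossCaseSummary:
    def test_mean_of_reported_percents(self):
        # per-case shoulder percents 32.2/40.1/26.9/40.8 -> 35.0
        table = area_table_from_measurements(
            {
                "a": {"shoulder": 32.2},
                "b": {"shoulder": 40.1},
                "c": {"shoulder": 26.9},
                "d": {"shoulder": 40.8},
            },
            {"a": 100.0, "b": 100.0, "c": 100.0, "d": 100.0},
        )
        assert cross_case_summary(table)["shoulder"] == 35.0

    def test_published_all_cases_means(self):
        table = datasets.representation_area_table()
        means = cross_case_summary(table)
        assert means["shoulder"] == 35.0
        assert means["digit"] == 5.3
        assert means["tongue"] == 29.5

    def test_single_case_mean_is_its_own_percent(self):
        table = area_table_from_measurements({"a": {"tongue": 30.9}}, {"a": 81.6})
        assert cross_case_summary(table)["tongue"] == table.reported_percent().loc["a", "tongue"]


def stub_case(case_id, group_counts, threshold_sites, total_sites):
    """Stub sites reproducing given bookkeeping: per-group movement sites,
    of which ``threshold_sites`` carry resolvable staircases."""
    group_field = {"PM/M1": "M1", "3a": "3a", "3b": "3b", "1/2/PPC": "PPC"}
    sites = []
    with_threshold = threshold_sites
    for gname, count in group_counts.items():
        for i in range(count):
            if with_threshold > 0:
                site = make_site(
                    f"{gname}-{i}", (i, 0), parts=("tongue",), case_id=case_id,
                    field=group_field[gname],
                )
                with_threshold -= 1
            else:  # movement site whose staircase did not bracket
                lab = MovementLabel("tongue")
                from cortimap.protocol import StimTrial

                site = make_site(
                    f"{gname}-{i}", (i, 0), parts=(lab,), case_id=case_id,
                    field=group_field[gname],
                    trials={lab: (StimTrial(70, False), StimTrial(120, True))},
                )
            sites.append(site)
    movement = sum(group_counts.values())
    for i in range(total_sites - movement):
        sites.append(make_site(f"nr-{i}", (i, 1), case_id=case_id))
    return sites


class TestSiteCountSummary:
    def test_published_bookkeeping_totals(self):
        """Stub cases with the published per-case bookkeeping pool to 633
        total, 541 movement and 521 threshold sites."""
        counts = datasets.site_counts()
        groups = datasets.field_group_counts()
        cases = {
            case: stub_case(
                case,
                groups.loc[case].to_dict(),
                counts.loc[case, "threshold_sites"],
                counts.loc[case, "total_sites"],
            )
            for case in datasets.CASES
        }
        summary = site_count_summary(cases)
        assert summary.loc["all", "total_sites"] == 633
        assert summary.loc["all", "movement_sites"] == 541
        assert summary.loc["all", "threshold_sites"] == 521
        group_cols = [c for c in summary.columns if c.startswith("movement_sites[")]
        assert summary.loc["all", group_cols].sum() == 541

    def test_additive_under_case_split(self):
        sites = [make_site(f"s{i}", (i, 0), parts=("tongue",), field="3b") for i in range(6)]
        whole = site_count_summary({"K1": sites})
        halves = site_count_summary({"K1a": sites[:3], "K1b": sites[3:]})
        assert whole.loc["all", "movement_sites"] == halves.loc["all", "movement_sites"]
        assert whole.loc["all", "total_sites"] == halves.loc["all", "total_sites"]

    def test_empty_input_all_zero(self):
        summary = site_count_summary({})
        assert (summary.loc["all"] == 0).all()
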