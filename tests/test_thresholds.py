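"""Threshold estimation: forced midpoint cases, the exhaustive bracket-search
oracle, and summary bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortimap.protocol import StimTrial
from cortimap.thresholds import (
    CEILING,
    FLOOR,
    MEASURED,
    UNRESOLVED,
    ThresholdError,
    estimate_threshold,
    site_threshold,
    threshold_summary,
)

from conftest import make_site


def trials(*pairs):
    return [StimTrial(c, obs) for c, obs in pairs]


def oracle_threshold(series, protocol):
    """Independent oracle: enumerate every (negative, positive) current pair
    and pick the bracket admissible under the staircase rule — the positive
    member must be the lowest positive overall, the negative member the
    largest tested current below it, and the gap within the applicable step.
    """
    pos = sorted({t.current_ua for t in series if t.observed})
    neg = sorted({t.current_ua for t in series if not t.observed})
    if set(pos) & set(neg):
        raise ThresholdError("contradictory")
    if not pos:
        return (None, CEILING)
    brackets = []
    for p, n in itertools.product(pos, neg):
        if n >= p:
            continue
        if p != min(pos):  # p must be the lowest positive
            continue
        if any(n < c < p for c in pos + neg):  # n must be adjacent below p
            continue
        mid = (p + n) / 2
        step = protocol.step_low_ua if mid < protocol.step_breakpoint_ua else protocol.step_high_ua
        brackets.append((p, n, mid, p - n <= step + 1e-9))
    lowest_pos = min(pos)
    if not any(n < lowest_pos for n in neg):
        return (lowest_pos, FLOOR)
    assert len(brackets) == 1  # exactly one adjacent pair under the lowest positive
    p, n, mid, ok = brackets[0]
    return (mid, MEASURED) if ok else (None, UNRESOLVED)


class TestEstimator:
    @pytest.mark.parametrize(
        "series, expected",
        [
            # midpoint forced by the averaging rule, fine-step regime
            ([(60, True), (50, False)], (55.0, MEASURED)),
            # coarse-step regime at/above the 150 uA breakpoint
            ([(200, True), (150, False)], (175.0, MEASURED)),
            # no movement at the 300 uA ceiling
            ([(300, False)], (None, CEILING)),
            # movement at the lowest tested current, nothing below
            ([(10, True)], (10.0, FLOOR)),
            # gap 50 in the 10 uA regime: no valid bracket, never interpolated
            ([(120, True), (70, False)], (None, UNRESOLVED)),
            # extra trials above the bracket change nothing
            ([(100, True), (60, True), (50, False), (30, False)], (55.0, MEASURED)),
            ([(150, True), (140, False)], (145.0, MEASURED)),
        ],
    )
    def test_forced_cases(self, protocol, series, expected):
        est = estimate_threshold(trials(*series), protocol)
        assert (est.threshold_ua, est.flag) == expected

    def test_contradictory_trials_error(self, protocol):
        with pytest.raises(ThresholdError):
            estimate_threshold(trials((60, True), (60, False)), protocol)

    def test_empty_series_error(self, protocol):
        with pytest.raises(ThresholdError):
            estimate_threshold([], protocol)

    def test_off_grid_current_warns(self, protocol):
        with pytest.warns(UserWarning, match="off the protocol step grid"):
            estimate_threshold(trials((33, True), (23, False)), protocol)

    def test_equivalent_to_exhaustive_oracle(self, protocol):
        """1,000 random staircases: estimator equals the pair-scan oracle."""
        rng = np.random.default_rng(42)
        grid = list(protocol.grid())
        for _ in range(1000):
            k = int(rng.integers(1, 7))
            currents = rng.choice(grid, size=k, replace=False)
            series = trials(*[(float(c), bool(rng.integers(2))) for c in currents])
            est = estimate_threshold(series, protocol)
            assert (est.threshold_ua, est.flag) == oracle_threshold(series, protocol)

    @given(
        lowest_pos=st.integers(2, 14),
        neg_offset=st.integers(1, 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_lowest_positive(self, protocol, lowest_pos, neg_offset):
        """Raising the lowest observed-positive current (holding the
        negative bracket) never lowers the estimate."""
        n = (lowest_pos - neg_offset) * 10.0
        lo = estimate_threshold(trials((lowest_pos * 10.0, True), (n, False)), protocol)
        hi = estimate_threshold(trials(((lowest_pos + 1) * 10.0, True), (n, False)), protocol)
        if lo.defined and hi.defined:
            assert hi.threshold_ua >= lo.threshold_ua


class TestSiteThreshold:
    def test_minimum_over_movement_series(self, protocol, taxonomy):
        t1 = taxonomy.parse("tongue")
        t2 = taxonomy.parse("lips")
        site = make_site(
            "s1",
            (0, 0),
            parts=(t1, t2),
            trials={
                t1: tuple(trials((90, False), (100, True))),
                t2: tuple(trials((30, False), (40, True))),
            },
        )
        est = site_threshold(site, protocol)
        assert est.threshold_ua == 35.0 and est.flag == MEASURED

    def test_nonresponsive_site(self, protocol):
        site = make_site("s1", (0, 0))
        est = site_threshold(site, protocol)
        assert est.threshold_ua is None and est.flag == CEILING


class TestSummary:
    def test_group_mean_and_counts(self, protocol):
        # grid brackets giving thresholds 15, 25, 35 -> mean 25
        sites = [
            make_site("s1", (0, 0), parts=("tongue",), field="3b", bracket=(10, 20)),
            make_site("s2", (1, 0), parts=("tongue",), field="3b", bracket=(20, 30)),
            make_site("s3", (2, 0), parts=("tongue",), field="3b", bracket=(30, 40)),
        ]
        summ = threshold_summary({"K1": sites}, protocol)
        row = summ["K1"].rows["3b"]
        assert row.site_count == 3
        assert row.mean_threshold_ua == pytest.approx(25.0)
        assert summ["K1"].movement_sites == 3

    def test_pooled_mean_is_weighted_mean_of_group_means(self, protocol):
        sites = [
            make_site("a1", (0, 0), parts=("tongue",), field="3b", bracket=(10, 20)),
            make_site("a2", (1, 0), parts=("tongue",), field="3b", bracket=(50, 60)),
            make_site("a3", (2, 0), parts=("hip",), field="M1", bracket=(20, 30)),
        ]
        summ = threshold_summary({"K1": sites}, protocol)["K1"]
        weighted = sum(
            r.threshold_count * r.mean_threshold_ua
            for r in summ.rows.values()
            if r.mean_threshold_ua is not None
        ) / sum(r.threshold_count for r in summ.rows.values())
        assert summ.mean_threshold_ua == pytest.approx(weighted)

    def test_counts_additive_and_permutation_invariant(self, protocol):
        sites = [
            make_site(f"s{i}", (i, 0), parts=("tongue",), field="3b") for i in range(5)
        ] + [make_site(f"n{i}", (i, 1)) for i in range(3)]
        fwd = threshold_summary({"K1": sites}, protocol)["all"]
        rev = threshold_summary({"K1": sites[::-1]}, protocol)["all"]
        assert (fwd.total_sites, fwd.movement_sites, fwd.threshold_sites) == (8, 5, 5)
        assert (rev.total_sites, rev.movement_sites, rev.threshold_sites) == (8, 5, 5)

    def test_floor_included_unresolved_excluded_from_means(self, protocol, taxonomy):
        lab = taxonomy.parse("tongue")
        floor_site = make_site(
            "f", (0, 0), parts=(lab,), field="3a", trials={lab: tuple(trials((10, True)))}
        )
        unresolved = make_site(
            "u", (1, 0), parts=(lab,), field="3a", trials={lab: tuple(trials((70, False), (120, True)))}
        )
        summ = threshold_summary({"K1": [floor_site, unresolved]}, protocol)["K1"]
        row = summ.rows["3a"]
        assert row.site_count == 2  # both are movement sites
        assert row.threshold_count == 1  # only the floor one carries a value
        assert row.mean_threshold_ua == pytest.approx(10.0)

    def test_empty_group_renders_na(self, protocol):
        from cortimap.thresholds import summary_table

        summ = threshold_summary({"K1": [make_site("s", (0, 0), parts=("hip",), field="M1")]}, protocol)
        table = summary_table(summ)
        assert np.isnan(table.loc["3b", ("K1", "threshold_ua")])
        assert table.loc["3b", ("K1", "sites")] == 0
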