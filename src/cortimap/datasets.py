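"""Published reference measurements from a four-case galago LT-ICMS study.

These are the printed summary numbers of the mapping study whose design
the synthetic generator emulates: per-case site bookkeeping with per-field
mean thresholds, and per-case representation areas (mm^2) for the
shoulder, digit and tongue against the excitable-cortex denominator.
They serve as inputs for reproducing the study's table arithmetic
(percentages and cross-case means are recomputed, not stored).
"""

from __future__ import annotations

import pandas as pd

CASES = ("K22-03", "K22-04", "K22-05", "K22-06")


def site_counts() -> pd.DataFrame:
    """Per-case total / movement / threshold site counts.

    Pooled over the four cases the totals are 633 penetration sites, 541
    movement-evoking sites and 521 sites with measured thresholds.
    """
    data = {
        "K22-03": {"total_sites": 113, "movement_sites": 101, "threshold_sites": 97},
        "K22-04": {"total_sites": 175, "movement_sites": 142, "threshold_sites": 138},
        "K22-05": {"total_sites": 176, "movement_sites": 140, "threshold_sites": 133},
        "K22-06": {"total_sites": 169, "movement_sites": 158, "threshold_sites": 153},
    }
    return pd.DataFrame.from_dict(data, orient="index")


def field_group_counts() -> pd.DataFrame:
    """Per-case movement-site counts by field group (rows sum to 541)."""
    data = {
        "K22-03": {"PM/M1": 43, "3a": 14, "3b": 40, "1/2/PPC": 4},
        "K22-04": {"PM/M1": 49, "3a": 23, "3b": 59, "1/2/PPC": 11},
        "K22-05": {"PM/M1": 64, "3a": 15, "3b": 58, "1/2/PPC": 3},
        "K22-06": {"PM/M1": 29, "3a": 19, "3b": 63, "1/2/PPC": 47},
    }
    return pd.DataFrame.from_dict(data, orient="index")


def field_group_mean_thresholds() -> pd.DataFrame:
    """Per-case mean thresholds (uA) by field group, plus the pooled row.

    Medians of the synthetic per-field threshold model follow this
    ordering (3a lowest, then PM/M1, 3b, and 1/2/PPC highest).
    """
    data = {
        "all": {"PM/M1": 32.0, "3a": 20.3, "3b": 55.1, "1/2/PPC": 79.7},
        "K22-03": {"PM/M1": 20.4, "3a": 10.4, "3b": 59.7, "1/2/PPC": 102.5},
        "K22-04": {"PM/M1": 31.9, "3a": 31.7, "3b": 74.7, "1/2/PPC": 140.0},
        "K22-05": {"PM/M1": 45.9, "3a": 25.0, "3b": 68.4, "1/2/PPC": 108.3},
        "K22-06": {"PM/M1": 20.9, "3a": 8.8, "3b": 21.9, "1/2/PPC": 62.3},
    }
    return pd.DataFrame.from_dict(data, orient="index")


def representation_areas_mm2() -> pd.DataFrame:
    """Per-case measured representation areas (mm^2).

    ``all`` is the excitable-cortex denominator of each case; shoulder,
    digit and tongue are the per-movement polygon areas measured on the
    suprathreshold maps (movements observed up to 300 uA).
    """
    data = {
        "K22-03": {"all": 81.6, "shoulder": 26.3, "digit": 7.6, "tongue": 30.9},
        "K22-04": {"all": 117.5, "shoulder": 47.2, "digit": 0.4, "tongue": 34.5},
        "K22-05": {"all": 128.6, "shoulder": 34.6, "digit": 6.0, "tongue": 31.5},
        "K22-06": {"all": 187.8, "shoulder": 76.5, "digit": 12.5, "tongue": 49.3},
    }
    return pd.DataFrame.from_dict(data, orient="index")


def bookkeeping_stub_sites() -> dict:
    """Synthetic stub sites reproducing the published per-case bookkeeping.

    For each case, the published movement-site counts per field group are
    realized as minimal stub sites (threshold-bearing staircases for the
    published threshold-site count, unresolved staircases for the rest,
    and nonresponsive sites up to the published total), so that the
    package's counting functions can recompute the study's totals from
    scratch.  Positions are placeholders; geometry is not represented.
    """
    from .protocol import StimTrial
    from .sites import StimSite
    from .taxonomy import MovementLabel

    group_field = {"PM/M1": "M1", "3a": "3a", "3b": "3b", "1/2/PPC": "PPC"}
    counts = site_counts()
    groups = field_group_counts()
    lab = MovementLabel("tongue")
    resolvable = (StimTrial(50.0, False), StimTrial(60.0, True))
    unresolved = (StimTrial(70.0, False), StimTrial(120.0, True))
    cases: dict[str, list[StimSite]] = {}
    for case in CASES:
        remaining_thresholds = int(counts.loc[case, "threshold_sites"])
        sites: list[StimSite] = []
        for gname, n in groups.loc[case].items():
            for i in range(int(n)):
                series = resolvable if remaining_thresholds > 0 else unresolved
                remaining_thresholds -= 1 if series is resolvable else 0
                sites.append(
                    StimSite(
                        case_id=case,
                        site_id=f"{gname}-{i}",
                        position=(float(i), 0.0),
                        field=group_field[gname],
                        movements=frozenset({lab}),
                        trials={lab: series},
                    )
                )
        for i in range(int(counts.loc[case, "total_sites"]) - len(sites)):
            sites.append(
                StimSite(case_id=case, site_id=f"nr-{i}", position=(float(i), 1.0))
            )
        cases[case] = sites
    return cases


def representation_area_table():
    """The published areas as an :class:`~cortimap.quantify.AreaTable`,
    ready for percentage and cross-case-mean arithmetic."""
    from .quantify import area_table_from_measurements

    df = representation_areas_mm2()
    areas = df.drop(columns=["all"])
    return area_table_from_measurements(
        {case: areas.loc[case].to_dict() for case in areas.index},
        df["all"].to_dict(),
    )
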