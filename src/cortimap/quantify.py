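"""Movement-representation areas, percentages and site bookkeeping.

For each case, the area of a movement's representation is the summed area
of cells whose label set includes that movement (a multi-label cell
contributes its full area to each of its movements, so percentages over
movements intentionally sum to more than 100).  Percentages are taken
against the case's excitable denominator — the union of movement-evoking
cells, not the whole clipped region.  Cross-case averages are the simple
mean of the per-case reported percentages.

Reported values are rounded half away from zero to one decimal; full
precision is retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .sites import StimSite
from .taxonomy import MovementLabel
from .tessellation import CaseMap
from .thresholds import FIELD_GROUPS, annotate_thresholds

Selector = "str | Callable[[MovementLabel], bool]"


class QuantifyError(ValueError):
    pass


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.05 -> 0.1, -0.05 -> -0.1)."""
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _as_predicate(selector, known_parts: frozenset[str] | None = None):
    if callable(selector):
        return selector
    part = str(selector)
    if known_parts is not None and part not in known_parts:
        raise QuantifyError(f"unknown body part {part!r}")

    def pred(label: MovementLabel) -> bool:
        # body-part selectors ignore direction and laterality
        return label.body_part == part

    return pred


def movement_area(case_map: CaseMap, selector, taxonomy=None) -> float:
    """Total area (mm^2) of cells whose label set matches ``selector``.

    ``selector`` is a body-part name (direction/laterality ignored) or a
    predicate over :class:`MovementLabel`.  When a taxonomy is supplied,
    an unknown body-part name is an error.
    """
    known = frozenset(taxonomy.body_parts) if taxonomy is not None else None
    pred = _as_predicate(selector, known)
    return sum(c.area_mm2 for c in case_map.cells if any(pred(l) for l in c.labels))


@dataclass
class AreaTable:
    """Per-case, per-movement areas and percentages (study-table shape).

    ``areas`` holds full-precision mm^2 values indexed by case with one
    column per movement; ``all_mm2`` is the per-case excitable denominator.
    """

    areas: pd.DataFrame
    all_mm2: pd.Series
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def percent(self) -> pd.DataFrame:
        """Full-precision percentages of the excitable denominator."""
        return 100.0 * self.areas.div(self.all_mm2, axis=0)

    def reported_percent(self) -> pd.DataFrame:
        """One-decimal reporting percentages (half away from zero)."""
        return self.percent.map(round_half_away)

    def reported(self) -> pd.DataFrame:
        """Human-facing table: mm^2 and % per case plus the denominator."""
        out = pd.DataFrame(index=self.areas.index)
        out["all_mm2"] = self.all_mm2.map(lambda v: round_half_away(v, 1))
        for mv in self.areas.columns:
            out[f"{mv}_mm2"] = self.areas[mv].map(lambda v: round_half_away(v, 1))
            out[f"{mv}_pct"] = self.reported_percent()[mv]
        return out


def area_table(
    maps: Sequence[CaseMap],
    movements: Sequence,
) -> AreaTable:
    """Build the per-case area/percentage table from case maps."""
    if not maps:
        raise QuantifyError("need at least one case map")
    records: dict[str, dict[str, float]] = {}
    denoms: dict[str, float] = {}
    flags: dict[str, str] = {}
    names = [m if isinstance(m, str) else getattr(m, "__name__", str(m)) for m in movements]
    for cm in maps:
        row = {}
        for mv, name in zip(movements, names):
            row[name] = movement_area(cm, mv)
        records[cm.case_id] = row
        denom = cm.excitable_area_mm2
        denoms[cm.case_id] = denom
        if denom <= 0:
            flags[cm.case_id] = "zero responsive area; percents undefined"
    areas = pd.DataFrame.from_dict(records, orient="index", columns=names)
    all_mm2 = pd.Series(denoms, name="all_mm2").replace(0.0, math.nan)
    return AreaTable(areas=areas, all_mm2=all_mm2, flags=flags)


def area_table_from_measurements(
    areas_mm2: Mapping[str, Mapping[str, float]],
    all_mm2: Mapping[str, float],
) -> AreaTable:
    """Build an :class:`AreaTable` directly from measured areas.

    Used when per-case representation areas were measured externally
    (e.g. published per-case mm^2 values) rather than from case maps.
    """
    areas = pd.DataFrame.from_dict({k: dict(v) for k, v in areas_mm2.items()}, orient="index")
    return AreaTable(areas=areas, all_mm2=pd.Series(dict(all_mm2), name="all_mm2"))


def cross_case_summary(table: AreaTable) -> pd.Series:
    """All-cases mean percentage per movement.

    The simple mean of the per-case *reported* (one-decimal) percentages,
    itself reported to one decimal — matching how study tables average the
    printed per-case cells.
    """
    reported = table.reported_percent()
    if reported.dropna(how="all").empty:
        raise QuantifyError("no case with defined percents")
    return reported.mean(axis=0, skipna=True).map(round_half_away)


def site_count_summary(
    cases: Mapping[str, Sequence[StimSite]] | Sequence[Sequence[StimSite]],
) -> pd.DataFrame:
    """Total / movement / threshold site counts per case, per field group,
    and pooled.  Counts are additive over cases and over field groups.
    Empty input yields an all-zero pooled row."""
    if not isinstance(cases, Mapping):
        cases = {
            str(sites[0].case_id) if sites else f"case{i}": sites
            for i, sites in enumerate(cases)
        }
    rows = {}
    for case_id, sites in cases.items():
        annotated = annotate_thresholds(sites)
        row = {
            "total_sites": len(annotated),
            "movement_sites": sum(1 for s in annotated if s.responsive),
            "threshold_sites": sum(1 for s in annotated if s.threshold_ua is not None),
        }
        for gname, members in FIELD_GROUPS.items():
            row[f"movement_sites[{gname}]"] = sum(
                1 for s in annotated if s.responsive and s.field in members
            )
        rows[case_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        cols = ["total_sites", "movement_sites", "threshold_sites"] + [
            f"movement_sites[{g}]" for g in FIELD_GROUPS
        ]
        df = pd.DataFrame(columns=cols, dtype=int)
    df.loc["all"] = df.sum(axis=0).astype(int) if len(df) else 0
    return df
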