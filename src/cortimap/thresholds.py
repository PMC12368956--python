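"""Movement-threshold estimation and per-field threshold summaries.

The threshold of a movement is the average of (i) the lowest current at
which the movement was observed and (ii) the next-lowest tested current at
which it was not.  The staircase tests in 10 uA steps for thresholds below
150 uA and 50 uA steps at or above, so a valid bracket has a gap equal to
the applicable step; a wider gap leaves the threshold unresolved (never
interpolated).  Movement at the lowest tested current with nothing below
reports that current with flag ``floor``; no movement at the ceiling is
``ceiling_nonresponsive``.

Summaries mirror the study-style layout: total / movement / threshold site
counts plus per field-group site counts and mean thresholds, with fields
pooled into PM/M1, 3a, 3b, and 1/2/PPC (the latter because 1/2 and PPC
boundaries are often indistinct in flattened preparations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .protocol import StimProtocol, StimTrial
from .sites import StimSite

#: Field-group pooling used in threshold summaries.
FIELD_GROUPS: dict[str, tuple[str, ...]] = {
    "PM/M1": ("PM", "M1"),
    "3a": ("3a",),
    "3b": ("3b",),
    "1/2/PPC": ("1/2", "PPC"),
}

MEASURED = "measured"
FLOOR = "floor"
CEILING = "ceiling_nonresponsive"
UNRESOLVED = "unresolved"


class ThresholdError(ValueError):
    """Trial series is internally contradictory."""


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_ua: float | None
    flag: str

    @property
    def defined(self) -> bool:
        return self.threshold_ua is not None


def estimate_threshold(
    trials: Sequence[StimTrial],
    protocol: StimProtocol | None = None,
) -> ThresholdEstimate:
    """Estimate one movement's threshold from its trial series.

    Returns the midpoint of the lowest movement-positive current and the
    highest tested negative current strictly below it, provided their gap
    does not exceed the step applicable at that threshold.
    """
    protocol = protocol or StimProtocol()
    if not trials:
        raise ThresholdError("empty trial series")
    by_current: dict[float, set[bool]] = {}
    for t in trials:
        by_current.setdefault(t.current_ua, set()).add(t.observed)
        if not protocol.on_grid(t.current_ua):
            warnings.warn(
                f"trial current {t.current_ua} uA is off the protocol step grid",
                stacklevel=2,
            )
    for current, outcomes in by_current.items():
        if len(outcomes) > 1:
            raise ThresholdError(
                f"contradictory trials at {current} uA (both observed and not observed)"
            )
    positives = sorted(c for c, o in by_current.items() if True in o)
    negatives = sorted(c for c, o in by_current.items() if False in o)
    if not positives:
        return ThresholdEstimate(None, CEILING)
    lowest_pos = positives[0]
    negs_below = [c for c in negatives if c < lowest_pos]
    if not negs_below:
        return ThresholdEstimate(lowest_pos, FLOOR)
    highest_neg = max(negs_below)
    midpoint = 0.5 * (lowest_pos + highest_neg)
    step = protocol.step_at(midpoint)
    if lowest_pos - highest_neg > step + 1e-9:
        return ThresholdEstimate(None, UNRESOLVED)
    return ThresholdEstimate(midpoint, MEASURED)


def site_threshold(site: StimSite, protocol: StimProtocol | None = None) -> ThresholdEstimate:
    """Per-site threshold: the minimum over the site's movement-specific
    thresholds; nonresponsive sites are ceiling-flagged."""
    protocol = protocol or StimProtocol()
    if not site.movements and not site.trials:
        return ThresholdEstimate(None, CEILING)
    estimates = [estimate_threshold(ts, protocol) for ts in site.trials.values()]
    defined = [e for e in estimates if e.defined]
    if defined:
        return min(defined, key=lambda e: e.threshold_ua)
    if site.movements:
        # movements recorded but no series resolved
        return ThresholdEstimate(None, UNRESOLVED)
    return ThresholdEstimate(None, CEILING)


def annotate_thresholds(
    sites: Iterable[StimSite], protocol: StimProtocol | None = None
) -> list[StimSite]:
    """Return sites with ``threshold_ua``/``threshold_flag`` filled in."""
    from dataclasses import replace

    out = []
    for s in sites:
        est = site_threshold(s, protocol)
        out.append(replace(s, threshold_ua=est.threshold_ua, threshold_flag=est.flag))
    return out


@dataclass(frozen=True)
class GroupRow:
    site_count: int  # movement sites located in the group
    threshold_count: int  # of these, sites with a defined threshold
    mean_threshold_ua: float | None  # unweighted mean over threshold sites


@dataclass(frozen=True)
class ThresholdSummary:
    """Site bookkeeping and mean thresholds for one case (or pooled)."""

    group: str  # case id or "all"
    total_sites: int
    movement_sites: int
    threshold_sites: int
    mean_threshold_ua: float | None
    rows: Mapping[str, GroupRow]


def _mean(vals: Sequence[float]) -> float | None:
    return sum(vals) / len(vals) if vals else None


def _summarize(group: str, sites: Sequence[StimSite], protocol: StimProtocol) -> ThresholdSummary:
    annotated = annotate_thresholds(sites, protocol)
    thresholds = [s.threshold_ua for s in annotated if s.threshold_ua is not None]
    rows: dict[str, GroupRow] = {}
    for gname, members in FIELD_GROUPS.items():
        in_group = [s for s in annotated if s.field in members]
        movement = [s for s in in_group if s.responsive]
        th = [s.threshold_ua for s in movement if s.threshold_ua is not None]
        rows[gname] = GroupRow(len(movement), len(th), _mean(th))
    return ThresholdSummary(
        group=group,
        total_sites=len(annotated),
        movement_sites=sum(1 for s in annotated if s.responsive),
        threshold_sites=len(thresholds),
        mean_threshold_ua=_mean(thresholds),
        rows=rows,
    )


def threshold_summary(
    cases: Mapping[str, Sequence[StimSite]] | Sequence[Sequence[StimSite]],
    protocol: StimProtocol | None = None,
) -> dict[str, ThresholdSummary]:
    """Per-case summaries plus a pooled ``"all"`` summary.

    Counts are additive over cases; group means are unweighted means over
    the threshold-bearing sites in the group (floor thresholds enter at
    their floor value; unresolved and nonresponsive sites are excluded
    from means but nonresponsive sites still count toward totals).
    """
    protocol = protocol or StimProtocol()
    if not isinstance(cases, Mapping):
        cases = {str(sites[0].case_id) if sites else f"case{i}": sites for i, sites in enumerate(cases)}
    out: dict[str, ThresholdSummary] = {}
    pooled: list[StimSite] = []
    for case_id, sites in cases.items():
        out[case_id] = _summarize(case_id, sites, protocol)
        pooled.extend(sites)
    out["all"] = _summarize("all", pooled, protocol)
    return out


def summary_table(summaries: Mapping[str, ThresholdSummary]) -> pd.DataFrame:
    """Render summaries as a study-style table: rows are totals then field
    groups; column pairs (site count, mean threshold) per case with the
    pooled column first.  Undefined means render as NaN ("n/a")."""
    order = ["all"] + [k for k in summaries if k != "all"]
    data: dict[tuple[str, str], list] = {}
    index = ["Total Sites", "Mvmt Sites", "Thresh Sites", *FIELD_GROUPS]
    for key in order:
        s = summaries[key]
        counts = [s.total_sites, s.movement_sites, s.threshold_sites]
        means: list[float | None] = [None, None, s.mean_threshold_ua]
        for g in FIELD_GROUPS:
            counts.append(s.rows[g].site_count)
            means.append(s.rows[g].mean_threshold_ua)
        data[(key, "sites")] = counts
        data[(key, "threshold_ua")] = [math.nan if m is None else m for m in means]
    return pd.DataFrame(data, index=index)
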