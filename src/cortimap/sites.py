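"""Stimulation sites and the delimited site-table format.

A :class:`StimSite` is one electrode penetration: its position on the
flattened cortex (mm; x increases lateral, y increases rostral, case-local
origin at a declared landmark), depth, cortical field, the set of evoked
movements, and the per-movement trial series from which thresholds are
estimated.

Site tables are UTF-8 CSV with columns::

    case_id, site_id, x_mm, y_mm, depth_um, field,
    movements, current_ua, observed, max_current_ua

Each row is one stimulation trial; ``movements`` is a semicolon-joined list
of ``body_part[:direction][:bilateral]`` labels naming the series the trial
belongs to (empty on a negative trial means the trial applies to every
series at that site; a nonresponsive site is a single negative row with an
empty ``movements`` cell).  Rows sharing a ``site_id`` merge into one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .protocol import StimProtocol, StimTrial
from .taxonomy import MovementLabel, MovementTaxonomy

FIELDS = ("PM", "M1", "3a", "3b", "1/2", "PPC", "unassigned")

SITE_TABLE_COLUMNS = (
    "case_id",
    "site_id",
    "x_mm",
    "y_mm",
    "depth_um",
    "field",
    "movements",
    "current_ua",
    "observed",
    "max_current_ua",
)


class SiteTableError(ValueError):
    """A site table violates the documented schema."""


@dataclass(frozen=True)
class StimSite:
    """One electrode penetration and everything recorded at it."""

    case_id: str
    site_id: str
    position: tuple[float, float]
    depth_um: float = 1800.0
    field: str = "unassigned"
    movements: frozenset[MovementLabel] = frozenset()
    trials: Mapping[MovementLabel, tuple[StimTrial, ...]] = None  # type: ignore[assignment]
    max_current_ua: float = 300.0
    threshold_ua: float | None = None
    threshold_flag: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.trials is None:
            object.__setattr__(self, "trials", {})
        if self.field not in FIELDS:
            raise SiteTableError(f"unknown cortical field {self.field!r}")
        if self.threshold_ua is not None and self.threshold_ua > self.max_current_ua:
            raise SiteTableError(
                f"threshold {self.threshold_ua} exceeds max current {self.max_current_ua}"
            )

    @property
    def responsive(self) -> bool:
        return bool(self.movements)

    def body_parts(self) -> frozenset[str]:
        return frozenset(m.body_part for m in self.movements)

    def with_field(self, field_name: str, extra_flags: tuple[str, ...] = ()) -> "StimSite":
        return replace(self, field=field_name, flags=self.flags + extra_flags)


def _site_from_rows(
    case_id: str,
    site_id: str,
    rows: pd.DataFrame,
    taxonomy: MovementTaxonomy,
    protocol: StimProtocol,
) -> StimSite:
    first = rows.iloc[0]
    pos = (float(first["x_mm"]), float(first["y_mm"]))
    for col in ("x_mm", "y_mm", "depth_um", "field", "max_current_ua"):
        vals = rows[col].unique()
        if len(vals) > 1:
            raise SiteTableError(
                f"site {case_id}/{site_id}: column {col!r} differs across trial rows: {vals}"
            )
    max_current = float(first["max_current_ua"]) if not pd.isna(first["max_current_ua"]) else protocol.max_current_ua
    field_name = (
        "unassigned"
        if pd.isna(first["field"])
        else (str(first["field"]).strip() or "unassigned")
    )

    trials: dict[MovementLabel, list[StimTrial]] = {}
    site_negatives: list[StimTrial] = []
    movements: set[MovementLabel] = set()
    seen: set[tuple[str, float]] = set()
    for _, row in rows.iterrows():
        labels = taxonomy.parse_many(str(row["movements"]) if not pd.isna(row["movements"]) else "")
        observed = _parse_observed(row["observed"])
        trial = StimTrial(float(row["current_ua"]), observed)
        key = (";".join(sorted(str(l) for l in labels)), trial.current_ua)
        if key in seen:
            raise SiteTableError(
                f"site {case_id}/{site_id}: duplicate trial row at {trial.current_ua} uA "
                f"for movements {key[0] or '<none>'}"
            )
        seen.add(key)
        if labels:
            for lab in labels:
                trials.setdefault(lab, []).append(trial)
                if observed:
                    movements.add(lab)
        else:
            if observed:
                raise SiteTableError(
                    f"site {case_id}/{site_id}: positive trial with no movement label"
                )
            site_negatives.append(trial)
    # unlabeled negative trials apply to every series at the site
    for lab in trials:
        trials[lab].extend(site_negatives)
    return StimSite(
        case_id=case_id,
        site_id=site_id,
        position=pos,
        depth_um=float(first["depth_um"]),
        field=field_name,
        movements=frozenset(movements),
        trials={lab: tuple(sorted(ts, key=lambda t: t.current_ua)) for lab, ts in trials.items()},
        max_current_ua=max_current,
    )


def _parse_observed(value) -> bool:
    text = str(value).strip().lower()
    if text in ("yes", "y", "true", "1"):
        return True
    if text in ("no", "n", "false", "0"):
        return False
    raise SiteTableError(f"cannot parse observed value {value!r} (expected yes/no)")


def read_site_table(
    path: str | Path,
    taxonomy: MovementTaxonomy,
    protocol: StimProtocol | None = None,
) -> list[StimSite]:
    """Read a site-table CSV into a list of :class:`StimSite`.

    Rows with equal ``site_id`` merge their trials into one site.  Unknown
    movement labels are errors, never silently dropped.
    """
    protocol = protocol or StimProtocol()
    df = pd.read_csv(
        path,
        dtype={"case_id": str, "site_id": str, "movements": str},
        float_precision="round_trip",
    )
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteTableError(f"site table {path} missing required columns: {missing}")
    sites: list[StimSite] = []
    for (case_id, site_id), rows in df.groupby(["case_id", "site_id"], sort=False):
        sites.append(_site_from_rows(str(case_id), str(site_id), rows, taxonomy, protocol))
    return sites


def write_site_table(sites: Iterable[StimSite], path: str | Path) -> None:
    """Write sites to the documented CSV schema (one row per trial).

    Negative trials shared by every series at a site (identical trial in
    all series) are written once with an empty ``movements`` cell; a
    nonresponsive site becomes a single negative row at its max current.
    """
    records: list[dict] = []
    for site in sites:
        base = {
            "case_id": site.case_id,
            "site_id": site.site_id,
            "x_mm": site.position[0],
            "y_mm": site.position[1],
            "depth_um": site.depth_um,
            "field": site.field,
            "max_current_ua": site.max_current_ua,
        }
        if not site.trials:
            records.append(
                base | {"movements": "", "current_ua": site.max_current_ua, "observed": "no"}
            )
            continue
        # negatives present identically in every series are site-level
        shared: set[StimTrial] = None  # type: ignore[assignment]
        for ts in site.trials.values():
            negs = {t for t in ts if not t.observed}
            shared = negs if shared is None else shared & negs
        shared = shared or set()
        for trial in sorted(shared, key=lambda t: t.current_ua):
            records.append(
                base | {"movements": "", "current_ua": trial.current_ua, "observed": "no"}
            )
        for lab in sorted(site.trials, key=str):
            for trial in site.trials[lab]:
                if trial in shared and not trial.observed:
                    continue
                records.append(
                    base
                    | {
                        "movements": str(lab),
                        "current_ua": trial.current_ua,
                        "observed": "yes" if trial.observed else "no",
                    }
                )
    df = pd.DataFrame.from_records(records, columns=list(SITE_TABLE_COLUMNS))
    df.to_csv(path, index=False)
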