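#!/usr/bin/env python
"""Per-field threshold and site bookkeeping for the synthetic study.

Estimates each site's movement threshold from its trial staircase
(midpoint of the lowest effective and the next-lower ineffective current)
and tabulates site counts and mean thresholds per field group, per case
and pooled — the structure of a classic mapping-study summary table.
Also prints the published reference counts for comparison of structure.
"""

import glob
from pathlib import Path

from cortimap import datasets
from cortimap.protocol import StimProtocol
from cortimap.sites import read_site_table
from cortimap.taxonomy import default_taxonomy
from cortimap.thresholds import summary_table, threshold_summary

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "table_thresholds_synthetic.csv"


def main() -> None:
    taxonomy, protocol = default_taxonomy(), StimProtocol()
    cases: dict = {}
    for path in sorted(glob.glob(str(STUDY / "sites_*.csv"))):
        for s in read_site_table(path, taxonomy, protocol):
            cases.setdefault(s.case_id, []).append(s)
    if not cases:
        raise SystemExit("no study found; run 01_simulate_study.py first")
    table = summary_table(threshold_summary(cases, protocol))
    table.round(1).to_csv(OUT)
    print(f"wrote {OUT}\n")
    print(table.round(1).to_string())
    pooled = table[("all", "threshold_ua")]
    print(
        "\nField ordering of mean thresholds (synthetic): "
        f"3a ({pooled['3a']:.0f} uA) < PM/M1 ({pooled['PM/M1']:.0f}) "
        f"< 3b ({pooled['3b']:.0f}) < 1/2/PPC ({pooled['1/2/PPC']:.0f}) uA"
    )
    print("\nPublished reference mean thresholds (uA):")
    print(datasets.field_group_mean_thresholds().to_string())


if __name__ == "__main__":
    main()
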