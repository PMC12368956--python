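#!/usr/bin/env python
"""Generate the default four-case synthetic study.

Writes per-case site tables (CSV), region geometry (GeoJSON) and the
planted-truth manifest under results/study/.  The default parameters
emulate galago-like sensorimotor maps: a 10 x 18 mm flattened map split
into PM/M1/3a/3b/1-2/PPC strips, a medial-to-lateral
hindlimb-trunk-forelimb-face somatotopic gradient, fractured multi-
movement sites, field-specific thresholds (lowest in 3a and motor cortex,
highest in posterior parietal fields) and a medial-3b dropout.
"""

import json
from pathlib import Path

from cortimap.simulate import SimParams, simulate_study, write_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    params = SimParams(seed=42, n_sites=160)
    study = simulate_study(params, n_cases=4)
    listing = write_study(study, OUT)
    n_sites = sum(len(c.sites) for c in study.cases)
    n_resp = sum(1 for c in study.cases for s in c.sites if s.responsive)
    print(f"wrote {len(study.cases)} cases ({n_sites} sites, {n_resp} responsive) to {OUT}")
    print(json.dumps(listing, indent=1))


if __name__ == "__main__":
    main()
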