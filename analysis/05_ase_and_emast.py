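#!/usr/bin/env python
"""Allele-specific expression scoring and the EMAST decision rule.

Reproduces the cohort's qualitative ASE calls from their summary statistics
(quadruplicates reconstructed to the reported mean +/- SD), demonstrates
recovery of a known true ASE from noisy synthetic replicates, and sweeps
the EMAST caller over 0-6 unstable markers to show the first positive call
at exactly 2 of 6.
"""

import argparse
import json
import math
from pathlib import Path

from lynchlike.allelic_expression import SNuPEReplicate, compute_ase
from lynchlike.msi_emast import call_emast
from lynchlike.synthetic import (
    MarkerSpec,
    SnupeSpec,
    simulate_marker_profiles,
    simulate_snupe,
)

OUT = Path(__file__).resolve().parents[1] / "results"

# reported quadruplicate summaries: (label, mean, sd)
REPORTED = [
    ("MSH6 c.1618_1620del untreated", 0.69, 0.03),
    ("MSH6 c.1618_1620del puromycin", 0.65, 0.06),
    ("MSH6 c.1153_1155del puromycin", 1.02, 0.09),
    ("MSH6 c.3150_3161dup untreated", 1.04, 0.14),
    ("MSH6 c.3150_3161dup puromycin", 1.16, 0.26),
]


def quadruplicate(mean, sd):
    d = sd * math.sqrt(3) / 2  # m±d twice -> sample SD = 2d/√3
    return [SNuPEReplicate(1.0, v)
            for v in (mean - d, mean - d, mean + d, mean + d)]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=4)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)
    results = {"ase_calls": {}, "emast_sweep": {}}

    for label, mean, sd in REPORTED:
        res = compute_ase(quadruplicate(mean, sd))
        results["ase_calls"][label] = {
            "mean": res.mean_ase, "sd": res.sd_ase, "call": res.imbalance_call}
        print(f"{label}: ASE {res.mean_ase:.2f}±{res.sd_ase:.2f} -> {res.imbalance_call}")

    table = simulate_snupe(SnupeSpec(seed=args.seed, true_ase=0.7))
    reps = [SNuPEReplicate(r.gdna_ratio, r.cdna_ratio) for r in table.itertuples()]
    rec = compute_ase(reps)
    results["ase_recovery"] = {"true": 0.7, "estimated": rec.mean_ase}
    print(f"recovery: true ASE 0.7 estimated as {rec.mean_ase:.3f}")

    for k in range(7):
        call = call_emast(simulate_marker_profiles(
            MarkerSpec(seed=args.seed, n_unstable=k)))
        results["emast_sweep"][k] = call.emast_positive
        print(f"EMAST with {k}/6 unstable markers: "
              f"{'positive' if call.emast_positive else 'negative'}")

    out = OUT / "ase_emast.json"
    with open(out, "w") as fh:
        json.dump(results, fh, indent=2)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
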