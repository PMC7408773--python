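#!/usr/bin/env python
"""Multifactorial likelihood classification of the cohort's MSH6 variants.

Recomputes, from the packaged evidence table (priors, per-tumor likelihood
ratios, cosegregation LRs), the adjusted prior, eligible-tumor LR product,
odds for causality, posterior odds/probability and IARC class for each
variant, and writes the resulting table.

Finding: all three variants reach posterior probability >= 0.98; the
classifier assigns class 4 (likely pathogenic) to c.1153_1155del and
class 5 (pathogenic) to c.1618_1620del and c.3150_3161dup.
"""

from pathlib import Path

from lynchlike.workflows import run_table3

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    table = run_table3()
    out = OUT / "multifactorial_evidence.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {out}")
    assert (table["posterior_probability"] >= 0.98).all()


if __name__ == "__main__":
    main()
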