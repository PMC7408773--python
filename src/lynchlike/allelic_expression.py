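"""Allele-specific expression (ASE) from primer-extension peak ratios.

A single-nucleotide primer-extension (SNuPE) replicate yields the
variant/wildtype peak ratio in genomic DNA and in cDNA.  The per-replicate
ASE is the cDNA ratio normalized by the gDNA ratio; a value of 1.0 means
both alleles are expressed equally, values below 1.0 mean reduced
expression of the variant allele.  The imbalance call compares the
mean +/- 2 SD interval over replicates against 1.0.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import List, Sequence

import pandas as pd

from lynchlike.errors import ValidationError

log = logging.getLogger(__name__)

REDUCED = "reduced_expression"
BALANCED = "balanced"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class SNuPEReplicate:
    gdna_variant_over_wt: float
    cdna_variant_over_wt: float

    def __post_init__(self):
        if self.gdna_variant_over_wt <= 0 or self.cdna_variant_over_wt <= 0:
            raise ValidationError("SNuPE peak ratios must be positive")

    @property
    def ase(self) -> float:
        return self.cdna_variant_over_wt / self.gdna_variant_over_wt


@dataclass(frozen=True)
class ASEResult:
    mean_ase: float
    sd_ase: float
    n_replicates: int
    imbalance_call: str


def compute_ase(
    replicates: Sequence[SNuPEReplicate],
    sd_multiplier: float = 2.0,
) -> ASEResult:
    """Mean/SD of per-replicate ASE and the allelic-imbalance call.

    ``reduced_expression`` when mean + k*SD < 1, ``inconclusive`` when
    mean - k*SD > 1, else ``balanced`` (the interval contains 1.0).
    SD is the n-1 sample form (0 for a single replicate).
    """
    if not replicates:
        raise ValidationError("at least one SNuPE replicate required")
    if len(replicates) < 4:
        log.warning("only %d replicates (assay designed for quadruplicates)",
                    len(replicates))
    values = [r.ase for r in replicates]
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    if mean + sd_multiplier * sd < 1.0:
        call = REDUCED
    elif mean - sd_multiplier * sd > 1.0:
        call = INCONCLUSIVE
    else:
        call = BALANCED
    return ASEResult(mean, sd, len(values), call)


def read_snupe_table(path) -> dict:
    """Read a replicate TSV (replicate_id, gdna_ratio, cdna_ratio, condition).

    Conditions (e.g. untreated vs puromycin-treated cultures) are analyzed
    separately; returns {condition: [SNuPEReplicate, ...]}.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for _, row in df.iterrows():
        cond = str(row.get("condition", "untreated"))
        out.setdefault(cond, []).append(
            SNuPEReplicate(float(row["gdna_ratio"]), float(row["cdna_ratio"]))
        )
    return out
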