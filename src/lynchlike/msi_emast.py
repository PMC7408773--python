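"""EMAST calling from paired normal/tumor tetranucleotide marker profiles.

EMAST (elevated microsatellite alterations at selected tetranucleotide
repeats) is scored over a panel of tetranucleotide markers, six in the
standard design.  A marker is unstable when the tumor shows any allele
length absent from the paired normal profile; the sample is EMAST-positive
when at least ``threshold`` (default 2) markers are unstable.  Allele
dropout (tumor alleles a strict subset of normal) is treated as stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, List, Sequence

import pandas as pd

from lynchlike.errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_MARKERS = tuple(f"MARKER{i}" for i in range(1, 7))


@dataclass(frozen=True)
class MarkerProfile:
    marker_id: str
    normal_alleles: FrozenSet[int]
    tumor_alleles: FrozenSet[int]

    def __post_init__(self):
        for name, alleles in (("normal", self.normal_alleles),
                              ("tumor", self.tumor_alleles)):
            if not alleles:
                raise ValidationError(
                    f"marker {self.marker_id}: empty {name} allele set"
                )
            if any(not 50 <= a <= 500 for a in alleles):
                raise ValidationError(
                    f"marker {self.marker_id}: allele length outside [50, 500] bp"
                )
            if len(alleles) > 2:
                log.warning("marker %s: more than 2 %s alleles",
                            self.marker_id, name)


@dataclass(frozen=True)
class EmastCall:
    unstable_markers: tuple
    n_unstable: int
    n_total: int
    emast_positive: bool


def call_marker_instability(profile: MarkerProfile) -> bool:
    """Unstable iff the tumor shows any novel allele length."""
    return not profile.tumor_alleles <= profile.normal_alleles


def call_emast(profiles: Sequence[MarkerProfile], threshold: int = 2) -> EmastCall:
    """Count unstable markers; positive at >= threshold unstable of the panel."""
    if not profiles:
        raise ValidationError("at least one marker profile required")
    ids = [p.marker_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate marker ids in profile set")
    if len(profiles) != 6:
        log.warning("EMAST panel has %d markers (standard design uses 6)",
                    len(profiles))
    unstable = tuple(p.marker_id for p in profiles if call_marker_instability(p))
    return EmastCall(
        unstable_markers=unstable,
        n_unstable=len(unstable),
        n_total=len(profiles),
        emast_positive=len(unstable) >= threshold,
    )


def read_marker_table(path) -> dict:
    """Read marker TSV (sample_id, marker_id, tissue, allele_lengths).

    ``allele_lengths`` is comma-separated; returns
    {sample_id: [MarkerProfile, ...]} pairing normal and tumor rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict = {}
    for (sample, marker), grp in df.groupby(["sample_id", "marker_id"], sort=False):
        tissues = {}
        for _, row in grp.iterrows():
            alleles = frozenset(int(x) for x in str(row["allele_lengths"]).split(","))
            tissues[str(row["tissue"])] = alleles
        if "normal" not in tissues or "tumor" not in tissues:
            raise ValidationError(
                f"sample {sample} marker {marker}: need both normal and tumor rows"
            )
        out.setdefault(sample, []).append(
            MarkerProfile(marker, tissues["normal"], tissues["tumor"])
        )
    return out
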