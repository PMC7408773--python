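"""Germline panel-variant filtering and per-case final classification.

Implements the screening thresholds applied to the colorectal-cancer gene
panel calls (Phred quality, alternative-allele ratio, read depth, population
frequency, prior InSiGHT class) and the decision rules that turn a case's
variant inventory into its final label: Lynch syndrome (LS), Lynch-like
syndrome (LLS) or one of its carrier subtypes, or a different Mendelian
syndrome altogether.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from lynchlike.errors import ValidationError

# final classification labels
LS = "LS"
LLS = "LLS"
LLS_MMR_VUS = "LLS_MMR_VUS_carrier"
LLS_VUS = "LLS_VUS_carrier"
LLS_MUTYH = "LLS_monoallelic_MUTYH_carrier"
OTHER_SYNDROME = "other_syndrome"

#: pathogenic variants in these non-MMR genes define a Mendelian CRC
#: syndrome of their own (configurable); biallelic MUTYH is handled in code.
DEFAULT_SYNDROME_GENES = {"APC": "FAP"}


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    gene: str
    cdna_change: str
    protein_change: Optional[str] = None
    phred_qual: float = 0.0
    read_depth: int = 0
    alt_allele_ratio: float = 0.0
    maf_exac: Optional[float] = None
    maf_esp: Optional[float] = None
    insight_class: Optional[int] = None
    clinvar_label: Optional[str] = None
    gene_category: str = "MMR"  # MMR / other_CRC_gene

    def __post_init__(self):
        if not 0.0 <= self.alt_allele_ratio <= 1.0:
            raise ValidationError(
                f"alt allele ratio {self.alt_allele_ratio} outside [0, 1]"
            )
        if self.read_depth < 0:
            raise ValidationError("read depth must be non-negative")


@dataclass(frozen=True)
class FilterThresholds:
    min_phred: float = 30.0
    min_alt_ratio: float = 0.05
    min_depth: int = 38
    max_population_maf: float = 0.01
    exclude_insight_classes: Tuple[int, ...] = (1, 2)

    def __post_init__(self):
        if self.max_population_maf <= 0 or self.max_population_maf > 1:
            raise ValidationError("max_population_maf must be in (0, 1]")
        if min(self.min_phred, self.min_alt_ratio, self.min_depth) < 0:
            raise ValidationError("thresholds must be non-negative")


def passes_thresholds(call: VariantCall, th: FilterThresholds) -> bool:
    # population MAF: maximum over available databases; absence of frequency
    # evidence (both null) never filters a variant out
    maf = max(call.maf_exac or 0.0, call.maf_esp or 0.0)
    return (
        call.phred_qual >= th.min_phred
        and call.alt_allele_ratio >= th.min_alt_ratio
        and call.read_depth >= th.min_depth
        and maf <= th.max_population_maf
        and call.insight_class not in th.exclude_insight_classes
    )


def filter_variant_calls(
    calls: Sequence[VariantCall],
    th: Optional[FilterThresholds] = None,
) -> List[VariantCall]:
    """Stable, idempotent filter keeping calls that meet every threshold."""
    th = th or FilterThresholds()
    return [c for c in calls if passes_thresholds(c, th)]


# ---------------------------------------------------------------------------
# Case classification
# ---------------------------------------------------------------------------

@dataclass
class CaseRecord:
    """One cohort case: its variant inventory and derived final label.

    ``mmr_variants`` entries are ``(gene, cdna_change, initial_class,
    final_class)``: the InSiGHT class at identification and the class after
    pathogenicity assessment (multifactorial / splicing / database revision).
    """

    case_id: str
    mmr_variants: List[Tuple[str, str, int, int]] = field(default_factory=list)
    #: other-gene variants as (gene, label) with label in {pathogenic, vus}
    other_gene_variants: List[Tuple[str, str]] = field(default_factory=list)
    epimutation: bool = False
    mutyh_biallelic: bool = False

    @property
    def final_classification(self) -> str:
        return classify_case(
            mmr_classes=[final for (_, _, _, final) in self.mmr_variants],
            other_gene_variants=self.other_gene_variants,
            epimutation=self.epimutation,
            mutyh_biallelic=self.mutyh_biallelic,
        )


def classify_case(
    mmr_classes: Sequence[int],
    other_gene_variants: Sequence[Tuple[str, str]],
    epimutation: bool,
    mutyh_biallelic: bool = False,
    syndrome_genes: Optional[Mapping[str, str]] = None,
) -> str:
    """Priority decision rules for a case's final classification.

    1. Any MMR variant of class >= 4, or a constitutional MMR epimutation,
       makes the case LS.
    2. Otherwise a pathogenic variant in a non-MMR Mendelian CRC syndrome
       gene (or biallelic MUTYH) reclassifies the case to that syndrome.
    3. Otherwise an MMR class-3 variant labels the case an MMR VUS carrier.
    4. Otherwise a monoallelic pathogenic MUTYH variant labels it a
       monoallelic MUTYH carrier.
    5. Otherwise any other-gene VUS / predicted-pathogenic variant labels it
       a VUS carrier.
    6. Otherwise plain LLS.
    """
    syndrome_genes = dict(DEFAULT_SYNDROME_GENES if syndrome_genes is None else syndrome_genes)
    for c in mmr_classes:
        if c not in (1, 2, 3, 4, 5):
            raise ValidationError(f"unknown IARC class value {c!r}")
    for _, label in other_gene_variants:
        if label not in ("pathogenic", "vus"):
            raise ValidationError(f"unknown other-gene variant label {label!r}")

    if epimutation or any(c >= 4 for c in mmr_classes):
        return LS
    if mutyh_biallelic or any(
        gene in syndrome_genes and label == "pathogenic"
        for gene, label in other_gene_variants
    ):
        return OTHER_SYNDROME
    if any(c == 3 for c in mmr_classes):
        return LLS_MMR_VUS
    if any(gene == "MUTYH" and label == "pathogenic"
           for gene, label in other_gene_variants):
        return LLS_MUTYH
    if other_gene_variants:
        return LLS_VUS
    return LLS


def count_cohort(records: Sequence[CaseRecord]) -> Dict:
    """Deterministic cohort tallies over case labels and variant classes.

    Besides per-label case counts, reports distinct mismatch-repair variants
    reaching final class >= 4, the subset of those that were reclassified
    (identified as class 3, upgraded on assessment), and distinct variants
    of unknown significance (class 3 at identification) with their carrier
    counts.  Variant identity is (gene, cDNA change).
    """
    seen = set()
    for r in records:
        if r.case_id in seen:
            raise ValidationError(f"duplicate case id {r.case_id!r}")
        seen.add(r.case_id)

    labels = Counter(r.final_classification for r in records)
    final4plus = set()
    reclassified = set()
    vus_carriers: Dict[Tuple[str, str], int] = {}
    for r in records:
        for gene, cdna, initial, final in r.mmr_variants:
            key = (gene, cdna)
            if final >= 4:
                final4plus.add(key)
                if initial <= 3:
                    reclassified.add(key)
            if initial == 3:
                vus_carriers[key] = vus_carriers.get(key, 0) + 1
    return {
        "n_cases": len(records),
        "by_classification": dict(labels),
        "n_ls": labels.get(LS, 0),
        "n_variants_final_class4_or_5": len(final4plus),
        "n_variants_reclassified_class4_or_5": len(reclassified),
        "n_distinct_mmr_vus": len(vus_carriers),
        "n_mmr_vus_carriers": sum(vus_carriers.values()),
    }
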