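"""Multifactorial likelihood classification of mismatch-repair variants.

Combines a prior probability of pathogenicity with likelihood ratios from
tumor characteristics and pedigree cosegregation into posterior odds and a
posterior probability, then maps the posterior onto the IARC five-class
scheme:

    prior_odds      = prior / (1 - prior)
    odds_causality  = LR_tumor * LR_segregation
    posterior_odds  = prior_odds * odds_causality
    posterior_prob  = posterior_odds / (1 + posterior_odds)

Tumor-characteristic LRs come from a configurable lookup table keyed by
cancer type, MSI/IHC category and age band (calibrated externally); tumors
that triggered ascertainment of a proband (index tumors) are excluded from
the product to avoid counting the selection event as evidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from lynchlike.errors import ConfigError, ValidationError
from lynchlike.pedigree import (
    Pedigree,
    PenetranceModel,
    combine_family_lrs,
    cosegregation_bayes_factor,
)

log = logging.getLogger(__name__)

#: default IARC class boundaries on the posterior probability of
#: pathogenicity: class 5 p>0.99, class 4 0.95<p<=0.99, class 3
#: 0.05<=p<=0.95, class 2 0.001<=p<0.05, class 1 p<0.001.
DEFAULT_IARC_THRESHOLDS = {"class5": 0.99, "class4": 0.95, "class2": 0.05, "class1": 0.001}

#: default prior-adjustment rules: cap every prior at 0.9; for variant
#: categories with unreliable prior calibration, floor sub-0.5 priors at 0.5.
DEFAULT_PRIOR_RULES = {"cap": 0.9, "floor": 0.5, "floor_categories": ("in_frame_indel",)}


@dataclass(frozen=True)
class TumorFeature:
    patient_id: str
    is_proband: bool
    is_index_tumor: bool
    cancer_type: str  # CRC / EC / OC / other
    age_dx: int
    msi_status: str = "unknown"  # MSI-H / MSS / unknown
    ihc_pattern: str = "unknown"

    def __post_init__(self):
        if self.is_index_tumor and not self.is_proband:
            raise ValidationError(
                f"{self.patient_id}: only a proband's tumor can be the index tumor"
            )


class LikelihoodTable:
    """Tumor-characteristic LR lookup keyed by (cancer_type, category, age band).

    ``category`` is the MSI/IHC label (e.g. ``"MSI-H & MSH6 loss"``); keys not
    present fall back to ``default_lr`` (1.0) with a logged warning.
    """

    def __init__(
        self,
        entries: Mapping[Tuple[str, str, Tuple[int, int]], float],
        default_lr: float = 1.0,
    ):
        self.entries: Dict[Tuple[str, str, Tuple[int, int]], float] = {}
        for (ct, cat, band), lr in entries.items():
            band = tuple(band)
            if lr <= 0:
                raise ConfigError(f"non-positive LR for {(ct, cat, band)}")
            if band[0] >= band[1]:
                raise ConfigError(f"degenerate age band {band}")
            self.entries[(ct, cat, band)] = float(lr)
        if default_lr <= 0:
            raise ConfigError("default LR must be positive")
        self.default_lr = float(default_lr)

    def lookup(self, tumor: TumorFeature) -> float:
        category = tumor.ihc_pattern
        if tumor.msi_status != "unknown":
            category = f"{tumor.msi_status} & {tumor.ihc_pattern}"
        for (ct, cat, (lo, hi)), lr in self.entries.items():
            if ct == tumor.cancer_type and cat == category and lo <= tumor.age_dx < hi:
                return lr
        log.warning(
            "no LR entry for tumor (%s, %s, age %d); using default %.2f",
            tumor.cancer_type, category, tumor.age_dx, self.default_lr,
        )
        return self.default_lr

    @classmethod
    def from_yaml(cls, path) -> "LikelihoodTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = {
            (e["cancer_type"], e["category"], tuple(e["age_band"])): e["lr"]
            for e in doc.get("entries", [])
        }
        return cls(entries, default_lr=doc.get("default_lr", 1.0))


@dataclass
class MultifactorialResult:
    """One variant's full multifactorial audit trail."""

    variant_id: str
    prior_raw: float
    prior_used: float
    tumor_lr_total: float
    segregation_lr_total: float
    odds_for_causality: float
    posterior_odds: float
    posterior_probability: float
    iarc_class: int
    tumor_breakdown: List[Tuple[TumorFeature, float]] = field(default_factory=list)
    family_lrs: List[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "prior_raw": self.prior_raw,
            "prior_used": self.prior_used,
            "tumor_lr_total": self.tumor_lr_total,
            "segregation_lr_total": self.segregation_lr_total,
            "odds_for_causality": self.odds_for_causality,
            "posterior_odds": self.posterior_odds,
            "posterior_probability": self.posterior_probability,
            "iarc_class": self.iarc_class,
            "tumor_breakdown": [
                {"patient_id": t.patient_id, "cancer_type": t.cancer_type,
                 "age_dx": t.age_dx, "lr": lr}
                for t, lr in self.tumor_breakdown
            ],
            "family_lrs": list(self.family_lrs),
        }


def adjust_prior(
    prior_raw: float,
    variant_category: str,
    rules: Optional[Mapping] = None,
) -> float:
    """Apply the prior-adjustment rule: cap high priors, floor unreliable ones."""
    if not 0.0 <= prior_raw <= 1.0:
        raise ValidationError(f"prior {prior_raw} outside [0, 1]")
    rules = dict(DEFAULT_PRIOR_RULES if rules is None else rules)
    prior = min(prior_raw, rules["cap"])
    if variant_category in tuple(rules["floor_categories"]) and prior < rules["floor"]:
        prior = rules["floor"]
    return prior


def tumor_lr_product(
    tumors: Sequence[TumorFeature],
    table: LikelihoodTable,
) -> Tuple[float, List[Tuple[TumorFeature, float]]]:
    """Product of tumor-characteristic LRs over eligible tumors.

    Eligibility: index tumors (the ascertainment tumor of a proband) are
    excluded; additional tumors of probands and every tumor of a tested
    non-proband carrier count.
    """
    if not tumors:
        log.warning("empty tumor list; tumor LR defaults to 1.0")
        return 1.0, []
    breakdown: List[Tuple[TumorFeature, float]] = []
    total = 1.0
    for t in tumors:
        if t.is_index_tumor:
            continue
        lr = table.lookup(t)
        breakdown.append((t, lr))
        total *= lr
    return total, breakdown


def combine_evidence(
    prior_used: float,
    tumor_lr_total: float,
    segregation_lr_total: float,
    variant_id: str = "",
    iarc_thresholds: Optional[Mapping[str, float]] = None,
) -> MultifactorialResult:
    """Fold prior and likelihood ratios into posterior odds/probability."""
    if not 0.0 < prior_used < 1.0:
        raise ValidationError(f"prior_used {prior_used} degenerate (must be in (0,1))")
    if tumor_lr_total <= 0 or segregation_lr_total <= 0:
        raise ValidationError("likelihood ratios must be positive")
    prior_odds = prior_used / (1.0 - prior_used)
    odds_for_causality = tumor_lr_total * segregation_lr_total
    posterior_odds = prior_odds * odds_for_causality
    posterior_probability = posterior_odds / (1.0 + posterior_odds)
    return MultifactorialResult(
        variant_id=variant_id,
        prior_raw=prior_used,
        prior_used=prior_used,
        tumor_lr_total=tumor_lr_total,
        segregation_lr_total=segregation_lr_total,
        odds_for_causality=odds_for_causality,
        posterior_odds=posterior_odds,
        posterior_probability=posterior_probability,
        iarc_class=iarc_class(posterior_probability, iarc_thresholds),
    )


def iarc_class(
    posterior_probability: float,
    thresholds: Optional[Mapping[str, float]] = None,
) -> int:
    """Map a posterior probability of pathogenicity to IARC class 1-5."""
    p = posterior_probability
    if not 0.0 <= p <= 1.0 or math.isnan(p):
        raise ValidationError(f"posterior probability {p} outside [0, 1]")
    th = dict(DEFAULT_IARC_THRESHOLDS if thresholds is None else thresholds)
    if p > th["class5"]:
        return 5
    if p > th["class4"]:
        return 4
    if p >= th["class2"]:
        return 3
    if p >= th["class1"]:
        return 2
    return 1


def classify_variant(
    variant_id: str,
    pedigrees: Sequence[Pedigree],
    tumors: Sequence[TumorFeature],
    prior_raw: float,
    variant_category: str,
    table: LikelihoodTable,
    pen: PenetranceModel,
    prior_rules: Optional[Mapping] = None,
    iarc_thresholds: Optional[Mapping[str, float]] = None,
) -> MultifactorialResult:
    """End-to-end multifactorial classification of one variant."""
    prior_used = adjust_prior(prior_raw, variant_category, prior_rules)
    tumor_total, breakdown = tumor_lr_product(tumors, table)
    family_lrs = [cosegregation_bayes_factor(ped, pen) for ped in pedigrees]
    seg_total = combine_family_lrs(family_lrs) if family_lrs else 1.0
    result = combine_evidence(
        prior_used, tumor_total, seg_total,
        variant_id=variant_id, iarc_thresholds=iarc_thresholds,
    )
    result.prior_raw = prior_raw
    result.tumor_breakdown = breakdown
    result.family_lrs = family_lrs
    return result
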