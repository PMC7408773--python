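"""End-to-end fixture workflows: the multifactorial evidence table and the
cohort bookkeeping.

``run_table3`` recomputes, from the packaged evidence fixture (priors,
per-tumor LRs, segregation LRs), the adjusted priors, eligible-tumor LR
products, odds for causality, posterior odds/probabilities and IARC classes
for the three MSH6 variants assessed by multifactorial likelihood analysis.
``run_cohort`` applies the case-classification rules to the packaged
115-case cohort fixture and tallies the results.

Reported values are rounded half-away-from-zero at serialization only
(2 dp for odds/LRs, 3 dp for probabilities); internal math is full
precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from lynchlike.errors import ValidationError
from lynchlike.multifactorial import (
    LikelihoodTable,
    MultifactorialResult,
    TumorFeature,
    adjust_prior,
    combine_evidence,
    iarc_class,
    tumor_lr_product,
)
from lynchlike.pedigree import combine_family_lrs
from lynchlike.variant_screen import CaseRecord, count_cohort


def round_half_up(x: float, places: int) -> float:
    """Half-away-from-zero rounding used for report serialization."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fixture_path(name: str):
    return resources.files("lynchlike.fixtures") / name


def _split_msi_ihc(label: str) -> Tuple[str, str]:
    if " & " in label:
        msi, ihc = label.split(" & ", 1)
        return msi, ihc
    if label.startswith("MSI"):
        return label, "unknown"
    return "unknown", label


def load_table3_fixture(path=None) -> List[dict]:
    path = path or _fixture_path("table3_evidence.yaml")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return doc["variants"]


def run_table3(path=None, neutral_lrs: bool = False) -> pd.DataFrame:
    """Recompute the multifactorial evidence table from the packaged fixture.

    ``neutral_lrs=True`` replaces every LR by 1 (sanity mode: the posterior
    must then equal the adjusted prior).
    """
    rows = []
    for var in load_table3_fixture(path):
        prior_used = adjust_prior(var["prior_raw"], var["category"])
        tumors: List[TumorFeature] = []
        entries: Dict = {}
        for t in var["tumors"]:
            msi, ihc = _split_msi_ihc(t["msi_ihc"])
            tf = TumorFeature(
                patient_id=t["patient"], is_proband=t["proband"],
                is_index_tumor=t["index"], cancer_type=t["cancer"],
                age_dx=t["age"], msi_status=msi, ihc_pattern=ihc,
            )
            tumors.append(tf)
            if t.get("lr") is not None and not t["index"]:
                lr = 1.0 if neutral_lrs else float(t["lr"])
                category = f"{msi} & {ihc}" if msi != "unknown" else ihc
                entries[(t["cancer"], category, (t["age"], t["age"] + 1))] = lr
        table = LikelihoodTable(entries, default_lr=1.0)
        tumor_total, breakdown = tumor_lr_product(tumors, table)
        seg_lrs = [1.0] * len(var["segregation_lrs"]) if neutral_lrs else [
            float(x) for x in var["segregation_lrs"]
        ]
        seg_total = combine_family_lrs(seg_lrs)
        res = combine_evidence(
            prior_used, tumor_total, seg_total, variant_id=var["variant_id"]
        )
        rows.append({
            "variant_id": var["variant_id"],
            "prior_raw": var["prior_raw"],
            "prior_used": prior_used,
            "tumor_lr_total": round_half_up(tumor_total, 2),
            "segregation_lr_total": round_half_up(seg_total, 2),
            "odds_for_causality": round_half_up(res.odds_for_causality, 2),
            "posterior_odds": round_half_up(res.posterior_odds, 2),
            "posterior_probability": round_half_up(res.posterior_probability, 3),
            "iarc_class": res.iarc_class,
            "n_eligible_tumors": len(breakdown),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _parse_mmr(cell: str) -> List[Tuple[str, str, int, int]]:
    out = []
    if not cell:
        return out
    for item in cell.split(";"):
        gene, cdna, initial, final = item.split(":")
        out.append((gene, cdna, int(initial), int(final)))
    return out


def _parse_other(cell: str) -> List[Tuple[str, str]]:
    out = []
    if not cell:
        return out
    for item in cell.split(";"):
        gene, label = item.split(":")
        out.append((gene, label))
    return out


def load_cohort_fixture(path=None) -> List[CaseRecord]:
    path = path or _fixture_path("table1_cases.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"case_id", "mmr_variants", "other_variants", "epimutation",
                "mutyh_biallelic"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"cohort fixture missing columns {sorted(required - set(df.columns))}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(CaseRecord(
            case_id=str(row["case_id"]),
            mmr_variants=_parse_mmr(row["mmr_variants"]),
            other_gene_variants=_parse_other(row["other_variants"]),
            epimutation=row["epimutation"] == "1",
            mutyh_biallelic=row["mutyh_biallelic"] == "1",
        ))
    return records


def run_cohort(path=None) -> dict:
    """Classify every cohort case and tally the cohort summary."""
    records = load_cohort_fixture(path)
    summary = count_cohort(records)
    summary["cases"] = {r.case_id: r.final_classification for r in records}
    return summary
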