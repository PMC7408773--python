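"""Beta-value methylome comparison and constitutional-epimutation detection.

Methylation-array data enter as a matrix of per-CpG beta values (methylation
fractions in [0, 1]) over samples with group labels.  Group comparison uses
a per-site Welch two-sample t-test with Benjamini-Hochberg FDR control
across tested sites; region-level results aggregate member sites by mean
and combine their p-values by the Stouffer method.  This is a transparent
reimplementation of the usual array group-comparison workflow, not a clone
of any particular array-processing suite.

A constitutional promoter epimutation — soma-wide hypermethylation of one
allele — shows up as a hemimethylated signal (beta near 0.5) over a promoter
DMR that is essentially unmethylated in controls.  The detector flags a test
sample when its DMR mean lies in the hemimethylation window, exceeds the
control mean by a margin, and is a strong outlier in control-z units.

Coordinates: site positions are 1-based (array-manifest convention);
regions are BED 0-based half-open.  A site at 1-based position ``pos``
falls in region ``[start, end)`` iff ``start < pos <= end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lynchlike.errors import ValidationError

log = logging.getLogger(__name__)

UNDERPOWERED = "underpowered_comparison"


# ---------------------------------------------------------------------------
# Containers and I/O
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Per-CpG methylation fractions over labeled samples.

    ``sites`` has columns cpg_id, chrom, pos (1-based); ``values`` is a
    (n_sites, n_samples) float array in [0, 1] with NaN for missing.
    """

    sites: pd.DataFrame
    samples: List[str]
    groups: Dict[str, str]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("beta values must lie in [0, 1]")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(
                    f"site positions not strictly increasing on {chrom}"
                )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample {sample_id!r}") from None

    def group_members(self, group: str) -> List[str]:
        members = [s for s in self.samples if self.groups.get(s) == group]
        if not members:
            raise ValidationError(f"no samples in group {group!r}")
        return members


@dataclass(frozen=True)
class Region:
    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    kind: str = "dmr"  # cpg_island / promoter / tiling / dmr

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"region {self.name}: start >= end")


@dataclass
class RegionSet:
    regions: List[Region] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "kind"],
            dtype={"chrom": str, "name": str, "kind": str},
        )
        regions = [
            Region(str(r["name"]), str(r["chrom"]), int(r["start"]),
                   int(r["end"]), str(r.get("kind", "dmr")))
            for _, r in df.iterrows()
        ]
        return cls(regions)


def site_in_region(pos_1based: int, start0: int, end0: int) -> bool:
    """1-based site position vs BED 0-based half-open interval."""
    return start0 < pos_1based <= end0


def load_beta_matrix(beta_path, sample_sheet_path) -> BetaMatrix:
    """Load beta TSV (cpg_id, chrom, pos, one column per sample) + sample sheet."""
    df = pd.read_csv(beta_path, sep="\t", comment="#")
    for col in ("cpg_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValidationError(f"beta matrix missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("cpg_id", "chrom", "pos")]
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric beta value in column {col!r}: {exc}")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    return BetaMatrix(
        sites=df[["cpg_id", "chrom", "pos"]].reset_index(drop=True),
        samples=sample_cols,
        groups=groups,
        values=values,
    )


def write_beta_matrix(bm: BetaMatrix, beta_path, sample_sheet_path, header=None):
    out = bm.sites.copy()
    for j, s in enumerate(bm.samples):
        out[s] = bm.values[:, j]
    with open(beta_path, "w") as fh:
        if header:
            for line in header:
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(
        {"sample_id": bm.samples,
         "group": [bm.groups.get(s, "") for s in bm.samples]}
    ).to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Differential methylation
# ---------------------------------------------------------------------------

def site_differential_methylation(
    bm: BetaMatrix,
    group_a: str,
    group_b: str,
    min_group_size: int = 11,
    fdr_alpha: float = 0.05,
    effect_threshold: float = 0.20,
) -> pd.DataFrame:
    """Per-site Welch t-test with BH-FDR across tested sites.

    Sites with fewer than 3 non-missing values in either group are reported
    untested.  Significance is only claimed when both groups reach
    ``min_group_size`` samples (the groups-larger-than-10 rule); otherwise
    every site carries the ``underpowered_comparison`` flag.
    """
    idx_a = [bm.sample_index(s) for s in bm.group_members(group_a)]
    idx_b = [bm.sample_index(s) for s in bm.group_members(group_b)]
    a = bm.values[:, idx_a]
    b = bm.values[:, idx_b]
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    tested = (n_a >= 3) & (n_b >= 3)

    mean_a = np.full(len(bm.sites), np.nan)
    mean_b = np.full(len(bm.sites), np.nan)
    with np.errstate(invalid="ignore"):
        mean_a[n_a > 0] = np.nanmean(a[n_a > 0], axis=1)
        mean_b[n_b > 0] = np.nanmean(b[n_b > 0], axis=1)

    p = np.full(len(bm.sites), np.nan)
    if tested.any():
        res = stats.ttest_ind(
            a[tested], b[tested], axis=1, equal_var=False, nan_policy="omit"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals[~np.isfinite(pvals)] = 1.0  # zero-variance identical groups
        p[tested] = pvals

    q = np.full(len(bm.sites), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    powered = len(idx_a) >= min_group_size and len(idx_b) >= min_group_size
    if not powered:
        log.warning(
            "group sizes %d vs %d below %d: flagged %s, no significance claims",
            len(idx_a), len(idx_b), min_group_size, UNDERPOWERED,
        )
    delta = mean_a - mean_b
    out = bm.sites.copy()
    out["mean_beta_a"] = mean_a
    out["mean_beta_b"] = mean_b
    out["delta_beta"] = delta
    out["p_value"] = p
    out["fdr_q"] = q
    out["tested"] = tested
    out["significant"] = powered & tested & (q < fdr_alpha)
    out["large_effect"] = np.abs(delta) > effect_threshold
    out["flag"] = "" if powered else UNDERPOWERED
    return out


def region_aggregate(site_results: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Region-level aggregation: mean of member-site means, Stouffer p, BH-FDR.

    Regions with no member sites are omitted.  The Stouffer combination uses
    equal weights: z = sum(norm.isf(p_i)) / sqrt(k).
    """
    rows = []
    for reg in regions.regions:
        members = site_results[
            (site_results["chrom"] == reg.chrom)
            & (site_results["pos"] > reg.start)
            & (site_results["pos"] <= reg.end)
        ]
        if members.empty:
            continue
        tested = members[members["tested"] & np.isfinite(members["p_value"])]
        if len(tested):
            pclip = np.clip(tested["p_value"].to_numpy(), 1e-300, 1 - 1e-16)
            z = stats.norm.isf(pclip).sum() / np.sqrt(len(pclip))
            p_comb = float(stats.norm.sf(z))
        else:
            p_comb = np.nan
        mean_a = float(members["mean_beta_a"].mean())
        mean_b = float(members["mean_beta_b"].mean())
        rows.append({
            "region": reg.name, "chrom": reg.chrom, "start": reg.start,
            "end": reg.end, "kind": reg.kind, "n_sites": len(members),
            "mean_beta_a": mean_a, "mean_beta_b": mean_b,
            "delta_beta": mean_a - mean_b, "p_value": p_comb,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["region", "chrom", "start", "end", "kind", "n_sites",
                     "mean_beta_a", "mean_beta_b", "delta_beta", "p_value",
                     "fdr_q", "significant", "large_effect"]
        )
    testable = np.isfinite(out["p_value"].to_numpy())
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = multipletests(out.loc[testable, "p_value"], method="fdr_bh")[1]
    out["fdr_q"] = q
    out["significant"] = out["fdr_q"] < 0.05
    out["large_effect"] = out["delta_beta"].abs() > 0.20
    return out


# ---------------------------------------------------------------------------
# Constitutional epimutation detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpimutationCall:
    sample_id: str
    region: str
    mean_beta_sample: float
    control_mean: float
    control_sd: float
    z_score: float
    call: bool
    flag: str = ""


def detect_epimutation(
    bm: BetaMatrix,
    dmr: Region,
    test_sample: str,
    control_samples: Sequence[str],
    hemi_window: Tuple[float, float] = (0.25, 0.75),
    min_delta: float = 0.20,
    min_z: float = 5.0,
) -> EpimutationCall:
    """Flag a hemimethylated promoter DMR in one sample against controls.

    The call requires the test sample's DMR mean beta to (i) fall in the
    hemimethylation window (one methylated allele, one unmethylated), (ii)
    exceed the control mean by ``min_delta``, and (iii) be a ``min_z``-sigma
    outlier against the per-sample control DMR means.  Fully methylated
    signals fall outside the window and are flagged for manual review
    rather than called.
    """
    mask = (
        (bm.sites["chrom"] == dmr.chrom)
        & (bm.sites["pos"] > dmr.start)
        & (bm.sites["pos"] <= dmr.end)
    ).to_numpy()
    if mask.sum() == 0:
        raise ValidationError(f"DMR {dmr.name} covers no sites in the matrix")
    if mask.sum() < 3:
        log.warning("DMR %s covers only %d sites (>= 3 recommended)",
                    dmr.name, mask.sum())
    if len(control_samples) < 10:
        log.warning("only %d controls (>= 10 recommended)", len(control_samples))

    test_mean = float(np.nanmean(bm.values[mask, bm.sample_index(test_sample)]))
    ctrl_means = np.array([
        np.nanmean(bm.values[mask, bm.sample_index(s)]) for s in control_samples
    ])
    control_mean = float(ctrl_means.mean())
    control_sd = float(ctrl_means.std(ddof=1)) if len(ctrl_means) > 1 else 0.0
    z = (test_mean - control_mean) / control_sd if control_sd > 0 else np.inf

    in_window = hemi_window[0] <= test_mean <= hemi_window[1]
    exceeds = (test_mean - control_mean) > min_delta and z > min_z
    flag = ""
    if exceeds and not in_window and test_mean > hemi_window[1]:
        flag = "fully_methylated_review"
    return EpimutationCall(
        sample_id=test_sample,
        region=dmr.name,
        mean_beta_sample=test_mean,
        control_mean=control_mean,
        control_sd=control_sd,
        z_score=float(z),
        call=bool(in_window and exceeds),
        flag=flag,
    )


def default_mlh1_dmr() -> Region:
    """The shipped MLH1 promoter DMR definition (GRCh37; editable BED config)."""
    from pathlib import Path

    path = Path(__file__).parent / "config" / "mlh1_dmr.bed"
    rs = RegionSet.from_bed(path)
    for reg in rs.regions:
        if reg.name == "MLH1_DMR":
            return reg
    raise ValidationError("MLH1_DMR not found in shipped config")
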