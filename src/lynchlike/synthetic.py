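"""Synthetic-data generators with the statistical structure each stage assumes.

Every generator is a pure function of its spec (which carries the seed):
rerunning with the same spec reproduces identical output.  Independent
pseudo-random streams are derived from the master seed by stable labeled
sub-seeding (CRC32 of the generator label), so adding a generator never
perturbs the draws of another.

What the generators emulate — and what they do not — is documented in the
package methods note: pedigrees are non-inbred two/three-generation families
gene-dropped under the dominant two-class model; beta matrices have the
bimodal island/background mixture of blood methylomes with optional
hemimethylated promoter DMRs and group mean shifts; the variant, marker and
SNuPE tables are small ground-truth-by-construction toys.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from lynchlike.errors import ConfigError, ValidationError
from lynchlike.methylome import BetaMatrix, Region, RegionSet
from lynchlike.msi_emast import MarkerProfile
from lynchlike.pedigree import (
    CARRIER,
    NON_CARRIER,
    UNTESTED,
    Individual,
    Pedigree,
    PenetranceModel,
    PhenotypeEvent,
    default_penetrance,
)
from lynchlike.variant_screen import VariantCall


def sub_rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream for one generator, stable under label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    seed: int = 0
    family_size_range: Tuple[int, int] = (5, 10)
    hypothesis: str = "pathogenic"  # phenotype-generating model
    allele_frequency: float = 0.05  # simulation default; chosen so that
    # conditioning on a carrier proband is feasible by rejection
    test_fraction: float = 0.6  # genotype observation mask for non-probands
    penetrance: Optional[PenetranceModel] = None
    max_retries: int = 20000

    def __post_init__(self):
        if self.hypothesis not in ("pathogenic", "neutral"):
            raise ConfigError(f"unknown hypothesis {self.hypothesis!r}")
        lo, hi = self.family_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("invalid family size range")


_AGE_RANGES = {0: (60, 85), 1: (35, 60), 2: (10, 35)}  # per generation


def _build_structure(rng: np.random.Generator, target: int) -> List[dict]:
    """Non-inbred 2-3 generation family skeleton of roughly `target` members."""
    members = [
        {"id": "F1", "father": None, "mother": None, "sex": "male", "gen": 0},
        {"id": "F2", "father": None, "mother": None, "sex": "female", "gen": 0},
    ]
    if target <= 2:
        return members[: max(target, 1)]
    n_children = max(1, min(int(rng.integers(1, 5)), target - 2))
    child_ids = []
    for i in range(n_children):
        cid = f"C{i+1}"
        members.append({
            "id": cid, "father": "F1", "mother": "F2",
            "sex": "male" if rng.random() < 0.5 else "female", "gen": 1,
        })
        child_ids.append(cid)
    k = 0
    while len(members) < target and child_ids:
        cid = child_ids[k % len(child_ids)]
        child = next(m for m in members if m["id"] == cid)
        spouse_id = f"S{cid}"
        if not any(m["id"] == spouse_id for m in members):
            members.append({
                "id": spouse_id, "father": None, "mother": None,
                "sex": "female" if child["sex"] == "male" else "male", "gen": 1,
            })
        if len(members) >= target:
            break
        gid = f"G{cid}{k+1}"
        father, mother = (
            (cid, spouse_id) if child["sex"] == "male" else (spouse_id, cid)
        )
        members.append({
            "id": gid, "father": father, "mother": mother,
            "sex": "male" if rng.random() < 0.5 else "female", "gen": 2,
        })
        k += 1
    return members


def _draw_ages(rng, members) -> Dict[str, int]:
    return {
        m["id"]: int(rng.integers(*_AGE_RANGES[m["gen"]])) for m in members
    }


def _gene_drop(rng, members, carrier_prior: float) -> Dict[str, str]:
    genotypes: Dict[str, str] = {}
    for m in members:  # members listed parents-before-children
        if m["father"] is None:
            genotypes[m["id"]] = (
                CARRIER if rng.random() < carrier_prior else NON_CARRIER
            )
        else:
            p = {
                (NON_CARRIER, NON_CARRIER): 0.0,
                (NON_CARRIER, CARRIER): 0.5,
                (CARRIER, NON_CARRIER): 0.5,
                (CARRIER, CARRIER): 0.75,
            }[(genotypes[m["father"]], genotypes[m["mother"]])]
            genotypes[m["id"]] = CARRIER if rng.random() < p else NON_CARRIER
    return genotypes


def _invert_cumulative(pen: PenetranceModel, ct, sex, gclass, u, censor) -> Optional[int]:
    """Age at onset via inverse cumulative risk; None if no event by censor."""
    if u >= pen.cumulative_risk(ct, sex, gclass, censor):
        return None
    lo = pen.age_bands[0][0]
    prev_f, prev_age = 0.0, lo
    for (s, e) in pen.age_bands:
        f = pen.cumulative_risk(ct, sex, gclass, e)
        if u < f:
            age = prev_age + (e - prev_age) * (u - prev_f) / (f - prev_f)
            return int(min(round(age), censor))
        prev_f, prev_age = f, e
    return None  # pragma: no cover


def _draw_phenotypes(rng, members, ages, genotypes, pen, hypothesis):
    phenos: Dict[str, List[PhenotypeEvent]] = {m["id"]: [] for m in members}
    for m in members:
        gclass = NON_CARRIER if hypothesis == "neutral" else genotypes[m["id"]]
        for ct in pen.cancer_types:
            age = _invert_cumulative(
                pen, ct, m["sex"], gclass, rng.random(), ages[m["id"]]
            )
            if age is not None:
                phenos[m["id"]].append(PhenotypeEvent(ct, max(age, 1)))
    return phenos


def simulate_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Gene-dropped family with an affected carrier proband.

    Under the neutral hypothesis phenotypes are drawn first (non-carrier
    risks for everyone), the proband is a uniformly random affected member,
    and genotypes are then rejection-sampled until the proband is a carrier.
    Because phenotype and proband choice are genotype-independent, the
    accepted relatives' genotypes follow exactly the Mendelian conditional
    given the proband's carrier status — the distribution the cosegregation
    denominator assumes, which makes E[LR] = 1 exact.

    Under the pathogenic hypothesis genotypes are drawn first, phenotypes
    follow the genotype-specific risks, and the proband is a random affected
    carrier.
    """
    rng = sub_rng(spec.seed, "pedigree")
    pen = spec.penetrance or default_penetrance()
    target = int(rng.integers(spec.family_size_range[0],
                              spec.family_size_range[1] + 1))
    members = _build_structure(rng, target)
    ages = _draw_ages(rng, members)
    carrier_prior = 2 * spec.allele_frequency * (1 - spec.allele_frequency)

    proband_id = None
    genotypes = phenos = None
    if spec.hypothesis == "neutral":
        for _ in range(spec.max_retries):
            phenos = _draw_phenotypes(rng, members, ages, {}, pen, "neutral")
            affected = [i for i, evs in phenos.items() if evs]
            if affected:
                proband_id = affected[int(rng.integers(len(affected)))]
                break
        else:
            raise ValidationError("no affected individual after max retries")
        for _ in range(spec.max_retries):
            genotypes = _gene_drop(rng, members, carrier_prior)
            if genotypes[proband_id] == CARRIER:
                break
        else:
            raise ValidationError("no carrier proband after max retries")
    else:
        for _ in range(spec.max_retries):
            genotypes = _gene_drop(rng, members, carrier_prior)
            phenos = _draw_phenotypes(rng, members, ages, genotypes, pen,
                                      "pathogenic")
            affected_carriers = [
                i for i, evs in phenos.items()
                if evs and genotypes[i] == CARRIER
            ]
            if affected_carriers:
                proband_id = affected_carriers[int(rng.integers(len(affected_carriers)))]
                break
        else:
            raise ValidationError("no affected carrier after max retries")

    individuals = {}
    for m in members:
        iid = m["id"]
        observed = iid == proband_id or rng.random() < spec.test_fraction
        individuals[iid] = Individual(
            id=iid,
            family_id="SIM",
            father_id=m["father"],
            mother_id=m["mother"],
            sex=m["sex"],
            genotype=genotypes[iid] if observed else UNTESTED,
            is_proband=iid == proband_id,
            ascertainment="clinic",
            phenotypes=phenos[iid],
            censor_age=ages[iid],
        )
    return Pedigree(individuals, allele_frequency=spec.allele_frequency)


def write_pedigree_files(ped: Pedigree, ped_path, phen_path):
    rows, prows = [], []
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    for ind in ped.members():
        rows.append({
            "family_id": ind.family_id, "individual_id": ind.id,
            "father_id": ind.father_id or "0",
            "mother_id": ind.mother_id or "0",
            "sex": sex_code[ind.sex], "genotype": ind.genotype,
            "proband": int(ind.is_proband), "censor_age": ind.censor_age,
        })
        for ev in ind.phenotypes:
            prows.append({"individual_id": ind.id,
                          "cancer_type": ev.cancer_type, "age_dx": ev.age_dx})
    pd.DataFrame(rows).to_csv(ped_path, sep="\t", index=False)
    pd.DataFrame(prows, columns=["individual_id", "cancer_type", "age_dx"]
                 ).to_csv(phen_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Beta matrices
# ---------------------------------------------------------------------------

@dataclass
class BetaSpec:
    seed: int = 0
    n_sites: int = 10_000
    groups: Dict[str, int] = field(default_factory=lambda: {"A": 12, "B": 12})
    island_fraction: float = 0.3   # low-methylation island compartment
    island_beta: Tuple[float, float] = (1.0, 20.0)     # Beta(a, b) params
    background_beta: Tuple[float, float] = (20.0, 2.0)
    # group mean-shift spike (differential-methylation power scenarios)
    n_shift_sites: int = 0
    shift_delta: float = 0.4
    shift_baseline: float = 0.3
    shift_sd: float = 0.05
    shift_group: str = "B"
    # hemimethylated DMR carriers (constitutional epimutation scenarios)
    dmr_n_sites: int = 0
    dmr_carriers: Tuple[str, ...] = ()
    dmr_carrier_mean: float = 0.48
    dmr_carrier_conc: float = 100.0  # Beta concentration a+b for carriers
    dmr_control_beta: Tuple[float, float] = (1.0, 30.0)


def simulate_beta_matrix(spec: BetaSpec) -> Tuple[BetaMatrix, RegionSet]:
    """Bimodal blood-methylome-like beta matrix with optional spikes.

    Sites 1..dmr_n_sites form a contiguous promoter DMR: designated carrier
    samples draw from a Beta centered at ``dmr_carrier_mean`` (hemimethylated),
    everyone else from the near-zero island distribution.  ``n_shift_sites``
    sites after the DMR get a group mean shift of ``shift_delta`` for
    ``shift_group`` (truncated-normal noise, sd ``shift_sd``).
    """
    rng = sub_rng(spec.seed, "beta")
    samples, groups = [], {}
    for g, n in spec.groups.items():
        for i in range(n):
            sid = f"{g}{i+1:02d}"
            samples.append(sid)
            groups[sid] = g
    unknown = [c for c in spec.dmr_carriers if c not in samples]
    if unknown:
        raise ConfigError(f"DMR carriers not among samples: {unknown}")
    if spec.dmr_n_sites + spec.n_shift_sites > spec.n_sites:
        raise ConfigError("spiked sites exceed total site count")

    n, m = spec.n_sites, len(samples)
    values = np.empty((n, m))
    is_island = rng.random(n) < spec.island_fraction
    a = np.where(is_island, spec.island_beta[0], spec.background_beta[0])
    b = np.where(is_island, spec.island_beta[1], spec.background_beta[1])
    values[:] = rng.beta(a[:, None], b[:, None], size=(n, m))

    dmr_lo, dmr_hi = 0, spec.dmr_n_sites
    if spec.dmr_n_sites:
        ca, cb = spec.dmr_control_beta
        values[dmr_lo:dmr_hi, :] = rng.beta(ca, cb, size=(spec.dmr_n_sites, m))
        ka = spec.dmr_carrier_mean * spec.dmr_carrier_conc
        kb = (1 - spec.dmr_carrier_mean) * spec.dmr_carrier_conc
        for c in spec.dmr_carriers:
            j = samples.index(c)
            values[dmr_lo:dmr_hi, j] = rng.beta(ka, kb, size=spec.dmr_n_sites)

    shift_lo, shift_hi = dmr_hi, dmr_hi + spec.n_shift_sites
    if spec.n_shift_sites:
        base = rng.normal(spec.shift_baseline, spec.shift_sd,
                          size=(spec.n_shift_sites, m))
        shifted = [j for j, s in enumerate(samples)
                   if groups[s] == spec.shift_group]
        base[:, shifted] += spec.shift_delta
        values[shift_lo:shift_hi, :] = np.clip(base, 0.0, 1.0)

    pos = 1000 + 100 * np.arange(n)  # 1-based, 100 bp spacing
    sites = pd.DataFrame({
        "cpg_id": [f"cg{i:08d}" for i in range(n)],
        "chrom": "chr1",
        "pos": pos,
    })
    regions = []
    if spec.dmr_n_sites:
        regions.append(Region("SIM_DMR", "chr1", int(pos[dmr_lo] - 1),
                              int(pos[dmr_hi - 1]), "dmr"))
    if spec.n_shift_sites:
        regions.append(Region("SIM_SHIFT", "chr1", int(pos[shift_lo] - 1),
                              int(pos[shift_hi - 1]), "tiling"))
    bm = BetaMatrix(sites=sites, samples=samples, groups=groups, values=values)
    return bm, RegionSet(regions)


# ---------------------------------------------------------------------------
# Toy tables: variants, markers, SNuPE
# ---------------------------------------------------------------------------

@dataclass
class VariantTableSpec:
    seed: int = 0
    n_passing: int = 1
    include_single_violations: bool = True


def simulate_variant_table(spec: VariantTableSpec) -> List[VariantCall]:
    """Calls with known filter fate: n all-passing + 5 single-violation calls.

    Each violating call fails exactly one screening rule (Phred, allele
    ratio, depth, population MAF, prior InSiGHT class).
    """
    rng = sub_rng(spec.seed, "variants")
    calls: List[VariantCall] = []

    def ok(i, **kw):
        base = dict(
            sample_id=f"S{i}", gene="MSH6", cdna_change=f"c.{100+i}A>G",
            phred_qual=float(rng.integers(40, 90)),
            read_depth=int(rng.integers(50, 200)),
            alt_allele_ratio=float(rng.uniform(0.35, 0.55)),
            maf_exac=None, maf_esp=None, insight_class=None,
        )
        base.update(kw)
        return VariantCall(**base)

    for i in range(spec.n_passing):
        calls.append(ok(i))
    if spec.include_single_violations:
        calls.append(ok(90, phred_qual=29.0))
        calls.append(ok(91, alt_allele_ratio=0.04))
        calls.append(ok(92, read_depth=37))
        calls.append(ok(93, maf_exac=0.02))
        calls.append(ok(94, insight_class=2))
    return calls


@dataclass
class MarkerSpec:
    seed: int = 0
    n_markers: int = 6
    n_unstable: int = 2


def simulate_marker_profiles(spec: MarkerSpec) -> List[MarkerProfile]:
    """Tetranucleotide marker panel with exactly n_unstable unstable markers."""
    if spec.n_unstable > spec.n_markers:
        raise ConfigError("more unstable markers than markers")
    rng = sub_rng(spec.seed, "markers")
    profiles = []
    unstable_idx = set(rng.choice(spec.n_markers, spec.n_unstable, replace=False))
    for i in range(spec.n_markers):
        base = int(rng.integers(100, 200)) // 4 * 4
        normal = frozenset({base, base + 4})
        if i in unstable_idx:
            tumor = frozenset({base - 4, base + 4})  # novel shortened allele
        else:
            tumor = normal
        profiles.append(MarkerProfile(f"MARKER{i+1}", normal, tumor))
    return profiles


@dataclass
class SnupeSpec:
    seed: int = 0
    true_ase: float = 0.7
    n_replicates: int = 4
    noise_sd: float = 0.02  # lognormal sigma on each measured peak ratio
    gdna_ratio: float = 1.0  # heterozygous gDNA: variant/wildtype near 1


def simulate_snupe(spec: SnupeSpec) -> pd.DataFrame:
    """SNuPE replicate table with known true ASE and lognormal peak noise."""
    if spec.true_ase <= 0:
        raise ConfigError("true ASE must be positive")
    rng = sub_rng(spec.seed, "snupe")
    rows = []
    for i in range(spec.n_replicates):
        g = spec.gdna_ratio * np.exp(rng.normal(0, spec.noise_sd))
        c = spec.gdna_ratio * spec.true_ase * np.exp(rng.normal(0, spec.noise_sd))
        rows.append({"replicate_id": f"rep{i+1}", "gdna_ratio": g,
                     "cdna_ratio": c, "condition": "untreated"})
    return pd.DataFrame(rows)
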