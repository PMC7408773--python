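"""Pedigree representation and cosegregation Bayes factors.

The model is the standard autosomal-dominant two-class construction used in
quantitative cosegregation analysis of rare cancer-predisposition alleles:
each individual is either a *carrier* (heterozygote; the negligible mass of
pathogenic homozygotes is folded into this class) or a *non-carrier*.
Founders carry with Hardy-Weinberg probability ``2q(1-q)`` where ``q`` is the
pathogenic allele frequency; transmission to children follows Mendelian
two-class probabilities; phenotypes enter through age- and sex-specific
cumulative-risk (penetrance) liability classes.

The cosegregation likelihood ratio (a Bayes factor) compares the probability
of the observed relatives' genotypes, given the family's phenotypes and the
proband's positive test, under the hypothesis that the variant is pathogenic
(carrier penetrance applies to carriers) versus neutral (everyone expresses
the non-carrier risk).  Both conditional probabilities are exact pedigree
likelihood ratios; the likelihood itself is computed by variable elimination
over the binary genotype variables, which is exact on arbitrary pedigree
graphs and scales far beyond the brute-force enumeration used as an oracle
in the test-suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from lynchlike.errors import ConfigError, PedigreeError, ValidationError

CARRIER = "carrier"
NON_CARRIER = "non_carrier"
UNTESTED = "untested"

GENOTYPES = (NON_CARRIER, CARRIER)  # domain order: index 0 / 1

# P(child class | father class, mother class); two-class fold of the
# dominant diallelic model (het x het -> 3/4 carrier incl. homozygote).
_TRANSMISSION = np.array(
    [
        [[1.0, 0.0], [0.5, 0.5]],
        [[0.5, 0.5], [0.25, 0.75]],
    ]
)


@dataclass(frozen=True)
class PhenotypeEvent:
    """A cancer diagnosis (or the explicit 'unaffected' null event)."""

    cancer_type: str  # CRC, EC, OC, other, unaffected
    age_dx: int

    def __post_init__(self):
        if not 0 <= self.age_dx <= 120:
            raise ValidationError(f"age_dx {self.age_dx} outside [0, 120]")


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str = "unknown"  # male / female / unknown
    genotype: str = UNTESTED
    is_proband: bool = False
    ascertainment: str = "unknown"  # clinic / population / unknown
    phenotypes: List[PhenotypeEvent] = field(default_factory=list)
    censor_age: int = 0

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id}: exactly one parent recorded; "
                "founders must have neither, non-founders both"
            )
        if self.genotype not in (CARRIER, NON_CARRIER, UNTESTED):
            raise ValidationError(f"unknown genotype code {self.genotype!r}")
        for ev in self.phenotypes:
            if ev.cancer_type != "unaffected" and ev.age_dx > self.censor_age:
                raise ValidationError(
                    f"individual {self.id}: censor_age {self.censor_age} < "
                    f"phenotype age {ev.age_dx}"
                )


@dataclass
class Pedigree:
    """A family graph plus the population frequency of the pathogenic allele."""

    individuals: Dict[str, Individual]
    allele_frequency: float = 1e-4

    def __post_init__(self):
        if not 0 < self.allele_frequency < 0.5:
            raise ConfigError(
                f"allele frequency {self.allele_frequency} outside (0, 0.5)"
            )
        self._validate_structure()

    def _validate_structure(self):
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.id}: dangling parent id {pid!r}"
                    )
        # acyclicity through parent links (DFS with colors)
        state: Dict[str, int] = {}

        def visit(iid: str):
            state[iid] = 1
            ind = self.individuals[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if state.get(pid) == 1:
                    raise PedigreeError(f"cycle through parent links at {pid!r}")
                if pid not in state:
                    visit(pid)
            state[iid] = 2

        for iid in self.individuals:
            if iid not in state:
                visit(iid)

    @property
    def carrier_prior(self) -> float:
        q = self.allele_frequency
        return 2.0 * q * (1.0 - q)

    def probands(self) -> List[Individual]:
        return [i for i in self.individuals.values() if i.is_proband]

    def members(self) -> List[Individual]:
        return list(self.individuals.values())


# ---------------------------------------------------------------------------
# Penetrance
# ---------------------------------------------------------------------------

class PenetranceModel:
    """Age-banded cumulative cancer risks per (cancer type, sex, genotype class).

    ``age_bands`` is an ordered list of half-open integer intervals
    ``[start, end)`` covering the supported age range.  ``risks`` maps
    ``(cancer_type, sex, genotype_class)`` to the cumulative risk reached at
    the *end* of each band; the cumulative-risk function F is the piecewise
    linear interpolant through (band boundaries, cumulative values) with
    F(first band start) = 0.

    Liability contributions:

    * an individual diagnosed with cancer ``c`` at age ``a`` contributes
      ``F(a) - F(start of the band containing a)`` — the incidence captured
      within the diagnosis liability class;
    * an individual unaffected by ``c`` up to ``censor_age`` contributes
      ``1 - F(censor_age)``.

    Sex ``unknown`` uses the male/female average.  Sex-inapplicable cancers
    (e.g. endometrial risk for a male) have F = 0 and contribute 1.
    """

    def __init__(
        self,
        age_bands: Sequence[Tuple[int, int]],
        risks: Mapping[Tuple[str, str, str], Sequence[float]],
    ):
        bands = [tuple(b) for b in age_bands]
        if not bands:
            raise ConfigError("penetrance model needs at least one age band")
        for (s, e) in bands:
            if s >= e:
                raise ConfigError(f"degenerate age band [{s}, {e})")
        for (a, b) in zip(bands, bands[1:]):
            if a[1] != b[0]:
                raise ConfigError("age bands must be contiguous and ordered")
        self.age_bands = bands
        self.risks: Dict[Tuple[str, str, str], Tuple[float, ...]] = {}
        for key, vals in risks.items():
            vals = tuple(float(v) for v in vals)
            if len(vals) != len(bands):
                raise ConfigError(
                    f"risk vector for {key} has {len(vals)} entries, "
                    f"expected {len(bands)}"
                )
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigError(f"risk outside [0,1] for {key}")
            if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"cumulative risk not non-decreasing for {key}")
            self.risks[tuple(key)] = vals

    @property
    def cancer_types(self) -> List[str]:
        return sorted({k[0] for k in self.risks})

    # -- cumulative risk -----------------------------------------------------

    def _vector(self, cancer_type: str, sex: str, genotype_class: str):
        if sex == "unknown":
            vm = self._vector(cancer_type, "male", genotype_class)
            vf = self._vector(cancer_type, "female", genotype_class)
            if vm is None:
                return vf
            if vf is None:
                return vm
            return tuple(0.5 * (a + b) for a, b in zip(vm, vf))
        return self.risks.get((cancer_type, sex, genotype_class))

    def cumulative_risk(
        self, cancer_type: str, sex: str, genotype_class: str, age: float
    ) -> float:
        vec = self._vector(cancer_type, sex, genotype_class)
        if vec is None:
            return 0.0
        lo = self.age_bands[0][0]
        if age <= lo:
            return 0.0
        prev_f, prev_age = 0.0, lo
        for (s, e), f in zip(self.age_bands, vec):
            if age < e:
                return prev_f + (f - prev_f) * (age - prev_age) / (e - prev_age)
            prev_f, prev_age = f, e
        return vec[-1]

    def band_start(self, age: float) -> float:
        """Largest band boundary strictly below ``age`` (a diagnosis exactly
        on a boundary belongs to the liability class it closes)."""
        boundaries = [self.age_bands[0][0]] + [e for (_, e) in self.age_bands]
        below = [b for b in boundaries if b < age]
        return below[-1] if below else boundaries[0]

    # -- liability -----------------------------------------------------------

    def phenotype_likelihood(self, ind: Individual, genotype_class: str) -> float:
        """P(individual's phenotype record | genotype class)."""
        lik = 1.0
        events = [e for e in ind.phenotypes if e.cancer_type != "unaffected"]
        affected_types = set()
        for ev in events:
            if ev.cancer_type == "other":
                continue  # no liability class configured; uninformative
            f_hi = self.cumulative_risk(ev.cancer_type, ind.sex, genotype_class, ev.age_dx)
            f_lo = self.cumulative_risk(
                ev.cancer_type, ind.sex, genotype_class, self.band_start(ev.age_dx)
            )
            lik *= max(f_hi - f_lo, 0.0)
            affected_types.add(ev.cancer_type)
        for ct in self.cancer_types:
            if ct in affected_types:
                continue
            f = self.cumulative_risk(ct, ind.sex, genotype_class, ind.censor_age)
            lik *= 1.0 - f
        return lik

    # -- serialization ---------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PenetranceModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        bands = [tuple(b) for b in doc["age_bands"]]
        risks = {}
        for ct, by_sex in doc["risks"].items():
            for sex, by_class in by_sex.items():
                for gclass, vec in by_class.items():
                    risks[(ct, sex, gclass)] = vec
        return cls(bands, risks)

    @classmethod
    def flat(cls, risk: float = 0.0) -> "PenetranceModel":
        """Degenerate model: identical risk for carriers and non-carriers."""
        bands = [(0, 120)]
        risks = {}
        for ct in ("CRC",):
            for sex in ("male", "female"):
                for gc in (CARRIER, NON_CARRIER):
                    risks[(ct, sex, gc)] = [risk]
        return cls(bands, risks)


def default_penetrance() -> PenetranceModel:
    """The shipped replaceable penetrance configuration."""
    path = Path(__file__).parent / "config" / "penetrance_default.yaml"
    return PenetranceModel.from_yaml(path)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
              "male": "male", "female": "female", "unknown": "unknown"}


def read_pedigree(
    ped_path, phenotype_path, allele_frequency: float = 1e-4
) -> Pedigree:
    """Read a PED-like TSV plus a phenotype TSV into a validated Pedigree.

    PED columns: family_id, individual_id, father_id, mother_id, sex(1/2/0),
    genotype(carrier/non_carrier/untested), proband(0/1), censor_age.
    Unknown parents coded "0" become null.  Phenotype columns:
    individual_id, cancer_type, age_dx.
    """
    ped = pd.read_csv(ped_path, sep="\t", dtype=str)
    phen = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    required = ["family_id", "individual_id", "father_id", "mother_id",
                "sex", "genotype", "proband", "censor_age"]
    missing = [c for c in required if c not in ped.columns]
    if missing:
        raise ValidationError(f"pedigree file missing columns {missing}")
    if ped["individual_id"].duplicated().any():
        dup = ped.loc[ped["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise PedigreeError(f"duplicate individual id {dup!r}")

    events: Dict[str, List[PhenotypeEvent]] = {}
    for _, row in phen.iterrows():
        events.setdefault(str(row["individual_id"]), []).append(
            PhenotypeEvent(str(row["cancer_type"]), int(row["age_dx"]))
        )

    individuals: Dict[str, Individual] = {}
    for _, row in ped.iterrows():
        iid = str(row["individual_id"])
        father = None if str(row["father_id"]) in ("0", "nan") else str(row["father_id"])
        mother = None if str(row["mother_id"]) in ("0", "nan") else str(row["mother_id"])
        if pd.isna(row["censor_age"]):
            raise ValidationError(f"individual {iid}: censor_age missing")
        individuals[iid] = Individual(
            id=iid,
            family_id=str(row["family_id"]),
            father_id=father,
            mother_id=mother,
            sex=_SEX_CODES.get(str(row["sex"]), "unknown"),
            genotype=str(row["genotype"]),
            is_proband=str(row["proband"]) in ("1", "true", "True"),
            phenotypes=events.get(iid, []),
            censor_age=int(row["censor_age"]),
        )
    return Pedigree(individuals, allele_frequency=allele_frequency)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

def _unary_factors(
    ped: Pedigree,
    pen: PenetranceModel,
    hypothesis: str,
    fixed_genotypes: Mapping[str, str],
    exclude_phenotypes: Iterable[str] = (),
) -> Dict[str, np.ndarray]:
    if hypothesis not in ("pathogenic", "neutral"):
        raise ValidationError(f"unknown hypothesis {hypothesis!r}")
    for iid in fixed_genotypes:
        if iid not in ped.individuals:
            raise ValidationError(f"fixed genotype for unknown individual {iid!r}")
    excluded = set(exclude_phenotypes)
    h = ped.carrier_prior
    unary: Dict[str, np.ndarray] = {}
    for iid, ind in ped.individuals.items():
        vec = np.ones(2)
        if ind.is_founder:
            vec *= np.array([1.0 - h, h])
        if iid not in excluded:
            if hypothesis == "pathogenic":
                pheno = np.array(
                    [pen.phenotype_likelihood(ind, NON_CARRIER),
                     pen.phenotype_likelihood(ind, CARRIER)]
                )
            else:  # neutral: phenotype independent of genotype class
                p = pen.phenotype_likelihood(ind, NON_CARRIER)
                pheno = np.array([p, p])
            vec *= pheno
        g = fixed_genotypes.get(iid)
        if g is not None:
            if g not in (CARRIER, NON_CARRIER):
                raise ValidationError(f"cannot fix genotype {g!r}")
            mask = np.zeros(2)
            mask[GENOTYPES.index(g)] = 1.0
            vec *= mask
        unary[iid] = vec
    return unary


def pedigree_loglikelihood(
    ped: Pedigree,
    pen: PenetranceModel,
    hypothesis: str,
    fixed_genotypes: Optional[Mapping[str, str]] = None,
    exclude_phenotypes: Iterable[str] = (),
) -> float:
    """Exact log-likelihood of phenotypes and fixed genotypes.

    Sums, over every genotype-class configuration consistent with
    ``fixed_genotypes``, the product of founder priors, Mendelian
    transmission probabilities and phenotype liabilities.  Computed by
    variable elimination with a min-degree ordering; exact on any pedigree
    graph and equal to brute-force enumeration.
    """
    fixed_genotypes = dict(fixed_genotypes or {})
    unary = _unary_factors(ped, pen, hypothesis, fixed_genotypes, exclude_phenotypes)

    # Factors: dict var-tuple -> ndarray over {0,1}^k (axis order = tuple order)
    factors: List[Tuple[Tuple[str, ...], np.ndarray]] = []
    for iid, vec in unary.items():
        factors.append(((iid,), vec))
    for iid, ind in ped.individuals.items():
        if not ind.is_founder:
            factors.append(
                ((ind.father_id, ind.mother_id, iid), _TRANSMISSION.copy())
            )

    log_scale = 0.0
    variables = set(ped.individuals)

    def multiply(fs: List[Tuple[Tuple[str, ...], np.ndarray]]):
        vars_out: List[str] = []
        for vs, _ in fs:
            for v in vs:
                if v not in vars_out:
                    vars_out.append(v)
        arr = np.ones((2,) * len(vars_out))
        for vs, a in fs:
            idx = [vars_out.index(v) for v in vs]
            expanded = np.moveaxis(
                a.reshape(a.shape + (1,) * (len(vars_out) - len(vs))),
                range(len(vs)),
                idx,
            )
            arr = arr * expanded
        return tuple(vars_out), arr

    while variables:
        # min-degree: variable appearing with fewest distinct neighbors
        def degree(v):
            nbrs = set()
            for vs, _ in factors:
                if v in vs:
                    nbrs.update(vs)
            nbrs.discard(v)
            return len(nbrs)

        var = min(variables, key=lambda v: (degree(v), v))
        involved = [f for f in factors if var in f[0]]
        rest = [f for f in factors if var not in f[0]]
        vs, arr = multiply(involved)
        arr = arr.sum(axis=vs.index(var))
        vs = tuple(v for v in vs if v != var)
        peak = float(arr.max())
        if peak <= 0.0:
            return -math.inf
        arr = arr / peak
        log_scale += math.log(peak)
        if vs:
            rest.append((vs, arr))
        else:
            log_scale += math.log(float(arr))
        factors = rest
        variables.discard(var)

    for vs, arr in factors:  # pragma: no cover - all vars eliminated above
        log_scale += math.log(float(arr.sum()))
    return log_scale


def pedigree_loglikelihood_bruteforce(
    ped: Pedigree,
    pen: PenetranceModel,
    hypothesis: str,
    fixed_genotypes: Optional[Mapping[str, str]] = None,
    exclude_phenotypes: Iterable[str] = (),
) -> float:
    """Enumeration over all 2^n genotype configurations (test oracle)."""
    fixed_genotypes = dict(fixed_genotypes or {})
    unary = _unary_factors(ped, pen, hypothesis, fixed_genotypes, exclude_phenotypes)
    ids = list(ped.individuals)
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(ids)):
        assign = dict(zip(ids, combo))
        p = 1.0
        for iid, g in assign.items():
            p *= unary[iid][g]
        for iid, ind in ped.individuals.items():
            if not ind.is_founder:
                p *= _TRANSMISSION[assign[ind.father_id], assign[ind.mother_id],
                                   assign[iid]]
        total += p
    return math.log(total) if total > 0 else -math.inf


def cosegregation_bayes_factor(
    ped: Pedigree,
    pen: PenetranceModel,
    likelihood=pedigree_loglikelihood,
) -> float:
    """Cosegregation LR: P(genotypes | phenotypes, pathogenic) / (... neutral).

    Conditions on every proband's carrier genotype (the ascertainment event)
    and excludes proband phenotypes from the liability product.  Returns 1.0
    when no relative besides the proband(s) has a genotype on record.
    """
    probands = ped.probands()
    if not probands:
        raise ValidationError("cosegregation requires a proband")
    for p in probands:
        if p.genotype != CARRIER:
            raise ValidationError(
                f"proband {p.id} is not a confirmed carrier; the method "
                "conditions on the proband's positive test"
            )
    proband_ids = {p.id for p in probands}
    observed = {
        i.id: i.genotype
        for i in ped.members()
        if i.genotype != UNTESTED
    }
    if set(observed) == proband_ids:
        return 1.0

    conditioning = {pid: CARRIER for pid in proband_ids}
    log_lr = 0.0
    for hyp, sign in (("pathogenic", +1), ("neutral", -1)):
        num = likelihood(ped, pen, hyp, observed, exclude_phenotypes=proband_ids)
        den = likelihood(ped, pen, hyp, conditioning, exclude_phenotypes=proband_ids)
        if math.isinf(num):
            raise ValidationError(
                "observed genotype configuration is impossible under "
                "Mendelian transmission"
            )
        log_lr += sign * (num - den)
    return math.exp(log_lr)


def combine_family_lrs(lrs: Sequence[float]) -> float:
    """Product of independent per-family segregation LRs for one variant."""
    out = 1.0
    for lr in lrs:
        if lr <= 0:
            raise ValidationError(f"non-positive likelihood ratio {lr}")
        out *= lr
    return out
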