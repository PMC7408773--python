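"""Shared fixtures and the random-pedigree builder used by property tests."""

from __future__ import annotations

import numpy as np
import pytest

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


@pytest.fixture(scope="session")
def pen() -> PenetranceModel:
    return default_penetrance()


def random_pedigree(
    rng: np.random.Generator,
    max_members: int = 8,
    q: float = 0.05,
    genotype_fraction: float = 0.6,
    with_proband: bool = False,
) -> Pedigree:
    """Random non-degenerate pedigree with random genotypes/phenotypes.

    Grows by repeatedly either adding a founder or mating two existing
    individuals of opposite sex, so structures include multi-sibships,
    half-sibs and multiple founder couples.
    """
    members = {}
    counter = [0]

    def add(father=None, mother=None, sex=None):
        counter[0] += 1
        iid = f"I{counter[0]}"
        members[iid] = {
            "father": father,
            "mother": mother,
            "sex": sex or ("male" if rng.random() < 0.5 else "female"),
        }
        return iid

    add(sex="male")
    add(sex="female")
    target = int(rng.integers(3, max_members + 1))
    while len(members) < target:
        males = [i for i, m in members.items() if m["sex"] == "male"]
        females = [i for i, m in members.items() if m["sex"] == "female"]
        if males and females and rng.random() < 0.7:
            add(father=str(rng.choice(males)), mother=str(rng.choice(females)))
        else:
            add()

    # genotypes by gene-dropping so observed configurations stay Mendelian-
    # consistent; members were created parents-before-children
    h = 2 * q * (1 - q)
    for _ in range(1000):
        truth = {}
        for iid, m in members.items():
            if m["father"] is None:
                truth[iid] = CARRIER if rng.random() < h else NON_CARRIER
            else:
                p = {0: 0.0, 1: 0.5, 2: 0.75}[
                    (truth[m["father"]] == CARRIER) + (truth[m["mother"]] == CARRIER)
                ]
                truth[iid] = CARRIER if rng.random() < p else NON_CARRIER
        carriers = [i for i, g in truth.items() if g == CARRIER]
        if not with_proband or carriers:
            break
    proband_id = str(rng.choice(carriers)) if with_proband else None

    individuals = {}
    for iid, m in members.items():
        censor = int(rng.integers(25, 85))
        phenos = []
        if rng.random() < 0.4:
            phenos.append(PhenotypeEvent("CRC", int(rng.integers(20, censor + 1))))
        genotype = UNTESTED
        if iid == proband_id or rng.random() < genotype_fraction:
            genotype = truth[iid]
        individuals[iid] = Individual(
            id=iid,
            family_id="RAND",
            father_id=m["father"],
            mother_id=m["mother"],
            sex=m["sex"],
            genotype=genotype,
            is_proband=iid == proband_id,
            phenotypes=phenos,
            censor_age=censor,
        )
    return Pedigree(individuals, allele_frequency=q)
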