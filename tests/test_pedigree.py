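"""Pedigree I/O, exact likelihoods and cosegregation Bayes factors."""

import math

import numpy as np
import pytest

from lynchlike.errors import PedigreeError, ValidationError
from lynchlike.pedigree import (
    CARRIER,
    NON_CARRIER,
    UNTESTED,
    Individual,
    Pedigree,
    PenetranceModel,
    PhenotypeEvent,
    combine_family_lrs,
    cosegregation_bayes_factor,
    pedigree_loglikelihood,
    pedigree_loglikelihood_bruteforce,
    read_pedigree,
)
from tests.conftest import random_pedigree

PED_HEADER = "family_id\tindividual_id\tfather_id\tmother_id\tsex\tgenotype\tproband\tcensor_age\n"
PHEN_HEADER = "individual_id\tcancer_type\tage_dx\n"


def write_trio(tmp_path, child_father="F"):
    ped = tmp_path / "fam.ped.tsv"
    phen = tmp_path / "fam.phen.tsv"
    ped.write_text(
        PED_HEADER
        + "FAM\tF\t0\t0\t1\tuntested\t0\t70\n"
        + "FAM\tM\t0\t0\t2\tuntested\t0\t68\n"
        + f"FAM\tC\t{child_father}\tM\t1\tcarrier\t1\t40\n"
    )
    phen.write_text(PHEN_HEADER + "C\tCRC\t38\n")
    return ped, phen


class TestReadPedigree:
    def test_trio_roundtrip(self, tmp_path):
        ped_path, phen_path = write_trio(tmp_path)
        ped = read_pedigree(ped_path, phen_path)
        founders = [i for i in ped.members() if i.is_founder]
        assert len(founders) == 2
        assert len(ped.members()) == 3
        child = ped.individuals["C"]
        assert child.is_proband and child.genotype == CARRIER
        assert child.phenotypes == [PhenotypeEvent("CRC", 38)]

    def test_child_as_own_father_is_structural_error(self, tmp_path):
        ped_path, phen_path = write_trio(tmp_path, child_father="C")
        with pytest.raises(PedigreeError):
            read_pedigree(ped_path, phen_path)

    def test_dangling_parent_rejected(self, tmp_path):
        ped_path = tmp_path / "p.tsv"
        phen_path = tmp_path / "ph.tsv"
        ped_path.write_text(PED_HEADER + "FAM\tA\tX\tY\t1\tuntested\t0\t50\n")
        phen_path.write_text(PHEN_HEADER)
        with pytest.raises(PedigreeError, match="dangling"):
            read_pedigree(ped_path, phen_path)

    def test_duplicate_individual_rejected(self, tmp_path):
        ped_path = tmp_path / "p.tsv"
        phen_path = tmp_path / "ph.tsv"
        ped_path.write_text(
            PED_HEADER
            + "FAM\tA\t0\t0\t1\tuntested\t0\t50\n"
            + "FAM\tA\t0\t0\t2\tuntested\t0\t50\n"
        )
        phen_path.write_text(PHEN_HEADER)
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(ped_path, phen_path)

    def test_af3_family_members_with_published_diagnoses(self, tmp_path):
        # family AF3: proband III3 (CRC at 47), II2 (EC 56 + CRC 75), II11 (CRC 68)
        ped_path = tmp_path / "af3.tsv"
        phen_path = tmp_path / "af3.phen.tsv"
        ped_path.write_text(
            PED_HEADER
            + "AF3\tI1\t0\t0\t1\tuntested\t0\t90\n"
            + "AF3\tI2\t0\t0\t2\tuntested\t0\t88\n"
            + "AF3\tII2\tI1\tI2\t2\tcarrier\t0\t76\n"
            + "AF3\tII11\tI1\tI2\t1\tcarrier\t0\t70\n"
            + "AF3\tSII2\t0\t0\t1\tuntested\t0\t80\n"
            + "AF3\tIII3\tSII2\tII2\t2\tcarrier\t1\t48\n"
        )
        phen_path.write_text(
            PHEN_HEADER
            + "III3\tCRC\t47\n"
            + "II2\tEC\t56\n"
            + "II2\tCRC\t75\n"
            + "II11\tCRC\t68\n"
        )
        ped = read_pedigree(ped_path, phen_path)
        phenotyped = [i for i in ped.members() if i.phenotypes]
        assert len(phenotyped) == 3
        assert len(ped.individuals["II2"].phenotypes) == 2


class TestLikelihood:
    def test_single_founder_closed_form(self, pen):
        ind = Individual("A", "F", None, None, sex="male",
                         genotype=CARRIER, censor_age=50)
        ped = Pedigree({"A": ind}, allele_frequency=0.01)
        ll = pedigree_loglikelihood(ped, pen, "pathogenic", {"A": CARRIER})
        q = 0.01
        survival = 1.0 - pen.cumulative_risk("CRC", "male", CARRIER, 50)
        assert ll == pytest.approx(math.log(2 * q * (1 - q) * survival), abs=1e-12)

    def test_neutral_hypothesis_decouples_genotypes(self, pen):
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, max_members=7)
        ll = pedigree_loglikelihood(ped, pen, "neutral", {})
        expected = sum(
            math.log(pen.phenotype_likelihood(i, NON_CARRIER))
            for i in ped.members()
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_elimination_equals_bruteforce(self, pen, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, max_members=8)
        obs = {i.id: i.genotype for i in ped.members() if i.genotype != UNTESTED}
        for hyp in ("pathogenic", "neutral"):
            fast = pedigree_loglikelihood(ped, pen, hyp, obs)
            slow = pedigree_loglikelihood_bruteforce(ped, pen, hyp, obs)
            if math.isinf(slow):
                assert math.isinf(fast)
            else:
                assert abs(fast - slow) < 1e-10

    def test_unknown_hypothesis_rejected(self, pen):
        ind = Individual("A", "F", None, None, genotype=CARRIER, censor_age=50)
        ped = Pedigree({"A": ind})
        with pytest.raises(ValidationError):
            pedigree_loglikelihood(ped, pen, "bogus", {})


def four_member_family(sib_genotype=CARRIER, sib_age=35, extra=None):
    """Founder couple, carrier proband, affected young sibling."""
    inds = {
        "F": Individual("F", "T", None, None, sex="male", censor_age=75),
        "M": Individual("M", "T", None, None, sex="female", censor_age=70),
        "P": Individual("P", "T", "F", "M", sex="female", genotype=CARRIER,
                        is_proband=True, censor_age=45,
                        phenotypes=[PhenotypeEvent("CRC", 44)]),
        "S": Individual("S", "T", "F", "M", sex="male", genotype=sib_genotype,
                        censor_age=sib_age,
                        phenotypes=[PhenotypeEvent("CRC", sib_age)]),
    }
    if extra:
        inds.update(extra)
    return Pedigree(inds, allele_frequency=1e-4)


class TestCosegregationBayesFactor:
    def test_only_proband_genotyped_gives_unit_lr(self, pen):
        inds = {
            "F": Individual("F", "T", None, None, censor_age=70),
            "M": Individual("M", "T", None, None, censor_age=70),
            "P": Individual("P", "T", "F", "M", genotype=CARRIER,
                            is_proband=True, censor_age=40),
        }
        ped = Pedigree(inds)
        assert cosegregation_bayes_factor(ped, pen) == 1.0

    def test_flat_penetrance_gives_unit_lr(self):
        flat = PenetranceModel.flat(0.1)
        ped = four_member_family()
        assert cosegregation_bayes_factor(ped, flat) == pytest.approx(1.0, abs=1e-12)

    def test_affected_carrier_sibling_supports_pathogenicity(self, pen):
        ped = four_member_family()
        lr = cosegregation_bayes_factor(ped, pen)
        # independent route: direct enumeration of both conditional probabilities
        obs = {"P": CARRIER, "S": CARRIER}
        log_lr = 0.0
        for hyp, sign in (("pathogenic", 1), ("neutral", -1)):
            num = pedigree_loglikelihood_bruteforce(
                ped, pen, hyp, obs, exclude_phenotypes=["P"])
            den = pedigree_loglikelihood_bruteforce(
                ped, pen, hyp, {"P": CARRIER}, exclude_phenotypes=["P"])
            log_lr += sign * (num - den)
        assert lr == pytest.approx(math.exp(log_lr), rel=1e-10)
        assert lr > 1.0

    def test_non_carrier_proband_rejected(self, pen):
        ped = four_member_family()
        ped.individuals["P"].genotype = NON_CARRIER
        with pytest.raises(ValidationError, match="proband"):
            cosegregation_bayes_factor(ped, pen)

    def test_invariant_under_relabeling_and_inert_relatives(self, pen):
        ped = four_member_family()
        lr = cosegregation_bayes_factor(ped, pen)

        relabel = {"F": "x1", "M": "x2", "P": "x3", "S": "x4"}
        inds = {}
        for iid, ind in ped.individuals.items():
            inds[relabel[iid]] = Individual(
                id=relabel[iid], family_id=ind.family_id,
                father_id=relabel.get(ind.father_id), mother_id=relabel.get(ind.mother_id),
                sex=ind.sex, genotype=ind.genotype, is_proband=ind.is_proband,
                phenotypes=list(ind.phenotypes), censor_age=ind.censor_age,
            )
        assert cosegregation_bayes_factor(
            Pedigree(inds, allele_frequency=1e-4), pen
        ) == pytest.approx(lr, rel=1e-12)

        ped2 = four_member_family(extra={
            "N": Individual("N", "T", "F", "M", genotype=UNTESTED, censor_age=0),
        })
        assert cosegregation_bayes_factor(ped2, pen) == pytest.approx(lr, rel=1e-10)

    def test_additional_affected_young_carrier_never_decreases_lr(self, pen):
        ped = four_member_family()
        lr = cosegregation_bayes_factor(ped, pen)
        ped2 = four_member_family(extra={
            "S2": Individual("S2", "T", "F", "M", sex="female", genotype=CARRIER,
                             censor_age=33, phenotypes=[PhenotypeEvent("CRC", 32)]),
        })
        assert cosegregation_bayes_factor(ped2, pen) >= lr


class TestCombineFamilyLrs:
    @pytest.mark.parametrize("lrs,expected", [
        ([1.0, 1.0, 1.0], 1.0),
        ([2.0, 3.5], 7.0),
    ])
    def test_product(self, lrs, expected):
        assert combine_family_lrs(lrs) == pytest.approx(expected)

    def test_sequential_combination_is_associative(self, pen):
        lrs = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            ped = random_pedigree(rng, max_members=6, with_proband=True)
            lrs.append(cosegregation_bayes_factor(ped, pen))
        assert combine_family_lrs(lrs) == pytest.approx(
            combine_family_lrs([combine_family_lrs(lrs[:2]), lrs[2]]), rel=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            combine_family_lrs([2.0, 0.0])


class TestInvariants:
    def test_phenotype_after_censor_rejected(self):
        with pytest.raises(ValidationError, match="censor_age"):
            Individual("A", "F", None, None, censor_age=40,
                       phenotypes=[PhenotypeEvent("CRC", 45)])

    def test_one_parent_only_rejected(self):
        with pytest.raises(PedigreeError):
            Individual("A", "F", "X", None, censor_age=40)

    def test_allele_frequency_bounds(self):
        ind = Individual("A", "F", None, None, censor_age=40)
        with pytest.raises(Exception):
            Pedigree({"A": ind}, allele_frequency=0.7)
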