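"""Beta matrices, differential methylation, FDR and epimutation detection."""

import numpy as np
import pandas as pd
import pytest

from lynchlike.errors import ValidationError
from lynchlike.methylome import (
    BetaMatrix,
    Region,
    RegionSet,
    detect_epimutation,
    load_beta_matrix,
    region_aggregate,
    site_differential_methylation,
    site_in_region,
    write_beta_matrix,
)
from lynchlike.synthetic import BetaSpec, simulate_beta_matrix


def small_matrix(values, groups=("A", "A", "B", "B")):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sites = pd.DataFrame({
        "cpg_id": [f"cg{i}" for i in range(n)],
        "chrom": "chr1",
        "pos": 100 * (np.arange(n) + 1),
    })
    samples = [f"s{j}" for j in range(m)]
    return BetaMatrix(sites=sites, samples=samples,
                      groups=dict(zip(samples, groups)), values=values)


class TestBetaMatrixIO:
    def test_toy_load_shape(self, tmp_path):
        beta = tmp_path / "b.tsv"
        sheet = tmp_path / "s.tsv"
        beta.write_text(
            "cpg_id\tchrom\tpos\ts1\ts2\n"
            "cg1\tchr1\t100\t0.1\t0.2\n"
            "cg2\tchr1\t200\t0.5\t0.6\n"
            "cg3\tchr1\t300\t0.9\t0.8\n"
        )
        sheet.write_text("sample_id\tgroup\ns1\tA\ns2\tB\n")
        bm = load_beta_matrix(beta, sheet)
        assert bm.values.shape == (3, 2)
        assert bm.groups == {"s1": "A", "s2": "B"}

    def test_out_of_range_beta_rejected(self, tmp_path):
        beta = tmp_path / "b.tsv"
        sheet = tmp_path / "s.tsv"
        beta.write_text("cpg_id\tchrom\tpos\ts1\ncg1\tchr1\t100\t1.2\n")
        sheet.write_text("sample_id\tgroup\ns1\tA\n")
        with pytest.raises(ValidationError):
            load_beta_matrix(beta, sheet)

    def test_non_numeric_cell_rejected(self, tmp_path):
        beta = tmp_path / "b.tsv"
        sheet = tmp_path / "s.tsv"
        beta.write_text("cpg_id\tchrom\tpos\ts1\ncg1\tchr1\t100\toops\n")
        sheet.write_text("sample_id\tgroup\ns1\tA\n")
        with pytest.raises(ValidationError, match="s1"):
            load_beta_matrix(beta, sheet)

    def test_round_trip_preserves_values_to_6dp(self, tmp_path):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=2, n_sites=50,
                                              groups={"A": 3, "B": 3}))
        write_beta_matrix(bm, tmp_path / "b.tsv", tmp_path / "s.tsv",
                          header=["synthetic"])
        back = load_beta_matrix(tmp_path / "b.tsv", tmp_path / "s.tsv")
        np.testing.assert_allclose(back.values, bm.values, atol=5e-7)
        assert back.samples == bm.samples


class TestSiteDifferentialMethylation:
    def test_identical_groups_no_signal(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(0, 1, size=(20, 4))
        values = np.hstack([half, half])
        bm = small_matrix(values, groups=("A",) * 4 + ("B",) * 4)
        res = site_differential_methylation(bm, "A", "B")
        assert np.allclose(res["delta_beta"], 0.0)
        assert not res["significant"].any()

    def test_group_swap_symmetry(self):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=5, n_sites=200,
                                              groups={"A": 12, "B": 12},
                                              n_shift_sites=10))
        ab = site_differential_methylation(bm, "A", "B")
        ba = site_differential_methylation(bm, "B", "A")
        np.testing.assert_allclose(ab["delta_beta"], -ba["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_underpowered_groups_claim_nothing(self):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=6, n_sites=100,
                                              groups={"A": 5, "B": 5},
                                              n_shift_sites=20))
        res = site_differential_methylation(bm, "A", "B")
        assert (res["flag"] == "underpowered_comparison").all()
        assert not res["significant"].any()

    def test_sparse_sites_reported_untested(self):
        values = np.full((3, 8), 0.5)
        values[0, :3] = np.nan   # 1 value left in group A
        bm = small_matrix(values, groups=("A",) * 4 + ("B",) * 4)
        res = site_differential_methylation(bm, "A", "B")
        assert not res.loc[0, "tested"]
        assert res.loc[1, "tested"] and res.loc[2, "tested"]

    def test_missing_values_elsewhere_leave_complete_sites_unchanged(self):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=7, n_sites=100,
                                              groups={"A": 12, "B": 12}))
        base = site_differential_methylation(bm, "A", "B")
        damaged = bm.values.copy()
        damaged[:10, :5] = np.nan
        bm2 = BetaMatrix(sites=bm.sites, samples=bm.samples,
                         groups=bm.groups, values=damaged)
        res = site_differential_methylation(bm2, "A", "B")
        np.testing.assert_allclose(res.loc[10:, "p_value"],
                                   base.loc[10:, "p_value"], atol=1e-12)

    def test_unknown_group_rejected(self):
        bm = small_matrix(np.full((2, 4), 0.5))
        with pytest.raises(ValidationError):
            site_differential_methylation(bm, "A", "Z")


def bh_bruteforce(pvals):
    """Literal step-up Benjamini-Hochberg as an independent oracle."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] / (rank / m))
        q[i] = val
        prev = val
    return q


class TestFdr:
    def test_bh_matches_bruteforce_exactly(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for n in (1, 10, 137, 1000):
            p = rng.uniform(0, 1, size=n)
            lib = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_array_equal(lib, bh_bruteforce(p))

    def test_fdr_q_at_least_p(self):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=8, n_sites=300,
                                              groups={"A": 12, "B": 12}))
        res = site_differential_methylation(bm, "A", "B")
        tested = res[res["tested"]]
        assert (tested["fdr_q"] >= tested["p_value"] - 1e-15).all()


class TestRegionAggregate:
    def test_single_site_region_equals_site(self):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=9, n_sites=20,
                                              groups={"A": 12, "B": 12}))
        sites = site_differential_methylation(bm, "A", "B")
        pos = int(sites.loc[4, "pos"])
        regions = RegionSet([Region("one", "chr1", pos - 1, pos)])
        reg = region_aggregate(sites, regions)
        assert len(reg) == 1
        assert reg.loc[0, "n_sites"] == 1
        assert reg.loc[0, "p_value"] == pytest.approx(
            sites.loc[4, "p_value"], rel=1e-9)
        assert reg.loc[0, "delta_beta"] == pytest.approx(
            sites.loc[4, "delta_beta"], abs=1e-12)

    def test_stouffer_sharpens_identical_evidence(self):
        from scipy import stats

        p0 = 0.03
        sites = pd.DataFrame({
            "cpg_id": ["a", "b", "c"], "chrom": "chr1",
            "pos": [100, 200, 300],
            "mean_beta_a": 0.5, "mean_beta_b": 0.4, "delta_beta": 0.1,
            "p_value": p0, "fdr_q": p0, "tested": True,
        })
        reg = region_aggregate(sites, RegionSet([Region("r", "chr1", 0, 1000)]))
        expected = float(stats.norm.sf(np.sqrt(3) * stats.norm.isf(p0)))
        assert reg.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)
        assert reg.loc[0, "p_value"] < p0

    def test_empty_region_set(self):
        bm, _ = simulate_beta_matrix(BetaSpec(seed=9, n_sites=10,
                                              groups={"A": 3, "B": 3}))
        sites = site_differential_methylation(bm, "A", "B")
        assert region_aggregate(sites, RegionSet([])).empty

    def test_coordinate_convention(self):
        # BED [100, 200) covers 1-based positions 101..200
        assert not site_in_region(100, 100, 200)
        assert site_in_region(101, 100, 200)
        assert site_in_region(200, 100, 200)
        assert not site_in_region(201, 100, 200)


@pytest.fixture(scope="module")
def cohort():
    spec = BetaSpec(seed=13, n_sites=500, groups={"CTRL": 41, "CASE": 1},
                    dmr_n_sites=10, dmr_carriers=("CASE01",))
    bm, regions = simulate_beta_matrix(spec)
    return bm, regions.regions[0]


class TestDetectEpimutation:
    def test_hemimethylated_carrier_detected(self, cohort):
        bm, dmr = cohort
        controls = [s for s in bm.samples if s.startswith("CTRL")]
        call = detect_epimutation(bm, dmr, "CASE01", controls)
        assert call.call
        assert 0.25 <= call.mean_beta_sample <= 0.75
        assert call.z_score > 5

    def test_no_false_positives_leave_one_out(self, cohort):
        bm, dmr = cohort
        controls = [s for s in bm.samples if s.startswith("CTRL")]
        for held_out in controls:
            rest = [c for c in controls if c != held_out]
            assert not detect_epimutation(bm, dmr, held_out, rest).call

    def test_fully_methylated_sample_flagged_not_called(self, cohort):
        bm, dmr = cohort
        controls = [s for s in bm.samples if s.startswith("CTRL")]
        hot = bm.values.copy()
        j = bm.sample_index("CASE01")
        mask = ((bm.sites["chrom"] == dmr.chrom)
                & (bm.sites["pos"] > dmr.start)
                & (bm.sites["pos"] <= dmr.end)).to_numpy()
        hot[mask, j] = 0.95
        bm2 = BetaMatrix(sites=bm.sites, samples=bm.samples,
                         groups=bm.groups, values=hot)
        call = detect_epimutation(bm2, dmr, "CASE01", controls)
        assert not call.call
        assert call.flag == "fully_methylated_review"

    def test_dmr_without_sites_rejected(self, cohort):
        bm, _ = cohort
        empty = Region("empty", "chrX", 0, 100)
        with pytest.raises(ValidationError):
            detect_epimutation(bm, empty, "CASE01", ["CTRL01"])

    def test_published_summary_values_yield_a_call(self):
        # hemimethylated blood signal: DMR mean 0.48 against near-zero controls
        rng = np.random.default_rng(3)
        n_sites, n_ctrl = 10, 41
        values = np.empty((n_sites, n_ctrl + 1))
        values[:, :n_ctrl] = rng.normal(0.03, 0.01, size=(n_sites, n_ctrl)).clip(0, 1)
        values[:, n_ctrl] = rng.normal(0.48, 0.02, size=n_sites).clip(0, 1)
        samples = [f"c{i}" for i in range(n_ctrl)] + ["case"]
        sites = pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(n_sites)],
                              "chrom": "chr3",
                              "pos": 100 + np.arange(n_sites)})
        bm = BetaMatrix(sites=sites, samples=samples,
                        groups={s: "blood" for s in samples}, values=values)
        dmr = Region("MLH1_DMR", "chr3", 0, 1000)
        call = detect_epimutation(bm, dmr, "case", samples[:n_ctrl])
        assert call.call
        assert call.mean_beta_sample == pytest.approx(0.48, abs=0.03)
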