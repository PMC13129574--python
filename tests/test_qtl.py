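"""Kosambi map functions, map estimation, EM interval mapping, permutations."""

import numpy as np
import pandas as pd
import pytest

from leafspec.containers import GeneticMap, RILPanel
from leafspec.qtl import (
    colocalization,
    estimate_map,
    extract_qtls,
    genotype_prob_a,
    im_scan,
    kosambi,
    kosambi_inverse,
    perm_threshold,
    QTLScan,
    ril_expansion,
    ril_shrink,
    scan_phenotypes,
)
from leafspec.synth import QTLEffect, gen_ril_panel


class TestKosambi:
    def test_zero_recombination_is_zero_distance(self):
        assert kosambi(0.0) == 0.0
        assert kosambi_inverse(0.0) == 0.0

    def test_quarter_recombination_closed_form(self):
        assert kosambi(0.25) == pytest.approx(25.0 * np.log(3.0), abs=1e-12)

    def test_round_trip_identity(self):
        r = np.arange(0.01, 0.50, 0.01)
        np.testing.assert_allclose(kosambi_inverse(kosambi(r)), r, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)

    def test_ril_expansion_round_trip(self):
        r = np.arange(0.0, 0.5, 0.01)
        np.testing.assert_allclose(ril_shrink(ril_expansion(r)), r, atol=1e-12)


class TestEstimateMap:
    def test_identical_columns_give_zero_interval(self):
        gmap = GeneticMap.uniform(n_chrom=1, markers_per_chrom=[2], spacing_cM=0.0)
        panel, _ = gen_ril_panel(100, gmap, seed=0)
        est, intervals = estimate_map(panel)
        assert intervals["d_cM"].iloc[0] == 0.0
        assert est.table["pos_cM"].tolist() == [0.0, 0.0]

    def test_estimated_distance_within_binomial_tolerance(self):
        r_true, n = 0.1, 2000
        d_true = kosambi(r_true)
        gmap = GeneticMap.uniform(n_chrom=1, markers_per_chrom=[2], spacing_cM=d_true)
        panel, _ = gen_ril_panel(n, gmap, seed=1)
        est, intervals = estimate_map(panel)
        R = ril_expansion(r_true)
        se = np.sqrt(R * (1 - R) / n)
        lo = kosambi(ril_shrink(R - 3 * se))
        hi = kosambi(ril_shrink(R + 3 * se))
        assert lo < intervals["d_cM"].iloc[0] < hi

    def test_generative_round_trip_reproduces_recombination(self):
        gmap = GeneticMap.uniform(n_chrom=2, markers_per_chrom=[5, 5], spacing_cM=15.0)
        panel, _ = gen_ril_panel(400, gmap, seed=2)
        est, intervals = estimate_map(panel)
        regen, _ = gen_ril_panel(2000, est, seed=3)
        _, re_intervals = estimate_map(regen)
        for (_, a), (_, b) in zip(intervals.iterrows(), re_intervals.iterrows()):
            se = np.sqrt(a.R_obs * (1 - a.R_obs) / 2000) if a.R_obs > 0 else 0.02
            assert abs(a.R_obs - b.R_obs) < 4 * se + 1e-9

    def test_unlinked_interval_flagged(self):
        geno = pd.DataFrame(
            {
                "m1": ["A"] * 10 + ["B"] * 10,
                "m2": ["B"] * 10 + ["A"] * 10,
            },
            index=[f"L{i}" for i in range(20)],
        )
        gmap = GeneticMap(
            pd.DataFrame(dict(marker=["m1", "m2"], chrom=[1, 1], pos_cM=[0.0, 10.0]))
        )
        pheno = pd.DataFrame({"DH": np.arange(20.0)}, index=geno.index)
        _, intervals = estimate_map(RILPanel(geno, gmap, pheno))
        assert intervals["unlinked"].iloc[0]


class TestGenotypeProbabilities:
    def test_at_marker_probabilities_are_indicators(self):
        gmap = GeneticMap.uniform(n_chrom=1, markers_per_chrom=[3], spacing_cM=10.0)
        panel, _ = gen_ril_panel(30, gmap, seed=4)
        codes = panel.genotypes.map(lambda v: 1.0 if v == "A" else 0.0).to_numpy()
        pa = genotype_prob_a(codes, np.array([0.0, 10.0, 20.0]), 10.0)
        np.testing.assert_array_equal(pa, codes[:, 1])

    def test_midpoint_between_concordant_markers_stays_confident(self):
        codes = np.array([[1.0, 1.0], [0.0, 0.0]])
        pa = genotype_prob_a(codes, np.array([0.0, 10.0]), 5.0)
        assert pa[0] > 0.9 and pa[1] < 0.1

    def test_missing_flank_falls_back_to_single_flank(self):
        codes = np.array([[1.0, np.nan], [np.nan, np.nan]])
        pa = genotype_prob_a(codes, np.array([0.0, 10.0]), 5.0)
        expected = 1.0 - ril_expansion(kosambi_inverse(5.0))
        assert pa[0] == pytest.approx(expected)
        assert pa[1] == 0.5


@pytest.fixture(scope="module")
def panel():
    gmap = GeneticMap.uniform()
    return gen_ril_panel(96, gmap, qtls=[QTLEffect("PG", 3, 40.0, 1.0)], seed=5)[0]


@pytest.fixture(scope="module")
def small_panel():
    gmap = GeneticMap.uniform(n_chrom=3, markers_per_chrom=[5, 5, 5])
    return gen_ril_panel(60, gmap, seed=6)[0]


class TestIntervalMapping:

    def test_lod_at_marker_equals_marker_regression(self, panel):
        """EM at a fully genotyped marker reduces to the closed-form
        (n/2) log10(RSS0/RSS1) of the two-group regression."""
        scan = im_scan(panel, "PG", step_cM=10.0)
        y = panel.phenotypes["PG"].to_numpy()
        n = len(y)
        for marker, chrom, pos in [("c3m5", 3, 40.0), ("c8m3", 8, 20.0)]:
            x = panel.genotype_codes(marker)
            a, b = y[x > 0], y[x < 0]
            rss1 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            closed = n / 2 * np.log10(rss0 / rss1)
            row = scan.grid.query("chrom == @chrom and pos_cM == @pos").index[0]
            assert scan.lod["PG"][row] == pytest.approx(closed, abs=1e-6)

    def test_constant_phenotype_scans_flat_zero(self, panel):
        y = np.full(panel.n_lines, 3.0)
        _, lod, conv = scan_phenotypes(panel, y[None, :], step_cM=10.0)
        assert (lod == 0).all() and conv.all()

    def test_lod_invariant_to_affine_phenotype_transform(self, panel):
        y = panel.phenotypes["PG"].to_numpy()
        _, lod_a, _ = scan_phenotypes(panel, y[None, :], step_cM=10.0)
        _, lod_b, _ = scan_phenotypes(panel, (7.0 - 2.5 * y)[None, :], step_cM=10.0)
        np.testing.assert_allclose(lod_a, lod_b, atol=1e-6)

    def test_peak_near_planted_qtl(self, panel):
        scan = im_scan(panel, "PG", step_cM=5.0)
        peak = scan.grid.iloc[int(scan.lod["PG"].idxmax())]
        assert peak["chrom"] == 3
        assert abs(peak["pos_cM"] - 40.0) <= 10.0

    def test_unknown_trait_rejected(self, panel):
        with pytest.raises(KeyError):
            im_scan(panel, "nope")


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum_of_max_lods(self, small_panel):
        panel = small_panel
        thr_all = perm_threshold(panel, "DH", n_perm=100, alpha=1.0, seed=1, step_cM=10.0)
        thr_95 = perm_threshold(panel, "DH", n_perm=100, alpha=0.05, seed=1, step_cM=10.0)
        assert thr_all <= thr_95

    def test_threshold_bitwise_reproducible(self, small_panel):
        panel = small_panel
        a = perm_threshold(panel, "DH", n_perm=120, alpha=0.05, seed=9, step_cM=10.0)
        b = perm_threshold(panel, "DH", n_perm=120, alpha=0.05, seed=9, step_cM=10.0)
        assert a == b

    def test_too_few_permutations_rejected(self, small_panel):
        panel = small_panel
        with pytest.raises(ValueError):
            perm_threshold(panel, "DH", n_perm=50)


class TestExtractQTLs:
    @staticmethod
    def _scan(lods, thresholds):
        chroms = [1] * 5 + [2] * 5
        pos = list(np.arange(5) * 10.0) * 2
        grid = pd.DataFrame(dict(chrom=chroms, pos_cM=pos))
        return QTLScan(grid=grid, lod=pd.DataFrame(lods), thresholds=thresholds)

    def test_all_below_threshold_gives_empty_list(self):
        scan = self._scan({"DH": np.ones(10)}, {"DH": 3.0})
        assert extract_qtls(scan) == []

    def test_two_planted_loci_on_distinct_chromosomes_recovered(self):
        gmap = GeneticMap.uniform()
        panel, _ = gen_ril_panel(
            96,
            gmap,
            qtls=[QTLEffect("PG", 2, 50.0, 2.0), QTLEffect("PG", 9, 30.0, 2.0)],
            seed=7,
        )
        scan = im_scan(panel, "PG", step_cM=5.0)
        scan.thresholds = {"PG": 3.0}
        found = extract_qtls(scan)
        assert sorted(q.chrom for q in found) == [2, 9]

    def test_support_interval_uses_lod_drop(self):
        lod = np.array([0.0, 2.6, 4.0, 2.7, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        scan = self._scan({"DH": lod}, {"DH": 3.0})
        (q,) = extract_qtls(scan, lod_drop=1.5)
        # neighbours at 2.6/2.7 stay above peak - 1.5 = 2.5; the zeros do not
        assert (q.peak_cM, q.ci_lo_cM, q.ci_hi_cM) == (20.0, 10.0, 30.0)

    def test_colocalized_traits_flagged(self):
        gmap = GeneticMap.uniform()
        panel, _ = gen_ril_panel(
            96,
            gmap,
            qtls=[
                QTLEffect("PG", 3, 40.0, 2.0),
                QTLEffect("MW", 3, 40.0, 2.0),
                QTLEffect("DH", 10, 70.0, 2.0),
            ],
            seed=8,
        )
        Y = panel.phenotypes[["PG", "MW", "DH"]].to_numpy().T
        grid, lod, _ = scan_phenotypes(panel, Y, step_cM=10.0)
        scan = QTLScan(
            grid=grid,
            lod=pd.DataFrame(lod, columns=["PG", "MW", "DH"]),
            thresholds=dict.fromkeys(["PG", "MW", "DH"], 3.0),
        )
        pairs = colocalization(extract_qtls(scan))
        assert any({a.trait, b.trait} == {"PG", "MW"} and a.chrom == 3 for a, b in pairs)
        assert not any("DH" in {a.trait, b.trait} for a, b in pairs)


class TestPCTraits:
    @pytest.fixture(scope="class")
    @staticmethod
    def pcs():
        from leafspec.containers import WavelengthGrid
        from leafspec.qtl import pc_traits
        from leafspec.synth import gen_grain_spectra

        gmap = GeneticMap.uniform()
        panel, _ = gen_ril_panel(40, gmap, seed=9)
        grid = WavelengthGrid.spanning(450.0, 2499.5, 5.0)
        grain, _ = gen_grain_spectra(panel, grid, seed=10)
        return pc_traits(grain)

    def test_naming_convention(self, pcs):
        assert "P_A_PC9" in pcs.columns
        assert "B_N_PC1" in pcs.columns

    def test_sixty_trait_columns(self, pcs):
        assert pcs.shape[1] == 60  # 10 components x 3 regions x 2 forms

    def test_duplicated_spectra_rows_get_identical_scores(self):
        from leafspec.containers import WavelengthGrid
        from leafspec.qtl import pc_traits
        from leafspec.synth import gen_grain_spectra

        gmap = GeneticMap.uniform(n_chrom=2, markers_per_chrom=[3, 3])
        panel, _ = gen_ril_panel(10, gmap, seed=11)
        grid = WavelengthGrid.spanning(450.0, 2499.5, 10.0)
        grain, _ = gen_grain_spectra(panel, grid, seed=12, noise_sd=0.0)
        # copy line RIL002's spectra over RIL005's in both sample forms
        src = (grain.meta["cultivar"] == "RIL002").to_numpy()
        dst = (grain.meta["cultivar"] == "RIL005").to_numpy()
        grain.values[dst] = grain.values[src]
        pcs = pc_traits(grain)
        np.testing.assert_allclose(
            pcs.loc["RIL002"].to_numpy(), pcs.loc["RIL005"].to_numpy(), atol=1e-8
        )
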