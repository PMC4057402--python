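import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mcqtl.io import GeneticMap
from mcqtl.phenostats import compute_line_means, pheno_correlation
from mcqtl.simpop import (
    QTLLocus,
    QTLModel,
    TRITICALE_GENOMES,
    TraitSimSpec,
    haldane_r,
    make_even_map,
    make_map,
    simulate_dh_family,
    simulate_paired_trial,
    simulate_preset,
    simulate_trial,
)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_r(0.0) == 0.0

    def test_asymptote(self):
        assert haldane_r(1e6) == pytest.approx(0.5)

    def test_ten_cM(self):
        assert haldane_r(10.0) == pytest.approx(0.0906346234610091, abs=1e-12)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            haldane_r(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e4),
           st.floats(min_value=0.0, max_value=1e4))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, d1, d2):
        r1, r2 = haldane_r(d1), haldane_r(d2)
        # the open bound 0.5 is reached only at float precision
        assert 0.0 <= r1 <= 0.5
        if d1 <= d2:
            assert r1 <= r2


class TestMakeMap:
    def test_positions_within_length(self):
        gmap = make_map([("A", 1, 100.0, 2)], seed=0)
        pos = gmap.chrom_positions("1A")
        assert len(pos) == 2 and (pos >= 0).all() and (pos <= 100).all()

    def test_deterministic(self):
        a = make_map([("B", 2, 80.0, 5)], seed=42)
        b = make_map([("B", 2, 80.0, 5)], seed=42)
        pd.testing.assert_frame_equal(a.markers, b.markers)

    def test_triticale_preset_has_21_chromosomes(self):
        gmap = make_map(TRITICALE_GENOMES, seed=0)
        chroms = gmap.chromosomes
        assert len(chroms) == 21
        for genome in "ABR":
            assert sum(1 for _, g in chroms if g == genome) == 7


class TestDHFamily:
    def test_identical_parents_give_identical_lines(self, tiny_map):
        alleles = np.array([0, 1, 0])
        md = simulate_dh_family(alleles, alleles, 10, tiny_map, seed=1)
        assert (md.genotype == 2.0).all()  # everyone carries the ref allele

    def test_zero_distance_markers_coinherited(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker_id": ["a", "b"], "chromosome": ["1A", "1A"],
            "position_cM": [5.0, 5.0]}))
        md = simulate_dh_family(np.array([0, 0]), np.array([1, 1]), 500,
                                gmap, seed=2)
        assert (md.genotype[:, 0] == md.genotype[:, 1]).all()

    def test_unlinked_markers_recombine_freely(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker_id": ["a", "b"], "chromosome": ["1A", "1A"],
            "position_cM": [0.0, 1000.0]}))
        md = simulate_dh_family(np.array([0, 0]), np.array([1, 1]), 10000,
                                gmap, seed=3)
        rec = np.mean(md.genotype[:, 0] != md.genotype[:, 1])
        assert rec == pytest.approx(0.5, abs=0.015)

    def test_genotypes_are_homozygous_and_balanced(self):
        gmap = make_even_map([("A", 1, 100.0, 10)])
        md = simulate_dh_family(np.zeros(10, int), np.ones(10, int), 2000,
                                gmap, seed=4)
        assert np.isin(md.genotype, (0.0, 2.0)).all()
        freqs = (md.genotype == 2.0).mean(axis=0)
        # 1:1 segregation within binomial error (~3 SE at n=2000)
        assert np.all(np.abs(freqs - 0.5) < 3 * np.sqrt(0.25 / 2000))

    def test_map_expansion_matches_haldane(self):
        gmap = make_even_map([("A", 1, 70.0, 8)])
        md = simulate_dh_family(np.zeros(8, int), np.ones(8, int), 10000,
                                gmap, seed=5)
        pos = gmap.chrom_positions("1A")
        for j in range(7):
            r_exp = haldane_r(pos[j + 1] - pos[j])
            r_obs = np.mean(md.genotype[:, j] != md.genotype[:, j + 1])
            se = np.sqrt(r_exp * (1 - r_exp) / 10000)
            assert abs(r_obs - r_exp) < 3 * se

    def test_invalid_line_count(self, tiny_map):
        with pytest.raises(ValueError):
            simulate_dh_family(np.zeros(3, int), np.ones(3, int), 0, tiny_map)


class TestTrial:
    def test_pure_location_effects(self, small_population):
        spec = TraitSimSpec(var_g=0.0, var_e=0.0, var_gxl=0.0, n_locations=2,
                            mean=5.0)
        trial, g = simulate_trial(small_population, QTLModel([], polygenic_sd=0.0),
                                  spec, seed=6)
        assert (g == 0).all()
        for _, sub in trial.groupby("location"):
            assert sub["value"].nunique() == 1

    def test_variance_ratio_recovered(self):
        # the full-size preset requests a 9:1 genotypic to GxL variance ratio
        from mcqtl.phenostats import estimate_vc

        data = simulate_preset("triticale647", seed=11)
        vc = estimate_vc(data.trial_a)
        assert vc.var_g / vc.var_gxl == pytest.approx(9.0, abs=2.0)
        assert vc.var_g == pytest.approx(3.0, rel=0.15)

    def test_paired_noiseless_identical_genetics_correlate_perfectly(
            self, small_population):
        fams = small_population.family.family_ids
        loci = [QTLLocus("1A", 30.0, {f: 1.0 for f in fams})]
        spec = TraitSimSpec(var_g=1.0, var_e=0.0, n_locations=1)
        trial_a, g_a, trial_b, g_b = simulate_paired_trial(
            small_population, QTLModel(loci, polygenic_sd=0.0),
            QTLModel(loci, polygenic_sd=0.0), spec, spec, rho_poly=1.0, seed=8)
        assert np.corrcoef(g_a, g_b)[0, 1] == pytest.approx(1.0)
        la = compute_line_means(trial_a)
        lb = compute_line_means(trial_b)
        assert pheno_correlation(la, lb)[0] == pytest.approx(1.0)

    def test_off_map_locus_rejected(self, small_population):
        spec = TraitSimSpec(var_g=1.0, var_e=0.1)
        bad = QTLModel([QTLLocus("9R", 10.0, {"DH06": 1.0})])
        with pytest.raises(ValueError, match="not on map"):
            simulate_trial(small_population, bad, spec, seed=9)


class TestPairedPresetCorrelation:
    def test_blue_correlation_near_target(self):
        # adjusted-mean correlation of the paired traits targets 0.88
        rs = []
        for seed in range(10):
            data = simulate_preset("triticale_mini", seed=seed)
            la = compute_line_means(data.trial_a, trait="wh")
            lb = compute_line_means(data.trial_b, trait="ft")
            rs.append(pheno_correlation(la, lb)[0])
        assert 0.85 <= np.mean(rs) <= 0.92
        assert all(0.80 <= r <= 0.95 for r in rs)


def test_preset_truth_table_matches_architecture():
    data = simulate_preset("triticale_mini", seed=3)
    truth = data.truth
    assert len(truth) == 9
    majors = truth.nlargest(3, "pg_true")
    assert set(majors["chromosome"]) == {"2A", "1B", "2R"}
    # the 5A-analogue only segregates in EAW74; the 5R-analogue not in EAW74
    row_a = truth[truth["chromosome"] == "2A"].iloc[0]
    assert row_a["effect_EAW74"] != 0.0
    assert row_a[["effect_DH06", "effect_DH07", "effect_EAW78"]].eq(0).all()
    row_r = truth[truth["chromosome"] == "2R"].iloc[0]
    assert row_r["effect_EAW74"] == 0.0
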