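import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from mcqtl.io import GeneticMap, FamilyStructure, MarkerData, RunConfig
from mcqtl.phenostats import LineValues
from mcqtl.scan import (
    QTLRecord,
    ScanResult,
    estimate_pg,
    expected_count,
    genome_scan,
    identify_qtl,
    lod_score,
    permutation_threshold,
    select_cofactors,
)
from mcqtl.simpop import QTLLocus, QTLModel, haldane_r, simulate_line_values


# --- independent oracle: enumerate the gamete Markov chain over the two
# flanking intervals ------------------------------------------------------

def enumerated_count(left, right, d_left, d_right):
    """P(carrying the reference allele | flanks) by direct enumeration of
    the hidden locus state, times two."""
    def trans(x, y, r):
        return 1.0 - r if x == y else r

    r1, r2 = haldane_r(d_left), haldane_r(d_right)
    states = [0, 1]  # 1 = carries reference allele (count 2 at a marker)
    al = None if np.isnan(left) else int(left == 2.0)
    ar = None if np.isnan(right) else int(right == 2.0)
    num = 0.0
    den = 0.0
    for q in states:
        p = 0.5  # stationary start
        if al is not None:
            p *= trans(al, q, r1)
        if ar is not None:
            p *= trans(q, ar, r2)
        den += p
        if q == 1:
            num += p
    return 2.0 * num / den


GENO_STATES = (0.0, 2.0, np.nan)
DISTANCES = [(0.0, 5.0), (10.0, 10.0), (3.0, 27.0), (50.0, 1.0), (100.0, 100.0)]


class TestExpectedCount:
    @pytest.mark.parametrize("gl,gr", list(itertools.product(GENO_STATES, repeat=2)))
    @pytest.mark.parametrize("dl,dr", DISTANCES)
    def test_matches_enumeration_oracle(self, gl, gr, dl, dr):
        got = expected_count(gl, gr, dl, dr)
        want = enumerated_count(gl, gr, dl, dr)
        assert got == pytest.approx(want, abs=1e-12)
        assert 0.0 <= got <= 2.0

    def test_at_marker_equals_genotype(self):
        assert expected_count(2.0, 0.0, 0.0, 7.0) == 2.0
        assert expected_count(0.0, 2.0, 0.0, 7.0) == 0.0

    def test_both_missing_gives_prior_mean(self):
        assert expected_count(np.nan, np.nan, 5.0, 5.0) == 1.0

    @given(
        st.sampled_from([0.0, 2.0]), st.sampled_from([0.0, 2.0]),
        st.floats(min_value=0.0, max_value=200.0),
        st.floats(min_value=0.0, max_value=200.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_oracle_agreement_property(self, gl, gr, dl, dr):
        # discordant flanks at (effectively) zero distance are impossible
        assume(not (haldane_r(dl) == 0.0 and haldane_r(dr) == 0.0
                    and gl != gr))
        assert expected_count(gl, gr, dl, dr) == pytest.approx(
            enumerated_count(gl, gr, dl, dr), abs=1e-12)


class TestLodScore:
    def test_null_equals_full(self):
        assert lod_score(1.0, 1.0, 50) == 0.0

    def test_closed_form(self):
        assert lod_score(10 ** 0.1, 1.0, 100) == pytest.approx(5.0, abs=1e-9)

    def test_matches_gaussian_profile_likelihood(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 500))
            rss1 = float(rng.uniform(0.5, 5.0))
            rss0 = rss1 * float(rng.uniform(1.0, 3.0))

            def loglik(rss):
                s2 = rss / n
                return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

            want = (loglik(rss1) - loglik(rss0)) / np.log(10)
            assert lod_score(rss0, rss1, n) == pytest.approx(want, abs=1e-9)

    def test_invalid_rss(self):
        with pytest.raises(ValueError):
            lod_score(0.0, 1.0, 10)


def _line_values(geno, arr):
    return LineValues(values=pd.Series(arr, index=geno.line_ids))


class TestGenomeScan:
    def test_zero_variance_phenotype_flat_zero(self, small_population):
        y = _line_values(small_population, np.ones(small_population.n_lines))
        res = genome_scan(y, small_population, (), RunConfig(scan_step=5.0))
        assert (res.frame["lod"] == 0.0).all()

    def test_lod_nonnegative_with_noise(self, small_population):
        rng = np.random.default_rng(5)
        y = _line_values(small_population, rng.normal(0, 1, small_population.n_lines))
        res = genome_scan(y, small_population, (), RunConfig(scan_step=2.0))
        assert (res.frame["lod"] >= 0.0).all()
        assert res.frame["lod"].max() > 0.0

    def test_noiseless_qtl_peaks_at_its_interval(self, small_population):
        fams = small_population.family.family_ids
        model = QTLModel([QTLLocus("1A", 30.0, {f: 1.0 for f in fams})],
                         polygenic_sd=0.0)
        y, _ = simulate_line_values(small_population, model, 1.0, 1.0, seed=6)
        res = genome_scan(y, small_population, (), RunConfig())
        peak = res.frame.loc[res.frame["lod"].idxmax()]
        assert peak["chromosome"] == "1A"
        pos = small_population.gmap.chrom_positions("1A")
        lo = pos[pos <= 30.0].max() if (pos <= 30.0).any() else pos[0]
        hi = pos[pos >= 30.0].min() if (pos >= 30.0).any() else pos[-1]
        assert lo - 1e-9 <= peak["position_cM"] <= hi + 1e-9

    def test_effects_nan_for_monomorphic_families(self, small_population):
        rng = np.random.default_rng(7)
        y = _line_values(small_population, rng.normal(0, 1, small_population.n_lines))
        res = genome_scan(y, small_population, (), RunConfig(scan_step=10.0))
        assert res.effects.shape == (len(res.frame), 4)

    def test_distant_orthogonal_cofactor_changes_nothing(self):
        # hand-built design: within the single family the cofactor column is
        # exactly orthogonal to every tested marker and to the phenotype
        gmap = GeneticMap(pd.DataFrame({
            "marker_id": ["a1", "a2", "b1", "b2"],
            "chromosome": ["1A", "1A", "1B", "1B"],
            "position_cM": [0.0, 20.0, 0.0, 20.0]}))
        n = 8
        lines = [f"l{i}" for i in range(n)]
        fam = FamilyStructure(
            pd.DataFrame([("F1", "p", "q", n)],
                         columns=["family_id", "parent1", "parent2", "n_lines"]),
            pd.Series(["F1"] * n, index=pd.Index(lines, name="line_id")))
        a = np.array([0, 0, 0, 0, 2, 2, 2, 2], float)
        b = np.array([0, 0, 2, 2, 0, 0, 2, 2], float)  # orthogonal to a
        geno = MarkerData(lines, np.column_stack([a, a, b, b]), fam, gmap)
        y = _line_values(geno, a - a.mean() + np.array([0.1, -0.1] * 4))
        from mcqtl.scan import Cofactor

        cfg = RunConfig(scan_step=5.0)
        res0 = genome_scan(y, geno, (), cfg)
        res1 = genome_scan(y, geno, (Cofactor("b1", "1B", 0.0),), cfg)
        on_1a = res0.frame["chromosome"] == "1A"
        d = np.abs(res0.frame.loc[on_1a, "lod"].to_numpy()
                   - res1.frame.loc[on_1a, "lod"].to_numpy())
        assert d.max() < 1e-6


class TestCofactorSelection:
    def test_monomorphic_genotypes_select_nothing(self, tiny_map):
        n = 20
        lines = [f"l{i}" for i in range(n)]
        fam = FamilyStructure(
            pd.DataFrame([("F1", "p", "q", n)],
                         columns=["family_id", "parent1", "parent2", "n_lines"]),
            pd.Series(["F1"] * n, index=pd.Index(lines, name="line_id")))
        geno = MarkerData(lines, np.full((n, 3), 2.0), fam, tiny_map)
        rng = np.random.default_rng(8)
        y = _line_values(geno, rng.normal(0, 1, n))
        assert select_cofactors(y, geno) == []

    def test_noise_traits_rarely_select(self, power_population):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = _line_values(power_population,
                             rng.normal(0, 1, power_population.n_lines))
            counts.append(len(select_cofactors(y, power_population)))
        assert np.median(counts) <= 2

    def test_strong_qtl_attracts_a_cofactor(self, power_population):
        fams = power_population.family.family_ids
        hits = 0
        for seed in range(20):
            model = QTLModel([QTLLocus("1A", 40.0,
                                       {f: np.sqrt(0.25 * 3.0) for f in fams})])
            y, _ = simulate_line_values(power_population, model, 3.0, 0.87,
                                        seed=200 + seed)
            cofs = select_cofactors(y, power_population)
            if any(c.chromosome == "1A" and abs(c.position - 40.0) <= 10.0
                   for c in cofs):
                hits += 1
        assert hits >= 18


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, small_population):
        rng = np.random.default_rng(9)
        y = _line_values(small_population, rng.normal(0, 1, small_population.n_lines))
        cfg = RunConfig(n_permutations=100, scan_step=5.0)
        t_min = permutation_threshold(y, small_population, (), cfg, seed=1,
                                      alpha=1.0 - 1e-12)
        t_med = permutation_threshold(y, small_population, (), cfg, seed=1,
                                      alpha=0.5)
        t_10 = permutation_threshold(y, small_population, (), cfg, seed=1)
        assert t_min <= t_med <= t_10

    def test_scale_equivariance(self, small_population):
        rng = np.random.default_rng(10)
        yv = rng.normal(0, 1, small_population.n_lines)
        cfg = RunConfig(n_permutations=100, scan_step=5.0)
        t1 = permutation_threshold(_line_values(small_population, yv),
                                   small_population, (), cfg, seed=3)
        t2 = permutation_threshold(_line_values(small_population, 2 * yv),
                                   small_population, (), cfg, seed=3)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_deterministic_given_seed(self, small_population):
        rng = np.random.default_rng(11)
        y = _line_values(small_population, rng.normal(0, 1, small_population.n_lines))
        cfg = RunConfig(n_permutations=100, scan_step=5.0)
        assert permutation_threshold(y, small_population, (), cfg, seed=4) == \
            permutation_threshold(y, small_population, (), cfg, seed=4)

    def test_too_few_permutations_rejected(self, small_population):
        y = _line_values(small_population, np.arange(small_population.n_lines, dtype=float))
        with pytest.raises(ValueError):
            permutation_threshold(y, small_population, (),
                                  RunConfig(n_permutations=50))


def _profile(positions, lods, chrom="1A"):
    frame = pd.DataFrame({"chromosome": chrom, "position_cM": positions,
                          "lod": lods})
    return ScanResult(frame=frame, effects=np.zeros((len(positions), 1)),
                      family_ids=["F1"], cofactors=[])


class TestIdentifyQTL:
    def test_flat_profile_below_threshold(self):
        scan = _profile(np.arange(0, 50.0), np.full(50, 1.0))
        assert identify_qtl(scan, threshold=3.0) == []

    def test_triangular_falloff_geometry(self):
        pos = np.arange(30.0, 71.0)
        lod = 6.0 - 0.5 * np.abs(pos - 50.0)
        scan = _profile(pos, np.maximum(lod, 0.0))
        qtls = identify_qtl(scan, threshold=3.0, lod_falloff=1.0)
        assert len(qtls) == 1
        q = qtls[0]
        assert (q.position, q.ci_lo, q.ci_hi) == (50.0, 48.0, 52.0)

    def test_two_separated_peaks(self):
        pos = np.arange(0.0, 81.0)
        lod = np.maximum(6.0 - 0.8 * np.abs(pos - 20.0), 0.0) \
            + np.maximum(5.0 - 0.8 * np.abs(pos - 60.0), 0.0)
        qtls = identify_qtl(_profile(pos, lod), threshold=3.0)
        assert len(qtls) == 2
        assert [q.position for q in qtls] == [20.0, 60.0]

    def test_overlapping_intervals_merge_to_higher_peak(self):
        pos = np.arange(0.0, 41.0)
        lod = np.maximum(6.0 - 0.2 * np.abs(pos - 15.0), 0.0) \
            + np.maximum(5.5 - 0.2 * np.abs(pos - 25.0), 0.0)
        qtls = identify_qtl(_profile(pos, lod), threshold=3.0)
        assert len(qtls) == 1


class TestEstimatePg:
    def test_no_qtl_gives_zero(self, small_population):
        y = _line_values(small_population,
                         np.arange(small_population.n_lines, dtype=float))
        out = estimate_pg([], y, small_population, h2=0.9)
        assert out["pg_total"] == 0.0

    def test_noiseless_qtl_saturates(self, small_population):
        fams = small_population.family.family_ids
        model = QTLModel([QTLLocus("1A", 30.0, {f: 1.0 for f in fams})],
                         polygenic_sd=0.0)
        y, _ = simulate_line_values(small_population, model, 1.0, 1.0, seed=12)
        pos = small_population.gmap.chrom_positions("1A")
        at = float(pos[np.argmin(np.abs(pos - 30.0))])
        rec = QTLRecord("1A", at, at, at, 50.0)
        out = estimate_pg([rec], y, small_population, h2=1.0)
        assert out["pg_total"] > 90.0
        assert rec.pg_overall > 90.0

    def test_h2_out_of_range_rejected(self, small_population):
        y = _line_values(small_population,
                         np.arange(small_population.n_lines, dtype=float))
        with pytest.raises(ValueError):
            estimate_pg([], y, small_population, h2=0.0)


class TestMonotonicity:
    def test_stronger_qtl_never_lowers_median_peak_lod(self, small_population):
        fams = small_population.family.family_ids
        medians = []
        for beta in (0.3, 0.7, 1.2):
            lods = []
            for seed in range(8):
                model = QTLModel([QTLLocus("1A", 40.0, {f: beta for f in fams})])
                y, _ = simulate_line_values(small_population, model, 3.0,
                                            0.87, seed=300 + seed)
                res = genome_scan(y, small_population, (), RunConfig(scan_step=2.0))
                on = res.frame["chromosome"] == "1A"
                lods.append(res.frame.loc[on, "lod"].max())
            medians.append(np.median(lods))
        assert medians[0] <= medians[1] <= medians[2]
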