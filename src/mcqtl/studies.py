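"""Reference simulation studies validating the mapping pipeline.

Each study rebuilds its inputs from the generator, runs the full method and
measures an operating characteristic: the experiment-wise type I error of
the permutation threshold, QTL localization and pG recovery, sensitivity
and specificity of the epistasis scan, and the overfitting direction of
cross-validated pG.  The studies run at a reduced scale — five (or two)
chromosomes instead of twenty-one and a few hundred permutations instead
of two thousand — which leaves the operating characteristics themselves
unchanged while keeping each study within minutes on one core.

All randomness flows from a single seed through ``numpy.random
.SeedSequence``, so every study is reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import run_cv
from .epistasis import pair_scan
from .io import RunConfig
from .phenostats import LineValues
from .scan import (
    estimate_pg,
    genome_scan,
    identify_qtl,
    permutation_threshold,
    select_cofactors,
)
from .simpop import (
    QTLLocus,
    QTLModel,
    make_even_map,
    simulate_dh_family,
    simulate_line_values,
    stack_families,
)

#: family sizes of the emulated study population (647 DH lines total)
FAMILY_SIZES = (131, 120, 200, 196)


def _family_plan(sizes):
    return [("DH06", "Pa", "Pb", sizes[0]), ("DH07", "Pa", "Pc", sizes[1]),
            ("EAW74", "Pd", "Pe", sizes[2]), ("EAW78", "Pd", "Pf", sizes[3])]


def _genomes(n_chrom, length, n_markers):
    n_a = n_chrom - n_chrom // 2
    out = [("A", n_a, length, n_markers)]
    if n_chrom - n_a:
        out.append(("B", n_chrom - n_a, length, n_markers))
    return out


def simulate_study_population(rng, sizes=FAMILY_SIZES, n_chrom=5,
                              length=100.0, n_markers=20, hidden_loci=()):
    """Multi-family DH population on an evenly spaced map: four families
    from six parents (two half-sib pairs), polymorphism at roughly half the
    markers per family."""
    gmap = make_even_map(_genomes(n_chrom, length, n_markers))
    parents = {p: rng.integers(0, 2, gmap.n_markers)
               for p in ("Pa", "Pb", "Pc", "Pd", "Pe", "Pf")}
    members = []
    for fid, p1, p2, n in _family_plan(sizes):
        res = simulate_dh_family(
            parents[p1], parents[p2], n, gmap, rng=rng, family_id=fid,
            parent_names=(p1, p2), hidden_loci=list(hidden_loci) or None,
        )
        members.append(res if hidden_loci else (res, np.zeros((n, 0))))
    return stack_families(members)


def type_one_error_study(n_datasets=100, seed=0, n_per_family=50, n_chrom=5,
                         n_markers=20, n_permutations=200, alpha=0.10):
    """Experiment-wise false-positive rate of the permutation threshold.

    Simulates null populations (family mean differences but no QTL), runs
    cofactor selection, a permutation threshold and the genome scan on each,
    and reports the fraction of data sets whose genome-wide maximum LOD
    exceeds their own threshold.  Under a calibrated procedure this rate is
    at most ``alpha`` up to binomial error.
    """
    ss = np.random.SeedSequence(seed)
    cfg = RunConfig(n_permutations=n_permutations, alpha=alpha)
    exceed = 0
    thresholds, max_lods = [], []
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        geno, _ = simulate_study_population(
            rng, sizes=(n_per_family,) * 4, n_chrom=n_chrom,
            n_markers=n_markers)
        J = geno.family_indicator()
        y = pd.Series(J @ rng.normal(0.0, 0.5, J.shape[1])
                      + rng.normal(0.0, 1.0, geno.n_lines),
                      index=geno.line_ids)
        cofs = select_cofactors(y, geno, cfg)
        thr = permutation_threshold(y, geno, cofs, cfg, rng=rng)
        res = genome_scan(y, geno, cofs, cfg)
        thresholds.append(thr)
        max_lods.append(res.max_lod)
        if res.max_lod > thr:
            exceed += 1
    return {
        "rate": exceed / n_datasets,
        "n": n_datasets,
        "alpha": alpha,
        "mean_threshold": float(np.mean(thresholds)),
        "mean_max_lod": float(np.mean(max_lods)),
    }


def localization_study(n_reps=50, seed=0, pg_qtl=0.25, var_g=3.0, h2=0.87,
                       qtl=("3A", 52.7), n_chrom=5, n_markers=80,
                       pg_range=(15.0, 35.0), tol_cM=5.0):
    """Peak localization and pG recovery for a single QTL of known size.

    Each replicate simulates the full-size four-family population on a
    five-chromosome map with the QTL as a hidden (non-marker) locus
    explaining ``pg_qtl`` of the genotypic variance in every family, runs
    cofactor selection and the genome scan, and records the distance of the
    global LOD peak from the truth and the estimated pG of the top QTL.
    """
    ss = np.random.SeedSequence(seed)
    beta = float(np.sqrt(pg_qtl * var_g))
    dists, pgs = [], []
    cfg = RunConfig()
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        geno, hidden = simulate_study_population(
            rng, n_chrom=n_chrom, n_markers=n_markers, hidden_loci=[qtl])
        model = QTLModel([QTLLocus(qtl[0], qtl[1],
                                   {f: beta for f in geno.family.family_ids})])
        y, _ = simulate_line_values(geno, model, var_g, h2, rng=rng,
                                    true_counts=hidden)
        cofs = select_cofactors(y, geno, cfg)
        res = genome_scan(y, geno, cofs, cfg)
        peak = res.frame.loc[res.frame["lod"].idxmax()]
        dists.append(abs(float(peak["position_cM"]) - qtl[1])
                     if peak["chromosome"] == qtl[0] else np.inf)
        qtls = identify_qtl(res, threshold=3.0, lod_falloff=cfg.lod_falloff)
        if qtls:
            top = max(qtls, key=lambda q: q.lod)
            pgs.append(estimate_pg([top], y, geno, h2)["pg_total"])
        else:
            pgs.append(0.0)
    dists = np.array(dists)
    pgs = np.array(pgs)
    return {
        "frac_localized": float(np.mean(dists <= tol_cM)),
        "frac_pg_in_range": float(np.mean((pgs >= pg_range[0]) & (pgs <= pg_range[1]))),
        "n": n_reps,
        "median_dist_cM": float(np.median(dists)),
        "median_pg": float(np.median(pgs)),
    }


#: epistasis-study genome: the full 21-chromosome complement with one
#: marker per chromosome region (two regions 40 cM apart per chromosome),
#: the configuration in which the region-pair Bonferroni correction of the
#: pair scan is exactly calibrated.
_EPI_GENOMES = [("A", 7, 40.0, 2), ("B", 7, 40.0, 2), ("R", 7, 40.0, 2)]
_EPI_MIN_SEP = 20.0


def _epistasis_population(rng, force_markers=(), n_per_family=50):
    """Population for the pair-scan studies; markers listed in
    ``force_markers`` (chromosome, position) are made polymorphic in every
    family so a trait at those loci segregates everywhere."""
    gmap = make_even_map(_EPI_GENOMES)
    parents = {p: rng.integers(0, 2, gmap.n_markers)
               for p in ("Pa", "Pb", "Pc", "Pd", "Pe", "Pf")}
    for chrom, pos in force_markers:
        sub = gmap.chrom_markers(chrom)
        mid = sub.iloc[int(np.argmin(np.abs(sub["position_cM"] - pos)))]["marker_id"]
        j = gmap.marker_ids.index(mid)
        for p in ("Pa", "Pd"):
            parents[p][j] = 0
        for p in ("Pb", "Pc", "Pe", "Pf"):
            parents[p][j] = 1
    members = []
    for fid, p1, p2, n in _family_plan((n_per_family,) * 4):
        md = simulate_dh_family(parents[p1], parents[p2], n, gmap, rng=rng,
                                family_id=fid, parent_names=(p1, p2))
        members.append((md, np.zeros((n, 0))))
    return stack_families(members)[0]


def epistasis_recovery_study(n_reps=20, seed=0, h2=0.95,
                             loci=(("1A", 40.0), ("1B", 40.0)), gamma=2.0):
    """Sensitivity of the pair scan to a pure product interaction.

    The trait is gamma * 1[locus1 == 2] * 1[locus2 == 2] plus noise (both
    loci sit at markers segregating in every family); its orthogonal
    decomposition puts gamma^2/16 of variance in the pure interaction term,
    one third of the genetic variance.  A replicate counts as recovered
    when a significant pair lies within 10 cM of both true loci and its
    interaction pG is within a factor of two of the truth.
    """
    ss = np.random.SeedSequence(seed)
    truth_pg = 100.0 / 3.0  # (gamma^2/16) / (3 gamma^2/16)
    recovered = 0
    pgs = []
    cfg = RunConfig()
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        geno = _epistasis_population(rng, force_markers=loci)
        y = _interaction_trait(geno, loci, gamma, h2, rng)
        records = pair_scan(y, geno, h2, cfg, min_separation=_EPI_MIN_SEP)
        hit = None

        def near(det, tru):
            return det[0] == tru[0] and abs(det[1] - tru[1]) <= 10.0

        for r in records:
            d1, d2 = r.loci()
            ok = (near(d1, loci[0]) and near(d2, loci[1])) or (
                near(d1, loci[1]) and near(d2, loci[0]))
            if ok:
                hit = r if hit is None or r.p_value < hit.p_value else hit
        if hit is not None:
            pgs.append(hit.pg)
            if truth_pg / 2 <= hit.pg <= truth_pg * 2:
                recovered += 1
    return {"frac_recovered": recovered / n_reps, "n": n_reps,
            "truth_pg": truth_pg,
            "median_pg": float(np.median(pgs)) if pgs else 0.0}


def _interaction_trait(geno, loci, gamma, h2, rng):
    from .imputation import PositionEngine

    eng = PositionEngine(geno)
    a = [eng.counts(c, p) / 2.0 for c, p in loci]
    g = gamma * a[0] * a[1]
    g = g - g.mean()
    noise_sd = float(np.std(g)) * np.sqrt((1 - h2) / h2) if h2 < 1 else 0.0
    y = g + rng.normal(0.0, noise_sd, geno.n_lines)
    return LineValues(values=pd.Series(y, index=pd.Index(geno.line_ids,
                                                         name="line_id")))


def epistasis_specificity_study(n_reps=20, seed=0, h2=0.9,
                                loci=(("1A", 40.0), ("1B", 40.0)), beta=0.7):
    """Specificity: purely additive two-QTL traits should produce (almost)
    no significant interaction pairs at the region-corrected threshold.
    Returns the fraction of replicates with zero epistatic calls."""
    ss = np.random.SeedSequence(seed)
    clean = 0
    cfg = RunConfig()
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        geno = _epistasis_population(rng, force_markers=loci)
        model = QTLModel(
            [QTLLocus(c, p, {f: beta for f in geno.family.family_ids})
             for c, p in loci],
            polygenic_sd=0.0,
        )
        var_g = 2 * beta**2
        y, _ = simulate_line_values(geno, model, var_g, h2, rng=rng)
        records = pair_scan(y, geno, h2, cfg, min_separation=_EPI_MIN_SEP)
        if not records:
            clean += 1
    return {"frac_clean": clean / n_reps, "n": n_reps}


def cv_direction_study(runs=10, seed=0, h2=0.87, var_g=3.0,
                       cv_permutations=200):
    """Overfitting direction of cross-validated pG on the reduced preset
    (nine QTL, h2 0.87): the estimation-set pG should exceed the test-set
    pG in most runs.  Returns the fraction of runs with pg_ts < pg_es."""
    from .simpop import simulate_preset

    ss = np.random.SeedSequence(seed)
    s_pop, s_trait, s_cv = ss.spawn(3)
    data = simulate_preset("triticale_mini",
                           seed=int(s_pop.generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(s_trait)
    y, _ = simulate_line_values(data.geno, data.qtl_a, var_g, h2, rng=rng,
                                true_counts=data.hidden_counts)
    res = run_cv(y, data.geno, h2, RunConfig(), k=5, runs=runs,
                 seed=int(s_cv.generate_state(1)[0] % 2**31),
                 cv_permutations=cv_permutations)
    frac = float(np.mean(res.per_run["pg_ts"] < res.per_run["pg_es"]))
    return {"frac_ts_below_es": frac, "n_runs": runs,
            "pg_es": res.pg_es, "pg_ts": res.pg_ts,
            "relative_bias": res.relative_bias, "pg_ds": res.pg_ds,
            "qtl_ds": res.qtl_ds}
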