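"""Two-dimensional scan for pairwise epistatic interactions.

The single-locus model is extended by a second locus and an interaction
block: Y = J M + X_q B_q + X_q' B_q' + X_qq' B_qq' + e, where the
interaction column of family p is the product of the two within-family
mean-centred expected counts (centring makes the interaction orthogonal to
the main effects in balanced DH families).  The interaction term is tested
with an F-test of the full against the main-effects model; the per-test
alpha is the experiment-wise alpha divided by the number of independent
region pairs, assuming a fixed number of separate regions per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import PositionEngine
from .io import MarkerData, RunConfig
from .scan import _align_y, _fit, adjusted_r2, make_design_block

_VAR_TOL = 1e-12


@dataclass
class EpiRecord:
    """A significant pairwise interaction (loci in genome order)."""

    chrom1: str
    pos1: float
    chrom2: str
    pos2: float
    p_value: float
    pg: float

    def loci(self):
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


def epistasis_threshold(alpha: float, n_chrom: int,
                        regions_per_chrom: int = 2) -> float:
    """Per-test alpha: experiment-wise alpha divided by the number of
    possible independent region pairs C(R, 2) with R = chromosomes x
    regions per chromosome (one pair total keeps the full alpha)."""
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    n_regions = n_chrom * regions_per_chrom
    n_pairs = comb(n_regions, 2)
    return alpha / max(1, n_pairs)


def _region(gmap, chrom, pos, regions_per_chrom):
    length = gmap.chrom_length(chrom)
    j = min(int(pos / max(length, 1e-9) * regions_per_chrom),
            regions_per_chrom - 1)
    return (chrom, j)


def pair_scan(y, geno: MarkerData, h2: float, cfg: RunConfig | None = None,
              cofactors=(), min_separation: float = 20.0,
              marker_stride: int = 1, alpha_per_test=None) -> list:
    """Scan all marker pairs (>= ``min_separation`` cM apart on the same
    chromosome, or on different chromosomes) for interaction effects.

    Returns significant pairs after collapsing overlapping hits to the
    locally best (smallest p) pair per region pair.  ``marker_stride``
    thins the marker grid for large maps.  Perfectly collinear interaction
    columns cause the pair to be skipped.
    """
    cfg = cfg or RunConfig()
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    gmap = geno.gmap
    n_chrom = len(gmap.chromosome_names)
    if alpha_per_test is None:
        alpha_per_test = epistasis_threshold(
            cfg.epistasis_alpha, n_chrom, cfg.regions_per_chromosome)
    yv = _align_y(y, geno)
    n = len(yv)
    Y = yv[:, None]
    engine = PositionEngine(geno)
    J = geno.family_indicator()
    fam_codes = geno.family_codes()
    fam_ids = geno.family.family_ids
    markers = gmap.markers.iloc[::marker_stride]
    info = []
    for _, row in markers.iterrows():
        chrom, pos = row["chromosome"], float(row["position_cM"])
        counts = engine.counts(chrom, pos)
        block = make_design_block(counts, fam_codes, fam_ids, (chrom, pos))
        if block.n_columns == 0:
            continue
        centred = counts.copy()
        for p in range(len(fam_ids)):
            mask = fam_codes == p
            centred[mask] -= centred[mask].mean()
        info.append((chrom, pos, block, centred))
    cof_blocks = []
    for c in cofactors:
        counts = engine.counts(c.chromosome, c.position)
        blk = make_design_block(counts, fam_codes, fam_ids,
                                (c.chromosome, c.position))
        if blk.n_columns:
            cof_blocks.append((c, blk))
    hits = []
    for a in range(len(info)):
        ch1, p1, b1, c1 = info[a]
        for b in range(a + 1, len(info)):
            ch2, p2, b2, c2 = info[b]
            if ch1 == ch2 and abs(p2 - p1) < min_separation:
                continue
            inter_cols, inter_fams = [], []
            prod = c1 * c2
            for p, fam in enumerate(fam_ids):
                mask = fam_codes == p
                if fam not in b1.families or fam not in b2.families:
                    continue
                if np.var(prod[mask]) < _VAR_TOL:
                    continue
                col = np.zeros(n)
                col[mask] = prod[mask]
                inter_cols.append(col)
                inter_fams.append(fam)
            if not inter_cols:
                continue
            active_cofs = [
                blk.matrix for c, blk in cof_blocks
                if not any(
                    c.chromosome == ch and abs(c.position - pp) < cfg.cofactor_window
                    for ch, pp in ((ch1, p1), (ch2, p2))
                )
            ]
            X_main = np.hstack([J, b1.matrix, b2.matrix] + active_cofs)
            X_int = np.column_stack(inter_cols)
            X_full = np.hstack([X_main, X_int])
            rss_m = _fit(X_main, Y)[0][0]
            rss_f, beta = _fit(X_full, Y)[0][0], None
            df_int = X_int.shape[1]
            df_resid = n - X_full.shape[1]
            if df_resid <= 0 or rss_f < _VAR_TOL * n:
                continue
            if rss_m - rss_f < -1e-9:
                continue
            fstat = ((rss_m - rss_f) / df_int) / (rss_f / df_resid)
            p_val = float(stats.f.sf(max(fstat, 0.0), df_int, df_resid))
            if p_val < alpha_per_test:
                rss_base = _fit(J, Y)[0][0]
                df_base = n - J.shape[1]
                r2_full = adjusted_r2(rss_base, df_base, rss_f, df_resid)
                r2_main = adjusted_r2(rss_base, df_base, rss_m,
                                      n - X_main.shape[1])
                pg = max(0.0, 100.0 * (r2_full - r2_main) / h2)
                hits.append(EpiRecord(str(ch1), p1, str(ch2), p2,
                                      max(p_val, np.nextafter(0, 1)), pg))
    return _collapse_regions(hits, gmap, cfg.regions_per_chromosome)


def _collapse_regions(hits, gmap, regions_per_chrom):
    best: dict = {}
    for h in hits:
        r1 = _region(gmap, h.chrom1, h.pos1, regions_per_chrom)
        r2 = _region(gmap, h.chrom2, h.pos2, regions_per_chrom)
        key = tuple(sorted((r1, r2)))
        cur = best.get(key)
        if cur is None or (h.p_value, h.chrom1, h.pos1, h.pos2) < (
                cur.p_value, cur.chrom1, cur.pos1, cur.pos2):
            best[key] = h
    return sorted(best.values(),
                  key=lambda h: (h.chrom1, h.pos1, h.chrom2, h.pos2))


def write_epistasis_table(records, path) -> None:
    pd.DataFrame(
        [
            (r.chrom1, r.pos1, r.chrom2, r.pos2, r.p_value, r.pg)
            for r in records
        ],
        columns=["chrom1", "pos1_cM", "chrom2", "pos2_cM", "p_value", "pg"],
    ).to_csv(path, index=False, na_rep="NA")
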