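"""Expected reference-allele counts at arbitrary map positions.

At a tested position the design matrix of the joint scan needs, for every
DH line, the expected number (0--2) of the family's reference-parent allele
conditional on the genotypes of the flanking markers.  Because a DH line is
a doubled single gamete, the locus state is a two-state Markov chain along
the chromosome with transition probability given by the Haldane map
function (no crossover interference).

With r1 = r(d_left), r2 = r(d_right) and rT = r1 + r2 - 2*r1*r2 the
conditional probabilities of carrying the reference allele are

    flanks (2, 2):  (1-r1)(1-r2) / (1-rT)
    flanks (2, 0):  (1-r1) r2    / rT
    flanks (0, 2):  r1 (1-r2)    / rT
    flanks (0, 0):  r1 r2        / (1-rT)

multiplied by 2 to give a count.  A missing flank falls back to the nearest
non-missing marker on that side; with one informative side only, the
single-marker conditional 2(1-r) or 2r applies; with no information the
population expectation 1 is used (DH segregation is 1:1).
"""

from __future__ import annotations

import numpy as np

from .simpop import haldane_r

_EPS = 1e-300


def _count_from_flanks(gl, gr, dl, dr):
    """Vectorised expected count from flanking genotypes and distances.

    ``gl``/``gr`` are 0, 2 or NaN; distances in cM (ignored where the
    corresponding flank is NaN).
    """
    gl = np.asarray(gl, float)
    gr = np.asarray(gr, float)
    dl = np.where(np.isnan(gl), 0.0, np.asarray(dl, float))
    dr = np.where(np.isnan(gr), 0.0, np.asarray(dr, float))
    if (dl < 0).any() or (dr < 0).any():
        raise ValueError("flanking distances must be >= 0")
    r1 = haldane_r(dl)
    r2 = haldane_r(dr)
    rT = r1 + r2 - 2.0 * r1 * r2
    al = gl == 2.0
    ar = gr == 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p_both = np.where(
            al == ar,
            np.where(al, (1 - r1) * (1 - r2), r1 * r2) / np.maximum(1 - rT, _EPS),
            np.where(al, (1 - r1) * r2, r1 * (1 - r2)) / np.maximum(rT, _EPS),
        )
    # rT == 0 with discordant flanks is geometrically impossible; fall back
    # to the prior mean to keep the [0, 2] contract on inconsistent input.
    p_both = np.where((rT <= 0) & (al != ar), 0.5, p_both)
    p_left = np.where(al, 1 - r1, r1)
    p_right = np.where(ar, 1 - r2, r2)
    have_l = ~np.isnan(gl)
    have_r = ~np.isnan(gr)
    p = np.where(
        have_l & have_r,
        p_both,
        np.where(have_l, p_left, np.where(have_r, p_right, 0.5)),
    )
    return 2.0 * p


def expected_count(left_geno, right_geno, d_left, d_right) -> float:
    """Expected reference-allele count (in [0, 2]) for one DH line.

    ``left_geno``/``right_geno`` are the flanking-marker genotypes (0, 2 or
    NaN for missing) and ``d_left``/``d_right`` the cM distances from the
    evaluated position to those markers.
    """
    out = _count_from_flanks(
        np.array([left_geno], float),
        np.array([right_geno], float),
        np.array([d_left], float),
        np.array([d_right], float),
    )
    return float(out[0])


class PositionEngine:
    """Per-chromosome cache of flanking-marker lookups for a MarkerData.

    Missing genotypes fall back to the nearest non-missing marker on the
    same side, so the engine precomputes, for every line and marker index,
    the nearest informative marker to the left and to the right.
    """

    def __init__(self, geno):
        self.geno = geno
        self._chrom: dict[str, dict] = {}
        gmap = geno.gmap
        markers = gmap.markers
        col_of = {m: j for j, m in enumerate(gmap.marker_ids)}
        fam_codes = geno.family_codes()
        n_fam = geno.family.n_families
        for chrom in gmap.chromosome_names:
            sub = markers[markers["chromosome"] == chrom]
            cols = [col_of[m] for m in sub["marker_id"]]
            G = geno.genotype[:, cols]
            pos = sub["position_cM"].to_numpy(float)
            n, m = G.shape
            idx = np.arange(m)
            # a marker is informative for a line only if the call is present
            # AND the marker segregates in that line's family (a marker where
            # the parents carry the same allele says nothing about which
            # gamete was inherited)
            poly = np.zeros((n_fam, m), bool)
            for f in range(n_fam):
                Gf = G[fam_codes == f]
                poly[f] = (Gf == 0.0).any(axis=0) & (Gf == 2.0).any(axis=0)
            informative = ~np.isnan(G) & poly[fam_codes]
            left = np.where(informative, idx[None, :], -1)
            left = np.maximum.accumulate(left, axis=1)
            right = np.where(informative, idx[None, :], m)
            right = np.minimum.accumulate(right[:, ::-1], axis=1)[:, ::-1]
            self._chrom[chrom] = dict(G=G, pos=pos, left=left, right=right)

    def counts(self, chromosome: str, position: float) -> np.ndarray:
        """Expected count vector (one entry per line) at a map position."""
        c = self._chrom[chromosome]
        G, pos = c["G"], c["pos"]
        n, m = G.shape
        jL = int(np.searchsorted(pos, position, side="right")) - 1
        jR = int(np.searchsorted(pos, position, side="left"))
        rows = np.arange(n)
        if jL >= 0:
            li = c["left"][:, jL]
        else:
            li = np.full(n, -1)
        if jR < m:
            ri = c["right"][:, jR]
        else:
            ri = np.full(n, m)
        has_l = li >= 0
        has_r = ri < m
        gl = np.where(has_l, G[rows, np.clip(li, 0, m - 1)], np.nan)
        gr = np.where(has_r, G[rows, np.clip(ri, 0, m - 1)], np.nan)
        dl = np.where(has_l, position - pos[np.clip(li, 0, m - 1)], 0.0)
        dr = np.where(has_r, pos[np.clip(ri, 0, m - 1)] - position, 0.0)
        return _count_from_flanks(gl, gr, dl, dr)

    def flanking_interval(self, chromosome: str, position: float) -> tuple[float, float]:
        """The marker interval containing the position (chromosome ends clamp)."""
        pos = self._chrom[chromosome]["pos"]
        jL = int(np.searchsorted(pos, position, side="right")) - 1
        jR = int(np.searchsorted(pos, position, side="left"))
        lo = pos[jL] if jL >= 0 else pos[0]
        hi = pos[jR] if jR < len(pos) else pos[-1]
        return float(lo), float(hi)
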