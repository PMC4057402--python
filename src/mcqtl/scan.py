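"""Joint multi-family QTL genome scan with family-specific effects.

The model at a tested genome position is

    Y = J M + X_q B_q + X_c B_c + e

where Y holds the adjusted line means, J is the N x P family-membership
matrix with family means M, X_q holds the expected reference-allele count
(0--2) of each line at the tested position in its family's column (zero
elsewhere) with family-specific substitution effects B_q, and X_c are
equally-structured cofactor blocks absorbing QTL elsewhere in the genome.
Null (without X_q) and full models are fitted by least squares at every
grid position; the evidence is expressed as

    LOD = (n / 2) * log10(RSS_null / RSS_full).

Genome-wide significance comes from within-family permutations of Y;
support intervals from a LOD fall-off rule; and the proportion of
genotypic variance (pG) from the adjusted R^2 of the simultaneous
multi-QTL fit divided by the heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputation import PositionEngine, expected_count  # noqa: F401 (re-export)
from .io import MarkerData, RunConfig

_VAR_TOL = 1e-12


def lod_score(rss0: float, rss1: float, n: int) -> float:
    """LOD from null/full residual sums of squares of Gaussian LS fits.

    Equals the log10 likelihood ratio of the profiled Gaussian likelihoods;
    negative values (possible only through numerical noise) clip to 0.
    """
    if rss0 <= 0 or rss1 <= 0:
        raise ValueError("residual sums of squares must be positive")
    return max(0.0, 0.5 * n * np.log10(rss0 / rss1))


@dataclass(frozen=True)
class DesignBlock:
    """Family-specific expected-count block at one genome position."""

    matrix: np.ndarray  # n x k, one column per non-degenerate family
    families: tuple  # family ids of the columns
    position: tuple  # (chromosome, cM)
    degenerate: frozenset  # families monomorphic at this position

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def make_design_block(counts, fam_codes, family_ids, position=("", 0.0)) -> DesignBlock:
    """Build the N x P block from a count vector, dropping columns that are
    (near-)constant within their family — those families do not segregate
    at the position and get no effect there."""
    counts = np.asarray(counts, float)
    cols, used, degen = [], [], []
    for p, fam in enumerate(family_ids):
        mask = fam_codes == p
        vals = counts[mask]
        if vals.size == 0 or np.var(vals) < _VAR_TOL:
            degen.append(fam)
            continue
        col = np.zeros_like(counts)
        col[mask] = vals
        cols.append(col)
        used.append(fam)
    mat = np.column_stack(cols) if cols else np.empty((len(counts), 0))
    return DesignBlock(mat, tuple(used), tuple(position), frozenset(degen))


@dataclass(frozen=True)
class Cofactor:
    marker_id: str
    chromosome: str
    position: float


@dataclass
class ScanResult:
    """LOD profile and family-specific effect estimates along the map."""

    frame: pd.DataFrame  # chromosome, position_cM, lod
    effects: np.ndarray  # n_positions x P (NaN where family monomorphic)
    family_ids: list
    cofactors: list
    threshold: float | None = None

    def chrom_profile(self, chromosome):
        sub = self.frame[self.frame["chromosome"] == chromosome]
        return sub["position_cM"].to_numpy(float), sub["lod"].to_numpy(float)

    @property
    def max_lod(self) -> float:
        return float(self.frame["lod"].max())


@dataclass
class QTLRecord:
    """A detected QTL with support interval and pG shares."""

    chromosome: str
    position: float
    ci_lo: float
    ci_hi: float
    lod: float
    pg_overall: float = np.nan
    pg_family: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.ci_lo <= self.position <= self.ci_hi:
            raise ValueError("support interval must contain the peak")


# ---------------------------------------------------------------------------
# least-squares helpers


def _fit(X: np.ndarray, Y: np.ndarray):
    """Least squares via SVD (rank-revealing); returns (rss per column,
    coefficients)."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    return np.maximum(rss, 1e-300), beta


def _lod_matrix(rss0, rss1, n):
    with np.errstate(divide="ignore"):
        lod = 0.5 * n * np.log10(rss0 / rss1)
    return np.maximum(lod, 0.0)


def scan_positions(gmap, step: float) -> dict:
    """Per-chromosome evaluation grid: every ``step`` cM plus every marker."""
    out = {}
    for chrom in gmap.chromosome_names:
        mpos = gmap.chrom_positions(chrom)
        grid = np.arange(0.0, mpos[-1] + step / 2, step)
        allpos = np.unique(np.round(np.concatenate([grid, mpos]), 9))
        out[chrom] = allpos
    return out


def _cofactor_blocks(cofactors, engine, geno):
    fam_codes = geno.family_codes()
    fam_ids = geno.family.family_ids
    blocks = []
    for c in cofactors:
        counts = engine.counts(c.chromosome, c.position)
        blocks.append((c, make_design_block(counts, fam_codes, fam_ids,
                                            (c.chromosome, c.position))))
    return blocks


def _active_cofactors(cof_blocks, chrom, interval, window):
    """Indices of cofactors farther than ``window`` cM from the tested
    marker interval (same chromosome only; other chromosomes always kept)."""
    lo, hi = interval
    active = []
    for i, (c, _) in enumerate(cof_blocks):
        if c.chromosome == chrom:
            gap = max(0.0, lo - c.position, c.position - hi)
            if gap < window:
                continue
        active.append(i)
    return tuple(active)


def _scan_lod(Y, geno, cofactors, cfg, want_effects=False, engine=None):
    """LOD of the joint scan for each column of Y at every grid position.

    Shared workhorse of :func:`genome_scan` (single phenotype, effects
    requested) and :func:`permutation_threshold` (many permuted phenotypes
    at once).
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, n_y = Y.shape
    engine = engine or PositionEngine(geno)
    gmap = geno.gmap
    J = geno.family_indicator()
    fam_codes = geno.family_codes()
    fam_ids = geno.family.family_ids
    cof_blocks = _cofactor_blocks(cofactors, engine, geno)
    grid = scan_positions(gmap, cfg.scan_step)
    rss0_cache: dict = {}
    rows, lods = [], []
    effects = [] if want_effects else None
    for chrom in gmap.chromosome_names:
        for pos in grid[chrom]:
            interval = engine.flanking_interval(chrom, pos)
            active = _active_cofactors(cof_blocks, chrom, interval,
                                       cfg.cofactor_window)
            if active not in rss0_cache:
                X0 = np.hstack([J] + [cof_blocks[i][1].matrix for i in active]) \
                    if active else J
                rss0_cache[active] = (_fit(X0, Y)[0], X0)
            rss0, X0 = rss0_cache[active]
            counts = engine.counts(chrom, pos)
            block = make_design_block(counts, fam_codes, fam_ids, (chrom, pos))
            if block.n_columns == 0:
                lod = np.zeros(n_y)
                beta_fam = np.full(len(fam_ids), np.nan)
            else:
                X1 = np.hstack([X0, block.matrix])
                rss1, beta = _fit(X1, Y)
                lod = _lod_matrix(rss0, rss1, n)
                beta_fam = np.full(len(fam_ids), np.nan)
                if want_effects:
                    bq = beta[-block.n_columns:, 0]
                    for b, fam in zip(bq, block.families):
                        beta_fam[fam_ids.index(fam)] = b
            rows.append((chrom, float(pos)))
            lods.append(lod)
            if want_effects:
                effects.append(beta_fam)
    frame = pd.DataFrame(rows, columns=["chromosome", "position_cM"])
    lod_mat = np.vstack(lods)
    eff = np.vstack(effects) if want_effects else None
    return frame, lod_mat, eff


def genome_scan(y, geno: MarkerData, cofactors=(), cfg: RunConfig | None = None,
                engine=None) -> ScanResult:
    """LOD profile of the multiple-line cross model along the whole map.

    ``y`` is a LineValues (or Series) aligned to ``geno``; cofactors within
    ``cfg.cofactor_window`` cM of the tested marker interval are dropped
    from both the null and the full model at that position.
    """
    cfg = cfg or RunConfig()
    yv = _align_y(y, geno)
    frame, lod_mat, eff = _scan_lod(yv, geno, cofactors, cfg,
                                    want_effects=True, engine=engine)
    if np.var(yv) < _VAR_TOL:
        lod_mat = np.zeros_like(lod_mat)
    frame = frame.copy()
    frame["lod"] = lod_mat[:, 0]
    return ScanResult(frame=frame, effects=eff,
                      family_ids=geno.family.family_ids,
                      cofactors=list(cofactors))


def _align_y(y, geno):
    if hasattr(y, "reindex") and hasattr(y, "values") and hasattr(y, "trait"):
        return y.reindex(geno.line_ids)
    if isinstance(y, pd.Series):
        return y.loc[list(geno.line_ids)].to_numpy(float)
    arr = np.asarray(y, float)
    if arr.shape != (geno.n_lines,):
        raise ValueError("phenotype length != number of lines")
    return arr


def _within_family_permutations(yv, fam_codes, n_perm, rng):
    """n x n_perm matrix of phenotypes permuted within each family."""
    n = len(yv)
    out = np.empty((n, n_perm))
    fams = np.unique(fam_codes)
    for b in range(n_perm):
        col = np.empty(n)
        for f in fams:
            idx = np.flatnonzero(fam_codes == f)
            col[idx] = yv[rng.permutation(idx)]
        out[:, b] = col
    return out


def permutation_threshold(y, geno: MarkerData, cofactors=(),
                          cfg: RunConfig | None = None, seed=None, rng=None,
                          alpha=None, engine=None) -> float:
    """Genome-wide LOD threshold at experiment-wise error ``alpha``.

    Phenotype values are permuted within family (respecting the family-mean
    term of the model); the (1 - alpha) empirical quantile of the per-
    permutation maximum LOD is returned.  Deterministic given the seed.
    """
    cfg = cfg or RunConfig()
    if cfg.n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    alpha = cfg.alpha if alpha is None else alpha
    rng = np.random.default_rng(cfg.seed if seed is None else seed) if rng is None else rng
    yv = _align_y(y, geno)
    Y = _within_family_permutations(yv, geno.family_codes(),
                                    cfg.n_permutations, rng)
    _, lod_mat, _ = _scan_lod(Y, geno, cofactors, cfg, engine=engine)
    max_lods = lod_mat.max(axis=0)
    return float(np.quantile(max_lods, 1.0 - alpha, method="higher"))


# ---------------------------------------------------------------------------
# cofactor selection


def select_cofactors(y, geno: MarkerData, cfg: RunConfig | None = None,
                     max_cofactors=None, engine=None) -> list:
    """Forward selection of marker cofactors by the Schwarz criterion (BIC).

    Each candidate marker enters as a family-specific block (one column per
    segregating family) on top of the family means; selection stops when no
    candidate improves the BIC.  Deterministic; criterion ties break toward
    the lower (chromosome, position).
    """
    cfg = cfg or RunConfig()
    yv = _align_y(y, geno)
    n = len(yv)
    engine = engine or PositionEngine(geno)
    gmap = geno.gmap
    fam_codes = geno.family_codes()
    fam_ids = geno.family.family_ids
    J = geno.family_indicator()
    candidates = []
    for _, row in gmap.markers.iterrows():
        chrom, pos, mid = row["chromosome"], float(row["position_cM"]), row["marker_id"]
        counts = engine.counts(chrom, pos)
        block = make_design_block(counts, fam_codes, fam_ids, (chrom, pos))
        if block.n_columns:
            candidates.append((Cofactor(mid, chrom, pos), block))
    Y = yv[:, None]

    def bic(rss, k):
        return n * np.log(rss / n) + k * np.log(n)

    X = J
    k = J.shape[1]
    cur = bic(_fit(X, Y)[0][0], k)
    chosen: list = []
    remaining = list(range(len(candidates)))
    while remaining and (max_cofactors is None or len(chosen) < max_cofactors):
        best, best_bic = None, cur - 1e-9
        for i in remaining:
            blk = candidates[i][1]
            rss = _fit(np.hstack([X, blk.matrix]), Y)[0][0]
            b = bic(rss, k + blk.n_columns)
            if b < best_bic:  # strict <: first (map-ordered) candidate wins ties
                best, best_bic = i, b
        if best is None:
            break
        cof, blk = candidates[best]
        chosen.append(cof)
        X = np.hstack([X, blk.matrix])
        k += blk.n_columns
        cur = best_bic
        remaining.remove(best)
    return chosen


# ---------------------------------------------------------------------------
# QTL identification and pG


def identify_qtl(scan: ScanResult, threshold: float,
                 lod_falloff: float = 1.0) -> list:
    """Local LOD maxima above the threshold with fall-off support intervals.

    The support interval runs from the peak outward to the first grid
    position where the LOD has dropped by ``lod_falloff`` (chromosome ends
    truncate).  Peaks whose support intervals overlap are merged, keeping
    the higher peak (ties break toward the lower position).
    """
    records = []
    for chrom in scan.frame["chromosome"].unique():
        pos, lod = scan.chrom_profile(chrom)
        n = len(pos)
        peaks = []
        for i in range(n):
            if lod[i] <= threshold:
                continue
            left = lod[i - 1] if i > 0 else -np.inf
            right = lod[i + 1] if i < n - 1 else -np.inf
            if lod[i] > left and lod[i] >= right:
                peaks.append(i)
        chrom_records = []
        for i in peaks:
            target = lod[i] - lod_falloff
            lo = pos[0]
            for j in range(i - 1, -1, -1):
                if lod[j] <= target:
                    lo = pos[j]
                    break
            hi = pos[-1]
            for j in range(i + 1, n):
                if lod[j] <= target:
                    hi = pos[j]
                    break
            chrom_records.append(QTLRecord(chromosome=str(chrom),
                                           position=float(pos[i]),
                                           ci_lo=float(lo), ci_hi=float(hi),
                                           lod=float(lod[i])))
        records.extend(_merge_overlapping(chrom_records))
    return records


def _merge_overlapping(records):
    records = sorted(records, key=lambda r: r.position)
    changed = True
    while changed:
        changed = False
        for a in range(len(records) - 1):
            r1, r2 = records[a], records[a + 1]
            if r2.ci_lo <= r1.ci_hi:  # support intervals overlap
                keep = r1 if (r1.lod, -r1.position) >= (r2.lod, -r2.position) else r2
                records = records[:a] + [keep] + records[a + 2:]
                changed = True
                break
    return records


def adjusted_r2(rss_base, df_base, rss_model, df_model) -> float:
    """Adjusted coefficient of determination of a model relative to a base
    (nuisance-only) model."""
    return 1.0 - (rss_model / df_model) / (rss_base / df_base)


def _qtl_blocks(qtls, geno, engine=None):
    engine = engine or PositionEngine(geno)
    fam_codes = geno.family_codes()
    fam_ids = geno.family.family_ids
    return [
        make_design_block(engine.counts(q.chromosome, q.position),
                          fam_codes, fam_ids, (q.chromosome, q.position))
        for q in qtls
    ]


def estimate_pg(qtls, y, geno: MarkerData, h2: float, engine=None) -> dict:
    """Proportion of genotypic variance from the simultaneous multi-QTL fit.

    Overall pG = 100 * R2_adj / h2 where R2_adj is the adjusted R^2 of the
    QTL terms beyond the family means; per-QTL pG is the drop-one decrement
    of R2_adj in the same joint fit; per-family pG repeats the computation
    within each family's sub-sample (using the population h2 as proxy).
    QTLRecords are updated in place; returns
    {"pg_total": float, "pg_qtl": [...], "pg_family_total": {...}}.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    yv = _align_y(y, geno)
    n = len(yv)
    J = geno.family_indicator()
    fam_ids = geno.family.family_ids
    fam_codes = geno.family_codes()
    if not qtls:
        return {"pg_total": 0.0, "pg_qtl": [], "pg_family_total": {f: 0.0 for f in fam_ids}}
    blocks = _qtl_blocks(qtls, geno, engine)
    k_all = sum(b.n_columns for b in blocks)
    if J.shape[1] + k_all >= n:
        raise ValueError("more model columns than lines")
    Y = yv[:, None]
    rss_base = _fit(J, Y)[0][0]
    df_base = n - J.shape[1]
    X_full = np.hstack([J] + [b.matrix for b in blocks])
    rss_full = _fit(X_full, Y)[0][0]
    df_full = n - X_full.shape[1]
    r2_full = adjusted_r2(rss_base, df_base, rss_full, df_full)
    pg_total = max(0.0, 100.0 * r2_full / h2)
    pg_qtl = []
    for q in range(len(qtls)):
        others = [b.matrix for i, b in enumerate(blocks) if i != q]
        X_d = np.hstack([J] + others) if others else J
        rss_d = _fit(X_d, Y)[0][0]
        r2_d = adjusted_r2(rss_base, df_base, rss_d, n - X_d.shape[1])
        pg_qtl.append(max(0.0, 100.0 * (r2_full - r2_d) / h2))
    # per-family pG, within each family's sub-sample
    for q, rec in enumerate(qtls):
        rec.pg_overall = pg_qtl[q]
        rec.pg_family = {}
    pg_family_total = {}
    for p, fam in enumerate(fam_ids):
        mask = fam_codes == p
        nf = int(mask.sum())
        yf = Y[mask]
        ones = np.ones((nf, 1))
        cols = []
        fam_cols = []  # per-qtl column (or None)
        for b in blocks:
            if fam in b.families:
                j = b.families.index(fam)
                col = b.matrix[mask, j:j + 1]
                cols.append(col)
                fam_cols.append(col)
            else:
                fam_cols.append(None)
        if not cols or nf <= len(cols) + 1:
            pg_family_total[fam] = 0.0
            for rec in qtls:
                rec.pg_family[fam] = 0.0
            continue
        rss_b = _fit(ones, yf)[0][0]
        df_b = nf - 1
        Xf = np.hstack([ones] + cols)
        rss_f = _fit(Xf, yf)[0][0]
        r2_f = adjusted_r2(rss_b, df_b, rss_f, nf - Xf.shape[1])
        pg_family_total[fam] = max(0.0, 100.0 * r2_f / h2)
        for q, rec in enumerate(qtls):
            if fam_cols[q] is None:
                rec.pg_family[fam] = 0.0
                continue
            others = [c for i, c in enumerate(fam_cols) if i != q and c is not None]
            X_d = np.hstack([ones] + others) if others else ones
            rss_d = _fit(X_d, yf)[0][0]
            r2_d = adjusted_r2(rss_b, df_b, rss_d, nf - X_d.shape[1])
            rec.pg_family[fam] = max(0.0, 100.0 * (r2_f - r2_d) / h2)
    # overall pg on the records: drop-one decrements; keep joint total separately
    return {"pg_total": pg_total, "pg_qtl": pg_qtl,
            "pg_family_total": pg_family_total}


def fit_qtl_effects(qtls, y, geno: MarkerData, engine=None):
    """Joint LS fit of family means + all QTL blocks; returns (family_means
    dict, per-QTL effects list of dicts family -> beta)."""
    yv = _align_y(y, geno)
    J = geno.family_indicator()
    fam_ids = geno.family.family_ids
    blocks = _qtl_blocks(qtls, geno, engine)
    X = np.hstack([J] + [b.matrix for b in blocks]) if qtls else J
    _, beta = _fit(X, yv[:, None])
    beta = beta[:, 0]
    means = {f: float(beta[p]) for p, f in enumerate(fam_ids)}
    effects = []
    k = J.shape[1]
    for b in blocks:
        eff = {fam: float(beta[k + j]) for j, fam in enumerate(b.families)}
        effects.append(eff)
        k += b.n_columns
    return means, effects
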