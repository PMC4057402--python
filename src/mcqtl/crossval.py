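"""Fivefold cross-validation of the full mapping pipeline.

Each run partitions the lines into k family-stratified folds.  For every
fold, the remaining folds form the estimation set (ES): cofactor selection,
permutation threshold, QTL detection and pG estimation all run on the ES
alone.  In the held-out test set (TS) the ES QTL effects predict genetic
values; pG-TS is the shrinkage-adjusted squared correlation between the
prediction and the family-mean-adjusted observations, divided by the
heritability.  Averaging over fold instances gives pG-ES and pG-TS, whose
gap expresses the upward bias of pG estimated on the discovery data:

    relative bias = 100 * (pG_ES - pG_TS) / pG_ES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerData, RunConfig
from .scan import (
    estimate_pg,
    fit_qtl_effects,
    genome_scan,
    identify_qtl,
    permutation_threshold,
    select_cofactors,
)


@dataclass
class CVResult:
    n_runs: int
    k: int
    qtl_ds: int
    pg_ds: float
    qtl_es: float
    pg_es: float
    pg_ts: float
    relative_bias: float
    frequency: pd.DataFrame  # chromosome, position_cM, count (over fold instances)
    per_run: pd.DataFrame  # run -> mean pg_es, pg_ts

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["QTL_DS", "pG_DS", "QTL_ES", "pG_ES", "pG_TS",
                             "relative_bias"],
                "value": [self.qtl_ds, self.pg_ds, self.qtl_es, self.pg_es,
                          self.pg_ts, self.relative_bias],
            }
        )


def relative_bias(pg_es: float, pg_ts: float) -> float:
    """Percent bias of the estimation-set pG relative to the test-set pG."""
    if pg_es <= 0:
        raise ValueError("relative bias undefined for pg_es <= 0")
    return 100.0 * (pg_es - pg_ts) / pg_es


def stratified_folds(fam_codes, k, rng):
    """Partition indices into k folds, proportional within every family
    (fold sizes per family differ by at most one line)."""
    folds = [[] for _ in range(k)]
    start = 0
    for f in np.unique(fam_codes):
        idx = np.flatnonzero(fam_codes == f)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
        start += len(idx)  # rotate which fold gets the remainder
    return [np.sort(np.array(f)) for f in folds]


def _pipeline(y, geno, h2, cfg, seed):
    """Cofactors -> threshold -> scan -> QTL -> pG on one data set."""
    cofs = select_cofactors(y, geno, cfg)
    thr = permutation_threshold(y, geno, cofs, cfg, seed=seed)
    scan = genome_scan(y, geno, cofs, cfg)
    scan.threshold = thr
    qtls = identify_qtl(scan, thr, cfg.lod_falloff)
    pg = estimate_pg(qtls, y, geno, h2) if qtls else {"pg_total": 0.0}
    return qtls, pg["pg_total"], scan


def predict_qtl_values(qtls, y_train, geno_train: MarkerData,
                       geno_test: MarkerData):
    """Predicted QTL genetic values for test lines from effects estimated on
    the training lines; returns (prediction, observed-minus-family-mean
    helper).  Families without an estimated effect contribute zero."""
    from .imputation import PositionEngine

    means, effects = fit_qtl_effects(qtls, y_train, geno_train)
    engine = PositionEngine(geno_test)
    fam = geno_test.family.family_of(geno_test.line_ids)
    pred = np.zeros(geno_test.n_lines)
    for q, rec in enumerate(qtls):
        counts = engine.counts(rec.chromosome, rec.position)
        beta = np.array([effects[q].get(f, 0.0) for f in fam])
        pred += counts * beta
    fam_mean = np.array([means.get(f, np.nan) for f in fam])
    return pred, fam_mean


def run_cv(y, geno: MarkerData, h2: float, cfg: RunConfig | None = None,
           k: int = 5, runs: int = 20, seed: int = 0,
           cv_permutations: int = 200) -> CVResult:
    """Run ``runs`` replicates of k-fold cross-validation.

    ``cv_permutations`` caps the permutation count inside estimation sets
    (the full-data scan uses ``cfg.n_permutations``).  Deterministic given
    the seed.
    """
    cfg = cfg or RunConfig()
    if k < 2:
        raise ValueError("need k >= 2 folds")
    fam_codes = geno.family_codes()
    for f in np.unique(fam_codes):
        if (fam_codes == f).sum() < k:
            raise ValueError("every family needs at least k lines")
    ss = np.random.SeedSequence(seed)
    ds_seed, *fold_seeds = ss.spawn(1 + runs)
    qtls_ds, pg_ds, _ = _pipeline(y, geno, h2, cfg,
                                  seed=np.random.default_rng(ds_seed))
    cfg_cv = cfg.replace(n_permutations=min(cfg.n_permutations, cv_permutations))
    yv = y.reindex(geno.line_ids) if hasattr(y, "reindex") else np.asarray(y, float)
    n_qtl_es, pg_es_all, pg_ts_all = [], [], []
    per_run = []
    freq: dict = {}
    for run in range(runs):
        rng = np.random.default_rng(fold_seeds[run])
        folds = stratified_folds(fam_codes, k, rng)
        run_es, run_ts = [], []
        for fold in folds:
            es_idx = np.setdiff1d(np.arange(geno.n_lines), fold)
            geno_es = geno.subset(es_idx)
            geno_ts = geno.subset(fold)
            y_es = pd.Series(yv[es_idx], index=geno_es.line_ids)
            qtls, pg_es, _ = _pipeline(y_es, geno_es, h2, cfg_cv, seed=rng)
            n_qtl_es.append(len(qtls))
            for rec in qtls:
                key = (rec.chromosome, round(rec.position, 6))
                freq[key] = freq.get(key, 0) + 1
            if not qtls:
                pg_ts = 0.0
            else:
                pred, _ = predict_qtl_values(qtls, y_es, geno_es, geno_ts)
                fam_ts = geno_ts.family_indicator()
                obs = yv[fold]
                # centre both within test-set families: the comparison is
                # about QTL-driven deviations, family means are nuisance
                obs_c = obs - fam_ts @ (fam_ts.T @ obs / fam_ts.sum(axis=0))
                pred_c = pred - fam_ts @ (fam_ts.T @ pred / fam_ts.sum(axis=0))
                n_ts = len(fold)
                if np.var(pred_c) < 1e-12 or np.var(obs_c) < 1e-12:
                    pg_ts = 0.0
                else:
                    r = float(np.corrcoef(pred_c, obs_c)[0, 1])
                    r2_adj = 1.0 - (1.0 - r * r) * (n_ts - 1) / (n_ts - 2)
                    pg_ts = 100.0 * r2_adj / h2
            pg_es_all.append(pg_es)
            pg_ts_all.append(pg_ts)
            run_es.append(pg_es)
            run_ts.append(pg_ts)
        per_run.append((run, float(np.mean(run_es)), float(np.mean(run_ts))))
    pg_es_mean = float(np.mean(pg_es_all))
    pg_ts_mean = float(np.mean(pg_ts_all))
    rel = relative_bias(pg_es_mean, pg_ts_mean) if pg_es_mean > 0 else np.nan
    freq_df = pd.DataFrame(
        [(c, p, v) for (c, p), v in sorted(freq.items())],
        columns=["chromosome", "position_cM", "count"],
    )
    return CVResult(
        n_runs=runs, k=k, qtl_ds=len(qtls_ds), pg_ds=pg_ds,
        qtl_es=float(np.mean(n_qtl_es)), pg_es=pg_es_mean, pg_ts=pg_ts_mean,
        relative_bias=rel, frequency=freq_df,
        per_run=pd.DataFrame(per_run, columns=["run", "pg_es", "pg_ts"]),
    )
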