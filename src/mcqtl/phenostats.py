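"""Adjusted line means, variance components and heritability.

The trial stage condenses plot-level data into one adjusted mean (BLUE) per
line, then estimates genotypic, genotype-by-location and plot-error
variances by expected-mean-squares ANOVA on the line x location table of
cell means, and heritability on an entry-mean basis as

    h2 = var_g / (var_g + var_gxl / L + var_e / (L * rbar))

with L locations and rbar the harmonic-mean number of replicates per cell.
With a single location the same expression (without the GxL term) is the
repeatability.  This fixed-effects two-stage route replaces a mixed-model
fit; on balanced designs the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LineValues:
    """Per-line adjusted means for one trait (the mapping response Y)."""

    values: pd.Series  # index line_id -> adjusted mean
    trait: str = "trait"
    n_locations: int = 1

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate line_id in LineValues")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("LineValues must be finite")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    def reindex(self, line_ids) -> np.ndarray:
        return self.values.loc[list(line_ids)].to_numpy(float)


@dataclass
class VarianceComponents:
    var_g: float
    var_e: float
    var_gxl: float | None  # None when only one location (confounded)
    h2: float
    n_locations: int
    effective_reps: float

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


def _location_adjusted_means(sub: pd.DataFrame) -> pd.Series:
    """Within one location fit y = line + replicate by least squares (line
    effects absorbed) and return adjusted line means at the average
    replicate mix."""
    if len(sub) < 2:
        raise ValueError("a location needs at least 2 plots")
    y = sub["value"].to_numpy(float)
    lines = sub["line_id"].to_numpy()
    if "replicate" in sub.columns and sub["replicate"].nunique() > 1:
        Z = pd.get_dummies(sub["replicate"].astype(str), drop_first=True).to_numpy(float)
        df = pd.DataFrame(Z, index=lines)
        Zc = Z - df.groupby(level=0).transform("mean").to_numpy()
        yc = y - pd.Series(y, index=lines).groupby(level=0).transform("mean").to_numpy()
        tau, *_ = np.linalg.lstsq(Zc, yc, rcond=None)
        rep_part = Z @ tau
        adj = pd.Series(y - rep_part + rep_part.mean(), index=lines)
    else:
        adj = pd.Series(y, index=lines)
    return adj.groupby(level=0).mean()


def compute_line_means(trial: pd.DataFrame, trait="trait", checks=()) -> LineValues:
    """Two-stage fixed-effects adjustment of a plot table.

    Per location, additive line + replicate effects are fitted by least
    squares; the location-adjusted line estimates are then averaged across
    the locations in which each line was observed.  Check entries (repeated
    standards) take part in the adjustment but are dropped from the output.
    """
    if trial.empty:
        raise ValueError("empty trial table")
    df = trial.copy()
    if "location" not in df.columns:
        df["location"] = "LOC1"
    per_loc = []
    for _, sub in df.groupby("location", sort=False):
        per_loc.append(_location_adjusted_means(sub))
    means = pd.concat(per_loc, axis=1).mean(axis=1)
    if checks:
        means = means.drop(index=[c for c in checks if c in means.index])
    means.index.name = "line_id"
    return LineValues(values=means.sort_index(), trait=trait,
                      n_locations=df["location"].nunique())


def estimate_vc(trial: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components from the line x location ANOVA.

    Cell means m_il are analysed by a two-way ANOVA; the pooled within-cell
    variance estimates var_e; negative solutions are truncated to zero.
    Requires >= 2 locations for var_gxl (otherwise it is reported as
    unavailable and absorbed into the line x location residual).
    """
    df = trial.copy()
    if "location" not in df.columns:
        df["location"] = "LOC1"
    if df["line_id"].nunique() < 2:
        raise ValueError("need at least 2 lines")
    cells = df.groupby(["line_id", "location"])["value"].agg(["mean", "count", "var"])
    L = df["location"].nunique()
    # plot error from replicated cells
    dfree = (cells["count"] - 1).sum()
    var_e = float((cells["var"] * (cells["count"] - 1)).sum() / dfree) if dfree > 0 else 0.0
    rbar = float(stats.hmean(cells["count"]))
    wide = cells["mean"].unstack("location")
    line_means = wide.mean(axis=1)
    grand = float(line_means.mean())
    N = len(line_means)
    ms_g = L * float(((line_means - grand) ** 2).sum()) / (N - 1)
    if L >= 2:
        loc_means = wide.mean(axis=0)
        resid = wide.sub(line_means, axis=0).sub(loc_means, axis=1) + grand
        ms_gxl = float((resid**2).to_numpy().sum()) / ((N - 1) * (L - 1))
        var_gxl = max(0.0, ms_gxl - var_e / rbar)
        var_g = max(0.0, (ms_g - ms_gxl) / L)
        denom = var_g + var_gxl / L + var_e / (L * rbar)
    else:
        var_gxl = None
        var_g = max(0.0, ms_g - var_e / rbar)
        denom = var_g + var_e / rbar
    h2 = var_g / denom if denom > 0 else 0.0
    return VarianceComponents(
        var_g=var_g, var_e=var_e, var_gxl=var_gxl, h2=min(1.0, h2),
        n_locations=L, effective_reps=rbar,
    )


def pheno_correlation(a: LineValues, b: LineValues):
    """Product-moment correlation between two traits over common lines,
    with a two-sided significance test.  Returns (r, p_value)."""
    common = a.values.index.intersection(b.values.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common lines")
    x = a.values.loc[common].to_numpy(float)
    y = b.values.loc[common].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a trait")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_line_values(lv: LineValues, path) -> None:
    df = lv.values.rename("value").reset_index()
    df.to_csv(path, index=False, na_rep="NA")


def read_line_values(path, trait="trait", n_locations=1) -> LineValues:
    df = pd.read_csv(path, na_values=["NA"], dtype={"line_id": str})
    return LineValues(values=df.set_index("line_id")["value"], trait=trait,
                      n_locations=n_locations)
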