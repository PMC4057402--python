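"""Phenotypic stage: adjusted line means, variance components, correlation.

Condenses the plot tables into per-line adjusted means (BLUEs), estimates
genotypic / GxL / error variances and entry-mean heritability by
expected-mean-squares ANOVA, and reports the correlation between the two
traits.
"""

import pathlib

import pandas as pd

from mcqtl import io as mio
from mcqtl.phenostats import (
    compute_line_means,
    estimate_vc,
    pheno_correlation,
    write_line_values,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "tables"
TRAITS = {"winter_hardiness": 2, "frost_tolerance": 1}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    blues = {}
    rows = []
    for trait in TRAITS:
        trial = mio.read_phenotypes(DATA / f"pheno_{trait}.csv")
        lv = compute_line_means(trial, trait=trait)
        write_line_values(lv, OUT / f"blues_{trait}.csv")
        blues[trait] = lv
        vc = estimate_vc(trial)
        rows.append({
            "trait": trait, "var_g": vc.var_g, "var_gxl": vc.var_gxl,
            "var_e": vc.var_e, "h2": vc.h2, "n_locations": vc.n_locations,
            "effective_reps": vc.effective_reps,
        })
        gxl = "n.a." if vc.var_gxl is None else f"{vc.var_gxl:.2f}"
        print(f"{trait}: var_g={vc.var_g:.2f} var_gxl={gxl} "
              f"var_e={vc.var_e:.2f} h2={vc.h2:.2f}")
    pd.DataFrame(rows).to_csv(OUT / "variance_components.csv", index=False)
    r, p = pheno_correlation(*blues.values())
    print(f"trait correlation r={r:.2f} (p={p:.2g})")
    (OUT / "correlation.txt").write_text(f"r={r:.4f}\np={p:.3g}\n")


if __name__ == "__main__":
    main()
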