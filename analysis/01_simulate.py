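"""Simulate the study population and trials.

Generates one realisation of the full-scale preset: 647 DH lines in four
families (131/120/200/196) from six parents on a 21-chromosome A/B/R map,
two correlated trait architectures (three major + six minor QTL plus
polygenic background), a two-location partially replicated trial for the
winter-survival score and a one-location trial for the frost-damage score.
Writes the CSV inputs consumed by the downstream steps plus the QTL truth
table.
"""

import pathlib

from mcqtl import io as mio
from mcqtl.simpop import simulate_preset

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    data = simulate_preset("triticale647", seed=SEED)
    mio.write_genetic_map(data.gmap, OUT / "map.csv")
    mio.write_genotypes(data.geno, OUT / "geno.csv")
    mio.write_families(data.geno.family, OUT / "families.csv")
    mio.write_phenotypes(data.trial_a, OUT / "pheno_winter_hardiness.csv")
    mio.write_phenotypes(data.trial_b, OUT / "pheno_frost_tolerance.csv")
    data.truth.to_csv(OUT / "truth.csv", index=False)
    n_major = (data.truth["pg_true"] > 10).sum()
    print(f"simulated {data.geno.n_lines} DH lines, "
          f"{data.gmap.n_markers} markers on "
          f"{len(data.gmap.chromosome_names)} chromosomes (seed {SEED})")
    print(f"{len(data.truth)} QTL of which {n_major} major (pG > 10 %); "
          f"plots: {len(data.trial_a)} + {len(data.trial_b)}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
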