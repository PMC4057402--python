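"""Cross-trait reporting: overlaps, major QTL, per-genome summaries.

Applies the reporting conventions to the two QTL tables: QTL of the two
traits overlap when their support intervals come within 10 cM on the same
chromosome; a QTL is major when it explains more than 10 % of the
genotypic variance; per-genome totals sum single-QTL pG over the A, B and
R subgenomes.
"""

import pathlib

import pandas as pd

from mcqtl import io as mio
from mcqtl.report import classify_major, find_overlaps, genome_summary, overlap_frame

ROOT = pathlib.Path(__file__).resolve().parents[1]
TABLES = ROOT / "results" / "tables"
OUT = ROOT / "results" / "report"
TRAITS = ("winter_hardiness", "frost_tolerance")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    qtls = {t: mio.read_qtl_table(TABLES / f"qtl_{t}.csv") for t in TRAITS}
    comp = find_overlaps(qtls[TRAITS[0]], qtls[TRAITS[1]], window=10.0,
                         trait_a=TRAITS[0], trait_b=TRAITS[1])
    overlap_frame(comp).to_csv(OUT / "overlap.csv", index=False)
    print(f"{comp.n_overlap} QTL overlap between the traits "
          f"({', '.join(c for c, _, _ in comp.pairs)})")
    majors = []
    for t in TRAITS:
        for q in classify_major(qtls[t]):
            majors.append((t, q.chromosome, q.position, q.pg_overall))
        print(f"{t}: {sum(1 for q in classify_major(qtls[t]))} major QTL")
    pd.DataFrame(majors, columns=["trait", "chromosome", "position_cM", "pg"]) \
        .to_csv(OUT / "major.csv", index=False)
    gs = pd.concat({t: genome_summary(qtls[t]) for t in TRAITS},
                   names=["trait"])
    gs.to_csv(OUT / "genome_summary.csv")
    print(gs[["pg"]].round(1).to_string())


if __name__ == "__main__":
    main()
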