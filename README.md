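# mcqtl — multiple-line cross QTL mapping for multi-family DH populations

Winter-sown cereals such as hexaploid triticale (genomes A, B and R) must
survive frost, and breeders map the QTL behind winter hardiness and frost
tolerance in large populations of doubled-haploid (DH) lines derived from
several connected biparental families.  `mcqtl` is a tested pipeline for
exactly this setting: a joint genome scan across families on a shared
consensus map, permutation-based genome-wide thresholds, support
intervals, proportion-of-genotypic-variance (pG) estimation,
cross-validation of pG, a two-dimensional epistasis scan, and the
reporting conventions (major-QTL calls, cross-trait overlap, per-genome
summaries).  Because such field data are rarely public, the package ships
a first-class synthetic-data generator that reproduces the statistical
structure of a 647-line, four-family DH study, so every stage runs and is
validated end to end.

## The model

With N lines from P families, adjusted line means `Y` are modelled at each
genome position as

    Y = J·M + X_q·B_q + X_c·B_c + ε

where `J` (N×P) maps lines to families with means `M`; `X_q` holds the
expected number (0–2) of the family's reference-parent allele at the
tested position, computed from the flanking markers under the Haldane map
function; `B_q` are family-specific allele-substitution effects; and `X_c`
are cofactor blocks at markers chosen by forward-BIC selection (excluded
within 10 cM of the tested interval).  Each position is scored as
`LOD = (n/2)·log10(RSS_null/RSS_full)`; genome-wide significance comes
from within-family permutations (α = 0.10), support intervals from a
1.0-LOD fall-off, and `pG = 100·R²_adj/h²` from the simultaneous multi-QTL
fit.  The epistasis scan extends the model with a second locus and a
family-specific product interaction term, Bonferroni-corrected over
chromosome-region pairs.  See `docs/methods.md` for the full account.

## Worked example

```python
import mcqtl
from mcqtl import RunConfig
from mcqtl.phenostats import compute_line_means, estimate_vc
from mcqtl.scan import (select_cofactors, permutation_threshold,
                        genome_scan, identify_qtl, estimate_pg)

data = mcqtl.simulate_preset("triticale_mini", seed=7)   # 200 DH lines, 6 chromosomes
y = compute_line_means(data.trial_a, trait="winter_hardiness")
vc = estimate_vc(data.trial_a)
print(f"h2 = {vc.h2:.2f}, var_g = {vc.var_g:.2f}")

cfg = RunConfig(n_permutations=200)
cofactors = select_cofactors(y, data.geno, cfg)
threshold = permutation_threshold(y, data.geno, cofactors, cfg, seed=7)
scan = genome_scan(y, data.geno, cofactors, cfg)
qtls = identify_qtl(scan, threshold)
pg = estimate_pg(qtls, y, data.geno, vc.h2)
print(f"LOD threshold {threshold:.2f}; {len(qtls)} QTL; total pG {pg['pg_total']:.1f} %")
for q in qtls:
    print(f"  {q.chromosome} {q.position:5.1f} cM [{q.ci_lo:.1f}-{q.ci_hi:.1f}]"
          f" LOD {q.lod:5.1f}  pG {q.pg_overall:4.1f} %")
```

prints

```
h2 = 0.82, var_g = 2.81
LOD threshold 3.84; 4 QTL; total pG 51.1 %
  2A  50.5 cM [39.3-59.0] LOD   5.8  pG  7.5 %
  1B  70.0 cM [61.0-79.0] LOD   9.1  pG 13.8 %
  1R  85.5 cM [82.0-93.4] LOD   4.2  pG  5.2 %
  2R  58.4 cM [55.0-63.0] LOD  11.5  pG 20.9 %
```

The reduced preset plants three major QTL (on 2A — segregating in one
family only, 1B, and 2R) plus six minor ones; at this sample size (200
lines) the scan recovers the majors — the 2R-analogue at 58.4 cM against a
true position of 58.9 cM with pG 20.9 % against a realised truth of
~24 % — while most minor QTL stay below the threshold, the expected
behaviour for 2–3 % effects.  `data.truth` holds the generating positions
and effects for comparison.

## The analysis pipeline

`analysis/` contains numbered drivers that run the whole study at full
scale (647 lines, 21 chromosomes, 840 markers, two correlated traits) and
write their tables under `results/`:

```
python analysis/01_simulate.py      # population, trials, truth table
python analysis/02_phenotypes.py    # BLUEs, variance components, h², trait correlation
python analysis/03_scan.py          # thresholds, LOD profiles, QTL tables (both traits)
python analysis/04_crossval.py      # fivefold CV: pG-ES vs pG-TS, relative bias
python analysis/05_epistasis.py     # pairwise interaction scan
python analysis/06_report.py        # overlaps, major QTL, per-genome pG sums
```

On the default seed the full-scale scan detects all nine planted QTL per
trait with LOD thresholds near 4.6–4.8 and a total pG around 62 %, and the
trait correlation lands at 0.88.  A `mcqtl` console script exposes the
same steps (`mcqtl simulate|pheno|scan|cv|epistasis|report`) for running
on external CSV inputs.

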