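# Methods

`mcqtl` implements joint QTL linkage mapping for several connected
biparental doubled-haploid (DH) families sharing one consensus map, in the
style used for multi-family plant-breeding populations, together with the
synthetic-data generator that the test suite and the analysis scripts run
against.

## The mapping model

At a genome position the phenotype vector of adjusted line means is
modelled as

    Y = J M + X_q B_q + X_c B_c + e

* `J` (N x P) assigns each of the N lines to one of P families, `M` are
  family means — always in the model, never counted as QTL signal.
* `X_q` (N x P) holds, in the column of the line's family, the expected
  number (0–2) of the family's reference-parent allele at the tested
  position; `B_q` are family-specific allele-substitution effects.  A
  family in which the position does not segregate contributes no column
  (rather than a zero column), keeping the design full rank.
* `X_c` are cofactor blocks of the same construction at selected markers,
  absorbing QTL elsewhere in the genome.

Null (without `X_q`) and full models are fitted by least squares (SVD,
rank-revealing), and evidence is expressed as
`LOD = (n/2) * log10(RSS_null / RSS_full)`, clipped at zero.  The scan grid
is every `scan_step` cM (default 1) plus every marker position.  Cofactors
whose marker lies within `cofactor_window` cM (default 10) of the marker
interval containing the tested position are dropped from **both** models at
that position.

### Expected allele counts

A DH line is a doubled single gamete, so the locus state along a
chromosome is a two-state Markov chain with transition probability given
by the Haldane map function `r(d) = (1 - exp(-2d/100))/2` (no crossover
interference).  Conditioning on the two flanking markers gives closed
forms such as `2(1-r1)(1-r2)/(1-rT)` for concordant flanks, with
`rT = r1 + r2 - 2 r1 r2`; these are verified in the tests against
brute-force enumeration of the hidden-state chain to 1e-12.

Flank selection uses, per line, the nearest marker on each side that is
**informative**: present *and* segregating within that line's family.  A
marker whose parents carry the same allele is always "2" regardless of
which gamete was inherited and carries no linkage information; treating it
as informative biases counts toward 2 and measurably degrades localization
and power.  With one informative side the single-marker conditional
applies; with none, the population expectation 1 (DH segregation is 1:1).

### Cofactors, thresholds, QTL calls, pG

* **Cofactor selection** is forward selection over all markers, each
  entering as a family-specific block on top of the family means, with the
  Schwarz criterion (BIC) as entry rule; ties break toward the lower
  (chromosome, position).  BIC is deliberately conservative at N ≈ 650.
* **Genome-wide threshold**: phenotypes are permuted *within family*
  (the family-mean term is part of the null), the maximum LOD of each
  permuted scan is recorded, and the threshold is the empirical (1 - α)
  quantile (α = 0.10, 2000 permutations by default; the studies below use
  200 for tractability — the error-rate property is scale-free).
* **QTL identification**: local maxima above the threshold; the support
  interval extends outward to the first grid positions where the LOD has
  dropped by 1.0 (chromosome ends truncate); peaks with overlapping
  support intervals merge, keeping the higher peak.
* **pG** (proportion of genotypic variance): the simultaneous multi-QTL
  model (family means + all QTL blocks) is fitted once;
  `pG = 100 * R²_adj / h²` where `R²_adj` is the adjusted R² of the QTL
  terms beyond the family means.  Per-QTL pG is the drop-one decrement of
  `R²_adj` in the same joint fit; per-family pG repeats the computation in
  each family's sub-sample, using the population h² as proxy (flagged
  choice — family-specific heritabilities are not estimable here).  pG is
  floored at 0.

### Cross-validation

Fivefold, family-stratified (fold sizes per family within one line of
proportionality).  Everything data-dependent — cofactors, threshold, QTL
calls, effect estimates — is redone on each estimation set.  Test-set pG
is the shrinkage-adjusted squared correlation
`1 - (1 - r²)(n-1)/(n-2)` between predicted QTL genetic values and
family-mean-centred observations (both centred within test-set families),
divided by h²; it is deliberately *not* floored, so a null trait centres
at zero.  `relative bias = 100 (pG_ES - pG_TS) / pG_ES`.

### Epistasis scan

All marker pairs at least 20 cM apart (or on different chromosomes) are
tested by extending the model with the second locus and an interaction
block whose family-p column is the product of the two within-family
mean-centred counts (centring keeps the interaction orthogonal to the main
effects in balanced DH families).  The interaction term is tested with an
F test (exact under normality) against the main-effects model.  The
per-test α divides the experiment-wise α (0.05) by the number of
independent region pairs `C(R, 2)`, `R = chromosomes × 2` regions.
Overlapping significant pairs collapse to the smallest-p pair per region
pair.  Interaction pG is `100 ΔR²_adj / h²`.  Cofactors may be supplied
(they then obey the same 10 cM exclusion rule around either locus) but are
off by default.

Note the correction's working assumption: two effectively independent
regions per chromosome.  On long chromosomes with many weakly linked
markers the true number of independent pairs is much larger and the
familywise error exceeds α; the specificity study therefore runs on a
genome of 21 chromosomes with one marker per region, where the correction
is exactly calibrated.

## Phenotypic stage

Plot values are condensed to adjusted line means (BLUE-style) by two-stage
fixed-effects least squares: per location, line + replicate effects (lines
absorbed analytically, replicate effects centred at the observed replicate
mix), then averaging across locations.  This replaces a spatial mixed
model, whose layout information does not exist for synthetic data; on
balanced designs the two coincide.

Variance components come from expected mean squares on the line × location
cell-mean table: the pooled within-cell variance estimates the plot error
σ²e; with L ≥ 2 locations, `var_gxl = MS_GxL - σ²e/r̄` and
`var_g = (MS_G - MS_GxL)/L`, negative solutions truncated to zero, with
r̄ the harmonic-mean number of replicates per cell.  Entry-mean
heritability is `h² = var_g / (var_g + var_gxl/L + var_e/(L r̄))`; with one
location the same expression (GxL term absent, confounded) is the
repeatability.  These moment estimators are unbiased on balanced designs
(property-tested) and adequate for the near-balanced p-rep layouts the
generator produces.

## The synthetic-data generator

The generator emulates the study conditions end to end:

* **Population**: 647 DH lines in four families of 131/120/200/196 from
  six parents (two half-sib pairs), on a 21-chromosome map (7 per A/B/R
  subgenome, ~120 cM, 40 markers each, uniform-random positions).  Parents
  are random biallelic haplotypes, so roughly half the markers segregate
  in any family.  Meiosis is the Haldane Markov chain; a DH line is one
  doubled gamete.
* **Trait architecture**: three major QTL emulating the observed pattern —
  a 5A-analogue segregating only in family EAW74 (target pG 14 %), a
  1B-analogue in all families (12.5 %), a 5R-analogue absent from EAW74
  (24 %) — plus six minor QTL (~2.5 % each) and a polygenic background.
  QTL are simulated as *hidden* (non-marker) loci in the meiosis chain.
  Effects are sized from the sampling weights of the segregating families;
  the polygenic standard deviation is auto-calibrated per realisation so
  the genotypic variance hits its target exactly.  Genetic values are
  expressed as within-family deviations (family-mean differences are
  nuisance intercepts of the model, and removing them keeps the realised
  variance equal to the target).
* **Trials**: plot value = mean + location effect + genetic value + GxL
  draw + plot error, with ~45 % of lines duplicated per location (p-rep).
  The two-location trait uses σ²G = 3.00, σ²GxL = 0.33, σ²e = 0.81 (target
  h² ≈ 0.87); the one-location trait 2.36 / 0.34 (repeatability ≈ 0.91).
  Scores are not clamped to the 1–9 scale.
* **Paired traits**: the second trait shares all nine QTL with
  proportionally scaled effects and a polygenic correlation of 0.97, which
  places the adjusted-mean correlation at the 0.88 target.  A
  six-of-nine-shared architecture cannot reach 0.88 here — with two thirds
  of the genetic variance in QTL, the correlation would cap near 0.75 —
  so full sharing was chosen; the six-overlap reporting rule is exercised
  on the published summary table instead.
* **Reduced preset** (`triticale_mini`): same architecture and variance
  structure with 4 × 50 lines and six 100 cM chromosomes, for fast tests.

What the generator does **not** emulate: segregation distortion, dominance
(DH lines have none), genotyping error, spatial field trends, or the real
trial's incomplete-block layout.  Passing tests therefore certify the
statistical machinery under the model's own assumptions, not robustness to
those artefacts.

## Operating-characteristic studies (`mcqtl.studies`)

Scaled to minutes on one core; the scale choices are part of the study
designs:

* **Type I error**: 100 null populations (4 × 50 lines, 5 chromosomes,
  20 markers each), 200-permutation thresholds at α = 0.10; the fraction
  of null scans exceeding their own threshold is compared to α plus two
  binomial standard errors.
* **Localization / pG recovery**: 50 replicates of the full 647-line
  family structure on a 5-chromosome map with one evenly spaced marker per
  ~1.3 cM (the real consensus map is about 1 marker/cM) and a hidden QTL
  of pG 25 % at 52.7 cM; measured: peak within 5 cM, estimated pG within
  [15, 35].
* **Epistasis sensitivity/specificity**: 21 chromosomes × 2 markers
  (40 cM apart); a pure product-interaction trait (one third of its
  genetic variance in the pure interaction term) must be recovered with
  pG within a factor of two; purely additive traits must yield no calls.
* **CV direction**: 10 five-fold runs on the reduced preset (h² 0.87,
  nine QTL); estimation-set pG must exceed test-set pG in ≥ 80 % of runs.

## Numerical choices and edge cases

* Least squares via `numpy.linalg.lstsq` (SVD); design columns with
  within-family variance below 1e-12 are dropped.
* LOD at a position where no family segregates is defined as 0; a
  zero-variance phenotype scans flat at 0.
* Permutation quantiles use the "higher" interpolation (conservative);
  the threshold is scale-equivariant and deterministic given the seed.
* All randomness flows from `numpy.random.SeedSequence` spawns of a single
  seed.
* The file dialect is comma-separated UTF-8 with header row and `NA` for
  missing; positions are decimal cM, 0-based per chromosome; genomes are
  parsed from the trailing letter of the chromosome name (5A, 1B, 5R).
* Cross-trait overlap defaults to the support-interval gap rule
  (gap ≤ 10 cM); the peak-distance rule is available as `rule="point"`.
  On the published tables the interval rule reproduces the printed count
  of six overlaps, the point rule five.

## Known limitations

* Flanking-marker conditioning only (no full multipoint hidden-state
  smoothing); with dense maps the difference is negligible.
* The fixed 10 cM cofactor-exclusion window produces the usual composite
  interval mapping artefacts (profile steps at window boundaries) on
  sparse maps.
* Per-family pG uses the population h²; per-family heritabilities are not
  estimable from the available structure.
* The region-pair Bonferroni of the epistasis scan controls the familywise
  error only insofar as the two-regions-per-chromosome assumption holds
  for the map at hand.
* Peaks are reported at scan-grid resolution (default 1 cM).
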