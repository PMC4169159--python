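# Methods

## Screening model

The screening statistic is the per-well normalized biofilm score
s = ln(OD595/OD600): crystal-violet stain absorbance over total-biomass
absorbance, log-transformed. The log-ratio makes the score invariant to a
common scale on both ODs (plate-reader gain) and puts the parental
reference distribution close to Gaussian, which is the modelling
assumption everything downstream rests on.

Per strain and timepoint the median of the replicate scores is the unit of
analysis. Wells with biomass OD600 strictly below 0.01 are excluded before
aggregation (literally "less than 0.01": a well at exactly 0.010 is
retained). A strain × timepoint with fewer than `min_valid_replicates = 2`
valid wells reports no median and is EXCLUDED at that timepoint; one
surviving well of three is not a meaningful median. Zero or negative OD
values raise rather than clamp — they indicate instrument or parsing
faults.

The null model is empirical: mean μ and sample standard deviation σ
(n − 1 denominator, the standard choice for an empirical reference
sample) of the parental wells' *individual* scores at one timepoint —
medians are never fed to the fit. Cutoffs are μ ± kσ with k = 2, i.e.
two-sided P < 0.05 under normality. Skewness and excess kurtosis of the
reference sample are carried as diagnostics of the Gaussian assumption.
By default a separate null is fitted per timepoint; `shared_null` pools
all parental wells into a single model for designs that used one cutoff
pair throughout. Classification is strict: a median exactly at a cutoff
is NORMAL.

A final hit requires the same direction (LESS or MORE) at every required
timepoint (default 46 h and 96 h). EXCLUDED at any required timepoint
makes the final call EXCLUDED, not NONE, so data-quality failures remain
distinguishable from true negatives. No multiple-testing correction is
applied across the strain set — stringency is controlled by the ±2σ band
and the dual-timepoint intersection, which is the screen's own logic;
users needing FDR control should treat the calls as a ranked candidate
list.

Because cutoffs apply to medians of replicates while σ is a single-well
standard deviation, the realized per-timepoint false-call rate is well
below the nominal 2Φ(−2) ≈ 4.6% — the median of three Gaussians has
standard deviation ≈ 0.67σ, giving ≈ 0.3% per timepoint and a dual-
timepoint same-direction rate in the 10⁻⁵ range. The calibration tests
assert the conservative single-well bound.

## Synthetic data

The generator reproduces the study conditions: 4019 mutant strains, 288
parental wells per timepoint, triplicates at 46 h and 96 h, and a
parental score null N(1.278, 0.347²) whose parameters are the midpoint
and quarter-range of the cutoff pair (0.584, 1.972) they imply.

Per well, biomass is lognormal (log-mean −0.7, log-sd 0.5: median OD600
≈ 0.5 with a realistic 0.15–1.6 stationary-phase spread in a microtiter
format) and the score is μ + shift + N(0, σ), independent of biomass;
stain OD is then biomass × eˢᶜᵒʳᵉ. Noise is additive on the log-score
scale because that is the scale on which the null is asserted Gaussian.
Planted hits shift the mean by ±effect·σ; mutant well noise defaults to
the parental σ (no replicate-level variance for mutants is available to
emulate; `mutant_sigma` overrides). With probability `dropout_prob`
(default 0.01, roughly the failed-well rate of a real plate) a well's
biomass is redrawn uniformly in [0, 0.01), exercising the exclusion rule;
dropout stain values still follow biomass × eˢᶜᵒʳᵉ. One seeded
`numpy.random.Generator` stream per dataset makes output tables
byte-identical across reruns.

Dot blots draw a control intensity and a target intensity whose expected
ratio is fold × parental mean ratio, both with unit-mean lognormal noise
at a given CV (default 10%, n = 3). FISH counts are Binomial(n_cells,
true_fraction). Phenotype tables draw mat loss per biofilm-deficient gene
at `p_mat_given_biofilm` and nest invasion loss under mat loss at
`p_inv_given_mat`, mirroring the observed near-chain structure
(71 → 69 → 49).

What the generator does *not* emulate — and what passing tests therefore
do not establish about real plates: spatial (edge) effects, inter-plate
batch shifts, growth-curve kinetics linking biomass to timepoint,
non-Gaussian score tails, and correlated replicate failures. The
calibration results are statements about the pipeline's arithmetic and
its behaviour under the stated noise model, not about any laboratory
dataset.

## Expression, subpopulations, sets

Dot-blot replicates are normalized target/control per experiment; group
means are divided (mutant over parental) to give the fold, reported also
as log2 with parental at 0. The location test is two-sided Welch — the
test is otherwise unspecified in this assay tradition and Welch avoids an
equal-variance assumption indefensible at n = 3; a paired variant exists
for designs where mutant and parental blots share experiments. Tiers:
*** for p ≤ 0.01, ** for 0.01 < p < 0.05, * for 0.05 ≤ p < 0.1. The
boundary p = 0.05 is assigned to * so the tiers partition [0, 1]. Two
identical constant groups give p = 1 by convention.

Sessile fraction is 100·biofilm/(biofilm + planktonic) on OD — a biomass
proxy for the cell-count fraction, inheriting the assay's assumption that
OD is proportional to cells in both compartments. FISH fractions use
Wilson score intervals (well-behaved at small counts and at 0/n, unlike
Wald); two fractions are compared by Fisher's exact test.

Overlap significance is the hypergeometric upper tail P(X ≥ observed)
for two sets in a finite universe; `expected_overlap` = |a||b|/N is the
chance expectation, reported alongside the same-library identity
expectation where that argument applies (for two screens of one deletion
collection, the a-priori expectation is the smaller set itself, not
|a||b|/N — both numbers are reported, labelled). Percent overlaps are
stored at full precision and rounded to integers for display. Enrichment
runs the same test per category against a user-supplied annotation map
(no ontology download, no DAG propagation — results are
annotation-version explicit), collapses categories annotating identical
gene subsets onto the lowest-p representative, and corrects with
Bonferroni by default (matching the external term-finder tools this
replaces) or Benjamini-Hochberg. Gene identifiers are uppercased on
ingestion.

## Numerical and design choices

- Even replicate counts take the mean of the two central scores as the
  median (numpy convention).
- Exclusion threshold comparison is strict (<); cutoff comparisons are
  strict (<, >).
- The published per-mutant tables ship medians, not wells;
  `supplementary.reanalyze_median_table` applies the fixed printed
  cutoffs (0.584, 1.972) at both timepoints to such a table through the
  identical classification code. Tests drive this path with a
  deterministically constructed median table whose composition matches
  the printed per-timepoint hit counts (137/427/371 and 71/100 dual
  hits), since the original tables are not redistributable.
- Simulation sizes in the test suite and acceptance script (full 4019-
  strain screens over 10–20 seeds, 500-replicate refits and fold
  recoveries, 2000-seed interval-coverage checks) were chosen to put
  Monte-Carlo error well inside each asserted tolerance while keeping
  the default run in the tens of seconds.

## Known limitations

- The Gaussian null is assumed, not tested, at classification time; the
  skewness/kurtosis diagnostics are reported but do not gate calls.
- No plate-layout normalization (edge effects, row/column trends) — by
  design, matching the analysis this package models; screens with strong
  spatial structure need upstream correction.
- OD-based fractions conflate cell count with cell size/aggregation.
- The hypergeometric overlap test assumes exchangeable gene sampling;
  screens of the same library violate this, which is exactly why the
  identity expectation is reported next to it.
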