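# Methods

This note documents the models, numerical conventions and design choices
behind `hippocomp`, and what the synthetic-data checks do and do not show.

## Data tables and grouping

The packaged CSVs hold the study's printed summary tables: species
metadata (21 raw entries → 20 analyzed groups; the house mouse is analyzed
as wild-type, C57BL/6 and DBA, while Sprague-Dawley and Wistar rats are
pooled as the brown rat), per-group unilateral count estimates for the
five principal populations in the 13 groups counted in-house, Ki67/DCX
counts for 9 rodent groups, and convergence/divergence ratios for all 20
groups. Fixtures store plain decimal numbers (no thousands separators)
and round-trip bit-identically through the CSV writer/reader.

Seven groups (human, rhesus monkey, pig, dog, sengi, harvest mouse, brown
rat) enter the study only through literature-sourced means that are not
reprinted; their count cells are deliberately absent, and analyses that
need them fail with an explicit message unless user values are supplied.
One cell required curation: the printed cape mole-rat subicular mean is
incompatible with its own SD (it would imply a CV of 2.0 where every other
cell sits near 0.1–0.2) and with the printed CA1→SUB ratio for that group.
The fixture stores the value implied by that ratio (415,012 × 0.756 =
313,749), flagged `note=reconstructed`; it is the only cell not taken
verbatim from print.

Sex composition is stored as printed; entries recorded only as "n/a"
become `unknown`, and the harvest-mouse age ("adult") is stored as
missing.

## Per-animal scaling

Counts are log-transformed (natural log; the base cancels in the
z-scaling and a test asserts this) and z-scaled within each animal using
the n−1 SD. The n−1 convention follows the study's own worked example,
whose quoted SD of 30 for deviations (50, −30, −10, 0, −10) is the sample
value. The quoted first element "1.66" is 50/30 truncated; tests compare
at 0.01 rather than replicating truncation. A vector of equal counts has
no defined scaling and raises a dedicated zero-variance error.

## Correspondence analysis

The engine is the textbook chi-square CA (SVD of the standardized
residuals of `P = X/n`). Conventions:

- all `min(rows, cols) − 1` axes are computed; reports focus on the first
  two, as the published figures do;
- sign indeterminacy of the SVD is resolved per axis by making the column
  with the largest contribution point positive — deterministic and
  comparable across runs;
- contributions are mass × squared standard coordinate, in percent of the
  axis inertia; a rank-one (independence) table yields total inertia 0 and
  the inertia percentages are reported as zeros rather than 0/0;
- zero rows/columns and negative entries are rejected with errors naming
  the offending label or pointing to the offset shift.

Because the study ordinates z-scaled profiles, which contain negative
values while CA is defined for nonnegative tables, the default pipeline
adds a single global constant `−min(X)` (optionally plus an epsilon) so
the minimum becomes zero, and records the shift in all outputs. CA is not
shift-invariant, so the shift is part of the analysis definition; running
CA on raw counts or percent profiles is available as alternative paths.
How the original R ordination handled the negative values internally is
not documented; providing both explicit paths was chosen over guessing.

The engine was cross-checked against an independent implementation
(R `vegan::cca`) on the 20×4 ratio table; both give axis inertias
84.8106 / 13.2838 / 1.9056% and total inertia 0.1971258, frozen in the
test suite. Property tests cover the transition formula, permutation
equivariance, total-scaling invariance and the chi-square/eigenvalue
oracles.

Species-level caveat: the published inertia percentages come from
per-animal rows. On species means the first two axes of the ratio-table
ordination carry 98.1% rather than the published animal-level 93%,
because within-species scatter, which spreads inertia onto minor axes, is
absent from printed means. The per-animal raw data are not published, so
the species-level figure is the reproducible one; the synthetic cohort
analysis (below) restores animal-level rows generatively.

## Convergence/divergence ratios

Ratios are downstream/upstream (HIL/GC, CA3/GC, CA1/CA3, SUB/CA1),
verified against the magnitudes of the printed table (e.g. dog CA3→CA1 =
3.044 = CA1/CA3). When per-animal data exist, group ratios default to the
mean of per-animal ratios — the construction the printed table evidently
used, since ratios of printed group means deviate from it by up to ~9%
(mean-of-ratios ≠ ratio-of-means); on summary fixtures the ratio of means
is the only option and the mode is recorded in the output. Expansion-rate
classes use closed boundaries: r < 1 `below_one`, 1 ≤ r ≤ 2 `one_to_two`,
r > 2 `above_two`.

## Age normalization

The "negative exponential" decline of adult neurogenesis is a power law
in age (the printed extrapolation equation
`N_ref = N · e^{(ln ref − ln age)·Y}` is exactly `N · (ref/age)^Y`), so
exponent fitting is log–log OLS (via statsmodels, which also supplies the
slope standard error). Reference age defaults to 3 months. Packaged
exponents: literature curve −1.3933 (Ki67) and −1.2407 (DCX); study-refit
−1.1929 and −1.0798. The refit constants cannot be re-derived here (the
underlying per-animal ages/counts are unpublished) and are shipped as
constants. Per-animal ages are used when available; fixture-level runs
extrapolate from group mean ages and record that approximation. A
property test confirms that switching between the two exponent sets does
not reorder the groups by normalized DCX, mirroring the study's
robustness check.

## Stereology

`N̂ = ΣQ⁻ · period · (grid/frame)² · t̄_Q/h`, with the number-weighted
mean section thickness `t̄_Q = Σt_i q_i / Σq_i`. "Frame/grid" entries are
read as frame side / grid step in μm, the only reading consistent with
fractionator conventions. The CE uses the m = 0 smoothness class with the
240-denominator SURS variance,
`Var = (3(A − ΣQ) − 4B + C)/240`, `CE = sqrt(ΣQ + Var)/ΣQ`; which exact
historical variant the study used is not printed, and the 240-denominator
form is the conservative modern choice. CE²/CV² uses mean(CE²) over the
squared group CV and reports infinity (flagged) for degenerate
between-animal variance. Guard zones affect the virtual-tissue generator
(cells inside a guard zone are never counted), not the estimator.

## Synthetic data

Generators are pure functions of (parameters, seed), with the packaged
tables as default parameters — cohort sizes and age spreads from the
species table, count moments from the count table.

- **Cohorts**: per-population counts are lognormal, moment-matched to the
  printed mean/SD (positivity is required by the log transform; matching
  two moments reproduces the printed summaries at large n). Populations
  are drawn independently within an animal because the study publishes no
  within-animal covariances; real profiles are likely positively
  correlated, which would shift some inertia between axes. The acceptance
  band on the synthetic rodent ordination (±10 percentage points around
  the published 81%) absorbs this acknowledged approximation. Ages are
  lognormal around the group mean/SD; marker counts decline from the
  group's age anchor with the configured exponent and carry the group's
  observed noise CV.
- **Decline series**: `count = ref · (age/ref_age)^Y · ε` with unit-mean
  lognormal ε of chosen CV.
- **Virtual tissue**: cells uniform in a block; systematic random section
  phase, random grid offset and a sub-thickness disector give every cell
  inclusion probability `(1/period)(frame/grid)²(h/t)` exactly, making
  the fractionator estimate unbiased by construction — verified by Monte
  Carlo (mean within 2% over 1000 replicates) and compared with the
  predicted CE.

What passing synthetic tests show: the pipeline machinery (scaling →
shift → CA → reports) reproduces the study's qualitative structure —
mole-rats separate from other rodents on the leading axis; adding
neurogenesis hands the separating power to DCX, Ki67 and the hilus. What
they cannot show: exact published variance percentages (per-animal raw
data and seven literature-only group means are unavailable, and
within-animal correlations are unmodelled). In particular, the full
20-species panel with primates cannot be assembled from printed data, so
the "all species" fixture analysis covers the 13 printed groups, where the
hilus dominates axis 1 and CA3 ranks third rather than second.

## Problem sizes

Monte-Carlo checks use 150–1000 replicates of tissues with 2000–5000
cells and ~60 sections, and cohorts of tens of animals per group —
problem sizes chosen so the full suite runs in seconds while the
binomial/lognormal sampling error stays well inside the asserted
tolerances.

## Known limitations

- Printed group summaries cannot reproduce the published animal-level
  ratio table more tightly than a few percent (mean-of-ratios vs
  ratio-of-means) nor the animal-level inertia percentages exactly; those
  comparisons are tolerance- or property-based by design.
- The fixture neurogenesis table contains no mole-rat groups (the study
  drew their neurogenesis values from literature), so mole-rat exclusion
  in the neurogenesis variant is a no-op on fixtures; exclusion
  robustness is exercised on the principal-cell rodent analysis instead.
- No phylogenetic modelling, no plotting beyond tabular scatter exports,
  no alternative decline forms, and no supplementary-point projection in
  the CA.
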