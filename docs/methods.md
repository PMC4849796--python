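# Methods

## Survey data model and quality control

The unit of analysis is the *survey line*: one replicate pass of one transect,
split into consecutive bins of nominally 3 km (1–3 km accepted, since effort
interruptions shorten terminal bins).  Each bin carries a count, its length,
the usable strip width, mean depth, centroid position, and mean SST/SSS; each
line carries the survey date and the line-level atmosphere/ocean covariates.

A line enters the dispersion analysis only if it passes all of:

| rule | reason code | rationale |
|---|---|---|
| total count ≥ 1 | `no_sightings` | no dispersion information |
| total count ≥ 2 | `single_sighting` | one sighting forces Gx = 1 trivially |
| every bin in [1, 3] km (inclusive) | `short_bin` | equal-area assumption |
| every strip ≥ 100 m | `narrow_strip` | visibility-degraded counting |
| contiguous 0-based bin indices | `incomplete` | interrupted effort |

All rules are evaluated (no short-circuit) so the report lists every reason a
line fails, and the retained set is monotone in the thresholds.  Bin-index
gaps in input files are a hard validation error at parse time; the
`incomplete` code exists for lines constructed programmatically.

## Dispersion intensity: Green's index

`Gx = (S²/x̄ − 1)/(Σx − 1)` with S² the sample variance (n−1 denominator).
On integer counts it is exactly calibrated: 1 when all mass is in one bin,
0 when variance equals the mean (Poisson-like randomness), −1/(Σx−1) for
constant counts.  We compute `S²/x̄` in the algebraically equivalent form
`(nΣx² − (Σx)²)/((n−1)Σx)`, which is exact in floating point for integer
counts, so the calibration points are hit exactly rather than to 1e−16.

The index is applied to per-bin **counts** by default.  Applying it to
per-bin densities is supported (`x_kind="density"`) but changes the
calibration points because Gx is not scale-invariant; with equal bin areas
the count version is the canonical one.  Σx ≤ 1 raises a domain error: the
single-sighting and no-sighting lines must be excluded upstream, which is
precisely what the QC layer does.

## Dispersion form: Moran's I with a permutation null

`I = (n/W)·Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²` with **binary** rook
contiguity along the bin chain (wᵢⱼ = 1 iff |i−j| = 1, W = 2(n−1)).  Weights
are deliberately not row-standardized: row standardization changes I on the
worked calibration sequences (the alternating sequence would no longer reach
−1).  Bins are treated as an evenly spaced chain despite the 1–3 km length
variation; distance-decay weights are out of scope.

Significance is Monte Carlo: the counts are permuted across bins
(default 1,000 permutations), and `p = (1 + #{|I*| ≥ |I_obs|})/(1 + n_perm)`
— two-sided on |I| with the plus-one estimator, which is super-uniform under
the exchangeable null.  The permutation-null mean of I is −1/(n−1), not 0;
the null mean and SD are returned so users can see the offset, but the
conventional reading of I = 0 as "no autocorrelation" is left untouched.
Whether a one- or two-sided test was used in the original tooling is not
documented; two-sided on |I| is this package's definition and is recorded in
the result's `moran_alternative` field.  The same statistic applied to the
per-bin mean depths ("depth Moran's I") summarizes bathymetric patchiness;
it is NaN on constant-depth lines.

Permutation ties are counted with a 1e−12 absolute tolerance so a
permutation that reproduces the observed arrangement counts as a tie rather
than falling on either side through rounding.

## Covariates

Eighteen candidate variables per line: Julian day and cumulative Julian day
(days since the study's first survey), mean depth, mean latitude, line
length, mean SST and SSS, zonal and meridional wind, wind modulus
(`√(u² + v²)`), atmospheric pressure and its 24-h change (survey value minus
the value 24 h before), 6-hr and monthly upwelling indices at 36° N and
39° N, and the monthly PDO and NPGO indices.  Hydrographic bin series are
gap-filled before averaging: a single missing interior bin becomes the mean
of its two neighbors; runs of ≥ 2 missing bins and missing endpoints stay
missing and are flagged.  Density enters regressions as its natural log
(the base only rescales coefficients).  Standardization is the Z-score with
the sample SD, applied globally across all retained lines (the analysis is
fleet-wide, not per-cruise); Pearson correlations are invariant to it, so
the cross-correlation matrix may be computed on raw or Z-scored columns
interchangeably.  The correlation table renders in the conventional layout —
r above the diagonal, p below, `ns` for p > 0.10 — with pairwise-complete
rows and a minimum of 3 pairs per cell.

## Hierarchical path model

The hypothesis-driven layer arranges 16 variables in nine ordered levels
(responses Gx / Moran's I / log density at level I; SST & SSS; 6-hr
upwelling; monthly upwelling; wind modulus; wind components; Δpressure;
pressure; PDO & NPGO as the exogenous top).  Temporal, spatial and
line-length variables are excluded by construction: the hierarchy claims to
capture the system regardless of them, and the exploratory layer tests that
claim.  Only two edge types are estimated:

* within-level Pearson correlations (symmetric);
* between-level standardized partial-regression coefficients: each lower
  variable is regressed jointly on the *full* set of variables in the level
  immediately above, and each predictor contributes its partial coefficient,
  SE, and t-test p.  With a single upper variable this reduces exactly to
  the Pearson r.  Joint regression (rather than one-at-a-time
  residualization) is the standard path-analysis estimator; one-at-a-time
  fits can be had by calling `between_level_edges` with singleton upper sets.

No skip-level edges exist in the model, by design: a generating dependency
that jumps levels shows up only as attenuated adjacent coefficients — the
structural-misfit signature the hierarchy is meant to expose.  Degrees of
freedom are n − (#predictors) − 1 per regression.  A standardized upper-level
design with condition number > 30 attaches a collinearity warning to its
edges but still reports coefficients.  Significance tiers follow path-diagram
convention: `ns` (p ≥ 0.1, dashed), `marginal` (0.05 < p < 0.1), `weak`
(0.01 < p ≤ 0.05), `mid` (0.001 < p ≤ 0.01), `strong` (p ≤ 0.001), with
negative edges drawn grey in the DOT output.  This is deliberately *not* a
structural-equation model: no latent variables, covariance fitting, or fit
indices.

## Exploratory layer

Pure forward stepwise selection (no removal step): at each step every
remaining candidate is tried in the current OLS model and the one with the
smallest partial-F p (≡ t-test of the new coefficient) enters if p ≤ 0.1.
Ties break by larger |standardized coefficient|, then column order; a
candidate that makes the design rank-deficient is skipped with a warning.
The final joint model supplies the reported standardized coefficients,
final p-values, and adjusted r².  The candidate pool for the dispersion
metrics adds density and depth Moran's I to the 18 environmental variables,
because abundance and bathymetric patchiness are themselves candidate
drivers of dispersion; the pool for density is the 18 alone.

Because 18+ candidates at p ≤ 0.1 invite spurious entries (under a global
null, most datasets admit at least one), every retained coefficient is also
flagged against the Bonferroni level 0.05/m, with m defaulting to the
candidate-family size (18); the flag, not the entry test, is the guarded
claim.

The per-line ANOVA is one-way fixed-effects with r² = SS_between/SS_total,
Tukey HSD on all line pairs (lines with a single replicate drop out of the
post-hoc with a warning, not out of the ANOVA), and a Kolmogorov-Smirnov
residual-normality check against a normal with the residuals' own mean and
sample SD.  The classical KS p-value is reported even though parameters are
estimated (the Lilliefors situation), mirroring common practice; it is
conservative, and the test suite checks exactly that (null p-values not
clustering near 0) rather than uniformity.

## Synthetic data generator

The generator emulates the study design, not albatross behavior: 7 parallel
lines × 6 replicate cruises (42 lines, matching the scale of the 41 retained
in the motivating survey series), line lengths uniform on 29–45 km cut into
3-km bins (a terminal remainder bin is kept if ≥ 1 km), 200-m strips, and a
shelf→slope depth ramp from 50 m to 1,084 m with Gaussian "bank" anomalies
(summit ≈ 40 m) on lines 2–4, reproducing the small-patch depth Moran's I
signature of lines crossing shallow banks.

Count regimes span the dispersion spectrum: `single_bin` (Gx = 1 by
construction), a 1-D **Thomas process** (Poisson parents at 0.05 km⁻¹, mean
8 offspring, 3-km cluster SD — clustered counts whose patch scale is
directly visible to Moran's I), `poisson` (Gx ≈ 0), `uniform`
(Gx = −1/(Σx−1)), plus an iid negative-binomial option that is overdispersed
but spatially unstructured (high Gx, null Moran's I) for separating the two
indices.  Default fixtures redraw a line's counts until the total reaches 2,
because the package analyses only such lines; this conditioning slightly
truncates the count distribution and is irrelevant to every calibration the
fixtures serve.

Line-level covariates are drawn from a multivariate normal whose default
correlation target is the empirical 14-variable cross-correlation matrix of
the study region (positive-semidefinite as printed, smallest eigenvalue
≈ 0.044; a nearest-PSD eigenvalue-clipping repair with warning covers
user-supplied targets).  Wind modulus and Δpressure are *derived* from the
drawn components rather than drawn, so the covariate-table invariants hold
in fixtures.  Monthly upwelling is a smoothed version of the 6-hr draw
(r ≈ 0.7); PDO/NPGO are a negatively correlated cruise-level pair.  An
optional effect model links standardized covariates to log expected counts
(Poisson) for power and selection tests.  `simulate_path_system` generates
from a linear recursive system laid out on any hierarchy — including planted
skip-level dependencies — and returns the *population* standardized partial
coefficients implied by the system's covariance, so recovery tests compare
estimates against exact targets rather than against raw generating weights.

What the generator does **not** emulate: real spatial autocorrelation in
hydrography beyond line-level means, observer/platform effects, tidal or
diel structure, and any behavioral movement model.  Tests passing on these
fixtures certify the statistical machinery, not ecological conclusions.

## Problem sizes and determinism

Every stochastic procedure takes a seed or a NumPy `Generator`; the pipeline
derives all randomness from one seed and reproduces outputs byte for byte.
Calibration suites use: 500 lines × 1,000 permutations for the type-I error
of the permutation test (expected rejection ≈ 0.048 at α = 0.05, accepted in
[0.03, 0.07]); 2,000 replicates for the regime ordering of mean Gx; 200
replicates at n = 500 for path-coefficient recovery (each edge's 2-SE
coverage ≥ 90%); 100 random datasets for stepwise-vs-enumeration
equivalence.  These sizes keep the full suite under a minute on one core
while leaving comfortable Monte Carlo margins.

## Known limitations

* The stepwise entry statistic of legacy GLM tools varies; the partial-F
  p-rule with the stated tie-breaks is this package's definition.
* Green's index on unequal-area bins (via densities) loses its printed
  bounds; the package warns through documentation, not at runtime.
* The permutation test treats bins as exchangeable under the null, ignoring
  bin-length variation within the 1–3 km band.
* KS normality p-values are conservative (estimated parameters); a
  Lilliefors-corrected p is not provided.
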