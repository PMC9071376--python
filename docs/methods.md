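# Methods

This note documents the statistical model behind `graftpop`, the
assumptions of the synthetic-population generator, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Reference normalization

All analyses operate on fold-changes against the self-graft reference:
FC(g, f) = mean over graft g's biological replicates of feature f,
divided by the same mean for the reference graft. Means are taken
*before* the ratio; this is not the mean of per-replicate ratios, and
the two differ whenever replicates are unbalanced or noisy. The
reference graft's own FC row is exactly 1 (log₂FC 0) by construction.
Features whose reference mean is zero or entirely missing cannot be
normalized and are dropped with a warning rather than producing
infinities.

MDA (malondialdehyde equivalents, the lipid-peroxidation proxy) is
commonly quantified batch-wise against a reference aliquot and therefore
arrives already on the fold-change scale. The population carries a flag
for this case (`mda_is_fold_change`, default true for user data): when
set, the MDA column is passed through as the replicate mean without
re-division. The bundled generator instead emits MDA on a scale whose
reference mean is 1 and clears the flag, so the ratio path applies
uniformly and the reference-row identity is exact for every feature.

Missing values are explicit: an empty cell (wide CSV) or absent row
(long CSV) is a missing measurement, a graft missing a feature in all
replicates has no FC for it, and all downstream statistics handle
missingness pairwise-complete. Measured values must be finite and
non-negative on the raw scale.

## Derived traits

From the eight primary measurements (PH, BN, FN, FFW, PFW, FDW, PDW,
MDA) the package derives TFW = FFW + PFW, TDW = FDW + PDW, harvest index
HI = FDW/TDW, the yield-partitioning ratio FFW/TFW, mean internode
length MIL = PH/BN, and mean fruit weight MFW = FFW/FN. Division by zero
(a plant with no branches or no fruit) yields a missing value, never
infinity. The identities hold to machine precision and HI and FFW/TFW
lie in [0, 1] whenever their inputs are non-negative.

## Population CV and outlier calls

Per-feature population variability is CV = sample sd (n−1 denominator)
of the FC column divided by its mean, computed on the FC scale (a
config switch allows log₂ for comparison); CV < 0.3 labels a feature
stable. The CV is invariant to rescaling a feature's raw values, since
FC already cancels scale. At least 3 contributing grafts are required.

Outliers per feature follow the Tukey boxplot rule on the log₂FC
column: outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], with quartiles by linear
interpolation (numpy's default, the "type 7" convention). The whisker
multiplier 1.5 is the boxplot default and configurable. The *outlier
signature* scan reports every graft that is an outlier in at least 6
metabolites, with the metabolite set involved, and the intersection of
those sets across reported grafts — the candidate shared signature. The
reference graft is included in CV and outlier columns by default (its
FC row is 1); a flag excludes it.

## Dispersion about the control

Per graft and feature panel, Var(X) = (1/(n−1)) Σᵢ (log₂FCᵢ)², i.e. a
variance about the control's log₂FC of zero rather than about the
graft's own mean. The two coincide only for mean-zero profiles:
log₂FC = (1, 1, 1) has dispersion 1.5 but sample variance 0. The
statistic is quadratically homogeneous and zero iff the graft matches
the reference on the panel. Grafts are clustered in (morphological
dispersion, metabolic dispersion) space by seeded k-means (k = 3,
standardized coordinates, 10 restarts). Because k-means labels are
arbitrary, semantic labels are anchored to centroid geometry: B is the
highest-morphological-dispersion centroid, A the highest-metabolic
among the rest (phenotype buffered by metabolic adjustment), C the
remaining low/low centroid; extra centroids are "other". A rectangular
threshold mode is available when clusters should be set by hand.

## Correlation networks

Pearson correlations are computed pairwise-complete within and between
feature families on the log₂FC matrix (for graft–graft analyses, a
median-centering helper renormalizes each feature to the population
median before the log). Two-sided p-values use the exact transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom; |r| = 1 maps to
p = 0. Multiplicity is handled per family across all computed pairs,
Benjamini–Hochberg by default with Holm selectable; the adjustment used
is recorded on the result object. Pairs with fewer than 4 complete
observations are skipped; zero-variance features give missing r with a
warning. Edges require q < 0.05 *and* |r| > 0.3 with strict
inequalities; passing `r_thresh=0` gives significance-only counting,
appropriate for within-metabolome tallies of positive/negative
correlations.

## Metabolic prediction

For trait y (log₂FC) and metabolite matrix X (log₂FC, grafts × 54), the
model is the L1-penalized least squares objective
(1/2n)·Σ(yᵢ − β₀ − xᵢᵀβ)² + λ·Σ|βⱼ|, solved by coordinate descent
(scikit-learn's implementation; convergence tolerance 1e-8, exact zeros
in the solution). Predictors are z-scored internally on the *training
rows only*, and coefficients are mapped back to the original scale.
Zero-variance columns are excluded with coefficient 0. λ = 0 is solved
as ordinary least squares; λ ≥ λ_max = maxⱼ|xⱼᵀ(y − ȳ)|/n (standardized
columns) gives the exact zero vector with intercept ȳ.

The penalty grid has 100 values log-spaced from λ_max down to
λ_max·10⁻⁴ (the n > p regime); the inner 10-fold cross-validation picks
the grid member minimizing mean validation MSE ("lambda.min"
semantics), ties resolved toward the larger penalty; a one-standard-
error rule is available by config. The grid is computed once per outer
training set; each inner fold re-standardizes on its own training rows.

The outer loop partitions grafts into 10 near-equal random folds
(uniform permutation sliced, no stratification; folds smaller than 4
are merged into a neighbor), repeated for 10 random re-partitions
(partition seed = base seed + repeat index), yielding 100 fits. Each
held-out fold's *predictability* is the Pearson r between predicted and
observed values on that fold — per-fold, not pooled, which is what
makes the count exactly 100. A prediction vector with zero variance
(the fully-shrunk null model) carries no ranking information; its
predictability is defined as 0 with p = 1. Selection frequency counts
the fits in which a metabolite's coefficient is nonzero (tolerance
1e-10 against solver substitution); "frequently selected" means ≥ 95%
of fits, stated on the 100-fit scale and applied proportionally when a
reduced number of fits is configured.

The permutation null re-runs each outer prediction 100 times with the
response permuted across all grafts — a fresh permutation per draw,
reusing the prediction's fold partition — recording the held-out
predictability, for 10,000 null values at full scale. The empirical p
compares the *mean* observed predictability against the pooled
*individual* null values with the +1/(N+1) estimator, so p is never
exactly zero. Two properties of this estimator are worth knowing.
First, it is powerful: a genuine signal pushes the observed mean far
into the null's upper tail. Second, it is conservative under the null:
the mean of k fold predictabilities has roughly 1/√k the spread of a
single null draw, so null empirical p concentrates near 0.5 and the
test rejects far less often than its nominal level. The calibration
test in the acceptance suite measures exactly this: at reduced scale
the null rejection rate is near zero rather than 5%. We keep the
estimator because it is the procedure's defining comparison; users
wanting a size-calibrated test should compare the observed mean against
a null of permutation *means* (computable from the stored null
distribution by block-averaging).

Standardization statistics never see held-out rows. A deliberate-
leakage switch (`leak_standardization`) computes them on all rows
instead; it exists solely so the test suite can demonstrate that the
guard is load-bearing (a train-only model is invariant to corruption of
the held-out rows; the leaky one is not). Standardization uses only X,
so this particular leak does not bias null predictability — the guard
matters for the integrity of the protocol and for any preprocessing
that does involve the response.

## The synthetic-population generator

The generator exists so that every stage has a recovery target with
known truth. It emulates, at graft level and on the log₂FC scale:

- **Metabolites**: a block-structured multivariate normal. Within-block
  correlation ρ = 0.7, zero between blocks; per-metabolite latent sd
  0.35, corresponding to an FC-scale CV around 0.25 — the stable-
  metabolite regime that covers over half of a typical leaf GC–MS
  panel. The six osmolytes (sorbose, galactose, sucrose, fructose,
  myo-inositol, proline) form the only six-member block; the remaining
  48 metabolites form correlated pairs. This makes the osmolyte
  signature the unique direction in which six metabolites can move
  together: with larger generic blocks, ordinary tail events produce
  spurious six-metabolite outlier grafts and the signature stops being
  identifiable even in principle.
- **Origin structure**: rootstock origins sampled with the collection's
  proportions (122 SLL, 45 SP, 36 SLC, 34 Other, 17 Wild per 254
  heterografts); modest mean shifts (±0.3 log₂) of the organic-acid
  block for SP and the sugar block for Wild rootstocks.
- **Outlier grafts**: 3 grafts receive +2 log₂ on the osmolyte block.
- **Traits**: planted traits (default FFW and FDW) are y = Xβ + ε with
  5-metabolite supports of alternating sign, one per block, β rescaled
  so the planted variance fraction hits the target R² = 0.5 on the
  realized metabolite matrix, and marginal log₂FC sd 0.4. PFW and PDW
  are generated to correlate 0.8 with FFW and FDW respectively
  (vegetative and fruit biomass move together); PH, FN and MDA are
  independent with sds 0.25/0.35/0.6, and BN has mean −0.5 (nearly all
  grafts branch less than the self-graft). Ratio traits (HI, FFW/TFW,
  MIL, MFW) are derived per replicate, so they inherit signal
  indirectly rather than being planted.
- **Back-transform and replicates**: raw value = reference mean ×
  2^log₂FC (reference means: PH 120 cm, BN 15, FN 60, FFW 2000 g, PFW
  1500 g, FDW 200 g, PDW 300 g; MDA and metabolites 1.0); each graft
  gets 3–4 replicates with mean-one lognormal noise at CV 0.12. The
  reference graft's latent log₂FC is identically zero.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: heterogeneous and heavy-tailed per-metabolite
dispersions (real CVs span 0.16–0.86 within one panel), measurement
batch effects and their correction, missing-not-at-random dropout,
nonlinear metabolite–trait relations, and genetic population structure
beyond categorical origin shifts. Recovery results on this generator
are best-case calibrations of the machinery, not guarantees about any
particular field experiment.

## Numerical choices and degenerate inputs

- Quartiles: linear interpolation (type 7) throughout.
- CV needs ≥ 3 grafts, outlier calls ≥ 5 values, dispersion ≥ 2
  features, correlations ≥ 4 complete pairs; below these the result is
  missing (with a warning) or the pair is skipped, never silently 0.
- CSV floats are written at full precision and parsed with round-trip
  precision, so write→read→write is byte-stable.
- All randomness flows from a single integer seed: the generator uses
  one `numpy` Generator; outer partitions use seed + repeat index;
  inner-CV and permutation streams are derived deterministically. Equal
  seeds give byte-identical outputs end to end.
- The fallback `outer_repeats = 1` (a single 10-fold pass) is allowed
  for reduced-scale runs; all other fold/grid counts must be ≥ 2.

## Problem sizes used in the bundled checks

The acceptance surface runs at sizes chosen to exercise the full-scale
behavior while staying desk-sized: signature recovery over 50 seeds of
the 255-graft default population; FDR calibration over 100 null
datasets of 54 features × 255 grafts; predictability recovery over 20
seeds at 5×10 outer folds; permutation power over 10 seeds at 1×10
folds with 10 permutations per prediction, and null calibration over
200 experiments at n = 40, p = 10. `scripts/acceptance.py` uses the
default population with 5×10 outer folds and 10 permutations per
prediction. Full-scale settings (10×10 folds, 100 permutations) are the
library defaults and run unchanged, only longer.
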