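# Methods

`medinet` re-implements, as a tested pipeline, a food-network analysis of
Mediterranean-Diet (MeDi) questionnaire data in multiple sclerosis: ordinal
intake scores are related through categorical mutual information, "eating
hubs" are read off the degree distribution of the resulting graph, the MS
and control networks are compared against a reshuffle null, and disability
and fatigue are modelled on hubs and lifestyle factors. Because no
participant-level data are distributable, the package ships a synthetic
cohort generator that plants the statistical structure the analysis
expects; every downstream stage is exercised against it.

## Questionnaire and anthropometric scoring

Nine food items (fruit, vegetables, legumes, cereals, fish, meat and cold
cuts, milk and derivatives, olive oil, alcohol) are each scored 0 (no
intake) to 2 (more than once a week). The total (0–18) maps onto four
adequacy bands — 0–4 not adequate, 5–9 poorly adequate, 10–15 sufficiently
adequate, 16–18 completely adequate — and items split into "positive"
(fruit, vegetables, legumes, cereals, fish, olive oil; 0–12) and "negative"
(meat, dairy, alcohol; 0–6) composites. The negative composite used by the
outcome models is the plain sum of the three negative items.

IPAQ activity bands are <700 / [700, 2520) / ≥2520 MET-min/week. The
source bands leave (2519, 2520) unstated; half-open intervals make every
category rule here a partition of its domain (the same convention closes
the BMI gaps at 24.9–25.0 and 29.9–30.0). Waist-circumference risk flags
use ≥94 cm (men) / ≥80 cm (women); waist-hip-ratio flags are strict
(>0.90 / >0.85), following the wording of the underlying cut-point
definitions. Pack-years are (cigarettes/day ÷ 20) × years smoked.

## Mutual-information networks and hubs

Eleven categorical variables enter the network: age in five classes
(<20, three 10-year bands, >49), sex, and the nine items. Dependence of a
pair (X, Y) is the plug-in mutual information of their contingency table,

    I(X;Y) = Σ_ij p̂_ij ln( p̂_ij / (p̂_i· p̂_·j) )   [nats],

with empty cells contributing zero. MI is symmetric, non-negative, bounded
by min(Ĥ(X), Ĥ(Y)), and requires no linearity assumption — the reason it
is preferred over correlation for ordinal intake scores. The matrix
diagonal stores plug-in entropies. No small-sample bias correction is
applied; the estimator is the plain plug-in form (see Limitations).

The MI matrix is dense, so turning it into a graph needs an edge rule.
Default: a pair is an edge when its MI is significant under a permutation
test (one margin permuted, p = (1 + #{MI_perm ≥ MI_obs}) / (1 + n_perm),
n_perm = 1000, α = 0.05). An alternative rule (edge ⇔ MI above the mean
off-diagonal MI) is selectable; both are interpretations, since "link" is
not otherwise defined for a dense similarity matrix. The permutation
default was chosen because it is calibrated: under independence the edge
rate matches α (verified by simulation in the test suite).

Hubs are nodes whose degree strictly exceeds mean(degrees) + SD(degrees),
with the sample (n−1) SD; a regular graph therefore has no hubs. Degrees
count unweighted neighbours; the diagonal never contributes.

## Two-group comparison (reshuffle null)

The 55 upper-triangle entries of both groups' MI matrices are pooled
(110 values). Each of 1,000 replicates partitions the pool at random,
without replacement, into two 55-entry matrices and subtracts them. The
observed difference matrix is converted to per-cell Z-scores against this
null and flagged where |z| > 1.96 (two-sided normal, α = 0.05); "no
difference" is declared when no cell is flagged. Two numerical choices:

* the null is *orientation-symmetrized* — each random partition contributes
  both orientations of its difference — so the null mean vanishes
  identically and swapping the groups negates every Z-score exactly;
* pooled entries are sorted before partitioning, making the null invariant
  to argument order. Cells with zero null SD get an undefined Z and are
  never significant. A Bonferroni column (α/55) is reported for
  transparency; the default verdict uses the raw per-cell rule.

Matrix entries, not subjects, are the exchangeable units. This is faithful
to the described procedure but ignores within-matrix dependence, and its
operating characteristics depend strongly on how spread out the pooled
entries are (see Limitations).

## Outcome models

EDSS is dichotomized at the clinical gap: class 0 for EDSS ≤ 1.5, class 1
for EDSS ≥ 2 (values strictly between are impossible on the 0.5 grid and
rejected). FSS is split at the cohort median, ties to class 0. Collinearity
among hub items is screened by pairwise Spearman correlations (uncorrected
p < 0.05, deliberately conservative); any significant pair disallows a
joint multiple model and mandates per-hub bivariate logistic regressions.
Logistic models are fitted by IRLS to a 1e-8 step tolerance with explicit
perfect-separation diagnostics — no silent estimates. Hierarchical OLS
enters predictor blocks cumulatively (default: smoking pack-years + IPAQ,
then the negative-foods composite), reporting R² per block and standardized
betas (outcome and predictors z-scored) for the final model.

The sensitivity analysis returns the minimum detectable absolute logistic
slope from the two-variance Wald power equation

    β √n = z_{1−α/2} / √I₀ + z_power / √I₁(β),

with I₀ = sd² p(1−p) the slope information under independence and
I₁(β) = E[x² p(x)(1−p(x))] the information under the alternative
(Gauss–Hermite quadrature, intercept solved for the target prevalence,
fixed-point iteration in β). Assumptions: standardized normal predictor,
balanced outcome unless stated, two-sided Wald test. At n = 424, α = 0.05,
power = 0.90 this yields β = 0.3195; a 10,000-replicate Monte-Carlo check
(batched IRLS) achieves power ≈ 0.90 at that slope. The single-variance
textbook form (both terms on I₀) is available as `information="null"` and
gives 0.3148 under the same inputs.

Descriptive group comparisons use the pooled-variance two-sample t-test
(Welch behind a flag) and Pearson's chi-square without continuity
correction.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Ordinal items.** Each group's nine items are sampled through a Gaussian
copula: a latent N(0, R) vector is discretised per item into the configured
3-level marginal. Target correlations are interpreted as *Spearman* (the
statistic reported for the observed hub items), and each latent pairwise
correlation is solved by monotone bisection so the population grade
(midrank) correlation of the discretised pair matches its target to 1e-4;
bivariate-normal rectangle probabilities come from `scipy`. An unattainable
target raises with the attainable range. The assembled latent matrix is
repaired to the nearest positive-definite correlation matrix by eigenvalue
clipping if needed. Default targets plant the six reported hub-pair
correlations (fruit–vegetables 0.33, fruit–cereals 0.13, fruit–fish 0.22,
vegetables–cereals 0.19, vegetables–fish 0.21, cereals–fish 0.12); all
other pairs are independent.

**Marginals.** Intake frequencies were never published numerically, so the
packaged defaults are an explicitly synthetic, plausible profile for an
Italian adult population, with the MS group differing from controls only
where a group difference was reported: more frequent fish, less frequent
alcohol. Demographics (age 42.6 ± 11.0 vs 40.9 ± 14.5 years, truncated to
[18, 80]; 67/68% female), anthropometrics (sex-specific truncated normals
for height, BMI, waist, hip) and lifestyle (a smoker mixture for
pack-years; lognormal IPAQ with group means ≈2200 vs ≈3700 MET-min/week)
follow the published group summary statistics.

**Outcomes (MS group only).** The disability class is drawn from a logistic
model on vegetables and fish intake with default slopes −0.36 and −0.34;
the default intercept 0.91 centres the class odds at the mean diet so the
two classes are roughly balanced. Continuous EDSS is placed in the band the
class implies ([0, 1.5] around 0.75, or [2, 5.5] around 3.75), carries a
standardized lifestyle signal η = 0.190·z(pack-years) − 0.138·z(IPAQ) +
0.098·z(negative foods), and is snapped to the clinical 0.5 grid. Banding,
clipping and snapping attenuate the latent signal, so the within-band gain
applied to η (2.7) was fixed by a one-off calibration simulation such that
regressing the finished EDSS on the three lifestyle predictors explains
≈6% of its variance on average at n = 424. FSS is linear in z(pack-years)
(+0.135) and z(IPAQ) (−0.169) around mean 3.8 with SD 1.7, plus Gaussian
noise (residual SD chosen so the planted standardized betas are also the
model R² shares), clipped to [1, 7]. Controls carry no EDSS/FSS — absent,
not zero.

**Randomness.** Everything flows from one master seed through fixed
per-stage substreams (item sampling, demographics, lifestyle, outcomes,
edge permutations, reshuffles), so a configuration reproduces its table
byte-for-byte and stages can be re-run in isolation.

### What the generator does and does not emulate

It reproduces: group sizes, group-specific marginal shifts (fish/alcohol),
the six pairwise rank correlations among the four positive-food items, the
direction and approximate size of every headline outcome association, and
outcome variable supports/grids. It does **not** reproduce the full
dependence fabric of real dietary data: the 30 remaining item pairs and all
age/sex–item pairs are independent by construction, and lifestyle is
independent of the disability class. Consequences worth knowing:

* With only six planted dependencies — two of them weak (ρ = 0.12, 0.13,
  detected by any α = 0.05 independence test with power well below 1 at
  n = 424) — the exact four-item hub set is recovered only in a minority of
  seeds; what is stable (and tested) is that the four planted items carry
  more mutual information among themselves than all other item pairs.
* The reshuffle comparison's null SD is set by the spread of the pooled
  entries. Real, densely dependent matrices make that spread large and the
  test very conservative; on this sparse fixture the spread is small while
  plug-in MI at n = 165 is heavy-tailed (≈ χ²₄ / 2n under independence), so
  some cell usually exceeds |z| = 1.96 even for exchangeable groups. The
  per-cell false-positive rate stays below 0.10, but a family-wise "no
  difference" verdict across all 55 cells is not typical here, unlike with
  dense real-data matrices.

Passing tests therefore demonstrate correctness of the machinery and of
the planted-signal recovery, not that sparse-fixture behaviour matches
dense real-data behaviour.

## Problem sizes

Default analyses use the full simulated cohort (424 + 165). Property-style
checks in the test suite use 20–50 seeds for network/comparison properties,
100 replicates for parameter recovery, 200 replicates for copula
calibration, and 10,000 replicates for the sensitivity-analysis power
check; these sizes keep each estimate's Monte-Carlo error well inside the
asserted tolerance.

## Known limitations

* Plug-in MI is biased upward by ≈ (R−1)(C−1)/(2n) nats; with unequal group
  sizes the bias does not cancel between groups. The comparison inherits
  this; a bias-corrected variant was evaluated and does not change the
  family-wise behaviour (the correction shrinks the pooled spread by about
  as much as it removes from the differences), so the plain estimator is
  kept for fidelity.
* Edge rules are interpretations; degree-based hubs are sensitive to single
  edges when degrees are small.
* EDSS is treated as continuous in the hierarchical models (to express
  variance explained) and as a dichotomy elsewhere; no ordinal model is
  fitted.
* The generator is not fitted to any real dataset and models no
  longitudinal progression.
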