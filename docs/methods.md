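# Methods

`swimtraj` analyses the 25 weeks of training that precede an elite
swimmer's season-best performance. This note documents the statistical
model, the quantification conventions, the synthetic-data generator, and
the numerical choices, in enough detail to audit every number the
package produces.

## Training-load quantification

**Intensity zones.** Swim speeds are zoned against an individual
blood-lactate/speed profile fitted on an incremental 6x200 m test.
`fit_lactate_profile` interpolates log(lactate) piecewise-linearly in
speed between stages — monotone for monotone data and exact at the
observed stages — and reads off the speeds `v2`, `v4`, `v6` at 2, 4 and
6 mmol/L. Crossings outside the observed range are extrapolated from
the terminal segment and flagged; a crossing farther than twice the
terminal segment's speed range is reported as a missing threshold
rather than guessed. Zone boundaries are closed on the upper end: a
speed exactly at `v4` is I2 ("from 2 to 4 mmol/L") and one exactly at
`v6` is I3 ("above 4 up to 6"); maximal sprinting is always I5. A
parametric alternative was considered and rejected for the default: the
piecewise interpolant is assumption-light and recovers simulated
thresholds exactly at zero noise. The distance/rest-interval speed
correction applied in elite practice is exposed only as a user-supplied
speed-offset hook (default: no correction), because its published
tables are not reproducible from first principles.

**Practical categories.** I1+I2 meters form MHI (moderate-to-heavy,
lactate <= 4 mmol/L), I3 is SI (severe), I4+I5 form EI (extreme);
dryland work is GC (general conditioning) and ST (maximal strength),
in minutes/week.

**TTL.** For each season, each of the five category series is rescaled
to percent of its own season maximum, so every nonzero category reaches
exactly 100 in at least one week; the weekly Total Training Load is the
arithmetic mean of the five normalized components. TTL is therefore
scale-invariant (multiplying all raw volumes by a constant changes
nothing) and comparable across swimmers. A category absent for a whole
season is dropped from the mean (denominator = number of present
categories) and flagged; a fixed denominator of 5 is available by
option. A 7-component variant (I1..I5 + GC + ST) exists because the
category count in the TTL mean is genuinely ambiguous in the source
description; the 5-category reading (MHI/SI/EI/GC/ST) is the default
since those are the declared practical categories.

**Derived metrics.** Weekly variation = mean |TTL(t) - TTL(t+1)| over
consecutive weeks. Progressivity compares the mean TTL of weeks 25..13
before the best performance (13 weeks, chronologically earlier) with
weeks 12..1 (12 weeks); delta = second minus first, positive =
progressive loading. Relative performance Pr (%) = 100 (P - M10WP) /
M10WP, the percent gap to the year's mean of the 10 best world times
for the event (lower is better); it absorbs era effects such as the
polyurethane-suit seasons. The intensity distribution is the season
mean of (MHI, SI, EI) over mean total in-water meters, treated as
compositional data: before multivariate testing it is mapped to
isometric log-ratio coordinates with the sequential-binary-partition
basis, coordinate j = sqrt(j/(j+1)) ln(gm(x_1..x_j)/x_{j+1}). Zeros are
replaced multiplicatively first (delta = 0.65 times the smallest
observed nonzero proportion, renormalized).

## Latent-class linear mixed model

Subject i in latent class g has

    y_i | class g  ~  N( X_i beta_g ,  Z_i B_g Z_i' + sigma^2 I ),
    P(class = g)   =  pi_g  (intercept-only multinomial logit),

where X_i is a natural cubic spline basis in weeks-before-best-
performance. The basis uses the truncated-power natural-spline
construction (columns = interior knots + 2, including intercept and
linear term), interior knots at equally spaced quantiles of the
observation times, boundary knots at the extremes, and is linear beyond
the boundary. Z_i is a random intercept by default (optionally
intercept + centered linear slope); B_g is the random-effect covariance,
`diagonal` or `unstructured`, and either common across classes or
proportional (B_g = w_g^2 B with w_K = 1 for identifiability). The
membership model carries no covariates, matching the unadjusted
trajectory analysis this package reproduces.

**Estimation.** Maximum likelihood by EM treating both the class label
and the random effects as missing data. Every M-step update is closed
form (weighted OLS on partial residuals for beta_g, moment updates for
B and sigma, mean posteriors for pi), so the marginal log-likelihood is
provably non-decreasing — an invariant asserted in the test suite at
1e-10 relative tolerance. Under the proportional structure, B and the
w_g are updated by a short exact conditional-maximization alternation
(ECM), which preserves monotonicity. The best EM run is polished with
L-BFGS on the marginal likelihood in an unconstrained parameterization
(logits, beta, log-Cholesky of B, log w, log sigma), accepted only on
improvement.

**Initialization and multi-start.** Per-subject ridge least-squares
spline coefficients are clustered with K-means; class curves start at
cluster means, later starts add 20% multiplicative seeded jitter.
Default 10 starts (pipeline and large simulation studies use 3-4 as a
deliberate problem-size choice; the fits are extremely stable on
separated trajectories).

**Convergence.** Relative log-likelihood change < 1e-8 and parameter
max-abs change < 1e-5 within 500 EM iterations. When a random-effect
variance heads to its boundary the EM map contracts geometrically and
stalls short of tolerance; `fit` then tries collapsing near-zero
components to exactly zero (B = 0 is an EM fixed point), keeps the
collapse only if the likelihood does not decrease, and refines with up
to 100 further EM iterations before re-assessing convergence. Variance
floors: sigma >= 1e-4; B is kept positive semi-definite by eigenvalue
clipping (diagonal entries clipped at 0 in diagonal mode).

**Labeling.** After fitting, classes are reordered by descending mean
fitted trajectory level; the likelihood is invariant under this
relabeling. Posterior class probabilities are pi_g-weighted density
ratios; modal assignment breaks exact ties toward the lowest class
index (logged). Observed class-mean curves are posterior-weighted
averages of the raw TTL values per week.

**Model choice.** A grid over K (1..5), interior knots (1..15) and the
covariance options is searched in two stages: within each K the
AIC-minimal converged configuration is kept; across K the BIC-minimal
K-best model is selected, with BIC using the number of subjects as N
(the mixture is defined at subject level). Free parameters: (K-1)
logits + K x (basis columns) + covariance entries (q diagonal or
q(q+1)/2 unstructured) + (K-1) proportional scales + 1 residual SD.
The full search table is always returned — the final call on K
involves judgment, so the table is the deliverable, not a hard-coded
winner. Cells that coincide for a scalar random effect
(diagonal = unstructured at q=1; proportional = common at K=1) are
fitted once. Non-converged cells stay in the table flagged and are
excluded from selection.

## Synthetic cohort generator

No training logs of the original cohort are deposited, so the generator
provides cohorts with known truth. Season i in class g has latent
TTL_i(t) = mu_g(t) + b_i (+ s_i (t - t-bar)) + eps_it, clipped to
[0, 100] (clips counted), with mu_g a smooth archetype curve:

* `long` — two macrocycles, load peaks ~21 and ~5 weeks out, progressive;
* `balanced` — two balanced macrocycles, peaks ~19 and ~10 weeks out,
  degressive;
* `stable_flat` — flat around 60% TTL with a single modest peak ~8 weeks
  out.

The archetypes are natural cubic splines through hand-chosen control
points that qualitatively match the three elite-sprint periodization
profiles; they are fixtures, not measured data. Defaults (chosen once):
class proportions 0.53/0.24/0.23; random-intercept SD 6 TTL points;
residual SD 4 points (these put the simulated week-to-week TTL
variation near 6%, inside the 4-8% range reported for elite cohorts);
random slope off; per-class relative performance Pr ~ N(6.0, 3.1),
N(6.8, 3.5), N(7.4, 2.9) percent; in-water composition targets
88/8/4% MHI/SI/EI and 65/35% GC/ST dryland.

Weekly raw volumes are back-computed from the latent TTL so that
re-running the TTL normalization reproduces it exactly: each of the
five components gets one "spike" week (among the five highest-TTL
weeks) where it equals 100 while the others absorb the deficit, and
zero-sum jitter (SD 8 points, rescaled to stay in [0, 99.5]) is added
elsewhere, so each component's maximum is exactly 100 and the weekly
component mean equals the latent TTL. Component percents convert to
meters/minutes via class-specific maxima split by the composition
targets, with fixed I1:I2 and I4:I5 shares within MHI and EI.

What the generator does **not** emulate: missed weeks or dropout,
within-swimmer correlation across seasons (swimmer-seasons are
independent), class-specific residual SDs (so the generated ordering of
per-class variability is driven by curve shape, not by noise levels),
measurement error in lactate-based zone assignment upstream of the
weekly logs, and real covariate-profile associations (covariates are
drawn uniformly). Passing recovery tests therefore demonstrates that
the estimation machinery works when the model is essentially correct
and classes are separated to a realistic degree — not that real
training data are this clean.

## Group characterization

Between-profile differences use one-way ANOVA and Kruskal-Wallis, both
always computed; Shapiro-Wilk per group and Levene's test at alpha =
0.05 decide which is marked primary. First-half/second-half changes use
paired t and Wilcoxon signed-rank with explicit handling of degenerate
difference vectors (constant nonzero differences are reported as
"p below machine floor" rather than an unstable statistic). Intensity
compositions are compared by one-way MANOVA on ilr coordinates;
Pillai's trace is computed from the between/within scatter matrices
with the standard F approximation and is invariant to the ilr basis
choice (verified in tests, including against statsmodels). Covariate
cross-tabs use chi-square with a warning when any expected count is
below 5. No multiplicity correction is applied by default, matching the
exploratory framing; Benjamini-Hochberg adjustment is available.

Peak-load weeks are not defined formally in the source analysis; the
detector here smooths the weighted class-mean trajectory with a 3-point
moving average and takes local maxima with prominence >= 2 TTL points
and separation >= 3 weeks, keeping the top two by height (all
thresholds configurable).

## Problem sizes and reproducibility

Simulation studies in the tests and the acceptance script use 105
seasons x 25 weeks (the sprint-cohort scale), 10 replicates for
recovery/selection studies, a reduced search grid (K 1..4, interior
knots {2, 3, 5}, diagonal-common covariance — the structure options
coincide at q = 1 anyway), and 3 starts per fit; these are the
package's chosen study sizes and run in minutes on one CPU. All
randomness flows from a single root seed split into named per-stage
substreams (SHA-256 of "seed:stage", truncated below 2^31), so stages
re-run independently yet reproducibly; identical config + seed yields
byte-identical CSVs.

## Known limitations

* The LCMM assumes Gaussian residuals and a shared residual SD across
  classes; heavy-tailed or class-heteroscedastic data will distort
  posteriors.
* BIC-based class-count selection is asymptotic; at small n it can
  under-select, which is why the full search table is always emitted.
* TTL normalization ties each season's scale to its own maxima: a
  season whose true peak falls outside the 25-week window inflates its
  normalized loads.
* The boundary-collapse convergence step addresses variance components
  at zero, but likelihood ridges between nearly-identical classes can
  still leave EM slow; the multi-start + polish combination mitigates
  but does not eliminate this.
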