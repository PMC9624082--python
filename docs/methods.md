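# Methods

## Overview

`trichopheno` quantifies animal personality in *Trichogramma*-style arena
assays and asks whether the resulting traits are usable in genetic
improvement of biocontrol agents. The pipeline runs from raw video-tracking
trajectories (25 fps, 90-s trials of single females in a 24 x 18 cm arena
showing a 5.5-cm white disc on a dark background) to:

1. seven behavioural variables per trial (boldness, exploration, activity);
2. repeatability *R* of each variable (agreement ICC from a crossed
   random-intercept model);
3. two PCA personality scores over the repeatable variables;
4. phenotypic correlations between behavioural predictors and fitness traits;
5. broad-sense heritability *H²* from 24 isogenic lines (clonal design:
   between-line variance proxies genetic variance);
6. line comparisons with a compact letter display; and
7. genetic correlations as rank correlations of line-level predictors.

A synthetic-data generator with fully specified ground truth stands in for
the raw videos, so every stage is testable end to end offline.

## Arena geometry and behavioural variables

The arena is partitioned radially around the disc centre into four zones:
inner white disc (1), white border band (2), dark border band (3) and outer
dark field (4); the bands are 0.5 cm on each side of the printed disc edge
(radius 2.75 cm). Radial intervals are half-open with the boundary assigned
outward, so a point exactly on the printed border is already "dark": entry is
triggered on the first frame at or beyond the border. This tie rule is a
convention; the source experiment does not define one.

Variables, each computed only in its designated zone so the three trait
categories are as independent as the single assay allows:

| variable | zone | units | category |
|---|---|---|---|
| time to dark entry (censored at trial end) | first zone >= 3 | s | boldness |
| \|speed(2) - speed(1)\| | 1, 2 | cm/s | boldness |
| \|sinuosity(2) - sinuosity(1)\| | 1, 2 | cm^-1/2 | boldness |
| explored-area rate | 1 | cm²/s | exploration |
| path sinuosity | 1 | cm^-1/2 | exploration |
| activity rate (speed > 0.01 cm/s, strict) | 4 | – | activity |
| mean speed | 4 | cm/s | activity |

Sinuosity is the corrected index S = 2 [p ((1+c)/(1-c) + b²)]^(-1/2) with p
the mean step length, c the mean cosine of turning angles and b the CV of
step length, evaluated on raw (non-rediscretized) steps within each
zone-residence run of at least `min_steps = 10` steps and combined across
runs by step-count-weighted averaging of (p, c, b). Shorter runs yield a
missing value: turning statistics on a handful of steps are noise.
Explored area is occupancy of a square grid (cell 0.1 cm, anchored at the
disc centre) divided by zone-1 residence time; grid occupancy was chosen
because it is deterministic and its scale behaviour is exact. Per-step
quantities (speed, residence time) are attributed to the zone of the step's
starting point. Cleaning removes points implying speeds above 30 cm/s
(teleport artefacts), interpolates dropout gaps of at most 5 frames, and
splits the trajectory at longer gaps; no statistic crosses a split.

## Variance-component models

For each trait y we fit Gaussian crossed random-intercept models by REML:

- repeatability: y = mu + u_individual + u_session + e, with
  R = sigma²_individual / (sigma²_individual + sigma²_session + sigma²_e).
  Line and subline variance are deliberately folded into the individual
  effect, as in the source design.
- heritability: y = mu + u_line + u_subline + u_individual + u_session + e,
  with H² = sigma²_line / total. Fitness traits are measured once per
  female, so the individual effect is not separable from the residual and
  the model drops to {line, subline, session}.

All behavioural variables are modelled on the natural-log scale except the
explored-area rate; zeros receive an offset of half the smallest positive
value (recorded in the fit metadata). Censored time-to-dark trials enter at
the 90-s trial duration (higher = less bold) and in practice the variable is
used only for its repeatability test.

**Estimation.** Every supported model has `individual` (or the observation
itself) as the finest grouping, with all other factors constant within it.
The restricted likelihood therefore decomposes exactly into a
within-individual sum of squares against sigma²_e plus a low-dimensional
mixed model on the individual means whose covariance is diagonal plus a
low-rank term for the remaining factors (handled by the Woodbury identity).
One criterion evaluation is O(n_individuals); the analytic REML score is
implemented the same way. Variances are optimized by bounded L-BFGS-B
(non-negativity at the boundary, gradient tolerance 1e-8), with a restart
and a Nelder-Mead fallback guarded by a projected-gradient check. The
implementation is verified in the tests against a dense-matrix restricted
likelihood, the balanced one-way ANOVA closed form, and the BLUP shrinkage
closed form.

**Confidence intervals.** 95% CIs for R and H² use a parametric bootstrap
(default 1000 replicates, seed mandatory): simulate from the fitted model,
refit, and take bias-corrected (BC) percentile bounds. Two deliberate
choices, both made on simulation evidence at the full study size:

- *Simulation model for R.* Simulating repeatability bootstrap data from the
  two-factor fit treats females of the same isogenic line as independent and
  understates Var(R̂); measured coverage of the nominal 95% interval was
  ~80%. The pipeline therefore simulates from the four-factor model (when
  line/subline are available) while still refitting the two-factor model;
  coverage rises to ~91–95%.
- *BC rather than plain percentile.* For a group-level share with only 24
  groups the ratio estimator is skewed and plain percentile intervals sat at
  ~89% coverage over 200 replicate experiments; the median-bias-corrected
  percentile interval measured ~93%. Plain percentile remains available
  (`ci_method="percentile"`).

BLUPs (conditional means of the random effects at the REML estimates) serve
as "linear predictors": per individual for phenotypic correlations, per line
for genetic correlations. With an intercept or full cell-means fixed part in
the model they sum to zero exactly.

## Scores, correlations, line comparisons

PCA is computed on the correlation matrix of individual x day observations
(complete cases, transformed scale), so eigenvalues sum to the number of
variables. A variable enters when its repeatability CI excludes zero after
rounding the lower bound to the two decimals used in summary tables. The
stored loadings are orthonormal eigenvectors (scores = standardized row x
loadings); the variable-component correlations (eigenvector x sqrt
eigenvalue), the scale usually printed in tables, are exposed separately.
Axes are oriented so the explored-area rate loads positively on PC1
(exploration score) and mean speed positively on PC2 (activity score).
Individual-level scores are the mean of an individual's scored days — the
collapse rule is this package's choice; nothing in the source defines one.

Correlations are average-rank Spearman rho with percentile bootstrap 95% CIs
over resampled pairs (1000 bootstraps) and BH-FDR within each table family
(behaviour–behaviour, behaviour–fitness, genetic), never pooled across
families. The bootstrap p-value is the smallest level on a grid of 999
quantile levels at which the CI excludes zero. CI-based significance is the
primary flag, with adjusted p-values reported alongside. A trait whose line
variance is estimated at zero has identically zero line BLUPs; its genetic
correlations are reported as undefined rather than imputed.

Line comparisons fit the score with line as a fixed effect (cell means) and
individual, subline and session random; all 276 line pairs are tested with a
single-step max-|t| adjustment using the studentized-range distribution with
residual degrees of freedom n - 24 from the fixed-effect fit (an
approximation to the multivariate-t single-step method). The compact letter
display is built by insert-and-absorb and the shared-letter <=>
non-significant invariant is re-verified by a hard assertion on every run.

## Synthetic-data generator

The generator emulates the study design: 24 lines x 2 sublines x 17 sessions
x 3 females per line and session (1224 females), two 90-s trials each at
25 fps, with optional day-2 dropout. Six latent traits (activity = log
baseline speed; exploration = log turning concentration; boldness = log
border-response factor; log fecundity; longevity; tibia length) decompose
into line/subline/individual/session components; line effects are drawn
jointly across traits from a line-level correlation matrix whose defaults
carry corr(exploration, fecundity) = -0.6 (the published trade-off) and
corr(activity, tibia) = +0.5. Subline, session and individual effects are
independent across traits; a per-day residual is added per trial.

Trajectories are correlated random walks: an AR(1) speed process
(persistence 0.85) around the individual's baseline, clipped at zero —
clipped frames are pauses, which is what gives the activity rate its signal;
the speed-noise sd scales as mu^0.6, so slower individuals pause more.
Heading increments are wrapped-normal with sd proportional to
sqrt(speed/0.45): constant turning variance per unit path length, which
makes sinuosity speed-invariant so the exploration latent, not activity,
drives it. Inside the border band the target speed and the turning variance
are multiplied by the individual's border-response factor (mean 0.45: shy
females slow and straighten at the border). Walls reflect. Offspring counts
are Poisson around the exponentiated fecundity latent; longevity and tibia
are Gaussian.

Default latent variance components were moment-matched against pilot
simulations at the full study size so the *measured* traits land near the
published estimates (trajectory measurement noise dilutes the latent shares,
so latent shares exceed the targets). With the defaults, across replicate
experiments: R(mean speed) ~ 0.33–0.42 (target 0.35), R(activity rate)
~ 0.07–0.10 (0.08), R(sinuosity) ~ 0.24–0.26 (0.24), border contrasts
~ 0.10–0.18 (0.10–0.12); H²(mean speed) ~ 0.10–0.19 (0.11), H²(sinuosity)
~ 0.04–0.07 (0.06), fitness H² ~ 0.10 / 0.26–0.32 / 0.02–0.05 (offspring /
longevity / tibia).

**Known gaps between the generator and real data** (hence what passing tests
do and do not show): the explored-area rate retains speed leakage, so its
repeatability runs high (~0.35 vs 0.18) and the synthetic PC1 leans towards
activity — the built-in genetic trade-off is cleanest in the
sinuosity–offspring line correlation, attenuated from 0.6 to roughly 0.3–0.4
by line-predictor noise at 24 lines. Time-to-dark repeatability (~0.06–0.20)
exceeds the published 0.04 because the walker has no decision component:
crossing latency is more tightly determined by speed and turning than in
real wasps. The generator makes no attempt at oviposition behaviour,
host-egg structure or temperature effects.

## Problem sizes and runtime choices

The default test suite and `scripts/acceptance.py` simulate at the full
study size (1224 females, 2448 trials). Bootstrap counts are the package's
scaling choices: 1000 for one-off tables, 200 per CI inside the
100-replicate coverage study and the acceptance run, 100 in the end-to-end
recovery test, where CIs only gate variable selection. The coverage study
uses record-level simulation (latents plus day residuals) rather than
trajectories; trajectory generation is exercised by the end-to-end test and
the acceptance script.

## Degenerate inputs and numerical conventions

Empty trajectories, all-missing responses, single-level factors, constant
responses (all components zero, converged), zero zone residence (missing
value, never imputed), fewer than two repeatable variables (scoring refuses),
constant correlation margins (undefined, reported as missing) are all
handled explicitly. The REML criterion centres the response internally so
variance components are shift-invariant to numerical precision; fitted
variances below 1e-10 of the response variance are snapped to the zero
boundary.
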