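# Methods

This note documents the models and procedures implemented in `cpsrec`, the
defaults they ship with, and what the synthetic test conditions do and do not
establish about real data.

## Problem setting

Each record is one supervised endurance trial: 46 numeric indicators
describing the athlete and the beverage (anthropometry, sleep architecture,
HRV block, blood markers, lifestyle counts, beverage composition) plus the
dose columns `CHO` and `PRO` in g/kg/h, and the outcome "Rowing distance" in
meters over a 60-minute ergometer test.  The modeling goal is a regressor
`f(x, CHO, PRO) → meters` good enough to rank candidate dose regimens for an
individual; the recommendation goal is the argmax of `f` over a discrete
dose grid under two strategies (4:1 CPS and CHO-only).

## Synthetic cohort generator

The generator exists because the pipeline's reference cohort is private.  It
is a first-class, tested module, not a fixture: every statistical assumption
the pipeline relies on is planted explicitly so downstream stages have
ground truth.

**Marginals.**  Each feature has a declared family — truncated normal,
lognormal, or scaled Poisson count — with locations and scales chosen as
plausible values for trained male endurance rowers (e.g. weight 76 ± 8 kg,
resting HR 58 ± 7 bpm, RMSSD lognormal around 55 ms).  Values are produced
by pushing a Gaussian copula latent through the exact marginal quantile
function, so marginal moments are analytic and recovery tests can use real
standard errors.

**Collinearity.**  A feature may declare `collinear_with = (partner, ρ)`;
its copula latent is `ρ·z_partner + √(1-ρ²)·ε`.  The default schema plants
the strongest published pairs: Magnesium–Calcium at 1.00, thigh
circumferences at 0.88, skinfolds at 0.86, an HRV block (RMSSD/SDNN/SDSD/
HF/LF/total power) at 0.81–0.86, and beverage minerals tied to the dose
columns (Sodium/Magnesium/Calcium tracking CHO at 0.90–0.95, fat tracking
PRO at 0.97).  Planted copula correlations reproduce empirical Pearson r
within ±0.05 at n ≥ 1000; dose-linked pairs are slightly attenuated by the
discrete dose mixture and are held to looser checks.

**Doses.**  (CHO, PRO) are sampled from the trial-condition mixture of the
source designs: with probability 171/231 one of eight 4:1 CPS levels
(0.50–1.20 g/kg/h in 0.10 steps, PRO = CHO/4), otherwise one of five
crossover conditions (placebo, two CHO-only doses, a fixed 4:1 CPS, and a
personalized-CPS analogue with CHO uniform on the dose range).  Both
PRO = CHO/4 and PRO = 0 regimes therefore appear in every cohort.

**Outcome.**  `y = 14000 + Σ w_f z_f − k(CHO − c*_i)² + b_i·PRO + ε`,
with baseline weights `w` (meters per SD) loading on weight, explosive
power, training load, meal timing and blood markers; curvature
k = 3000 m/(g/kg/h)²; an individual optimum
`c*_i = clip(0.85 + Σ c_f z_f, 0.50, 1.20)`; protein effect
`b_i = ±400 m per g/kg/h`; and ε ~ N(0, 300²) m.  Responder status (the
sign of `b_i`) is a *deterministic* function of the record — an individual
responds iff the normal CDF of its standardized body-water percentage is at
most the responder fraction (default 0.7) — so the analytic optimum oracle
`true_optimal_dose` needs no hidden random state.  Under CPS the response
`−k(c − c*)² + b c/4` has its interior maximum at `c* + b/(8k)`; with a
negative protein effect the CHO-only curve dominates pointwise, which is
what the recommender must discover.  These defaults put the outcome near
14,000 ± 1,000 m, so a mean predictor has MAE in the high hundreds of
meters — the same order as the errors the method is meant to reduce.  This
is a design default, not a claim of equality with any empirical dataset.

**Seeding.**  One integer seed spawns a `SeedSequence` child per column plus
streams for doses and noise, so output is bit-reproducible and adding a
column does not perturb the others.

## Partitioning

Quartile bins are cut at the 25th/50th/75th empirical percentiles (linear
interpolation); a record exactly at a cut goes to the lower bin — a
deterministic convention.  The hold-out count is round-half-up of
`|bin| × test fraction` per bin, which yields the canonical 184/47 split of
a 231-record cohort at 20%.  CV folds are dealt round-robin within bins so
fold sizes differ by at most one and each fold spans the outcome range; the
fold assignment is stratified on the same bins as the split because the
split's intent (outcome balance) applies equally to validation folds.

## Hybrid feature selection

Three inputs are integrated deterministically: (1) the Pearson screen flags
pairs with |r| > 0.80 (zero-variance columns are excluded with a warning);
(2) a randomized-search-tuned XGBoost regressor, refit on the full
development set, supplies per-feature **total gain** importances normalized
to sum to one — gain is the least split-count-biased of the standard
importance measures; (3) explicit keep/drop lists operationalize domain
knowledge — there are no hidden heuristics.  For each flagged pair the
lower-importance member is dropped (keep-listed features are immune;
importance ties drop the lexicographically later name), then features below
an importance floor (default 0.005 of normalized gain) are dropped.  The
procedure is idempotent, and the packaged 21-feature default subset
(`SELECTED_FEATURES`) is the published working set of this selection.

## Augmentation

All three methods emit synthetic tables on the original scale, clipped per
column to the source min/max extended by 1% of the range, with hard zero
floors on nutrient and count columns.

* **Mixup**: pairs (i ≠ j) drawn uniformly with replacement;
  λ ~ Beta(0.20, 0.20); features and outcome interpolated jointly, so each
  synthetic row lies in the columnwise convex hull of its sources and
  clipping is a no-op except at floors.
* **Noise injection**: a uniformly chosen source row plus independent
  N(0, (0.05 σ_col)²) per feature; the outcome is copied unperturbed by
  default (`perturb_outcome` exposes the alternative).
* **WGAN-GP**: generator (ReLU) maps a latent normal vector to the z-scored
  feature+outcome space; critic (LeakyReLU 0.2) is trained on the
  Wasserstein objective with gradient penalty
  `λ_gp (‖∇_x̂ C(x̂)‖₂ − 1)²`, λ_gp = 10, at uniform real/fake
  interpolates, five critic updates per generator update.  The scaler is
  fitted on the training table only and inverted before clipping.

The networks are plain NumPy MLPs with manual backprop and Adam.  Because
the hidden activations are piecewise linear, the penalty's double-backprop
treats the activation-slope matrices as constants — the exact almost-
everywhere derivative — and the implementation is verified against finite
differences to ~1e-9 in the test suite.

**Training profiles.**  The full profile is the published recipe: latent
100, widths 128, Adam(5·10⁻⁵, 0.5, 0.9), batch 32, 10,000 generator cycles.
The packaged **reduced profile** (used by default in the pipeline and
tests) is scaled for desk-time budgets: latent 16, widths 32, batch 64,
1,500 cycles, and a two-timescale schedule — generator 5·10⁻⁵, critic
3·10⁻⁴ — plus a small-scale generator output init.  The faster critic is
what makes the reduced budget land a settled generator: with a single slow
rate the generator orbits the data distribution and the endpoint depends on
the phase of that orbit, whereas the two-timescale profile converged on
10/10 probe seeds of the 2-column Gaussian sanity check.  An "epoch" means
one generator update cycle (five critic batches plus one generator batch);
at batch 32 on a ~184-row table the full profile's 10,000 epochs are
consistent with this reading.

## Fidelity evaluation

Per shared column a two-sided Mann–Whitney U test (tie-corrected normal
approximation) compares original vs synthetic; Benjamini–Hochberg step-up
q-values are computed by a hand-implemented procedure cross-checked against
statsmodels to 1e-12.  A column "passes" when q ≥ 0.05 — failure to reject
distributional difference.  Correlation preservation is summarized by
max |Δr|, mean |Δr| (off-diagonal) and the Frobenius norm of the difference
of feature-correlation matrices.  Density curves use a Gaussian kernel with
a *pooled* Scott bandwidth shared by both samples (so shape differences are
not confounded by bandwidth differences) on a 256-point grid extended three
bandwidths past the pooled range, making each curve integrate to 1 within
1%.  Method ranking is lexicographic — most passing columns, then smallest
mean |Δr|, then smallest mean integrated absolute density difference — a
reproducible formalization of what is otherwise a visual judgment; the rule
is configuration, not a scientific claim.

## Modeling protocol

Scaling is family-specific and fitted on training data only: boosted trees
use raw features; kernel SVR standardizes X and keeps y in meters; the
feedforward net standardizes X and y independently and inverse-transforms
predictions.  The net is a NumPy dropout MLP (ReLU, Adam, MSE, up to 200
epochs, early stopping with patience 20 on a 10% inner split) because the
searched space includes a dropout rate, which scikit-learn's MLP does not
expose.

The augmented arm has three stages.  (1) **HPO** samples the published
per-family grids uniformly (50 iterations; 25 for the net; without
replacement when the grid is small) with 5-fold CV scored by negative MAE
on the development set plus an equal-size synthetic sample; the combined
table is built once, not regenerated per inner fold.  (2) **Dynamic CV**
refits the augmenter on each fold's training partition alone, appends an
equal-size synthetic sample, and validates on the untouched original fold
on the meter scale.  (3) **Final training** uses the development set plus a
double-size synthetic sample.  The baseline arm runs the same three stages
with no synthetic rows, on identical folds and seeds, so the two arms
differ only in augmentation.

Every fitted predictor records the original row labels behind its training
data (including augmenter and scaler fitting); `evaluate_holdout` refuses
any overlap, and augmenters refuse to serve a table other than the one they
were fitted on.  These provenance checks are hard failures, not warnings.

## Recommendation

The dose grid is inclusive, 0.50–1.20 g/kg/h in 0.01 steps (71 levels),
with levels rounded to the step precision to avoid float drift.  Stage one
predicts at PRO = CHO/4, stage two at PRO = 0, all other indicators held
constant.  With P₁ and P₂ the stage maxima, CPS is recommended iff
P₁ ≥ P₂ (ties to CPS, as specified); within a stage, ties between dose
levels resolve to the **lowest** CHO — at equal predicted performance the
smaller dose minimizes gastrointestinal load.  The procedure is exhaustive
enumeration over 142 candidates, so it trivially equals brute force; a test
asserts this against an independent re-implementation.

## What the synthetic conditions do and do not show

Passing tests on the synthetic cohort demonstrate that the machinery is
correct: splits and sample-size arithmetic are exact, augmenters obey their
stated laws, the fidelity suite is calibrated (identity data passes
everything), leakage is structurally impossible, and the recommender
recovers a *planted* optimum.  They do not show that WGAN-GP augmentation
improves generalization on real athlete data — the synthetic dose–response
is smoother and lower-dimensional than physiology, the marginals are
idealized, and record-level (not athlete-level) splitting is replicated
from the reference protocol even though repeated crossover trials of one
athlete could leak across partitions.  An optional grouped split mode is
the right control for that question on real data.

## Problem sizes and numerical choices

Default test and acceptance runs use the study-scale cohort (231 records,
184/47, five folds) with the reduced WGAN profile and modest HPO iteration
counts (the full 50-iteration searches and the 10,000-epoch generator
profile are presets away).  Tolerances: planted correlations ±0.05 at
n = 1000; Monte-Carlo checks at 20,000 draws use 3-standard-error bands;
oracle-agreement checks (Pearson, metrics, MWU, BH-FDR) are at 1e-9–1e-12.
Degenerate inputs have defined behavior throughout: all-tied outcomes
collapse to one quartile bin with a warning, zero-variance features are
excluded from correlation screens and flagged as KDE spikes, zero-variance
targets flag R² as undefined rather than dividing by zero.
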