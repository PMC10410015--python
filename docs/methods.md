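# Methods

This note documents the models, algorithms, numerical choices and
synthetic study conditions behind `physioage`. Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from external data.

## The age model and its objective

Chronological age (integer years, 12–79) is regressed on the biomarker
columns with gradient-boosted trees (XGBoost, histogram method, single
thread for bit-reproducibility). Missing biomarker values are routed
natively by the trees; no imputation feeds the main model. Defaults:
depth 4, learning rate 0.1, 200 rounds, subsample and column subsample
0.9, `min_child_weight` 5, base score = mean training age. A small
randomized search (`tune_hyperparameters`) is provided; the defaults are
deliberately modest so the whole pipeline runs on a laptop.

Squared-error boosting minimizes the *average* loss, so sparsely
populated ages — typically 70–79 in survey data — are predicted with a
strong pull toward the cohort mean. The age-normalized objective
rescales each individual's gradient by its age group's share of the
current error:

    grad_i = (ŷ_i − y_i) · mean|r| within age(i) / (mean|r| overall + ε)
    hess_i = 1

with ε = 1e-8 guarding the denominator and single-member age groups
using their own |residual| as the group mean. Group means use
**absolute** residuals in numerator and denominator: signed group means
shrink toward zero near convergence and would make the ratio wildly
unstable; the absolute form keeps the scaling in (0, ∞) and reduces
exactly to the plain residual when errors are balanced (one age group,
or equal group-wise error). The Hessian is constant 1, the standard
curvature for rescaled-residual objectives. The balancing effect is
measured, not assumed: with ages 70–79 undersampled fivefold in a noisy
regime (test R² ≈ 0.63, MAE ≈ 8.5 y), the (MAE over 70–79)/(overall
MAE) ratio drops under the age-normalized objective in every seed
tested (median over 5 seeds reported by the acceptance script).

## Exact interventional tree-Shapley explanations

No off-the-shelf attribution library is used; the engine
(`physioage._treeshap`) computes interventional Shapley values of the
tree ensemble against an explicit background population. For one
explained row `x`, one background row `z` and one tree, every leaf
reachable by a "mixed" path — following `x` at some diverging splits and
`z` at others — contributes

    +v · (a−1)! b! / (a+b)!   to each feature forced to x's side,
    −v · a! (b−1)! / (a+b)!   to each feature forced to z's side,

where `a` and `b` count the *unique* diverging features on the path
(repeated splits on a feature are routed consistently). Averaging over
background rows and summing over trees gives the exact Shapley values of
the coalition game v(S) = E_z f(x_S, z_\S). The implementation is
numba-compiled, precomputes per-row node routing, compares thresholds in
float32 (mirroring XGBoost's split evaluation) and accumulates in
float64; it is verified in the tests against brute-force enumeration of
all coalitions and satisfies efficiency to ~1e-12 years. Base values are
means of a float64 re-prediction over the background, so
`base + Σφ = prediction` is exact rather than float32-rounded.

Two reference populations define the two flavors:

* **global** — the whole dataset (optionally a uniform subsample for
  large cohorts; the stored base is always the mean prediction over the
  background actually used). PPA = base + row sum.
* **contextualized** — the individuals sharing the subject's
  chronological age. Integer ages are merged with neighboring ages until
  each group holds ≥ 50 individuals (left-to-right accumulation, the
  trailing remainder merged backward). Per-group base = mean group
  prediction; the row sum is the PPA deviation, and group-mean deviation
  is 0 by construction.

Contextualization **re-bases the explanation reference**; it does not
retrain a predictive model per age group. Retraining would change the
function being explained and break comparability of contributions across
ages — the point of contextualization is to explain *the same model*
against an age-matched norm. With a single age group the two flavors
coincide exactly.

## Dependence profiles and thresholds

For a variable, contextualized contributions are binned on a grid of
equal-frequency value bins (default 40) × age bins (default 6
equal-frequency). Per-cell means are smoothed along the value axis with
a 3-bin moving average (raw per-individual contributions are noisy
scatter), and cells whose |mean| is below `min_amplitude` (default 0.2
years) are treated as zero — a variable that never materially departs
from zero has no meaningful threshold. The per-age-bin crossing interval
is the bracket between the last negative and first positive bin center
in the monotone case, and the widest adjacent sign-change bracket
otherwise; no qualifying sign change yields no interval.

## Synthetic cohorts

The generator writes down the statistical structure the analysis
assumes. For variable `v` and individual `i` with age `a_i`:

    x_iv = M_v(a_i) + baseline_sd_v · z_iv + noise_sd_v · ε_iv

with `z_iv, ε_iv ~ N(0,1)` independent. `M_v` is the population age
profile; its standardized drift across the active age range is the
effect's **amplitude** `A_v` (units of baseline SD):

* *linear*: drift `A (a − 45.5)/67` in SD units across ages 12–79;
* *window*: the same drift compressed into `[a_lo, a_hi]`, flat outside;
* *sigmoid*: a drifting mean whose zero-contribution value (e.g. 5.5%
  for an HbA1c-like marker) can also step with age; deviations
  contribute with tanh-like saturation;
* *null*: flat profile, no age signal (amplitude 0 by invariant).

Amplitude is the age-informativeness knob: the larger the drift relative
to the within-age spread, the more the variable tells a model about age,
and the larger its explanation contributions. The age displacement a
deviation implies follows from inverting the local profile slope (a
one-SD deviation on a variable drifting `A` SDs over 67 years reads as
`67/A` years). The recorded **true contribution** is that displacement
weighted by the variable's share of the panel's total age information
(inverse implied-variance weights) — the attribution an efficient
combined estimate of the latent physiological state would assign. Row
sums give the true deviation, with an SD of a few years for
information-rich panels, on the scale of a model's same-age-referenced
prediction deviation. Null variables have weight zero, so their
contribution columns are exactly zero.

Ages are drawn from a survey-like histogram (ages 12–20 twice as dense,
70–79 thinned by 25%), sexes Bernoulli(0.5) with no sex-dependent
effects, inclusion years uniform over biennial cycles 1999–2017.
Missingness is MCAR over biomarker cells only (identity, demographics
and survival columns are never masked); the default rate is 0.6%.
Mortality is exponential proportional hazards,

    h_i = h_0 · exp(β · true_deviation_i + 0.085 · (a_i − 45.5)),

with administrative censoring (default 16 years of follow-up,
`h_0 = 0.004`/person-year, β = 0.05 per deviation-year) — the simplest
model consistent with the Cox analyses downstream; the age term gives a
Gompertz-like gradient (hazard doubling ≈ every 8 years).

The default 48-variable panel mimics a routine laboratory battery in
shape mixture and plausible units: one dominant HbA1c-like sigmoid
marker, window effects for alkaline phosphatase (adolescence), ALT
(young adulthood), folate and lymphocytes (old age), ~40 linear drifts
of varying strength, and two age-null electrolytes. It is deliberately
information-rich (held-out R² ≈ 0.97) so that structure-recovery tests
are sharp; real survey panels are noisier (R² ≈ 0.7), and experiments
that need that regime (the age-balance comparison) use weaker panels.

## Cohort preparation

Filters run variables-first, then individuals: biomarkers observed on
less than `min_coverage` (default 80%) of the cohort are dropped, then
individuals missing **strictly more than** 10% of the retained
biomarkers are dropped. Variables go first because the per-person rule
is only meaningful over the variables that will actually be analyzed;
the order is fixed and the composite is idempotent. Coverage is a
fraction rather than an absolute count so the rule scales with cohort
size.

Imputation (for the KDM/HD comparators and linear baselines only) is
scikit-learn's iterative round-robin imputer with a Bayesian ridge
estimator; observed cells are restored exactly after fitting. The
80:20 train/test split is stratified by integer age × sex with
largest-remainder allocation, so the test share of every stratum is
balanced and the total test count is exact.

## Comparators and validation

**KDM.** Each included biomarker is regressed on age
(`x_j = q_j + k_j a + e_j`, residual SD `s_j`); biomarkers with
|Pearson r with age| < 0.1 are excluded (a near-zero slope makes the
inverse regression unstable). The corrected estimator combines inverse
regressions with a chronological-age term:

    BA = [Σ_j (x_j − q_j) k_j / s_j² + CA / s_BA²] / [Σ_j k_j²/s_j² + 1/s_BA²]

with `s_BA²` calibrated as the training mean squared gap between the
first-stage (biomarker-only) estimate and chronological age. On a
noise-free linear biomarker the estimator inverts to chronological age
exactly (verified to 1e-6).

**HD.** Homeostatic dysregulation is the Mahalanobis distance from a
young reference population — default ages 18–30 with all biomarkers
inside their cohort-wide [1st, 99th] percentile bands. Right-skewed
biomarkers (sample skewness > 2) are log1p-transformed; variables are
standardized on the reference; a ridge term is added only if the
reference covariance is numerically singular. The quadratic form is
checked against an explicit inverse to 1e-8.

**Survival.** The metric under test is cut at its sample deciles (ties
to the lower decile), the 5th decile is the reference, and a Cox
proportional-hazards model (lifelines) adjusts for gender, age, year of
inclusion and the age × year interaction, on adults (≥ 18). Deciles
with zero events are flagged unstable. **Covariate associations** are
ordinary linear models of the metric on each covariate plus age and
gender (statsmodels), with AIC differences (dAIC) computed across
metrics fitted to the same covariate.

## Clustering and signatures

Contextualized contribution rows (chronological age is *not* a feature)
are clustered with Ward linkage on Euclidean distance and cut at k
clusters; k defaults to 10 but carries no automatic selection — a
silhouette-vs-k report (`silhouette_report`) is emitted for the analyst.
For every variable and cluster pair a two-sided Mann–Whitney test is
run. The effect size is r = |Z|/√(n1+n2) with Z the tie-corrected
normal deviate **without** continuity correction (so the fully separated
10-vs-10 case gives Z = 50/√175 = 3.78, r = 0.845); p-values use the
exact null distribution when n1+n2 ≤ 12 and the sample is tie-free, and
the tie- and continuity-corrected normal approximation otherwise.
Benjamini–Hochberg runs over the variables of one cluster pair by
default (pooling across pairs is available); a variable enters a
signature only with r ≥ 0.3 **and** adjusted q < 0.05 — a significant
but small effect is rejected by the effect-size gate. Cluster decision
profiles accumulate mean contributions in importance order; the terminal
value equals the cluster's mean PPA deviation exactly.

## Recursive feature elimination

Fit → explain globally → drop the variable with the smallest mean
|contribution| → repeat to a single variable. Importance ties drop the
lexicographically last name, and for speed the explanation step uses a
1000-row foreground subsample with a 128-row background — rankings, not
values, are needed. The minimal model is the smallest retained set whose
test R² ≥ 0.99 × the full model's (test-set R², not CV). Per-step
hyperparameter retuning is available (`retune=True`) but off by
default: reusing one configuration changes none of the qualitative
behavior on the panels tested and keeps the loop tractable.

## Study conditions for the measured experiments

The acceptance script and tests regenerate these from scratch:

* *Additivity*: n = 2000, 20 variables of random amplitude 1–10;
  global (500-row background) and contextualized gaps.
* *Age balance*: n = 10,000, 10 weak effects (amplitudes 1.5–3, noise
  SD 1.0 — held-out R² ≈ 0.63, the noisy-survey regime), ages 70–79
  thinned fivefold; median over 5 seeds.
* *Effect recovery*: n = 10,000, amplitudes 1–10; Spearman of amplitude
  vs mean |contextualized φ|.
* *Thresholds*: n = 20,000; sigmoid marker with midpoint 5.5% and a
  second marker whose midpoint steps 5.4% → 5.8% at age 50. Brackets are
  measured with the magnitude floor off — the floor suppresses spurious
  thresholds on null variables but blanks the near-zero bins around a
  real crossing and would overstate its width.
* *RFE*: n = 5000, five amplitude-5 (noise SD 1.0) + five null
  variables, 10 seeds. The informative variables are noisy enough that
  each carries non-redundant signal, so the <1% rule must keep all five.
* *Survival*: n = 20,000, six amplitude-3 effects (true-deviation SD
  ≈ 9 y), β = 0.05 and β = 0.
* *Clustering*: n = 2000; a dominant (amplitude-15) variable whose
  physiological deviation is two-valued (±1 SD about the age norm),
  five weaker nuisance variables; ARI against the planted archetypes.

## Known limitations

* Per-variable latent deviations are independent; real biomarkers share
  organ-level factors, which would correlate explanation columns and
  make clustering structure richer than the planted archetypes.
* Missingness is MCAR only; informative missingness is out of scope.
* Survival is exponential with administrative censoring; no competing
  risks, no survey weights.
* The default panel is more age-informative than real survey
  laboratory data; absolute performance numbers on it (R² ≈ 0.97) are
  not comparable to real-cohort values, which is why the experiments
  that depend on the error regime set their own noise levels.
* Interventional Shapley values scale with foreground × background
  size; very large cohorts should use the background caps (results are
  unbiased Monte-Carlo restrictions of the same estimand).
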