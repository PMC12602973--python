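# Methods

## Scope and data model

The package reimplements, as a tested pipeline, an analysis that predicts
whole-lung dose-volume parameters (V5, V10, V20, V30, in percent of lung
volume) of esophageal-cancer IMRT plans from three tumor geometry features:
relative position `P`, relative length `L` and mean axial cross-sectional
area `S` (cm²).  The clinical cohort behind the analysis (103 patients,
screened to 96) is not publicly deposited, so a synthetic-cohort generator
is a first-class component: it defines the study conditions under which
every downstream stage — screening, regression, network training,
cross-validation, audit — is exercised and checked.

A case is the record `(case_id, P, L, S, V5, V10, V20, V30)`.  Physical
invariants enforced everywhere: `P, L ∈ [0, 1]`, `S > 0`, outcomes in
[0, 100] percent, and DVH monotonicity `V5 ≥ V10 ≥ V20 ≥ V30` (the volume
receiving ≥ 5 Gy contains the volume receiving ≥ 10 Gy, and so on).

## Synthetic cohort generator

**Feature marginals.**  `P` follows a scaled Beta on [0.11, 0.83] whose
shape is fitted (Nelder-Mead on the quantile residuals) to the published
quartiles Q1 = 0.32, median = 0.38, Q3 = 0.49; the fitted shape is
Beta(3.21, 4.74).  `L` and `S` are truncated normals over ranges consistent
with the published per-case table — L on [0.4, 0.9] (mean 0.65, sd 0.125),
S on [10, 22] cm² (mean 16, sd 3) — linked by a Gaussian copula with
correlation 0.4.  Whether L and S correlate with P in the real cohort is
unknown; they are generated independently of P, and the correlation is a
configurable parameter.

**Inlier trimming.**  Inlier feature vectors are rejection-sampled to a
squared Mahalanobis distance (against the population feature moments) below
0.9 × χ²₀.₉₅(3).  Rationale: the cohort the generator emulates is itself a
*post-screening* dataset — by construction no retained case lies beyond the
screening cutoff — and without trimming the bounded "box-shaped" joint
distribution places ~2.7% of natural draws beyond the ellipsoidal cutoff
(box corners), which would make planted-outlier recovery ambiguous.  The
0.9 margin absorbs finite-sample fluctuation of the screening statistics.

**Response surfaces.**  Each output is a deterministic surface plus
Gaussian noise:

```
Vx = poly_x(P) + b_L,x (L − 0.65) + b_S,x (S − 16) + ε_x
```

V5 and V10 use concave parabolas with vertex at P = 0.45 (mid-lung tumors
expose the most lung to low doses); V20 and V30 use negative linear slopes
(as the tumor moves inferiorly, the heart displaces lung tissue near the
target and the high-dose lung volume falls).  The L and S slopes are
positive (longer/thicker targets irradiate more lung); their default
magnitudes are a package assumption (the source analysis references them to
prior work without printing coefficients) sized so that L and S jointly
explain roughly 30% of each outcome's variance.

**Noise calibration.**  For output `x` with target adjusted R² `r`
(defaults 0.177, 0.081, 0.06, 0.072 for the P-only regression), the noise
variance solves

```
var(poly_x(P)) / (var(poly_x(P)) + var(LS terms) + σ²) = r,
```

i.e. `σ² = noise_variance_for_target_r2(var_P, r) − var_LS`, with moments
estimated from a fixed-seed 200 000-sample feature draw so that calibration
depends only on the spec, never on the cohort seed.  Measured over 200
cohorts of n = 96, the mean fitted adjusted R² is 0.171 (V5, quadratic) and
0.074 (V30, linear) against targets 0.177 and 0.072.

**Post-processing.**  Outcomes are clipped to [0.1, 100] (the strictly
positive floor keeps per-sample relative errors defined) and projected onto
DVH monotonicity by replacing each record's quadruple with its descending
sort — a minimal perturbation that approximately preserves the marginals
(V20/V30 use near-equal P-slopes, so the occasional swap does not distort
the P-signal).

**Planted outliers.**  `outlier_count` records (default 7 of 103) receive
feature vectors placed at squared Mahalanobis distance 2 × χ²₀.₉₅(3) from
the *sample* mean/covariance of the generated inliers, in a uniformly random
whitened direction (redrawn if the point leaves the physical domain).
Measuring against the inlier sample statistics makes the planted distance
exact by construction; their outcomes still follow the response surface, so
they are feature outliers only — exactly what the screening stage tests.

**What the generator does not emulate.**  Real cohorts carry anatomical
detail (heart position, lung volume asymmetry), planner-dependent
optimization style, and feature-outcome dependencies beyond the additive
surface above.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative findings are reproducible
under the stated statistical structure — not that the printed clinical
accuracy figures transfer to real patients.

## Outlier screening

Classical (non-robust) Mahalanobis screening on the three features: sample
mean and covariance of the full input cohort, single pass, squared distance
compared against the inverse chi-square CDF at 1 − α with 3 degrees of
freedom (7.81 at α = 0.05, which is what identifies the feature space — a
7-dimensional feature+outcome screen would imply a different cutoff).
Strict inequality removes.  Robust (MCD-style) re-estimation is out of
scope.

## Curve regression

For each output on P, four families are fitted by OLS (statsmodels):
linear, quadratic, cubic, and logarithmic (`y = b0 + b1 ln x`).  Adjusted
R² follows `1 − (1 − R²)(n − 1)/(n − k − 1)`; coefficient p-values are
classical homoskedastic t-tests and the overall p-value is the F-test; no
multiple-testing correction is applied.  Selection takes the best adjusted
R², except that any family within 0.01 of the best wins if it is simpler
(fewer coefficients); equal-complexity ties follow the canonical order
(linear, quadratic, cubic, logarithmic).  This tie-break operationalizes
the "scatter-plot inspection" of interactive practice.  At the calibrated
effect sizes (adjusted R² 0.06–0.18, n = 96) family identification from a
single cohort is intrinsically noisy: the expected family (quadratic for
V5/V10, linear for V20/V30) wins in roughly 70–80% of cohorts, and the
tests assert majority selection.

## Network and training

Three-layer feedforward network, logistic sigmoid in both layers (the form
of the delta rule, with its `ŷ(1−ŷ)` factor, forces this choice), topology
3-6-4, net input `Σ w·activation − threshold`; 52 free parameters.
Features are min-max scaled on the training fold; percent outcomes are
divided by 100 to land in the sigmoid range.  Unseen data may scale outside
[0, 1] and is deliberately not clipped, keeping the inverse transform
exact.

Training is plain online backpropagation: per sample, output deltas
`δ = ŷ(1−ŷ)(y−ŷ)` and hidden deltas `δ = ŷ(1−ŷ) Σ w δ`, weight update
`w += η δ ŷ_upstream`, threshold update `b −= η δ`; each delta equals the
negative gradient of `½Σ(y−ŷ)²` with respect to the node's net input, which
the tests verify against central finite differences (max deviation < 1e-6
over 100 random draws).  Defaults: η = 0.1, epoch-level stopping at mean
squared error (over samples and the four outputs) ≤ 1e-5, epoch cap 10 000,
seeded shuffling; no momentum or weight decay.  On noisy cohorts the 1e-5
target sits below the noise floor, so training runs to the epoch cap; the
epoch MSE is non-increasing in ≥ 95% of epochs up to a 0.3% jitter
tolerance inherent to online (per-sample) updates.

## Genetic-algorithm initialization (GA-BP)

A real-coded GA searches the flat 52-parameter vector before gradient
training.  Fitness is `1/(MSE + 1e-8)` of the decoded *untrained* network
on the training fold (cheap, and it matches the "initial weights" role; an
inner-training fitness variant would be costlier and was not adopted).
Operators: roulette-wheel selection, per-gene arithmetic (blend) crossover
(rate 0.7), uniform-perturbation mutation (per-gene rate 0.05) whose
amplitude is self-adaptive — a multiple (default 1.0) of the current
per-gene population standard deviation, so exploration narrows as the
population converges — and elitism (1), gene bounds [−3, 3], population 30,
50 generations.  All GA hyperparameters are package choices exposed in
`GAConfig`; none are fixed by the source analysis, which specifies the
hybrid only as a flowchart.  As a generic minimizer benchmark, the same
engine drives a 52-dimensional sphere objective below 0.1 (median over 20
seeds) with a larger population (60, elitism 6, mutation rate 1.0) in 200
generations; with roulette selection the convergence bottleneck is
selection pressure, hence the benchmark's larger population.

## Evaluation protocol

Repeated k-fold cross-validation, k = 5 with 5 repeats (25 fold-results;
fold sizes 20/19/19/19/19 at n = 96).  Per (train, test) pair the scaler is
fitted on the training fold only, the model is trained with fold-specific
seeds derived from the harness seed, and test predictions are scored on the
percent scale per output:

* error index `EI = √(Σ(Ŝᵢ−Sᵢ)² / ΣSᵢ²)` — the square root covers the whole
  ratio (the scale-free reading consistent with reported magnitudes);
* predictive accuracy `PA = 100·n/N` with `n` the count of
  `|(Ŝᵢ−Sᵢ)/Sᵢ| < 0.2` — the magnitude reading: a +25% over-prediction is
  not "accurate";
* aggregation: per fold, then mean ± SD over the 25 fold-results (SD is the
  dispersion measure reported).

The Monte-Carlo model comparison (tests) runs both models over 30
independent study-sized cohorts with a matched per-fold budget of 60
backpropagation epochs — a problem size chosen so the full comparison runs
in minutes; the GA-BP advantage and the PA ordering V5 > V10 > V20 > V30
are stable at this budget (e.g. mean EI(V5) ≈ 0.096 BP vs ≈ 0.077 GA-BP
across the pilot cohorts).  Larger budgets narrow the EI gap but preserved
its direction in all configurations examined.

## Plan audit

For each audited output (V5 and V10 by default — the low-dose parameters
with demonstrated headroom), `excess = planned − predicted`; a case is
flagged when the excess exceeds a margin, default 5 percentage points
(configurable; the source analysis says only "a certain margin").  The
conformity index `CI = (V_D,PTV / V_D) · (V_D,PTV / V_PTV)` is implemented
and unit-tested against hand arithmetic; the published per-case CI values
are not reproducible because the underlying PTV volumes are not printed.
Heart mean dose and spinal-cord-PRV maximum dose are pass-through report
columns, not modeled quantities.

## Numerical and degenerate-input choices

* Singular feature covariance in screening raises with advice (inspect
  collinearity / regularize) rather than pseudo-inverting silently.
* Constant regression response returns R² = 0 with slope p-values 1 (the
  centered total sum of squares is zero, so the ratio is undefined).
* Constant features make min-max scaling degenerate and raise.
* A degenerate GA population (zero variance, no mutation) is returned
  as-is with a logged note.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit config fields; pipeline stage seeds derive deterministically
  from one global seed; cohort CSV writes are byte-stable.

## Known limitations

* The generator's additive response surface and the independence of (L, S)
  from P are assumptions; effect magnitudes for L and S are package
  defaults, not published values.
* Inlier trimming slightly compresses the extremes of the P distribution
  relative to the published min/max (the quartiles remain matched).
* Family selection rates and EI/PA magnitudes depend on the synthetic
  conditions; only directional/qualitative agreement with the published
  tables is claimed, and the published per-cohort values are not
  reproducible without the clinical data.
* One hidden layer only, width configurable (default 6); no alternative
  metaheuristics; no DICOM-RT ingestion or dose re-optimization.
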