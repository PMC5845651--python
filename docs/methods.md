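# Methods

This note documents the models implemented in `accumtowers`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Task geometry and stimulus generation

The maze stem is 330 cm: a 30-cm start buffer (view angle pinned to 0),
a 200-cm cue region and a 100-cm delay region.  Tower positions are stored
"as seen", in cm from the stem start; the earliest possible tower is at
10 cm because appearance is triggered at 10 cm proximity.  Analyses work in
cm; the accumulator model converts to meters (its leak is in m⁻¹).

Tower counts per side are Poisson with means **7.7 (rewarded side)** and
**2.3 (minority side)** *per cue period*.  The per-meter phrasing sometimes
used for these numbers is treated as a units slip: 7.7 + 2.3 = 10 towers
over the 2-m cue region is exactly the quoted overall density of 5 m⁻¹ and
matches the median of 10 total towers per trial.  Counts are capped at the
packing bound `1 + floor((200 − 10)/12) = 16` per side.

Positions are sampled **count-then-place**: given a count k, k ascending
positions with pairwise spacing ≥ 12 cm are drawn exactly (not by rejection)
with the gap transform — k uniform order statistics on
`[0, span − (k−1)·12]` stretched by `i·12`.  The refractory period applies
*within* each side; across sides towers are independent (only per-side
independence is consistent with up-to-16-per-side and up-to-25-total
counts).  A trial whose rewarded side does not end up with strictly more
towers is redrawn, so reward always sits on the majority side and ties
cannot occur.  Redrawing conditions the *realized* per-trial count means
slightly away from the Poisson parameters (≈ 7.96 / 2.17); the parameters
themselves are verified on unconditional draws.

## Debiasing and session shaping

Per finished trial, side-conditional error fractions `e_R`, `e_L` are
computed over the last 40 right-/left-rewarded trials with half-Gaussian
weights (σ = 20 trials, unit mass over available history).  `√e` is capped
into [0.15, 0.85] and the target right-trial probability is
`p_R = e_R/(e_R + e_L)` (cold start 0.5).  Side draws follow the
pseudo-random prescription: with the σ = 60 half-Gaussian empirical right
fraction `f̂`, right is drawn with probability `0.5·p_R` if `f̂ > p_R`,
`0.5·(1 + p_R)` if `f̂ < p_R`, and `p_R` at equality.

Sessions start in a visually guided warm-up maze; the animal advances to the
main maze after ≥ 10 warm-up trials at ≥ 85% correct, side bias ≤ 10% and
≥ 75% good-quality trials (travel ≤ 110% of nominal length).  In the main
maze a 40-trial running window below 55% correct triggers a 10-trial easy
block, exited unconditionally.  In simulation, warm-up and easy-block mazes
are performed at a fixed guided accuracy of 0.97 by every agent, since those
mazes carry an explicit visual guide and evidence policies do not apply;
analysis-side selection excludes those maze levels by default.

The view-angle controller maps treadmill displacements to
`Θ = atan2(−dX·sign(dY), |dY|)` and
`dθ/dt = sign(Θ)·min(exp(1.4·|Θ|^1.2) − 1, π)`; the raw sign convention
(negative for rightward displacement) is flipped once at log-writing time so
that package-wide positive θ = rightward, which makes the choice-decoder
definition read as an accuracy.

## Trial selection

Blocks are maximal runs of consecutive same-maze-level trials within a
session.  Selection applies, in order: maze-level filter, optional
opto-session exclusion, trial quality (excess travel > 110%, timeout,
abort), whole-block removal below 60% correct, optional trimming of the
first k trials of each block (history requirement), and a minimum of 1,000
surviving trials per mouse.  Block performance is computed over the
quality-surviving trials of the block, which makes the operation idempotent;
the history trim is inherently non-idempotent (it removes the first k trials
of each block on every application) and is excluded from the idempotence
guarantee.  An empty result raises, never returns silently, and a ledger of
per-criterion exclusion counts always accompanies the survivors.

## Psychometrics

Δ = #R − #L is binned by grouping *sorted unique values* in consecutive
triplets (a mirror-symmetric dataset with a multiple-of-three number of
unique values gets antisymmetric bins); the bin abscissa is the
trial-weighted mean Δ.  The 4-parameter sigmoid
`p_R = b + a/(1 + exp(−(Δ − Δ₀)/λ))` is fitted to binned proportions by
weighted least squares with per-bin binomial weights and bounds
`b ∈ [0, 0.5]`, `a ∈ [0, 1]` so that b and b + a are interpretable
asymptotes (the fitting objective is an open choice; a single-trial MLE
would also be defensible).  The slope is `a/4λ`.  Step-like data leave the
scale unresolved below the bin spacing; such fits are flagged and the slope
reported large-finite.  Binomial intervals are Jeffreys 1-σ: the
0.1587/0.8413 quantiles of Beta(k+½, n−k+½).

The surrogate top-block test fits a static per-mouse curve, then repeatedly
(default 200×) redraws all outcomes from it at the experienced Δs,
re-selects the top 10% of blocks (ranked by accuracy, ties broken by block
length then order; mice kept only with ≥ 300 surviving trials) and
recomputes the slope/lapse improvements; p is the fraction of surrogates
meeting or exceeding the observed improvement, and the population comparison
is a one-sided signed-rank test.

The performance-factors model bins |Δ| and total towers in groups of two and
effective durations in 10-cm bins (effective cue duration = last-minus-first
tower position, both sides pooled; effective delay = 300 minus last tower
position), computes per-mouse mean-subtracted percent correct per 3-way
cell, averages cells across mice, and fits a 3-predictor linear regression
whose coefficient t-statistics use n − p − 1 degrees of freedom.  The
binned-cell design attenuates coefficients somewhat; recovery tests use
correspondingly broad bands.

## Evidence weighting

The spatial logistic model regresses choice on net evidence in five equal
segments of [10, 200] cm (half-open bins, last closed).  The fit is an
unregularized MLE; complete separation is detected by exploding
coefficients and falls back to a tiny ridge (1e-6) with a warning.
Coefficient SDs come from 200 bootstrap refits.  The weight-decay ratio is
`mean(β₄, β₅)/mean(β₁, β₂)`; its null shuffles the five evidence entries
within each trial (column permutation per trial — equivalent to shuffling
tower bin labels for balanced designs) and refits 200 times, with p the
fraction of null ratios below the observed one.

## History-modulated choice models

The nested logistic family is

    p_R = ℓ_L + (1 − ℓ_L − ℓ_R) · σ( p₀ + (1 + β_e·e)(β₀ + β_Δᵀ·Δ) )
    ℓ_R = ½[1 − cos(β₀R + β_hᵀh)],  ℓ_L = ½[1 − cos(β₀L − β_hᵀh)]

with `p₀ = −ln(1/f_R − 1)` fixed from the data's right-choice fraction (all
free parameters at zero ⇒ p_R = f_R exactly), `h = (c±, o±, c±·o±)` from the
previous trial and `e = +1` after an error.  The cosine arguments are
clipped to [−π/2, π/2], the minimal reading that keeps ℓ ∈ [0, 0.5]; the
baselines β₀R, β₀L are box-constrained to [0, π/2].  The cosine block has
zero gradient exactly at the origin (a saddle), so the deterministic start
offsets the lapse baselines slightly; further random starts guard against
local optima.  Fitting maximizes the log likelihood minus an L1 penalty
(smoothed with ε = 1e-12 inside a square root so quasi-Newton methods
apply); the penalty weight is configurable (default 1e-3, effectively
unpenalized at the ns used here) and recorded in the fit.  Lapse magnitude
and evidence slope trade off along a likelihood ridge, so parameter-recovery
checks compare against bootstrap CIs (session-level resampling, preserving
the consecutive-trial structure) rather than fixed tolerances.

Cue-order evidence ranks pooled towers by position (right before left on
exact cross-side ties), groups ranks in triplets, and uses #R − #L per
triplet; the dimensionality D is the largest with ≥ 50 trials of ≥ 3D cues,
and vectors are scaled by `⟨|Δ|⟩_n^(−1/2)` where ⟨|Δ|⟩_n is the mean |Δ|
among trials with the same total count n.

Strategy models: the k-random-tower rule is the hypergeometric tail
P(k_R > k/2) (even-k ties count ½; k = 1 reduces to #R/(#R+#L); k is
clipped to the trial's total; zero towers default to 0.5), first/last-tower
rules are indicators, and all are modulated by side lapses measured on
single-sided trials.  The fixed-total linearity test compares the observed
p_R-vs-Δ curve at a fixed total (default 12) against the one-random-tower
line p = #R/total with a sum-of-squared-deviations statistic whose null is
simulated from the line model at the observed per-level counts (the
original shuffle construction is not fully specified; this substitute is
validated by its null calibration).

## Drift-diffusion model

The latent accumulator evolves over maze position y (meters): between
pulses `da = λ·a·dy + σ_a·dW`; each tower adds an impulse of magnitude
`±η·C` with `η ~ N(1, σ²_s)` (variance σ²_s·C²); `a₀ ~ N(0, σ²_i)`;
accumulation sticks at ±B; at trial end, absorbed mass chooses by its
bound's sign, unabsorbed mass by `a > bias`, and a lapse fraction chooses at
random.  (The three noises are named diffusion, stimulus and initial value;
the initial condition follows that naming.)  Adaptation C starts at 1,
recovers between pulses as `dC/dy = (1 − C)/τΦ` (closed-form exponential)
and multiplies by Φ at each pulse; both evidence streams share one
adaptation process by default (a `within_stream` switch is provided).
Parameters are bounded as: λ ∈ (−5, 5) m⁻¹, σ²a, σ²s ∈ (0, 200),
σ²i ∈ (0, 30), B ∈ (5, 25), Φ ∈ (0, 1.2), τΦ ∈ (0.001, 2) m,
bias ∈ (−5, 5), lapse ∈ [0, 1].

Likelihoods propagate the full distribution on a 281-point grid over
[−B, B] (end bins sticky), default step dy = 0.01 m over the 3-m stem.
All transition operators conserve mass and match moments exactly: the leak
map redistributes each node's mass to its two neighbors (mean-exact), the
per-step diffusion kernel is a CDF-discretized Gaussian with a three-point
variance correction (exact variance even when the per-step SD is below the
grid spacing), and impulses combine a two-point mean shift with a variance
kernel from which the shift's spurious variance `r(h − r)` is deducted.
Pulses are applied at the nearest step with mean and SD rescaled by
`exp(λ·(y_step − y_pulse))` so each pulse's contribution to the final mean
is exact despite step quantization.  Mass is conserved to ~1e-15 and
audited at 1e-8.  The scheme is first-order: halving the step changes p_R
by ~3e-5 at moderate noise, and the default resolution is accurate to
~1e-3 in p_R in the hardest corners; the authoritative correctness check is
agreement with an independent 100,000-path Monte-Carlo simulation (exact
linear-SDE transitions, 0.5-cm bound checks) within 3 Monte-Carlo SEs
across a 20-point parameter/trial grid.

Fitting is bounded quasi-Newton (L-BFGS-B) on unit-scaled coordinates with
finite differences (eps 2e-3 in unit space, chosen above the kernel-cache
quantization so gradients are informative), multi-start, with per-start
traces, grid settings and a mass audit recorded in the fit object.  The
recovery test uses 2,000 trials with the leak and the two dominant noise
variances free (search ranges λ ∈ (−2, 2), σ² ∈ (0.05, 30)) and the
remaining parameters at their generative values — enough to establish the
leak's sign and the sensory-vs-diffusion noise ordering at single-CPU
timescales; a full nine-parameter fit is the same call with `free`
defaulted.

## SDT counting model

`p_c = Φ((L − S)/√(σ²_L + σ²_S))`, the closed form of the
difference-of-Gaussians integral, with L/S the larger/smaller side counts
(0–15; trials with a 16+ side are excluded entirely).  The full form fits
σ_T per count by MLE on (L, S, outcome) cells (aggregate data recommended —
per-mouse counts leave many cells empty); the two-parameter forms tie
σ(n) = β₀ + β₁n (scalar variability) or σ²(n) = β₀ + β₁n (linear variance),
with β₀ ≥ 0 and a σ floor of 1e-3 (a fit on the floor is flagged; σ₀ is
kept as a free parameter in the full form).  The bootstrap comparison
resamples trials, refits both laws and reports each law's winning
proportion by model information.

## Model comparison

Cross-validation uses 70 runs of 3-fold splits by default, with fold
assignments drawn once per scheme and shared bit-identically across models;
trials are assigned i.i.d. because history features are precomputed on the
intact sequence before splitting.  The reference f_R for ln L₀ is computed
on the training fold (no leakage).  MI = (ln L − ln L₀)/(n·ln 2); per-mouse
summaries take the median over the 210 fold-evaluations (an alternative
run-level reading is a one-liner away from the stored per-fold table), and
pairwise significance is the proportion of shared fold-evaluations one
model underperforms the other, ties counting half; a fold where any model
fails is excluded pairwise for both.  The FDR rule is implemented literally
(flag P(i) ≤ αi/n per rank) with the canonical step-up sweep behind a flag,
labeled in output.

## Kinematics

θ(Y) is the view angle at the *first sample* with y ≥ Y (no interpolation),
robust to backtracking.  The per-position choice decoder solves, by
bisection on the empirical CDFs, for the boundary where the fraction of
right-choice trials above it equals the fraction of left-choice trials
below it; accuracy is the percent of right-choice trials above the
boundary (rank-based, hence invariant to monotone transforms of θ).
Running speed is the x-y *path length* over 0 < y < 300 cm divided by
traversal time (net displacement would understate backtracking).
Tower-triggered analysis subtracts the same-choice mean trajectory,
averages deviations in a 0–80 cm post-tower window separately for left and
right towers, and reports the across-trial 1-SD spread relative to the
right/left trace difference.

## Synthetic data: what it does and does not show

The trajectory generator is a *descriptive stand-in*, not a model anyone
fits: a choice-signed logistic profile in y (midpoint 200 cm, steepness
40 cm, amplitude 1.5 rad) whose midpoint advances 5 cm per |Δ| tower, plus
OU noise (SD 0.3 rad, 50-cm correlation length), riding on speeds of
61 ± 5 cm/s within and ± 8 cm/s across sessions — values chosen to
reproduce the qualitative structure of real trajectories (progressive
divergence by choice, mid-maze decodability, spread ≫ choice-mean
difference).  Choice agents similarly emulate the *structure* of real
behavior.  Passing tests therefore establish that the estimators recover
the truth under their own generative assumptions and that the
implementations match independent oracles; they do not establish that real
mice satisfy those assumptions (no satiety drift, no slow nonstationarity,
no motor-event taxonomy).

Problem sizes used by the validation suite (single CPU, minutes): stimulus
statistics at 20,000 trials; DDM-vs-Monte-Carlo at 20 grid points ×
100,000 paths; spatial-logistic recovery at 20,000 trials with 200
bootstraps; history-model recovery at 20,000 trials with 30 session-level
bootstraps; SDT recovery at 50,000 trials; DDM recovery at 2,000 trials;
null calibrations at 60 (weight-decay) and 200 (fixed-total) simulated
experiments; surrogate tests at 60 surrogates.

## Known limitations

- The propagation scheme is first-order; likelihood differences below
  ~1e-3 between close parameter sets are at the discretization floor.
- The history-trim selection rule is not idempotent (see above).
- The DAT-Cre maze variant (220/80 cm, sparser towers) ships as a config
  preset only and is not separately analyzed.
- No reaction-time modeling, hierarchical fits, reinforcement-learning or
  ideal-observer models; no figure-for-figure replication of real-mouse
  numbers (the underlying animal data are not public).
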