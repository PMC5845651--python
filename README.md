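# accumtowers

Simulation and analysis toolkit for the **accumulating-towers task**: a
pulse-based evidence-accumulation paradigm in which a head-fixed mouse runs
down the stem of a virtual T-maze, sees brief visual pulses ("towers") on
either side of the first 200 cm (the cue region), crosses a 100-cm delay
region, and is rewarded for turning to the arm on the side that showed more
towers.  Tower counts are Poisson (mean 7.7 per cue period on the rewarded
side, 2.3 on the minority side) with a 12-cm within-side refractory spacing,
which makes the stimulus set diverse yet tightly controlled and the data
suitable for model-based analysis.

The package is aimed at behavioral neuroscientists who run (or simulate)
this class of task and want a tested implementation of its full
computational stack:

- **Task protocol** — exact stimulus generation (Poisson counts, minimum-gap
  placement via the spacing transform), the side-debiasing algorithm
  `p_R = e_R/(e_R + e_L)` with half-Gaussian error weighting and the
  pseudo-random side-draw prescription, the within-session shaping state
  machine (warm-up → main ↔ easy block), and the treadmill view-angle
  controller `dθ/dt = sign(Θ)·min(exp(1.4·|Θ|^1.2) − 1, π)`.
- **Synthetic agents** — constant-probability, k-random-tower, first/last
  tower, history-modulated logistic, and Monte-Carlo drift-diffusion agents,
  plus a trajectory generator, all with ground-truth sidecars for parameter
  recovery.
- **Psychometrics** — the 4-parameter sigmoid
  `p_R = b + a/(1 + exp(−(Δ − Δ₀)/λ))` on Δ = #R − #L (slope `a/4λ`), the
  lapse rate (error % at |Δ| ≥ 10), Jeffreys 1-σ binomial intervals, the
  top-block surrogate test, and the performance ~ |Δ| + total + duration
  linear model.
- **Evidence weighting** — logistic regression of choice on net evidence in
  five spatial bins of the cue region, the late/early weight-decay ratio
  with its shuffle test, and minority-cue profiles.
- **Choice models** — alternation-bias statistics and a nested family of
  history-modulated logistic models
  `p_R = ℓ_L + (1 − ℓ_L − ℓ_R)·σ(p₀ + (1 + β_e e)(β₀ + β_Δᵀ·Δ))` with
  cosine-bounded, history-dependent lapses, spatial-bin or cue-order
  evidence, and L1-penalized fitting; hypergeometric k-random-tower
  strategy models.
- **Drift-diffusion model** — the nine-parameter pulse accumulator
  (λ, σ²a, σ²s, σ²i, B, Φ, τΦ, bias, lapse) over maze position with sensory
  adaptation and sticky bounds; exact trial likelihoods by mass-conserving
  distribution propagation, cross-validated against Monte-Carlo simulation.
- **SDT counting model** — `p_c = Φ((L − S)/√(σ²_L + σ²_S))` with per-count
  σ_T or two-parameter scalar-variability / linear-variance laws and their
  bootstrap comparison.
- **Model comparison** — shared-fold cross-validation and the model
  information index `MI = (ln L − ln L₀)/(n·ln 2)` in bits/trial;
  Benjamini-Hochberg FDR correction.
- **Kinematics** — first-crossing view angles θ(Y), per-position choice
  decoding with an equal-error boundary, running-speed summaries, and
  tower-triggered trajectory analysis.

## Worked example

Run the bundled pipeline on a simulated dataset (a one-random-tower agent
with 10% side lapses, 8 sessions of 250 closed-loop trials):

```sh
accumtowers run --seed 1 --out demo/
```

The report (`demo/report.md`) from this exact command reads, in part:

```
## psychometrics

overall accuracy 73.3% | slope 4.91 %/tower | lapse 15.1%

## model comparison

- evidence+history: 0.1368 bits/trial
- history_only: 0.0009 bits/trial
- constant: 0.0000 bits/trial
```

Read: the agent is right 73.3% of the time overall; each extra tower of net
evidence moves its choice probability by ~4.9 percentage points at the
psychometric midpoint; on easy trials (|Δ| ≥ 10) it still errs 15.1% of the
time (its lapse floor).  Cross-validated model information confirms that a
model using the spatially-binned evidence predicts choices far better
(0.14 bits/trial above the constant-rate reference) than trial history
alone (~0 bits/trial), as expected for a history-blind evidence user.

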