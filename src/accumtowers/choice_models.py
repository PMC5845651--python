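"""Trial-history analyses, history-modulated logistic choice models, and
alternative (heuristic) strategy models.

The central model is a nested logistic family: the right-choice probability
is a lapse-bounded logistic in the trial's evidence vector, where the lapse
rates on either side depend on the previous trial's choice and outcome
through a cosine-bounded linear form, and the evidence slope is allowed to
change after errors.  With every free parameter at zero the model reduces
exactly to a constant right-choice probability equal to the empirical
right-choice fraction, so all members are nested w.r.t. that trivial model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import hypergeom

from .datamodel import (
    TrialRecord,
    NoTrialsError,
    UndefinedStatisticError,
    ValidationError,
)
from .evidence_weighting import spatial_evidence_matrix

HALF_PI = math.pi / 2.0


# ---------------------------------------------------------------------------
# Alternative strategy models


@dataclass(frozen=True)
class StrategyModelSpec:
    """A heuristic decision rule plus experimentally measured side lapses.

    kinds: ``k_random`` (choose k towers at random, follow their majority),
    ``first_tower``, ``last_tower``.  ``lapse_r``/``lapse_l`` are the error
    fractions on single-sided trials (right/left choices on only-left /
    only-right trials respectively).
    """

    kind: str = "k_random"
    k: int = 1
    lapse_r: float = 0.0
    lapse_l: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("k_random", "first_tower", "last_tower", "history_only"):
            raise ValidationError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "k_random" and (self.k < 1):
            raise ValidationError("k must be >= 1")
        if self.lapse_r + self.lapse_l >= 1.0:
            raise ValidationError("lapse_r + lapse_l must be < 1")


def k_random_tower_pRm(n_right: int, n_left: int, k: int) -> float:
    """P(majority of k towers drawn without replacement are right-side).

    Hypergeometric tail; an even-k tie contributes 0.5.  Zero towers default
    to 0.5.  k is clipped to the total number of towers.
    """
    total = n_right + n_left
    if total == 0:
        return 0.5
    k = min(k, total)
    half = k / 2.0
    # P(k_R > k/2); ties at k even contribute half
    p = float(hypergeom.sf(math.floor(half), total, n_right, k))
    if k % 2 == 0:
        p += 0.5 * float(hypergeom.pmf(k // 2, total, n_right, k))
    return p


def strategy_pRm(spec: StrategyModelSpec, trial: TrialRecord) -> float:
    """The strategy's right-choice probability before lapse modulation."""
    if spec.kind == "k_random":
        if spec.k == 1:
            total = trial.n_right + trial.n_left
            return trial.n_right / total if total else 0.5
        return k_random_tower_pRm(trial.n_right, trial.n_left, spec.k)
    pooled = trial.all_towers()
    if not pooled:
        return 0.5
    if spec.kind == "first_tower":
        return 1.0 if pooled[0][1] == "R" else 0.0
    if spec.kind == "last_tower":
        return 1.0 if pooled[-1][1] == "R" else 0.0
    raise ValidationError(f"strategy kind {spec.kind!r} has no evidence rule")


def strategy_predict(spec: StrategyModelSpec, trial: TrialRecord) -> float:
    """Lapse-modulated right-choice probability of the heuristic strategy."""
    p_m = strategy_pRm(spec, trial)
    return spec.lapse_r + (1.0 - spec.lapse_r - spec.lapse_l) * p_m


def estimate_side_lapses(trials: Sequence[TrialRecord]) -> tuple[float, float]:
    """(lapse_r, lapse_l) from single-sided trials.

    lapse_r is the right-choice fraction on trials with only left towers
    (errors there are right choices); lapse_l the left-choice fraction on
    only-right trials.
    """
    only_left = [t for t in trials if t.n_right == 0 and t.n_left > 0]
    only_right = [t for t in trials if t.n_left == 0 and t.n_right > 0]
    if not only_left or not only_right:
        raise UndefinedStatisticError("need single-sided trials on both sides")
    lapse_r = sum(t.choice == "R" for t in only_left) / len(only_left)
    lapse_l = sum(t.choice == "L" for t in only_right) / len(only_right)
    return lapse_r, lapse_l


# ---------------------------------------------------------------------------
# History-modulated logistic model


@dataclass
class HistoryModelParams:
    """Free parameters of the history-modulated logistic choice model.

    ``beta_delta`` matches the evidence form in use: a 5-vector of spatial-bin
    weights, a cue-order-rank vector, or empty (history-only model).
    """

    beta0: float = 0.0
    beta_delta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_e: float = 0.0
    beta0_r: float = 0.0
    beta0_l: float = 0.0
    beta_h: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [[self.beta0], self.beta_delta, [self.beta_e, self.beta0_r, self.beta0_l], self.beta_h]
        )

    @classmethod
    def unpack(cls, x: np.ndarray, n_evidence: int) -> "HistoryModelParams":
        return cls(
            beta0=float(x[0]),
            beta_delta=np.asarray(x[1 : 1 + n_evidence], dtype=float),
            beta_e=float(x[1 + n_evidence]),
            beta0_r=float(x[2 + n_evidence]),
            beta0_l=float(x[3 + n_evidence]),
            beta_h=np.asarray(x[4 + n_evidence : 7 + n_evidence], dtype=float),
        )


def history_vector(prev_choice: str, prev_correct: bool) -> np.ndarray:
    """h = (previous-choice sign, previous-outcome sign, their product)."""
    c = 1.0 if prev_choice == "R" else -1.0
    o = 1.0 if prev_correct else -1.0
    return np.array([c, o, c * o])


def history_model_pR(
    params: HistoryModelParams,
    p0: float,
    evidence: np.ndarray,
    h: np.ndarray,
    prev_error: float,
) -> np.ndarray:
    """Vectorized right-choice probability of the history model.

    ``evidence``: (n, D) evidence vectors; ``h``: (n, 3) history vectors;
    ``prev_error``: (n,) +1 after an error, -1 otherwise.  ``p0`` is the
    logit of the dataset's right-choice fraction (not a free parameter).
    """
    arg_r = np.clip(params.beta0_r + h @ params.beta_h, -HALF_PI, HALF_PI)
    arg_l = np.clip(params.beta0_l - h @ params.beta_h, -HALF_PI, HALF_PI)
    lapse_r = 0.5 * (1.0 - np.cos(arg_r))
    lapse_l = 0.5 * (1.0 - np.cos(arg_l))
    drive = params.beta0
    if evidence.shape[1]:
        drive = drive + evidence @ params.beta_delta
    z = p0 + (1.0 + params.beta_e * prev_error) * drive
    core = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return lapse_l + (1.0 - lapse_l - lapse_r) * core


# ---------------------------------------------------------------------------
# Feature construction


def previous_trial_features(
    trials: Sequence[TrialRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(h, prev_error, valid) arrays from each trial's predecessor.

    A trial is valid only when its predecessor is the immediately preceding
    trial of the same session (consecutive trial indices); history features
    are precomputed here, before any cross-validation split.
    """
    n = len(trials)
    h = np.zeros((n, 3))
    prev_error = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i in range(1, n):
        prev, cur = trials[i - 1], trials[i]
        if (
            prev.mouse_id == cur.mouse_id
            and prev.session_id == cur.session_id
            and cur.trial_index == prev.trial_index + 1
        ):
            h[i] = history_vector(prev.choice, prev.correct)
            prev_error[i] = 1.0 if not prev.correct else -1.0
            valid[i] = True
    return h, prev_error, valid


@dataclass
class CueOrderDesign:
    """Per-trial evidence vectors from cue-order rank triplets.

    Pooled cues are ranked by position (R before L on exact ties); coordinate
    j is #R - #L among ranks 3(j-1)+1 .. 3j.  The dimensionality D is the
    largest with at least ``min_trials_last`` fully-informed trials; each
    vector is divided by sqrt(<|delta|>_n), the mean |#R - #L| over trials
    with the same total cue count n.
    """

    matrix: np.ndarray
    dimension: int
    normalization: dict


def build_cue_order_design(
    trials: Sequence[TrialRecord], min_trials_last: int = 50
) -> CueOrderDesign:
    counts = np.array([t.n_left + t.n_right for t in trials])
    d = 0
    while np.sum(counts >= 3 * (d + 1)) >= min_trials_last:
        d += 1
    if d == 0:
        raise NoTrialsError("dataset too small for any cue-order coordinate")
    norm_table: dict[int, float] = {}
    for n in np.unique(counts):
        deltas = [abs(t.delta) for t in trials if t.n_left + t.n_right == n]
        norm_table[int(n)] = float(np.mean(deltas))
    X = np.zeros((len(trials), d))
    for i, t in enumerate(trials):
        pooled = t.all_towers()
        for j in range(d):
            chunk = pooled[3 * j : 3 * (j + 1)]
            X[i, j] = sum(1 if s == "R" else -1 for _, s in chunk)
        scale = norm_table[t.n_left + t.n_right]
        if scale > 0:
            X[i] /= math.sqrt(scale)
    return CueOrderDesign(matrix=X, dimension=d, normalization=norm_table)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class HistoryModelFit:
    params: HistoryModelParams
    p0: float
    f_right: float
    evidence_form: str
    loglik: float
    penalty: float
    converged: bool
    n_trials: int
    design: Optional[CueOrderDesign] = None

    def predict_pR(self, trials: Sequence[TrialRecord]) -> np.ndarray:
        X = _evidence_matrix(trials, self.evidence_form, self.design)
        h, prev_error, _ = previous_trial_features(trials)
        return history_model_pR(self.params, self.p0, X, h, prev_error)


def _evidence_matrix(
    trials: Sequence[TrialRecord], form: str, design: Optional[CueOrderDesign]
) -> np.ndarray:
    if form == "spatial_bins":
        return spatial_evidence_matrix(trials)
    if form == "cue_order":
        d = design or build_cue_order_design(trials)
        if len(trials) != d.matrix.shape[0]:
            # rebuild per-trial vectors using the stored D and normalization
            X = np.zeros((len(trials), d.dimension))
            for i, t in enumerate(trials):
                pooled = t.all_towers()
                for j in range(d.dimension):
                    chunk = pooled[3 * j : 3 * (j + 1)]
                    X[i, j] = sum(1 if s == "R" else -1 for _, s in chunk)
                scale = d.normalization.get(t.n_left + t.n_right)
                if scale is None:
                    scale = float(np.mean(list(d.normalization.values())))
                if scale > 0:
                    X[i] /= math.sqrt(scale)
            return X
        return d.matrix
    if form == "none":
        return np.zeros((len(trials), 0))
    raise ValidationError(f"unknown evidence form {form!r}")


def fit_history_model(
    trials: Sequence[TrialRecord],
    evidence_form: str = "spatial_bins",
    penalty: float = 1e-3,
    n_starts: int = 3,
    rng: Optional[np.random.Generator] = None,
    require_history: bool = True,
) -> HistoryModelFit:
    """L1-penalized maximum-likelihood fit of the history-modulated model.

    ``penalty`` is the total L1 weight (applied to all free parameters); the
    L1 term is smoothed with a tiny epsilon so quasi-Newton optimization
    applies.  Trials without a valid immediately-preceding trial are dropped
    (the model needs one trial of history).
    """
    rng = rng or np.random.default_rng(0)
    h, prev_error, valid = previous_trial_features(trials)
    if require_history:
        keep = np.where(valid)[0]
        if len(keep) == 0:
            raise NoTrialsError("no trials with one trial of history")
    else:
        keep = np.arange(len(trials))
    kept_trials = [trials[i] for i in keep]
    design = build_cue_order_design(kept_trials) if evidence_form == "cue_order" else None
    X = _evidence_matrix(kept_trials, evidence_form, design)
    h = h[keep]
    prev_error = prev_error[keep]
    choices = np.array([1.0 if t.choice == "R" else 0.0 for t in kept_trials])
    f_right = float(np.clip(choices.mean(), 1e-6, 1 - 1e-6))
    p0 = -math.log(1.0 / f_right - 1.0)
    n_ev = X.shape[1]

    def negloglik(x: np.ndarray) -> float:
        params = HistoryModelParams.unpack(x, n_ev)
        p = history_model_pR(params, p0, X, h, prev_error)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = np.sum(choices * np.log(p) + (1 - choices) * np.log(1 - p))
        return -ll + penalty * np.sum(np.sqrt(x**2 + 1e-12))

    n_params = 7 + n_ev
    bounds = [(-10, 10)] * (1 + n_ev) + [(-5, 5)] + [(0, HALF_PI)] * 2 + [(-HALF_PI, HALF_PI)] * 3
    best = None
    for s in range(n_starts):
        if s == 0:
            # the cosine lapse block has zero gradient at the origin (a
            # saddle); start its baselines slightly inside the box
            x0 = np.zeros(n_params)
            x0[2 + n_ev] = 0.2  # beta0_r
            x0[3 + n_ev] = 0.2  # beta0_l
        else:
            x0 = rng.normal(0, 0.1, n_params)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = HistoryModelParams.unpack(best.x, n_ev)
    p = history_model_pR(params, p0, X, h, prev_error)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    loglik = float(np.sum(choices * np.log(p) + (1 - choices) * np.log(1 - p)))
    return HistoryModelFit(
        params=params,
        p0=p0,
        f_right=f_right,
        evidence_form=evidence_form,
        loglik=loglik,
        penalty=penalty,
        converged=bool(best.success),
        n_trials=len(kept_trials),
        design=design,
    )


# ---------------------------------------------------------------------------
# Trial-history summary statistics


def _consecutive_ok(trials: Sequence[TrialRecord], i: int, j: int) -> bool:
    a, b = trials[i], trials[j]
    return (
        a.mouse_id == b.mouse_id
        and a.session_id == b.session_id
        and b.trial_index - a.trial_index == j - i
    )


def alternation_bias(
    trials: Sequence[TrialRecord],
    condition: str = "post_reward",
    lag: int = 1,
    run_length: int = 1,
) -> float:
    """Alternation bias (%) for a history condition.

    Bias = P(choice opposite to the reference trial t0 | condition) minus the
    unconditional alternation percentage at the same lag.  Conditions:
    ``post_reward`` / ``post_error`` (t0 rewarded / not), and
    ``run_rewarded`` / ``run_unrewarded`` (t0 ends a run of ``run_length``
    identical rewarded / unrewarded choices).  Positive = alternation,
    negative = perseveration.
    """
    n = len(trials)
    alternate_all: list[bool] = []
    alternate_cond: list[bool] = []
    for i in range(n - lag):
        j = i + lag
        if not _consecutive_ok(trials, i, j):
            continue
        t0, tj = trials[i], trials[j]
        alt = tj.choice != t0.choice
        alternate_all.append(alt)
        if condition == "post_reward":
            if t0.correct:
                alternate_cond.append(alt)
        elif condition == "post_error":
            if not t0.correct:
                alternate_cond.append(alt)
        elif condition in ("run_rewarded", "run_unrewarded"):
            want_correct = condition == "run_rewarded"
            ok = t0.correct == want_correct
            for back in range(1, run_length):
                if i - back < 0 or not _consecutive_ok(trials, i - back, i):
                    ok = False
                    break
                tb = trials[i - back]
                if tb.choice != t0.choice or tb.correct != want_correct:
                    ok = False
                    break
            if ok:
                alternate_cond.append(alt)
        else:
            raise ValidationError(f"unknown condition {condition!r}")
    if not alternate_cond:
        raise UndefinedStatisticError(f"no trials satisfy condition {condition!r}")
    return 100.0 * (np.mean(alternate_cond) - np.mean(alternate_all))


def perseveration_run_mask(trials: Sequence[TrialRecord], run_len: int = 3) -> np.ndarray:
    """True for trials inside runs of >= run_len identical consecutive choices."""
    n = len(trials)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and trials[j + 1].choice == trials[i].choice
            and _consecutive_ok(trials, j, j + 1)
        ):
            j += 1
        if j - i + 1 >= run_len:
            mask[i : j + 1] = True
        i = j + 1
    return mask


def psychometric_excluding_perseveration(trials: Sequence[TrialRecord], run_len: int = 3):
    """Refit the psychometric after dropping perseveration bouts."""
    from .psychometrics import fit_psychometric

    mask = perseveration_run_mask(trials, run_len)
    kept = [t for t, m in zip(trials, mask) if not m]
    if not kept:
        raise NoTrialsError("perseveration exclusion removed every trial")
    return fit_psychometric(kept)


def fixed_total_linearity_test(
    trials: Sequence[TrialRecord],
    total: int = 12,
    n_null: int = 1000,
    rng: Optional[np.random.Generator] = None,
    min_trials: int = 200,
) -> tuple[float, float]:
    """Permutation-style test of the one-random-tower line at fixed #R + #L.

    Under the one-random-tower strategy, p_R at fixed total is linear in
    delta: p = #R/total.  The statistic is the sum over delta levels of the
    squared deviation of the observed right-choice fraction from that line;
    the null distribution is built by simulating choices from the line model
    at the observed per-level trial counts.  Returns (statistic, p-value).
    """
    rng = rng or np.random.default_rng(0)
    subset = [t for t in trials if t.n_left + t.n_right == total]
    if len(subset) < min_trials:
        raise NoTrialsError(
            f"only {len(subset)} trials at total={total}; need {min_trials}"
        )
    deltas = np.array([t.delta for t in subset])
    choices = np.array([1.0 if t.choice == "R" else 0.0 for t in subset])
    levels = np.unique(deltas)
    n_lv = np.array([(deltas == d).sum() for d in levels])
    obs_p = np.array([choices[deltas == d].mean() for d in levels])
    line_p = np.array([(d + total) / (2.0 * total) for d in levels])  # #R/total
    stat = float(np.sum((obs_p - line_p) ** 2))
    null = np.empty(n_null)
    for b in range(n_null):
        sim_p = rng.binomial(n_lv, line_p) / n_lv
        null[b] = np.sum((sim_p - line_p) ** 2)
    p_value = float(np.mean(null >= stat - 1e-15))
    return stat, p_value
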