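"""Spatial-bin logistic regression of choice on net evidence.

Choice is regressed on the net evidence (#R - #L) in each of five equal
segments of the cue region between 10 and 200 cm.  The late/early ratio of
fitted weights quantifies recency (> 1) or primacy (< 1); its significance
comes from refits with per-trial shuffled bin identities, and coefficient
errors from bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.optimize import minimize

from .datamodel import TrialRecord, UndefinedStatisticError

N_BINS = 5
BIN_EDGES_CM = np.linspace(10.0, 200.0, N_BINS + 1)


def spatial_bin_index(position_cm: float) -> int:
    """Bin 0-4 for a tower position; bins are [lo, hi), last bin closed."""
    idx = int(np.searchsorted(BIN_EDGES_CM, position_cm, side="right")) - 1
    return min(max(idx, 0), N_BINS - 1)


def spatial_evidence_matrix(trials: Sequence[TrialRecord]) -> np.ndarray:
    """(n_trials, 5) matrix of per-bin net evidence #R - #L."""
    X = np.zeros((len(trials), N_BINS))
    for i, t in enumerate(trials):
        for y in t.towers_right:
            X[i, spatial_bin_index(y)] += 1
        for y in t.towers_left:
            X[i, spatial_bin_index(y)] -= 1
    return X


def _logistic_mle(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, bool]:
    """Plain Newton/quasi-Newton logistic MLE with optional tiny ridge.

    Returns (coefficients incl. intercept first, separation_flag).  On
    (quasi-)complete separation the unregularized MLE diverges; that is
    detected by exploding coefficients and retried with a small ridge.
    """
    Xd = np.column_stack([np.ones(len(y)), X])

    def nll(b):
        z = Xd @ b
        # log(1 + e^z) - y z, numerically stable
        return float(np.sum(np.logaddexp(0.0, z) - y * z) + 0.5 * ridge * np.sum(b**2))

    def grad(b):
        p = 1.0 / (1.0 + np.exp(-(Xd @ b)))
        return Xd.T @ (p - y) + ridge * b

    res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="L-BFGS-B")
    beta = res.x
    separated = bool(np.max(np.abs(beta)) > 30.0)
    if separated and ridge == 0.0:
        warnings.warn("possible separation; refitting with ridge 1e-6", stacklevel=2)
        beta, _ = _logistic_mle(X, y, ridge=1e-6)
    return beta, separated


@dataclass
class SpatialLogisticFit:
    """Fitted spatial-bin logistic model: intercept, 5 weights, bootstrap SDs."""

    beta0: float
    beta: np.ndarray
    beta0_sd: float
    beta_sd: np.ndarray
    n_trials: int
    separated: bool

    def predict_pR(self, trials: Sequence[TrialRecord]) -> np.ndarray:
        X = spatial_evidence_matrix(trials)
        z = self.beta0 + X @ self.beta
        return 1.0 / (1.0 + np.exp(-z))


def fit_spatial_logistic(
    trials: Sequence[TrialRecord],
    n_boot: int = 200,
    rng: Optional[np.random.Generator] = None,
    warn_below: int = 500,
) -> SpatialLogisticFit:
    """Maximum-likelihood logistic fit of choice on per-bin net evidence.

    Coefficient SDs come from ``n_boot`` bootstrap resamples of the trials
    (sampling with replacement, refitting each time).
    """
    if len(trials) < warn_below:
        warnings.warn(f"only {len(trials)} trials; weights will be noisy", stacklevel=2)
    rng = rng or np.random.default_rng(0)
    X = spatial_evidence_matrix(trials)
    y = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    beta, separated = _logistic_mle(X, y)
    boots = np.empty((n_boot, N_BINS + 1))
    n = len(trials)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], _ = _logistic_mle(X[idx], y[idx])
    sds = boots.std(axis=0, ddof=1)
    return SpatialLogisticFit(
        beta0=float(beta[0]),
        beta=beta[1:].copy(),
        beta0_sd=float(sds[0]),
        beta_sd=sds[1:].copy(),
        n_trials=n,
        separated=separated,
    )


def decay_ratio_from_weights(beta: np.ndarray) -> float:
    """Late/early weight ratio: mean(beta4, beta5) / mean(beta1, beta2)."""
    early = 0.5 * (beta[0] + beta[1])
    late = 0.5 * (beta[3] + beta[4])
    if early <= 0:
        raise UndefinedStatisticError("early-bin mean weight <= 0; ratio undefined")
    return late / early


def weight_decay_ratio(
    fit: SpatialLogisticFit,
    trials: Sequence[TrialRecord],
    n_shuffle: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Decay ratio and its shuffle p-value.

    The null permutes each trial's five bin evidences (destroying any spatial
    structure while preserving the trial's evidence multiset), refits, and
    recomputes the ratio; p is the fraction of null ratios smaller than the
    observed one (small p = significant primacy).
    """
    rng = rng or np.random.default_rng(0)
    ratio = decay_ratio_from_weights(fit.beta)
    X = spatial_evidence_matrix(trials)
    y = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    n = len(trials)
    null = []
    for _ in range(n_shuffle):
        Xs = X.copy()
        for i in range(n):
            rng.shuffle(Xs[i])
        beta, _ = _logistic_mle(Xs, y)
        try:
            null.append(decay_ratio_from_weights(beta[1:]))
        except UndefinedStatisticError:
            continue
    if not null:
        raise UndefinedStatisticError("all shuffle refits had non-positive early weights")
    p = float(np.mean(np.array(null) < ratio))
    return ratio, p


def minority_cue_profile(trials: Sequence[TrialRecord]):
    """Percent of trials with >= 1 minority cue per spatial bin, by outcome.

    Returns a dict with per-bin percentages for correct and error trials, the
    correct-minus-error difference, and the per-outcome trial counts.  The
    minority side is the non-rewarded side.
    """
    has_minority = {"correct": np.zeros((0, N_BINS)), "error": np.zeros((0, N_BINS))}
    rows = {"correct": [], "error": []}
    for t in trials:
        minority_towers = t.towers_left if t.rewarded_side == "R" else t.towers_right
        row = np.zeros(N_BINS)
        for y in minority_towers:
            row[spatial_bin_index(y)] = 1.0
        rows["correct" if t.correct else "error"].append(row)
    out = {}
    for outcome in ("correct", "error"):
        if not rows[outcome]:
            out[outcome] = None
            continue
        arr = np.array(rows[outcome])
        out[outcome] = 100.0 * arr.mean(axis=0)
        out[f"n_{outcome}"] = len(rows[outcome])
    if out["correct"] is not None and out["error"] is not None:
        out["difference"] = out["error"] - out["correct"]
    else:
        out["difference"] = None
    return out
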