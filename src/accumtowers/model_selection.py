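"""Cross-validation, model-information scoring, and multiple-comparison rules.

Models are compared by cross-validated model information (MI): the excess
Bernoulli log likelihood of held-out choices over a trivial constant-rate
model, converted to bits per trial,

    MI = (ln L - ln L0) / (n_trials * ln 2)

where ln L0 uses the training-set right-choice fraction f_R.  The default
scheme is 70 runs of 3-fold cross-validation with fold assignments shared
across models, per-mouse medians over the 210 fold-evaluations, and paired
run-proportion p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from .datamodel import TrialRecord, ValidationError


def model_information(ln_l: float, ln_l0: float, n_trials: int) -> float:
    """Excess log likelihood over the trivial model in bits/trial."""
    if n_trials <= 0:
        raise ValidationError("n_trials must be positive")
    return (ln_l - ln_l0) / (n_trials * math.log(2.0))


class ChoiceModel(Protocol):
    """Anything fittable on trials that then predicts per-trial p(choice = R)."""

    def fit(self, trials: Sequence[TrialRecord]) -> "FittedChoiceModel": ...


class FittedChoiceModel(Protocol):
    def predict_pR(self, trials: Sequence[TrialRecord]) -> np.ndarray: ...


@dataclass
class CVScheme:
    """Seeded fold assignments, identical for every model evaluated.

    ``assignments(n)`` returns an (n_runs, n) array of fold labels; each
    run's labels partition the trials into ``n_folds`` near-equal folds.
    Trials are assigned i.i.d. (history features are precomputed on the full
    sequence before splitting, so per-trial predictions are independent).
    """

    n_runs: int = 70
    n_folds: int = 3
    seed: int = 0

    def assignments(self, n_trials: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        out = np.empty((self.n_runs, n_trials), dtype=int)
        base = np.arange(n_trials) % self.n_folds
        for r in range(self.n_runs):
            out[r] = base[rng.permutation(n_trials)]
        return out


@dataclass
class ModelEvaluation:
    """Per fold-evaluation scores of one model under a CV scheme."""

    name: str
    fold_loglik: np.ndarray  # (n_runs, n_folds) test-set ln L
    fold_loglik0: np.ndarray
    fold_n: np.ndarray
    fold_mi: np.ndarray
    failed_folds: np.ndarray  # boolean mask of folds where fit/predict failed

    @property
    def median_mi(self) -> float:
        ok = ~self.failed_folds
        return float(np.median(self.fold_mi[ok]))


def _bernoulli_loglik(p: np.ndarray, choices: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(choices * np.log(p) + (1 - choices) * np.log(1 - p)))


def crossval_evaluate(
    models: dict,
    trials: Sequence[TrialRecord],
    scheme: Optional[CVScheme] = None,
) -> dict:
    """Evaluate every model on identical CV subsamples; returns name -> evaluation.

    Per run and fold, each model is fitted on the training 2/3 and scored on
    the held-out 1/3; the reference f_R for ln L0 is computed on the training
    fold (no leakage).  A model failure on a fold flags that fold for every
    model so paired comparisons stay paired.
    """
    scheme = scheme or CVScheme()
    trials = list(trials)
    n = len(trials)
    labels = scheme.assignments(n)
    choices = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    shape = (scheme.n_runs, scheme.n_folds)
    evals = {
        name: ModelEvaluation(
            name=name,
            fold_loglik=np.zeros(shape),
            fold_loglik0=np.zeros(shape),
            fold_n=np.zeros(shape, dtype=int),
            fold_mi=np.zeros(shape),
            failed_folds=np.zeros(shape, dtype=bool),
        )
        for name in models
    }
    for r in range(scheme.n_runs):
        for f in range(scheme.n_folds):
            test_mask = labels[r] == f
            train_idx = np.where(~test_mask)[0]
            test_idx = np.where(test_mask)[0]
            train = [trials[i] for i in train_idx]
            test = [trials[i] for i in test_idx]
            f_r = float(np.clip(choices[train_idx].mean(), 1e-12, 1 - 1e-12))
            ln_l0 = _bernoulli_loglik(np.full(len(test_idx), f_r), choices[test_idx])
            fold_failed = False
            fold_ll = {}
            for name, model in models.items():
                try:
                    fitted = model.fit(train)
                    p = np.asarray(fitted.predict_pR(test), dtype=float)
                    fold_ll[name] = _bernoulli_loglik(p, choices[test_idx])
                except Exception:
                    fold_failed = True
                    fold_ll[name] = np.nan
            for name in models:
                ev = evals[name]
                ev.fold_loglik[r, f] = fold_ll[name]
                ev.fold_loglik0[r, f] = ln_l0
                ev.fold_n[r, f] = len(test_idx)
                ev.failed_folds[r, f] = fold_failed
                if not fold_failed:
                    ev.fold_mi[r, f] = model_information(fold_ll[name], ln_l0, len(test_idx))
                else:
                    ev.fold_mi[r, f] = np.nan
    return evals


def pairwise_run_p(eval_a: ModelEvaluation, eval_b: ModelEvaluation) -> float:
    """Proportion of shared fold-evaluations where model A underperforms B.

    Ties count half toward each, so a model against itself scores 0.5.
    Failed folds (for either model) are excluded pairwise.
    """
    ok = ~(eval_a.failed_folds | eval_b.failed_folds)
    a = eval_a.fold_mi[ok]
    b = eval_b.fold_mi[ok]
    if a.size == 0:
        raise ValidationError("no shared successful folds")
    return float(np.mean(a < b) + 0.5 * np.mean(a == b))


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05, stepup: bool = False) -> np.ndarray:
    """Benjamini-Hochberg significance flags, in the input order.

    Default is the literal per-rank rule: the i-th smallest p is significant
    iff P_(i) <= alpha * i / n.  ``stepup=True`` applies the canonical
    step-up sweep instead (every p up to the largest passing rank flagged).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if stepup:
        if np.any(passed):
            k = int(np.max(np.where(passed)[0]))
            flags[order[: k + 1]] = True
    else:
        flags[order] = passed
    return flags


# Convenience wrappers so library fits plug into crossval_evaluate directly.


@dataclass
class ConstantRateModel:
    """The trivial model: constant P(R) = training-set right fraction."""

    def fit(self, trials: Sequence[TrialRecord]) -> "ConstantRateModel._Fitted":
        f_r = float(np.mean([t.choice == "R" for t in trials]))
        return ConstantRateModel._Fitted(f_r)

    @dataclass
    class _Fitted:
        f_r: float

        def predict_pR(self, trials: Sequence[TrialRecord]) -> np.ndarray:
            return np.full(len(trials), np.clip(self.f_r, 1e-12, 1 - 1e-12))


@dataclass
class OracleModel:
    """Predicts from a supplied per-trial probability table (tests/benchmarks)."""

    table: dict  # (mouse_id, session_id, trial_index) -> p_R

    def fit(self, trials: Sequence[TrialRecord]) -> "OracleModel":
        return self

    def predict_pR(self, trials: Sequence[TrialRecord]) -> np.ndarray:
        return np.array(
            [self.table[(t.mouse_id, t.session_id, t.trial_index)] for t in trials]
        )
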