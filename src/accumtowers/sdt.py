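"""Signal-detection counting model of tower-count comparison.

Each side's perceived count is Gaussian around the true count with a
count-dependent standard deviation; the probability of a correct choice on a
trial with larger count L and smaller count S is

    p_c = Phi((L - S) / sqrt(sigma_L^2 + sigma_S^2))

the closed form of the difference-of-Gaussians integral.  The full model
fits one sigma_T per count T = 0..15; the two-parameter variants tie them to
a scaling law: scalar variability sigma(n) = b0 + b1 n, or linear variance
sigma^2(n) = b0 + b1 n.  Trials with 16+ towers on a side are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .datamodel import TrialRecord, ValidationError, NoTrialsError
from .model_selection import model_information

MAX_COUNT = 15
SIGMA_FLOOR = 1e-3
FORMS = ("full", "scalar", "linear_variance")


def sdt_trial_pc(L: int, S: int, sigma_L: float, sigma_S: float) -> float:
    """Probability correct for larger/smaller counts L >= S with their sigmas."""
    if S > L or S < 0:
        raise ValidationError("require L >= S >= 0")
    if sigma_L <= 0 or sigma_S <= 0:
        raise ValidationError("sigmas must be positive")
    return float(norm.cdf((L - S) / np.hypot(sigma_L, sigma_S)))


def sigma_from_law(form: str, b0: float, b1: float, counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if form == "scalar":
        s = b0 + b1 * counts
    elif form == "linear_variance":
        s = np.sqrt(np.maximum(b0 + b1 * counts, 0.0))
    else:
        raise ValidationError(f"unknown two-parameter form {form!r}")
    return np.maximum(s, SIGMA_FLOOR)


@dataclass
class SDTCounts:
    """Aggregated trial outcomes by (larger count, smaller count)."""

    L: np.ndarray
    S: np.ndarray
    n_correct: np.ndarray
    n_error: np.ndarray
    n_right_choices: int
    n_trials: int
    n_excluded: int


def aggregate_counts(trials: Sequence[TrialRecord]) -> SDTCounts:
    cells: dict[tuple[int, int], list[int]] = {}
    n_right = 0
    n_used = 0
    n_excluded = 0
    for t in trials:
        if t.n_left > MAX_COUNT or t.n_right > MAX_COUNT:
            n_excluded += 1
            continue
        L, S = max(t.n_left, t.n_right), min(t.n_left, t.n_right)
        c = cells.setdefault((L, S), [0, 0])
        c[0 if t.correct else 1] += 1
        n_right += t.choice == "R"
        n_used += 1
    if not cells:
        raise NoTrialsError("no trials with counts <= 15 per side")
    keys = sorted(cells)
    return SDTCounts(
        L=np.array([k[0] for k in keys]),
        S=np.array([k[1] for k in keys]),
        n_correct=np.array([cells[k][0] for k in keys]),
        n_error=np.array([cells[k][1] for k in keys]),
        n_right_choices=n_right,
        n_trials=n_used,
        n_excluded=n_excluded,
    )


def loglik_from_sigmas(counts: SDTCounts, sigma_by_count: np.ndarray) -> float:
    """Choice log likelihood with sigma_T looked up per side count."""
    s = np.maximum(np.asarray(sigma_by_count, dtype=float), SIGMA_FLOOR)
    z = (counts.L - counts.S) / np.hypot(s[counts.L], s[counts.S])
    pc = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
    return float(np.sum(counts.n_correct * np.log(pc) + counts.n_error * np.log(1 - pc)))


@dataclass
class SDTFit:
    form: str
    sigma_by_count: np.ndarray  # length 16, derived from the law for 2-param forms
    b0: Optional[float]
    b1: Optional[float]
    loglik: float
    mi: float
    n_trials: int
    converged: bool
    floored: bool


def _reference_loglik(counts: SDTCounts) -> float:
    f_r = np.clip(counts.n_right_choices / counts.n_trials, 1e-12, 1 - 1e-12)
    n_r = counts.n_right_choices
    n_l = counts.n_trials - n_r
    return float(n_r * np.log(f_r) + n_l * np.log(1 - f_r))


def fit_sdt(
    trials_or_counts,
    form: str = "full",
    n_starts: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> SDTFit:
    """Constrained MLE of the SDT model in one of its three forms.

    The full form needs aggregate (metamouse) data for stable per-count
    sigmas; the two-parameter forms are also usable per mouse.  b0 >= 0 is
    enforced; sigmas are floored at a small positive value, and a fit that
    lands on the floor is flagged.
    """
    if form not in FORMS:
        raise ValidationError(f"form must be one of {FORMS}")
    rng = rng or np.random.default_rng(0)
    counts = (
        trials_or_counts
        if isinstance(trials_or_counts, SDTCounts)
        else aggregate_counts(trials_or_counts)
    )
    ln_l0 = _reference_loglik(counts)
    present = np.union1d(counts.L, counts.S)

    if form == "full":
        def negll(log_s: np.ndarray) -> float:
            return -loglik_from_sigmas(counts, np.exp(log_s))

        best = None
        for s in range(n_starts):
            x0 = np.log(0.5 + 0.3 * np.arange(MAX_COUNT + 1))
            if s > 0:
                x0 = x0 + rng.normal(0, 0.3, size=len(x0))
            res = minimize(negll, x0, method="L-BFGS-B",
                           bounds=[(np.log(SIGMA_FLOOR), np.log(100.0))] * (MAX_COUNT + 1))
            if best is None or res.fun < best.fun:
                best = res
        sigmas = np.exp(best.x)
        ll = -float(best.fun)
        floored = bool(np.any(sigmas[present] <= SIGMA_FLOOR * 1.01))
        if floored:
            warnings.warn("fitted sigma at floor: near-noiseless data", stacklevel=2)
        return SDTFit(
            form="full", sigma_by_count=sigmas, b0=None, b1=None, loglik=ll,
            mi=model_information(ll, ln_l0, counts.n_trials),
            n_trials=counts.n_trials, converged=bool(best.success), floored=floored,
        )

    def negll2(x: np.ndarray) -> float:
        s = sigma_from_law(form, x[0], x[1], np.arange(MAX_COUNT + 1))
        return -loglik_from_sigmas(counts, s)

    best = None
    for s in range(n_starts):
        x0 = np.array([0.5, 0.3]) if s == 0 else np.abs(rng.normal([0.5, 0.3], [0.5, 0.3]))
        res = minimize(negll2, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    b0 = max(float(best.x[0]), 0.0)
    b1 = float(best.x[1])
    sigmas = sigma_from_law(form, b0, b1, np.arange(MAX_COUNT + 1))
    ll = loglik_from_sigmas(counts, sigmas)
    floored = bool(np.any(sigmas[present] <= SIGMA_FLOOR * 1.01))
    if floored:
        warnings.warn("fitted sigma at floor: near-noiseless data", stacklevel=2)
    return SDTFit(
        form=form, sigma_by_count=sigmas, b0=b0, b1=b1, loglik=ll,
        mi=model_information(ll, ln_l0, counts.n_trials),
        n_trials=counts.n_trials, converged=bool(best.success), floored=floored,
    )


def compare_scaling_laws(
    trials: Sequence[TrialRecord],
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Bootstrap comparison of scalar variability vs linear variance.

    Trials are resampled with replacement ``n_boot`` times; per replicate
    both two-parameter laws are refit and compared by model information.
    Returns the proportion of replicates each law wins (ties split) — the
    linear-variance winning proportion doubles as the significance of the
    scalar-variability claim.
    """
    rng = rng or np.random.default_rng(0)
    usable = [t for t in trials if t.n_left <= MAX_COUNT and t.n_right <= MAX_COUNT]
    if not usable:
        raise NoTrialsError("no trials usable for the SDT comparison")
    n = len(usable)
    scalar_wins = 0.0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [usable[i] for i in idx]
        counts = aggregate_counts(sample)
        mi_s = fit_sdt(counts, "scalar", n_starts=1).mi
        mi_v = fit_sdt(counts, "linear_variance", n_starts=1).mi
        if mi_s > mi_v:
            scalar_wins += 1.0
        elif mi_s == mi_v:
            scalar_wins += 0.5
    p_scalar = scalar_wins / n_boot
    return {
        "scalar_win_proportion": p_scalar,
        "linear_variance_win_proportion": 1.0 - p_scalar,
        "n_boot": n_boot,
        "n_trials": n,
    }
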