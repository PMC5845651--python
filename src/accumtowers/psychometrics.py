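"""Psychometric curves, lapse rates, block-selection surrogate tests, and the
performance-vs-factors linear model.

The psychometric function is a 4-parameter sigmoid
``p_R = b + a / (1 + exp(-(delta - delta0) / lam))`` fitted to per-bin
right-choice proportions (delta = #R - #L binned in groups of three unique
values, abscissa the trial-weighted mean).  Its slope at the midpoint is
``a / (4 lam)`` and the lapse rate is the error percentage on easy trials
(|delta| >= 10).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import beta as beta_dist, wilcoxon

from .datamodel import (
    TrialRecord,
    NoTrialsError,
    UndefinedStatisticError,
    iter_blocks,
    effective_durations,
)

LAPSE_DELTA_THRESHOLD = 10


def jeffreys_interval(k: int, n: int) -> tuple[float, float]:
    """Equal-tailed 1-sigma (68.27%) Jeffreys interval for a binomial fraction."""
    lo_q, hi_q = 0.158655, 0.841345
    lo = float(beta_dist.ppf(lo_q, k + 0.5, n - k + 0.5))
    hi = float(beta_dist.ppf(hi_q, k + 0.5, n - k + 0.5))
    return lo, hi


@dataclass
class DeltaBins:
    """Binned psychometric data: one row per bin of ~3 unique delta values."""

    abscissa: np.ndarray  # trial-weighted mean delta per bin
    p_right: np.ndarray
    n: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def bin_delta(trials: Sequence[TrialRecord], group_size: int = 3) -> DeltaBins:
    """Group sorted unique delta values in consecutive triplets.

    The bin abscissa is the mean delta weighted by trial count.  Grouping
    runs over unique values (not raw deltas), so a mirror-symmetric dataset
    with a multiple-of-three number of unique deltas yields bins that are
    antisymmetric about zero.
    """
    if not trials:
        raise NoTrialsError("no trials to bin")
    deltas = np.array([t.delta for t in trials])
    choices = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    uniq = np.unique(deltas)
    groups = [uniq[i : i + group_size] for i in range(0, len(uniq), group_size)]
    absc, pr, ns, lo, hi = [], [], [], [], []
    for g in groups:
        mask = np.isin(deltas, g)
        n = int(mask.sum())
        k = int(choices[mask].sum())
        absc.append(float(np.average(deltas[mask])))
        pr.append(k / n)
        ns.append(n)
        l, h = jeffreys_interval(k, n)
        lo.append(l)
        hi.append(h)
    return DeltaBins(
        abscissa=np.array(absc),
        p_right=np.array(pr),
        n=np.array(ns),
        ci_low=np.array(lo),
        ci_high=np.array(hi),
    )


def _sigmoid(delta, b, a, delta0, lam):
    return b + a / (1.0 + np.exp(-(delta - delta0) / lam))


@dataclass
class PsychometricFit:
    """4-parameter sigmoid fit; ``lam_sig`` is the sigmoid scale parameter."""

    b: float
    a: float
    delta0: float
    lam_sig: float
    bins: DeltaBins
    converged: bool
    n_trials: int

    @property
    def slope(self) -> float:
        """Derivative of the sigmoid at its midpoint, a / (4 lam)."""
        return self.a / (4.0 * self.lam_sig)

    @property
    def slope_percent_per_tower(self) -> float:
        return 100.0 * self.slope

    def predict(self, delta: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(delta, dtype=float), self.b, self.a, self.delta0, self.lam_sig)


LAM_FLOOR = 1e-2  # sigmoid scale floor; hitting it flags a step-like fit


def fit_psychometric(
    trials_or_bins, n_trials: Optional[int] = None
) -> PsychometricFit:
    """Weighted least-squares fit of the 4-parameter sigmoid to binned data.

    Accepts trials (binned internally) or a :class:`DeltaBins`.  Per-bin
    binomial weights; bounds keep ``b`` and ``b + a`` interpretable as lower
    and upper asymptotes.  Degenerate, step-like data pin ``lam_sig`` at a
    small floor and flag the fit instead of failing.
    """
    if isinstance(trials_or_bins, DeltaBins):
        bins = trials_or_bins
        n_total = int(bins.n.sum()) if n_trials is None else n_trials
    else:
        trials = list(trials_or_bins)
        bins = bin_delta(trials)
        n_total = len(trials)
    if len(bins.abscissa) < 4 or bins.abscissa.min() >= 0 or bins.abscissa.max() <= 0:
        warnings.warn("fewer than 4 bins spanning both signs of delta", stacklevel=2)
    p = bins.p_right
    sigma = np.sqrt(np.maximum(p * (1 - p), 0.25 / bins.n) / bins.n)
    lower = [0.0, 0.0, -15.0, LAM_FLOOR]
    upper = [0.5, 1.0, 15.0, 50.0]
    p0 = [max(min(p.min(), 0.45), 0.0), min(max(p.max() - p.min(), 0.1), 1.0), 0.0, 2.0]
    converged = True
    try:
        popt, _ = curve_fit(
            _sigmoid,
            bins.abscissa,
            p,
            p0=p0,
            sigma=sigma,
            bounds=(lower, upper),
            maxfev=10000,
        )
    except RuntimeError:
        warnings.warn("psychometric fit did not converge; returning flagged fit", stacklevel=2)
        popt = p0
        converged = False
    b, a, d0, lam = (float(v) for v in popt)
    # step-like data: every bin sits at an asymptote, so the scale is only
    # bounded above by the bin spacing and the slope is large-finite
    step_like = a > 0 and bool(
        np.all((p <= b + 0.02 * a + 1e-9) | (p >= b + 0.98 * a - 1e-9))
    )
    if lam <= LAM_FLOOR * 1.01 or step_like:
        warnings.warn(
            "step-like psychometric data: scale unresolved below bin spacing, "
            "slope is large-finite",
            stacklevel=2,
        )
        converged = False
    return PsychometricFit(
        b=b, a=a, delta0=d0, lam_sig=lam, bins=bins, converged=converged, n_trials=n_total
    )


def lapse_rate(trials: Sequence[TrialRecord]) -> tuple[float, tuple[float, float]]:
    """Error percentage among easy trials (|delta| >= 10) with Jeffreys interval."""
    easy = [t for t in trials if abs(t.delta) >= LAPSE_DELTA_THRESHOLD]
    if not easy:
        raise UndefinedStatisticError("no trials with |delta| >= 10; lapse undefined")
    k = sum(not t.correct for t in easy)
    n = len(easy)
    lo, hi = jeffreys_interval(k, n)
    return 100.0 * k / n, (100.0 * lo, 100.0 * hi)


# ---------------------------------------------------------------------------
# Surrogate top-block test


def _top_block_stats(trials: Sequence[TrialRecord], top_fraction: float, min_trials: int):
    """(slope, lapse) restricted to the best-performing fraction of blocks.

    Blocks are ranked by accuracy, ties broken by block length then block
    order (deterministic).  Returns None when fewer than ``min_trials``
    trials survive the selection.
    """
    blocks = iter_blocks(trials)
    scored = []
    for order, idxs in enumerate(blocks):
        acc = sum(trials[i].correct for i in idxs) / len(idxs)
        scored.append((acc, len(idxs), -order, idxs))
    scored.sort(reverse=True)
    n_top = max(1, math.ceil(top_fraction * len(blocks)))
    chosen: list[int] = []
    for _, _, _, idxs in scored[:n_top]:
        chosen.extend(idxs)
    if len(chosen) < min_trials:
        return None
    top_trials = [trials[i] for i in sorted(chosen)]
    fit = fit_psychometric(top_trials)
    lapse, _ = lapse_rate(top_trials)
    return fit.slope_percent_per_tower, lapse


@dataclass
class SurrogateTestResult:
    per_mouse: dict  # mouse -> dict with observed/surrogate improvements and p-values
    population_p_slope: Optional[float]
    population_p_lapse: Optional[float]
    excluded_mice: list


def surrogate_top_block_test(
    trials: Sequence[TrialRecord],
    n_surrogates: int = 200,
    top_fraction: float = 0.10,
    min_trials: int = 300,
    rng: Optional[np.random.Generator] = None,
) -> SurrogateTestResult:
    """Does top-block selection improve slope/lapse beyond static-curve sampling?

    For each mouse a static psychometric curve is fitted to all its trials.
    Each surrogate redraws every outcome from that curve at the experienced
    deltas, reselects the top fraction of blocks, and recomputes the slope
    and lapse improvements over the full dataset.  The per-mouse p-value is
    the fraction of surrogates whose improvement meets or exceeds the
    observed one; the population comparison is a one-sided signed-rank test
    of observed vs mean-surrogate improvements across mice.
    """
    rng = rng or np.random.default_rng(0)
    mice = sorted({t.mouse_id for t in trials})
    per_mouse = {}
    excluded = []
    obs_impr_slope, obs_impr_lapse = [], []
    sur_impr_slope, sur_impr_lapse = [], []
    for mouse in mice:
        mt = [t for t in trials if t.mouse_id == mouse]
        static = fit_psychometric(mt)
        full_slope = static.slope_percent_per_tower
        full_lapse, _ = lapse_rate(mt)
        top = _top_block_stats(mt, top_fraction, min_trials)
        if top is None:
            excluded.append(mouse)
            continue
        obs_slope_impr = top[0] - full_slope
        obs_lapse_impr = full_lapse - top[1]
        deltas = np.array([t.delta for t in mt])
        p_curve = np.clip(static.predict(deltas), 1e-6, 1 - 1e-6)
        s_slopes, s_lapses = [], []
        for _ in range(n_surrogates):
            sim_choice_r = rng.uniform(size=len(mt)) < p_curve
            sim_trials = []
            for t, r in zip(mt, sim_choice_r):
                choice = "R" if r else "L"
                outcome = "correct" if choice == t.rewarded_side else "error"
                sim_trials.append(dc_replace(t, choice=choice, outcome=outcome))
            sim_full = fit_psychometric(sim_trials)
            sim_full_lapse, _ = lapse_rate(sim_trials)
            sim_top = _top_block_stats(sim_trials, top_fraction, min_trials)
            if sim_top is None:
                continue
            s_slopes.append(sim_top[0] - sim_full.slope_percent_per_tower)
            s_lapses.append(sim_full_lapse - sim_top[1])
        if not s_slopes:
            excluded.append(mouse)
            continue
        s_slopes_arr = np.array(s_slopes)
        s_lapses_arr = np.array(s_lapses)
        per_mouse[mouse] = {
            "observed_slope_improvement": obs_slope_impr,
            "observed_lapse_improvement": obs_lapse_impr,
            "surrogate_slope_improvement_mean": float(s_slopes_arr.mean()),
            "surrogate_lapse_improvement_mean": float(s_lapses_arr.mean()),
            "p_slope": float(np.mean(s_slopes_arr >= obs_slope_impr)),
            "p_lapse": float(np.mean(s_lapses_arr >= obs_lapse_impr)),
        }
        obs_impr_slope.append(obs_slope_impr)
        obs_impr_lapse.append(obs_lapse_impr)
        sur_impr_slope.append(float(s_slopes_arr.mean()))
        sur_impr_lapse.append(float(s_lapses_arr.mean()))
    pop_p_slope = pop_p_lapse = None
    if len(obs_impr_slope) >= 5:
        d_slope = np.array(obs_impr_slope) - np.array(sur_impr_slope)
        d_lapse = np.array(obs_impr_lapse) - np.array(sur_impr_lapse)
        if np.any(d_slope != 0):
            pop_p_slope = float(wilcoxon(d_slope, alternative="greater").pvalue)
        if np.any(d_lapse != 0):
            pop_p_lapse = float(wilcoxon(d_lapse, alternative="greater").pvalue)
    return SurrogateTestResult(
        per_mouse=per_mouse,
        population_p_slope=pop_p_slope,
        population_p_lapse=pop_p_lapse,
        excluded_mice=excluded,
    )


# ---------------------------------------------------------------------------
# Performance vs |delta|, total towers, duration


@dataclass
class PerformanceFactorsFit:
    coefficients: np.ndarray  # |delta|, total towers, duration
    t_stats: np.ndarray
    p_values: np.ndarray
    dof: int
    n_points: int
    table: "np.ndarray"
    single_mouse: bool


def _factor_bins(trial: TrialRecord, duration: str) -> tuple[int, int, int]:
    adelta = abs(trial.delta) // 2  # groups of two
    total = (trial.n_left + trial.n_right) // 2
    cue_dur, delay_dur = effective_durations(trial)
    dur = cue_dur if duration == "cue" else delay_dur
    return int(adelta), int(total), int(dur // 10)  # 10-cm duration bins


def performance_factors(
    trials: Sequence[TrialRecord], duration: str = "cue"
) -> PerformanceFactorsFit:
    """3-parameter linear model of performance vs |delta|, total towers, duration.

    Per mouse, percent-correct is computed for every 3-way combination of the
    binned predictors and mean-subtracted; cells are then averaged across
    mice and fit with a 3-predictor linear regression (plus intercept, which
    is ~0 after mean subtraction).  Significance uses the coefficient
    t-statistic with n - p - 1 degrees of freedom.
    """
    mice = sorted({t.mouse_id for t in trials})
    single_mouse = len(mice) < 2
    if single_mouse:
        warnings.warn("single-mouse path: no across-mice averaging", stacklevel=2)
    cell_values: dict[tuple[int, int, int], list[float]] = {}
    for mouse in mice:
        mt = [t for t in trials if t.mouse_id == mouse]
        per_cell: dict[tuple[int, int, int], list[bool]] = {}
        for t in mt:
            try:
                key = _factor_bins(t, duration)
            except UndefinedStatisticError:
                continue
            per_cell.setdefault(key, []).append(t.correct)
        if not per_cell:
            continue
        perf = {k: 100.0 * np.mean(v) for k, v in per_cell.items()}
        mouse_mean = float(np.mean(list(perf.values())))
        for k, v in perf.items():
            cell_values.setdefault(k, []).append(v - mouse_mean)
    if not cell_values:
        raise NoTrialsError("no populated predictor cells")
    keys = sorted(cell_values)
    Y = np.array([np.mean(cell_values[k]) for k in keys])
    X = np.array([[2 * k[0], 2 * k[1], 10 * k[2]] for k in keys], dtype=float)
    Xd = sm.add_constant(X)
    model = sm.OLS(Y, Xd).fit()
    n, p = len(Y), 3
    dof = n - p - 1
    coef = model.params[1:]
    tstat = model.tvalues[1:]
    from scipy.stats import t as t_dist

    pvals = 2.0 * t_dist.sf(np.abs(tstat), dof)
    return PerformanceFactorsFit(
        coefficients=np.asarray(coef),
        t_stats=np.asarray(tstat),
        p_values=np.asarray(pvals),
        dof=dof,
        n_points=n,
        table=np.column_stack([X, Y]),
        single_mouse=single_mouse,
    )
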