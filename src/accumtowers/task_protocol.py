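"""Stimulus generation, side debiasing, session shaping, and VR controller math.

The task draws the rewarded side for each trial from a debiased Bernoulli,
then draws tower counts per side from Poisson distributions (mean 7.7 per cue
period for the rewarded side, 2.3 for the minority side) and places them
uniformly within the cue region subject to a 12-cm within-side refractory
spacing.  Trials where the rewarded side does not end up with strictly more
towers are redrawn, so the rewarded side always carries the majority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import (
    MazeConfig,
    ValidationError,
    WARMUP_MAZE_LEVEL,
    MAIN_MAZE_LEVEL,
    EASY_BLOCK_MAZE_LEVEL,
)

# ---------------------------------------------------------------------------
# Tower draws


def draw_positions_min_gap(
    rng: np.random.Generator, k: int, lo: float, hi: float, gap: float
) -> np.ndarray:
    """Exact sample of k ascending positions on [lo, hi] with spacing >= gap.

    Uses the gap/spacing transform: k uniform order statistics on the
    compressed interval [0, span - (k-1) gap] are stretched back by adding
    i*gap to the i-th point.  This is the uniform distribution on the
    constrained set (no rejection loop needed).
    """
    if k == 0:
        return np.empty(0)
    span = hi - lo
    free = span - (k - 1) * gap
    if free < 0:
        raise ValidationError(f"cannot place {k} towers with gap {gap} in span {span}")
    u = np.sort(rng.uniform(0.0, free, size=k))
    return lo + u + gap * np.arange(k)


def draw_positions_rejection(
    rng: np.random.Generator, k: int, lo: float, hi: float, gap: float
) -> np.ndarray:
    """Rejection-sampling reference for :func:`draw_positions_min_gap` (tests only)."""
    if k == 0:
        return np.empty(0)
    while True:
        pos = np.sort(rng.uniform(lo, hi, size=k))
        if k == 1 or np.min(np.diff(pos)) >= gap:
            return pos


def draw_towers(
    config: MazeConfig, rewarded_side: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one trial's tower positions; returns (towers_left, towers_right).

    Counts are Poisson (rewarded mean 7.7, minority 2.3) capped at the packing
    bound; the whole trial is redrawn until the rewarded side has strictly
    more towers.  Always terminates: the cap keeps every count feasible and a
    strict majority has positive probability.
    """
    if rewarded_side not in ("L", "R"):
        raise ValidationError("rewarded_side must be 'L' or 'R'")
    cap = config.max_towers_per_side
    lo, hi, gap = config.earliest_tower_cm, config.cue_region_cm, config.refractory_cm
    while True:
        n_rew = min(int(rng.poisson(config.mean_towers_rewarded)), cap)
        n_min = min(int(rng.poisson(config.mean_towers_minority)), cap)
        if n_rew > n_min:
            break
    pos_rew = draw_positions_min_gap(rng, n_rew, lo, hi, gap)
    pos_min = draw_positions_min_gap(rng, n_min, lo, hi, gap)
    if rewarded_side == "R":
        return pos_min, pos_rew
    return pos_rew, pos_min


# ---------------------------------------------------------------------------
# Side debiasing


def half_gaussian_weights(n: int, sigma: float) -> np.ndarray:
    """Weights over the past n trials, most recent last, normalized to unit mass."""
    ages = np.arange(n)[::-1]  # age 0 = most recent (last element)
    w = np.exp(-0.5 * (ages / sigma) ** 2)
    return w / w.sum()


@dataclass
class DebiaserState:
    """Rolling error history per rewarded side and the recent side sequence.

    ``right_errors``/``left_errors`` hold error indicators (1 = error) for
    right-/left-rewarded trials, oldest first.  ``recent_sides`` holds 1 for
    right-rewarded trials, for the sigma = 60 empirical-fraction window.
    """

    window: int = 40
    error_sigma: float = 20.0
    side_sigma: float = 60.0
    sqrt_cap: tuple[float, float] = (0.15, 0.85)
    right_errors: list[int] = field(default_factory=list)
    left_errors: list[int] = field(default_factory=list)
    recent_sides: list[int] = field(default_factory=list)

    @property
    def p_right(self) -> float:
        """Target probability of drawing a right trial, p_R = e_R / (e_R + e_L)."""
        if not self.right_errors or not self.left_errors:
            return 0.5
        e_r = self._weighted_error(self.right_errors)
        e_l = self._weighted_error(self.left_errors)
        return e_r / (e_r + e_l)

    def _weighted_error(self, errors: list[int]) -> float:
        recent = errors[-self.window :]
        w = half_gaussian_weights(len(recent), self.error_sigma)
        e = float(np.dot(w, recent))
        lo, hi = self.sqrt_cap
        return float(np.clip(math.sqrt(e), lo, hi) ** 2)

    @property
    def empirical_right_fraction(self) -> float:
        """sigma = 60 half-Gaussian weighted fraction of recent right trials."""
        if not self.recent_sides:
            return 0.5
        recent = self.recent_sides[-4 * int(self.side_sigma) :]
        w = half_gaussian_weights(len(recent), self.side_sigma)
        return float(np.dot(w, recent))


def debias_update(state: DebiaserState, rewarded_side: str, correct: bool) -> DebiaserState:
    """Record one finished trial's side and outcome; returns the same state."""
    err = 0 if correct else 1
    if rewarded_side == "R":
        state.right_errors.append(err)
        state.recent_sides.append(1)
    else:
        state.left_errors.append(err)
        state.recent_sides.append(0)
    return state


def right_draw_probability(p_r: float, empirical_fraction: float) -> float:
    """Pseudo-random prescription pushing the realized side fraction toward p_R.

    If the recent empirical right fraction exceeds p_R, right trials are drawn
    with probability 0.5 p_R; if it is below, with probability 0.5 (1 + p_R);
    at equality, with probability p_R.
    """
    if empirical_fraction > p_r:
        return 0.5 * p_r
    if empirical_fraction < p_r:
        return 0.5 * (1.0 + p_r)
    return p_r


def draw_trial_side(state: DebiaserState, rng: np.random.Generator) -> str:
    p = right_draw_probability(state.p_right, state.empirical_right_fraction)
    return "R" if rng.uniform() < p else "L"


# ---------------------------------------------------------------------------
# Session shaping state machine


@dataclass
class TrialResult:
    correct: bool
    rewarded_side: str
    good_quality: bool = True  # excess travel <= 110% of nominal length


@dataclass
class ProtocolState:
    """Phase of the within-session shaping protocol.

    A session starts with visually-guided warm-up trials; the animal advances
    to the main maze after >= 10 warm-up trials at >= 85% correct with side
    bias <= 10% and >= 75% good-quality trials.  In the main maze, a 40-trial
    running window triggers a fixed 10-trial easy block whenever accuracy
    drops below 55%.
    """

    phase: str = "warmup"
    warmup_min_trials: int = 10
    warmup_min_accuracy: float = 0.85
    warmup_max_side_bias: float = 0.10
    warmup_min_good_fraction: float = 0.75
    main_window: int = 40
    main_easy_threshold: float = 0.55
    easy_block_length: int = 10
    warmup_results: list[TrialResult] = field(default_factory=list)
    main_window_results: list[bool] = field(default_factory=list)
    easy_block_remaining: int = 0

    @property
    def maze_level(self) -> int:
        return {
            "warmup": WARMUP_MAZE_LEVEL,
            "main": MAIN_MAZE_LEVEL,
            "easy_block": EASY_BLOCK_MAZE_LEVEL,
        }[self.phase]


def _warmup_criteria_met(state: ProtocolState) -> bool:
    results = state.warmup_results
    if len(results) < state.warmup_min_trials:
        return False
    accuracy = sum(r.correct for r in results) / len(results)
    if accuracy < state.warmup_min_accuracy:
        return False
    right = [r for r in results if r.rewarded_side == "R"]
    left = [r for r in results if r.rewarded_side == "L"]
    if right and left:
        pc_r = sum(r.correct for r in right) / len(right)
        pc_l = sum(r.correct for r in left) / len(left)
        if abs(pc_r - pc_l) > state.warmup_max_side_bias:
            return False
    good = sum(r.good_quality for r in results) / len(results)
    return good >= state.warmup_min_good_fraction


def protocol_step(state: ProtocolState, result: TrialResult) -> int:
    """Record one finished trial and return the next trial's maze level."""
    if state.phase == "warmup":
        state.warmup_results.append(result)
        if _warmup_criteria_met(state):
            state.phase = "main"
    elif state.phase == "easy_block":
        state.easy_block_remaining -= 1
        if state.easy_block_remaining <= 0:
            state.phase = "main"
    else:  # main
        state.main_window_results.append(result.correct)
        if len(state.main_window_results) > state.main_window:
            state.main_window_results.pop(0)
        if len(state.main_window_results) == state.main_window:
            accuracy = sum(state.main_window_results) / state.main_window
            if accuracy < state.main_easy_threshold:
                state.phase = "easy_block"
                state.easy_block_remaining = state.easy_block_length
                state.main_window_results.clear()
    return state.maze_level


# ---------------------------------------------------------------------------
# View-angle controller


def displacement_angle(dx: float, dy: float) -> float:
    """Acute angle between the treadmill displacement vector and the Y axis.

    Raw rig convention: positive for leftward displacement.  The package-wide
    "positive = rightward" sign convention is applied at log-writing time, not
    here.
    """
    if dy == 0.0:
        return 0.0  # sign(0) = 0 kills the numerator
    return math.atan2(-dx * math.copysign(1.0, dy), abs(dy))


def view_angle_rate(theta_disp: float) -> float:
    """Exponential gain mapping displacement angle to view-angle rate (rad/s).

    Small angles are damped (stabilizing straight running in the stem) while
    large angles still allow sharp turns; the rate is capped at pi rad/s.
    """
    if theta_disp == 0.0:
        return 0.0
    magnitude = min(math.exp(1.4 * abs(theta_disp) ** 1.2) - 1.0, math.pi)
    return math.copysign(magnitude, theta_disp)


def view_angle_controller(dx: float, dy: float, dt: float) -> float:
    """Change in view angle over one controller step of duration dt seconds."""
    if dt <= 0:
        raise ValidationError("dt must be positive")
    return view_angle_rate(displacement_angle(dx, dy)) * dt
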