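"""Synthetic choice- and trajectory-generating agents.

Every analysis in the package is validated by parameter recovery on data from
these agents, whose ground-truth parameters (and per-trial choice
probabilities, where analytic) are recorded in a sidecar so tests never reach
into agent internals.

The DDM agent is a Monte-Carlo forward simulation of the accumulator SDE,
deliberately independent of the distribution-propagation likelihood in
:mod:`accumtowers.ddm` so the two implementations can cross-validate each
other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MazeConfig,
    TrialRecord,
    ValidationError,
    MAIN_MAZE_LEVEL,
)
from .task_protocol import (
    DebiaserState,
    ProtocolState,
    TrialResult,
    debias_update,
    draw_towers,
    draw_trial_side,
    protocol_step,
)
from .choice_models import (
    HistoryModelParams,
    StrategyModelSpec,
    history_model_pR,
    history_vector,
    strategy_predict,
)
from .ddm import DDMParams, trial_pulses

AGENT_KINDS = (
    "constant_p",
    "k_random_tower",
    "first_tower",
    "last_tower",
    "logistic_history",
    "ddm_mc",
)


@dataclass(frozen=True)
class AgentSpec:
    """A synthetic decision policy.

    kinds: ``constant_p`` (fixed P(R) = ``p``), ``k_random_tower`` /
    ``first_tower`` / ``last_tower`` (heuristic strategies with side lapses),
    ``logistic_history`` (the history-modulated logistic generative model),
    and ``ddm_mc`` (Monte-Carlo accumulator).
    """

    kind: str = "constant_p"
    p: float = 0.5
    k: int = 1
    lapse_r: float = 0.0
    lapse_l: float = 0.0
    ddm: Optional[DDMParams] = None
    history: Optional[HistoryModelParams] = None
    history_p0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValidationError(f"unknown agent kind {self.kind!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError("p must be a probability")
        if self.kind == "k_random_tower" and (self.k < 1 or self.k % 2 == 0):
            raise ValidationError("k must be odd and >= 1")


MC_STEP_M = 0.005  # Euler step of the Monte-Carlo accumulator (0.5 cm)
MC_STEM_M = 3.0


def ddm_mc_paths(
    trial: TrialRecord,
    params: DDMParams,
    n_paths: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate accumulator endpoints; returns the boolean right-choice array.

    Uses exact linear-SDE transitions between steps (decay exp(lam dy) plus
    the matching Gaussian increment), sticky bounds checked every 0.5 cm, and
    pulses applied at their exact positions with eta ~ N(1, sigma2_s).
    """
    lam, dy = params.lam, MC_STEP_M
    decay = math.exp(lam * dy)
    if abs(lam) > 1e-12:
        v_step = params.sigma2_a * math.expm1(2 * lam * dy) / (2 * lam)
    else:
        v_step = params.sigma2_a * dy
    s_step = math.sqrt(max(v_step, 0.0))
    ys, mags = trial_pulses(trial, params.phi, params.tau_phi)
    pulse_step = np.round(ys / dy).astype(int)
    a = rng.normal(0.0, math.sqrt(params.sigma2_i), size=n_paths)
    absorbed = np.zeros(n_paths, dtype=np.int8)  # 0 free, +1 right bound, -1 left
    n_steps = int(round(MC_STEM_M / dy))
    b = params.bound
    s_pulse = math.sqrt(max(params.sigma2_s, 0.0))
    for k in range(n_steps + 1):
        if k > 0:
            free = absorbed == 0
            if s_step > 0:
                a[free] = a[free] * decay + rng.normal(0.0, s_step, size=int(free.sum()))
            else:
                a[free] *= decay
        for idx in np.where(pulse_step == k)[0]:
            free = absorbed == 0
            eta = 1.0 + s_pulse * rng.standard_normal(int(free.sum())) if s_pulse > 0 else 1.0
            a[free] = a[free] + mags[idx] * eta
        hit_hi = (absorbed == 0) & (a >= b)
        hit_lo = (absorbed == 0) & (a <= -b)
        absorbed[hit_hi] = 1
        absorbed[hit_lo] = -1
    right = np.where(absorbed != 0, absorbed > 0, a > params.bias)
    if params.lapse > 0:
        lapse_mask = rng.uniform(size=n_paths) < params.lapse
        right = np.where(lapse_mask, rng.uniform(size=n_paths) < 0.5, right)
    return right


def ddm_mc_pR(
    trial: TrialRecord,
    params: DDMParams,
    n_paths: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Monte-Carlo right-choice probability and its binomial standard error."""
    rng = rng or np.random.default_rng(0)
    right = ddm_mc_paths(trial, params, n_paths, rng)
    p = float(np.mean(right))
    se = math.sqrt(max(p * (1 - p), 1e-12) / n_paths)
    return p, se


def agent_pR(
    agent: AgentSpec,
    trial: TrialRecord,
    history: Optional[tuple[str, bool]] = None,
) -> Optional[float]:
    """Analytic P(choice = R), or None for the Monte-Carlo DDM agent."""
    if agent.kind == "constant_p":
        return agent.p
    if agent.kind in ("k_random_tower", "first_tower", "last_tower"):
        kind = {"k_random_tower": "k_random"}.get(agent.kind, agent.kind)
        spec = StrategyModelSpec(
            kind=kind, k=agent.k, lapse_r=agent.lapse_r, lapse_l=agent.lapse_l
        )
        return strategy_predict(spec, trial)
    if agent.kind == "logistic_history":
        if agent.history is None:
            raise ValidationError("logistic_history agent needs history parameters")
        from .evidence_weighting import spatial_evidence_matrix

        X = spatial_evidence_matrix([trial])
        if history is None:
            h = np.zeros((1, 3))
            prev_error = np.zeros(1)
        else:
            h = history_vector(*history)[None, :]
            prev_error = np.array([1.0 if not history[1] else -1.0])
        return float(
            history_model_pR(agent.history, agent.history_p0, X, h, prev_error)[0]
        )
    return None  # ddm_mc: no closed form


def agent_choice(
    agent: AgentSpec,
    trial: TrialRecord,
    history: Optional[tuple[str, bool]],
    rng: np.random.Generator,
) -> tuple[str, Optional[float]]:
    """Draw a choice; returns (choice, analytic p_R or None)."""
    p = agent_pR(agent, trial, history)
    if p is None:
        if agent.ddm is None:
            raise ValidationError("ddm_mc agent needs DDM parameters")
        right = bool(ddm_mc_paths(trial, agent.ddm, 1, rng)[0])
        return ("R" if right else "L"), None
    return ("R" if rng.uniform() < p else "L"), p


# ---------------------------------------------------------------------------
# Trajectories


@dataclass(frozen=True)
class TrajectoryParams:
    """Generative knobs for synthetic running trajectories.

    This generator is a descriptive stand-in (no inference is run on its
    parameters): a choice-signed logistic view-angle profile in y whose
    midpoint moves earlier with evidence strength, plus OU noise, riding on a
    roughly constant running speed.  Speeds in cm/s, angles in radians.
    """

    mean_speed: float = 61.0
    within_session_speed_sd: float = 5.0
    across_session_speed_sd: float = 8.0
    theta_max: float = 1.5
    profile_midpoint_cm: float = 200.0
    profile_steepness_cm: float = 40.0
    evidence_gain_cm: float = 5.0  # midpoint advance per |delta| tower
    noise_sd: float = 0.3
    noise_tau_cm: float = 50.0
    dt: float = 0.05
    start_buffer_cm: float = 30.0

    def __post_init__(self) -> None:
        if self.mean_speed <= 0 or self.within_session_speed_sd < 0:
            raise ValidationError("speeds must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise scale must be >= 0")


def simulate_trajectory(
    trial: TrialRecord,
    choice: str,
    params: TrajectoryParams,
    rng: np.random.Generator,
    speed_offset: float = 0.0,
    total_length_cm: float = 330.0,
) -> pd.DataFrame:
    """One trial's (t, x, y, view_angle) samples; y strictly reaches the arms.

    The view angle is pinned to 0 in the start buffer (first 30 cm), then
    follows the choice-signed logistic profile whose midpoint is advanced by
    ``evidence_gain_cm`` per |delta| tower, plus OU noise.
    """
    speed = max(
        params.mean_speed + speed_offset + params.within_session_speed_sd * rng.standard_normal(),
        5.0,
    )
    sign = 1.0 if choice == "R" else -1.0
    midpoint = params.profile_midpoint_cm - params.evidence_gain_cm * abs(trial.delta)
    rows = []
    t = 0.0
    y = 0.0
    x = 0.0
    noise = 0.0
    step_cm = speed * params.dt
    alpha = math.exp(-step_cm / params.noise_tau_cm)
    sigma_eq = params.noise_sd * math.sqrt(max(1 - alpha**2, 0.0))
    while True:
        if y < params.start_buffer_cm:
            theta = 0.0
        else:
            profile = params.theta_max / (
                1.0 + math.exp(-(y - midpoint) / params.profile_steepness_cm)
            )
            theta = sign * profile + noise
            noise = alpha * noise + sigma_eq * rng.standard_normal() if params.noise_sd else 0.0
        rows.append((t, x, y, theta))
        if y >= total_length_cm:
            break
        x += step_cm * math.sin(theta)
        y += step_cm * math.cos(theta)
        y = max(y, rows[-1][2] + 0.1 * step_cm)  # keep forward progress
        t += params.dt
    df = pd.DataFrame(rows, columns=["t", "x", "y", "view_angle"])
    df.insert(0, "trial_index", trial.trial_index)
    df.insert(0, "session_id", trial.session_id)
    df.insert(0, "mouse_id", trial.mouse_id)
    return df


# ---------------------------------------------------------------------------
# Closed-loop dataset simulation


@dataclass
class SimulatedDataset:
    trials: list
    ground_truth: dict
    trajectories: Optional[pd.DataFrame] = None


GUIDED_ACCURACY = 0.97  # warm-up / easy-block mazes are visually guided


def simulate_dataset(
    agent: AgentSpec,
    n_sessions: int = 10,
    trials_per_session: int = 180,
    rng: Optional[np.random.Generator] = None,
    config: Optional[MazeConfig] = None,
    trajectory_params: Optional[TrajectoryParams] = None,
    mouse_id: str = "m1",
    include_protocol: bool = True,
    bad_trial_rate: float = 0.02,
) -> SimulatedDataset:
    """Closed-loop simulation of full sessions.

    The protocol draws each trial's rewarded side through the debiaser and
    pseudo-random prescription, draws towers, asks the agent for a choice,
    and feeds the outcome back into the debiaser and shaping state machine.
    Warm-up and easy-block mazes are visually guided, so every agent performs
    them at a fixed high accuracy regardless of its evidence policy.  A small
    fraction of trials is planted with excess travel beyond the 110%
    criterion to exercise the selection filters.  Ground truth (agent spec,
    per-trial analytic p_R where available) is returned as a sidecar dict.
    """
    rng = rng or np.random.default_rng(0)
    config = config or MazeConfig()
    trials: list[TrialRecord] = []
    gt_p: list[Optional[float]] = []
    traj_frames: list[pd.DataFrame] = []
    for s in range(n_sessions):
        session_id = f"s{s:03d}"
        debiaser = DebiaserState()
        protocol = ProtocolState() if include_protocol else None
        maze_level = protocol.maze_level if protocol else MAIN_MAZE_LEVEL
        history: Optional[tuple[str, bool]] = None
        block_id = 0
        prev_level = maze_level
        speed_offset = 0.0
        if trajectory_params is not None:
            speed_offset = trajectory_params.across_session_speed_sd * rng.standard_normal()
        for i in range(trials_per_session):
            if maze_level != prev_level:
                block_id += 1
                history = None  # block change breaks the consecutive-trial chain
                prev_level = maze_level
            side = draw_trial_side(debiaser, rng)
            if maze_level == MAIN_MAZE_LEVEL:
                towers_l, towers_r = draw_towers(config, side, rng)
            else:
                # guided mazes: towers only on the rewarded side
                n = max(int(rng.poisson(config.mean_towers_rewarded)), 1)
                n = min(n, config.max_towers_per_side)
                from .task_protocol import draw_positions_min_gap

                pos = draw_positions_min_gap(
                    rng, n, config.earliest_tower_cm, config.cue_region_cm, config.refractory_cm
                )
                towers_l, towers_r = (pos, np.empty(0)) if side == "L" else (np.empty(0), pos)
            trial = TrialRecord(
                mouse_id=mouse_id,
                session_id=session_id,
                block_id=block_id,
                maze_level=maze_level,
                trial_index=i,
                towers_left=tuple(np.round(towers_l, 2)),
                towers_right=tuple(np.round(towers_r, 2)),
                rewarded_side=side,
                choice=side,  # placeholder, replaced below
                outcome="correct",
            )
            if maze_level == MAIN_MAZE_LEVEL:
                choice, p_r = agent_choice(agent, trial, history, rng)
            else:
                correct_draw = rng.uniform() < GUIDED_ACCURACY
                choice = side if correct_draw else ("L" if side == "R" else "R")
                p_r = None
            outcome = "correct" if choice == side else "error"
            excess = 1.0 + abs(rng.normal(0.0, 0.02))
            if rng.uniform() < bad_trial_rate:
                excess = 1.2 + abs(rng.normal(0.0, 0.1))
            trial = TrialRecord(
                mouse_id=mouse_id,
                session_id=session_id,
                block_id=block_id,
                maze_level=maze_level,
                trial_index=i,
                towers_left=trial.towers_left,
                towers_right=trial.towers_right,
                rewarded_side=side,
                choice=choice,
                outcome=outcome,
                excess_travel_fraction=round(excess, 3),
            )
            trials.append(trial)
            gt_p.append(p_r)
            if trajectory_params is not None:
                traj_frames.append(
                    simulate_trajectory(trial, choice, trajectory_params, rng, speed_offset)
                )
            correct = outcome == "correct"
            debias_update(debiaser, side, correct)
            history = (choice, correct)
            if protocol is not None:
                good = excess <= 1.10
                maze_level = protocol_step(protocol, TrialResult(correct, side, good))
    ground_truth = {
        "agent_kind": agent.kind,
        "per_trial_pR": gt_p,
        "n_sessions": n_sessions,
        "trials_per_session": trials_per_session,
    }
    trajectories = pd.concat(traj_frames, ignore_index=True) if traj_frames else None
    return SimulatedDataset(trials=trials, ground_truth=ground_truth, trajectories=trajectories)


def write_ground_truth(dataset: SimulatedDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataset.ground_truth, fh, indent=1)
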