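"""Running-speed statistics, view-angle extraction, and choice decoding.

View angle at a maze position Y is defined as the angle at the first sample
where y(t) >= Y (no interpolation), which is robust to small amounts of
backtracking.  The per-position choice decoder uses the boundary that most
equally separates the right- and left-choice view-angle distributions;
decoding accuracy is the percent of right-choice trials above the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import TrialRecord, UndefinedStatisticError, ValidationError

DEFAULT_Y_GRID = np.arange(0.0, 300.0, 5.0)


def view_angle_at(y: np.ndarray, theta: np.ndarray, Y: float) -> float:
    """Theta at the first sample index where y >= Y (first-crossing sample)."""
    y = np.asarray(y, dtype=float)
    idx = np.nonzero(y >= Y)[0]
    if idx.size == 0:
        raise UndefinedStatisticError(f"trajectory never reaches y = {Y}")
    return float(np.asarray(theta, dtype=float)[idx[0]])


def trajectory_angles_on_grid(
    trajectories: pd.DataFrame, y_grid: np.ndarray = DEFAULT_Y_GRID
) -> pd.DataFrame:
    """Per-trial view angle at each grid position (first-crossing definition).

    Returns a frame keyed by (mouse_id, session_id, trial_index) with one
    column per grid position; trials that never reach a position hold NaN.
    """
    records = []
    for key, grp in trajectories.groupby(["mouse_id", "session_id", "trial_index"], sort=False):
        y = grp["y"].to_numpy()
        th = grp["view_angle"].to_numpy()
        row = dict(zip(["mouse_id", "session_id", "trial_index"], key))
        for Y in y_grid:
            idx = np.nonzero(y >= Y)[0]
            row[float(Y)] = float(th[idx[0]]) if idx.size else np.nan
        records.append(row)
    return pd.DataFrame(records)


@dataclass
class DecoderResult:
    y_grid: np.ndarray
    boundary: np.ndarray  # theta_cd(y); NaN where undefined
    accuracy_percent: np.ndarray

    def accuracy_at(self, Y: float) -> float:
        i = int(np.argmin(np.abs(self.y_grid - Y)))
        return float(self.accuracy_percent[i])


def _equal_error_boundary(theta_r: np.ndarray, theta_l: np.ndarray) -> float:
    """Boundary t where frac(theta_R > t) equals frac(theta_L < t), by bisection."""
    lo = min(theta_r.min(), theta_l.min()) - 1.0
    hi = max(theta_r.max(), theta_l.max()) + 1.0

    def f(t: float) -> float:
        return np.mean(theta_r > t) - np.mean(theta_l < t)

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def choice_decoder(
    choices: Sequence[str],
    theta_by_y: np.ndarray,
    y_grid: np.ndarray = DEFAULT_Y_GRID,
) -> DecoderResult:
    """Decode eventual choice from the view angle at each maze position.

    ``theta_by_y`` is (n_trials, n_y).  At each position the boundary
    equalizes the two classes' error fractions; accuracy is evaluated on
    right-choice trials.  Positions with only one class represented are
    undefined (NaN).
    """
    choices_arr = np.asarray([c == "R" for c in choices])
    theta_by_y = np.asarray(theta_by_y, dtype=float)
    n_y = theta_by_y.shape[1]
    if n_y != len(y_grid):
        raise ValidationError("theta_by_y width must match y_grid")
    boundary = np.full(n_y, np.nan)
    accuracy = np.full(n_y, np.nan)
    for j in range(n_y):
        col = theta_by_y[:, j]
        ok = ~np.isnan(col)
        tr = col[ok & choices_arr]
        tl = col[ok & ~choices_arr]
        if tr.size == 0 or tl.size == 0:
            continue
        t = _equal_error_boundary(tr, tl)
        boundary[j] = t
        accuracy[j] = 100.0 * np.mean(tr > t)
    return DecoderResult(y_grid=np.asarray(y_grid), boundary=boundary, accuracy_percent=accuracy)


# ---------------------------------------------------------------------------
# Tower-triggered view-angle deviations


@dataclass
class TowerTriggeredResult:
    offsets_cm: np.ndarray
    mean_right: np.ndarray  # mean deviation after right towers
    mean_left: np.ndarray
    spread: np.ndarray  # across-trial 1-SD of deviations per offset
    spread_ratio: float  # mean spread / mean |right - left| trace difference


def tower_triggered_view_angle(
    trials: Sequence[TrialRecord],
    theta_by_y: np.ndarray,
    y_grid: np.ndarray = DEFAULT_Y_GRID,
    window_cm: float = 80.0,
) -> TowerTriggeredResult:
    """Deviations of theta from the same-choice mean, locked to tower onsets.

    Per trial the same-choice mean trajectory is subtracted; deviations are
    sampled at offsets 0..window after each tower (y = 0 at the tower) and
    averaged separately for left and right towers.  ``spread_ratio`` compares
    the across-trial 1-SD spread to the mean |right - left| trace difference;
    large values argue against a stepwise view-angle mnemonic.
    """
    theta_by_y = np.asarray(theta_by_y, dtype=float)
    choices = np.array([t.choice == "R" for t in trials])
    dev = theta_by_y.copy()
    for is_r in (True, False):
        rows = choices == is_r
        if rows.any():
            mean_traj = np.nanmean(theta_by_y[rows], axis=0)
            dev[rows] = theta_by_y[rows] - mean_traj
    step = y_grid[1] - y_grid[0]
    offsets = np.arange(0.0, window_cm + step / 2, step)
    traces = {"R": [], "L": []}
    for i, trial in enumerate(trials):
        for side, towers in (("R", trial.towers_right), ("L", trial.towers_left)):
            for tower_y in towers:
                sample_y = tower_y + offsets
                cols = np.round((sample_y - y_grid[0]) / step).astype(int)
                valid = (cols >= 0) & (cols < len(y_grid))
                if not valid.all():
                    continue  # insufficient post-tower track on the grid
                row = dev[i, cols]
                if np.any(np.isnan(row)):
                    continue
                traces[side].append(row)
    if not traces["R"] or not traces["L"]:
        raise UndefinedStatisticError("no towers with a full post-tower window")
    arr_r = np.array(traces["R"])
    arr_l = np.array(traces["L"])
    mean_r = arr_r.mean(axis=0)
    mean_l = arr_l.mean(axis=0)
    spread = np.concatenate([arr_r, arr_l]).std(axis=0, ddof=1)
    diff = float(np.mean(np.abs(mean_r - mean_l)))
    ratio = float(np.mean(spread) / max(diff, 1e-12))
    return TowerTriggeredResult(
        offsets_cm=offsets,
        mean_right=mean_r,
        mean_left=mean_l,
        spread=spread,
        spread_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# Speed


@dataclass
class SpeedSummary:
    per_trial: pd.DataFrame  # mouse, session, trial, speed (cm/s)
    session_means: pd.DataFrame
    within_session_sd: float
    across_session_sd: float
    mean_speed: float


def speed_summary(trajectories: pd.DataFrame, stem_max_cm: float = 300.0) -> SpeedSummary:
    """Per-trial stem running speed and its within/across-session variability.

    Speed is the x-y path length over 0 < y < 300 cm divided by the traversal
    time (path length, not net displacement, so backtracking counts).
    Zero-duration trials are excluded.
    """
    rows = []
    for key, grp in trajectories.groupby(["mouse_id", "session_id", "trial_index"], sort=False):
        g = grp[(grp["y"] > 0) & (grp["y"] < stem_max_cm)]
        if len(g) < 2:
            continue
        dx = np.diff(g["x"].to_numpy())
        dy = np.diff(g["y"].to_numpy())
        dist = float(np.sum(np.hypot(dx, dy)))
        dt = float(g["t"].iloc[-1] - g["t"].iloc[0])
        if dt <= 0:
            continue
        rows.append({**dict(zip(["mouse_id", "session_id", "trial_index"], key)),
                     "speed": dist / dt})
    if not rows:
        raise UndefinedStatisticError("no trials with usable stem trajectories")
    per_trial = pd.DataFrame(rows)
    by_session = per_trial.groupby(["mouse_id", "session_id"])["speed"]
    session_means = by_session.mean().reset_index()
    within = float(by_session.std(ddof=1).mean())
    across = float(session_means["speed"].std(ddof=1))
    return SpeedSummary(
        per_trial=per_trial,
        session_means=session_means,
        within_session_sd=within,
        across_session_sd=across,
        mean_speed=float(per_trial["speed"].mean()),
    )


def view_angle_by_evidence(
    trials: Sequence[TrialRecord],
    theta_by_y: np.ndarray,
    y_grid: np.ndarray = DEFAULT_Y_GRID,
    delta_bins: Sequence[tuple[int, int]] = ((0, 2), (3, 5), (6, 20)),
) -> dict:
    """Mean choice-signed view angle per |delta| bin at each maze position.

    Right-choice trials contribute theta, left-choice trials -theta, so a
    positive trace means turning toward the eventual choice; stronger
    evidence should diverge earlier.
    """
    theta_by_y = np.asarray(theta_by_y, dtype=float)
    signed = np.where(
        np.array([t.choice == "R" for t in trials])[:, None], theta_by_y, -theta_by_y
    )
    adelta = np.array([abs(t.delta) for t in trials])
    out = {}
    for lo, hi in delta_bins:
        rows = (adelta >= lo) & (adelta <= hi)
        if rows.any():
            out[(lo, hi)] = np.nanmean(signed[rows], axis=0)
    return out
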