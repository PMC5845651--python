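"""Domain types, session-log serialization, and trial-selection filters.

Coordinate convention: ``y`` is 0 at the start of the maze stem and increases
toward the arms, in cm.  Tower positions are the "as-seen" positions within
the cue region.  View angle ``theta`` is in radians with positive values
meaning a rightward turn.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class SessionLogError(ValueError):
    """A session log file could not be parsed."""


class NoTrialsError(ValueError):
    """A selection step removed every trial; never returned silently."""


class UndefinedStatisticError(ValueError):
    """Requested quantity is undefined for the given data (e.g. no towers)."""


# Maze levels: the shaping sequence ends at the final accumulation maze.
WARMUP_MAZE_LEVEL = 10
MAIN_MAZE_LEVEL = 11
EASY_BLOCK_MAZE_LEVEL = 12


@dataclass(frozen=True)
class MazeConfig:
    """Geometry and stimulus-statistics constants of the T-maze.

    Defaults describe the standard maze: a 330-cm stem whose first 200 cm
    (cue region) can show towers and whose last 100 cm (delay region) cannot.
    Tower counts per side are Poisson with a mean of 7.7 for the rewarded
    side and 2.3 for the minority side per cue period (overall density
    5 m^-1), with a 12-cm within-side refractory spacing.
    """

    total_length_cm: float = 330.0
    cue_region_cm: float = 200.0
    delay_region_cm: float = 100.0
    start_buffer_cm: float = 30.0
    tower_visibility_trigger_cm: float = 10.0
    tower_lifetime_ms: float = 200.0
    refractory_cm: float = 12.0
    mean_towers_rewarded: float = 7.7
    mean_towers_minority: float = 2.3
    earliest_tower_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.cue_region_cm + self.delay_region_cm > self.total_length_cm - self.start_buffer_cm:
            raise ValidationError("cue + delay regions exceed maze length minus start buffer")
        if self.refractory_cm <= 0:
            raise ValidationError("refractory_cm must be positive")
        if self.mean_towers_rewarded <= 0 or self.mean_towers_minority < 0:
            raise ValidationError("tower count means must be positive")

    @property
    def max_towers_per_side(self) -> int:
        """Packing cap: most towers that fit one side given the refractory spacing."""
        span = self.cue_region_cm - self.earliest_tower_cm
        return 1 + int(math.floor(span / self.refractory_cm))

    @property
    def placeable_span_cm(self) -> float:
        return self.cue_region_cm - self.earliest_tower_cm


# The maze variant used for the DAT-Cre cohort (longer cue region, sparser
# towers); provided as a preset only.
DAT_CRE_MAZE = MazeConfig(
    cue_region_cm=220.0,
    delay_region_cm=80.0,
    refractory_cm=14.0,
    mean_towers_rewarded=(3.5 / 5.0) * 7.7 * 1.1,
    mean_towers_minority=(3.5 / 5.0) * 2.3 * 1.1,
)


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial; the atom of every analysis.

    ``towers_left``/``towers_right`` are ascending tower positions (cm).
    ``rewarded_side`` is the side with strictly more towers.  ``outcome``
    is redundant with ``choice == rewarded_side`` and is validated as such.
    """

    mouse_id: str
    session_id: str
    block_id: int
    maze_level: int
    trial_index: int
    towers_left: tuple[float, ...]
    towers_right: tuple[float, ...]
    rewarded_side: str
    choice: str
    outcome: str
    excess_travel_fraction: float = 1.0
    timed_out: bool = False
    aborted: bool = False
    opto: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "towers_left", tuple(float(t) for t in self.towers_left))
        object.__setattr__(self, "towers_right", tuple(float(t) for t in self.towers_right))

    @property
    def n_left(self) -> int:
        return len(self.towers_left)

    @property
    def n_right(self) -> int:
        return len(self.towers_right)

    @property
    def delta(self) -> int:
        """Signed evidence strength #R - #L."""
        return self.n_right - self.n_left

    @property
    def correct(self) -> bool:
        return self.choice == self.rewarded_side

    def all_towers(self) -> list[tuple[float, str]]:
        """Pooled (position, side) pairs sorted by position, R before L on ties."""
        pooled = [(y, "R") for y in self.towers_right] + [(y, "L") for y in self.towers_left]
        pooled.sort(key=lambda p: (p[0], p[1] != "R"))
        return pooled

    def validate(self, config: Optional[MazeConfig] = None) -> None:
        cfg = config or MazeConfig()
        for side, towers in (("left", self.towers_left), ("right", self.towers_right)):
            if any(b < a for a, b in zip(towers, towers[1:])):
                raise ValidationError(f"towers_{side} unsorted in trial {self.trial_index}")
            if any(b - a < cfg.refractory_cm - 1e-9 for a, b in zip(towers, towers[1:])):
                raise ValidationError(
                    f"towers_{side} violate refractory spacing in trial {self.trial_index}"
                )
            for y in towers:
                if not (cfg.earliest_tower_cm - 1e-9 <= y <= cfg.cue_region_cm + 1e-9):
                    raise ValidationError(
                        f"tower at {y} cm outside cue region in trial {self.trial_index}"
                    )
        if self.rewarded_side not in ("L", "R") or self.choice not in ("L", "R"):
            raise ValidationError("rewarded_side and choice must be 'L' or 'R'")
        if self.outcome not in ("correct", "error"):
            raise ValidationError("outcome must be 'correct' or 'error'")
        if (self.outcome == "correct") != (self.choice == self.rewarded_side):
            raise ValidationError(
                f"outcome inconsistent with choice/rewarded_side in trial {self.trial_index}"
            )
        if self.n_left != self.n_right:
            majority = "R" if self.n_right > self.n_left else "L"
            if self.rewarded_side != majority:
                raise ValidationError(
                    f"rewarded_side is not the majority side in trial {self.trial_index}"
                )


@dataclass(frozen=True)
class TrajectorySample:
    """One within-trial pose sample: time (s), position (cm), view angle (rad)."""

    t: float
    x: float
    y: float
    view_angle: float


@dataclass(frozen=True)
class SelectionCriteria:
    """Block/trial/mouse inclusion thresholds.

    Defaults: whole blocks kept only at >= 60% correct, trials kept only if
    total travel <= 110% of nominal maze length and neither timed out nor
    aborted, and mice kept only with >= 1,000 surviving trials.
    """

    min_block_performance: float = 0.60
    max_excess_travel: float = 1.10
    min_trials_per_mouse: int = 1000
    require_history_trials: int = 0
    exclude_opto_sessions: bool = False
    keep_maze_levels: tuple[int, ...] = (MAIN_MAZE_LEVEL,)

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_block_performance <= 1.0):
            raise ValidationError("min_block_performance must be in [0, 1]")
        if self.max_excess_travel < 1.0:
            raise ValidationError("max_excess_travel below 1 excludes every trial")
        if self.min_trials_per_mouse < 1:
            raise ValidationError("min_trials_per_mouse must be >= 1")
        if self.require_history_trials < 0:
            raise ValidationError("require_history_trials must be >= 0")


_REQUIRED_FIELDS = (
    "mouse_id",
    "session_id",
    "block_id",
    "maze_level",
    "trial_index",
    "towers_left",
    "towers_right",
    "rewarded_side",
    "choice",
    "outcome",
)


def write_session_log(trials: Iterable[TrialRecord], path) -> None:
    """Write trials as JSON Lines, one object per trial, positions to 2 decimals."""
    with open(path, "w") as fh:
        for trial in trials:
            rec = asdict(trial)
            rec["towers_left"] = [round(t, 2) for t in trial.towers_left]
            rec["towers_right"] = [round(t, 2) for t in trial.towers_right]
            fh.write(json.dumps(rec) + "\n")


def read_session_log(path, config: Optional[MazeConfig] = None) -> list[TrialRecord]:
    """Read a JSON-Lines session log, validating every record.

    Malformed lines raise :class:`SessionLogError` naming the line number and
    the missing/offending field; invariant violations raise
    :class:`ValidationError` with the line number.
    """
    trials: list[TrialRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionLogError(f"line {lineno}: invalid JSON ({exc})") from exc
            missing = [k for k in _REQUIRED_FIELDS if k not in obj]
            if missing:
                raise SessionLogError(f"line {lineno}: missing required field(s) {missing}")
            try:
                trial = TrialRecord(
                    mouse_id=str(obj["mouse_id"]),
                    session_id=str(obj["session_id"]),
                    block_id=int(obj["block_id"]),
                    maze_level=int(obj["maze_level"]),
                    trial_index=int(obj["trial_index"]),
                    towers_left=tuple(obj["towers_left"]),
                    towers_right=tuple(obj["towers_right"]),
                    rewarded_side=obj["rewarded_side"],
                    choice=obj["choice"],
                    outcome=obj["outcome"],
                    excess_travel_fraction=float(obj.get("excess_travel_fraction", 1.0)),
                    timed_out=bool(obj.get("timed_out", False)),
                    aborted=bool(obj.get("aborted", False)),
                    opto=bool(obj.get("opto", False)),
                )
                trial.validate(config)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            trials.append(trial)
    return trials


TRAJECTORY_COLUMNS = ["mouse_id", "session_id", "trial_index", "t", "x", "y", "view_angle"]


def write_trajectories(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SessionLogError(f"trajectory CSV missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Trial selection


@dataclass
class SelectionLedger:
    """Bookkeeping of how many trials each criterion removed.

    ``kept + sum of exclusions == n_input`` always holds; each trial is
    attributed to the first criterion (in the order below) that removed it.
    """

    n_input: int = 0
    n_kept: int = 0
    excluded_maze_level: int = 0
    excluded_bad_trial: int = 0  # excess travel, timeout, or abort
    excluded_low_performance_block: int = 0
    excluded_opto_session: int = 0
    excluded_history_warmup: int = 0
    excluded_low_trial_mouse: int = 0
    per_level_excluded: dict = field(default_factory=dict)

    def total_excluded(self) -> int:
        return (
            self.excluded_maze_level
            + self.excluded_bad_trial
            + self.excluded_low_performance_block
            + self.excluded_opto_session
            + self.excluded_history_warmup
            + self.excluded_low_trial_mouse
        )


def iter_blocks(trials: Sequence[TrialRecord]) -> list[list[int]]:
    """Indices of maximal runs of consecutive same-maze-level trials per session."""
    blocks: list[list[int]] = []
    prev_key = None
    for i, t in enumerate(trials):
        key = (t.mouse_id, t.session_id, t.maze_level, t.block_id)
        if key != prev_key:
            blocks.append([])
            prev_key = key
        blocks[-1].append(i)
    return blocks


def select_trials(
    trials: Sequence[TrialRecord], criteria: Optional[SelectionCriteria] = None
) -> tuple[list[TrialRecord], SelectionLedger]:
    """Apply block-wise data inclusion criteria; returns survivors + ledger.

    Order of application: maze-level filter (warm-up and easy-block mazes
    dropped), opto-session exclusion, trial-quality filter (excess travel,
    timeout, abort), whole-block performance threshold computed over the
    quality-surviving trials, per-block history warm-up trimming, then the
    per-mouse minimum trial count.  The operation is idempotent.
    """
    criteria = criteria or SelectionCriteria()
    ledger = SelectionLedger(n_input=len(trials))
    if not trials:
        raise NoTrialsError("no trials in input")

    drop_reason: dict[int, str] = {}

    if criteria.keep_maze_levels is not None:
        keep_levels = set(criteria.keep_maze_levels)
        for i, t in enumerate(trials):
            if t.maze_level not in keep_levels:
                drop_reason[i] = "maze_level"

    if criteria.exclude_opto_sessions:
        opto_sessions = {
            (t.mouse_id, t.session_id) for t in trials if t.opto
        }
        for i, t in enumerate(trials):
            if i not in drop_reason and (t.mouse_id, t.session_id) in opto_sessions:
                drop_reason[i] = "opto"

    for i, t in enumerate(trials):
        if i in drop_reason:
            continue
        if (
            t.excess_travel_fraction > criteria.max_excess_travel + 1e-12
            or t.timed_out
            or t.aborted
        ):
            drop_reason[i] = "bad_trial"

    for block in iter_blocks(trials):
        surviving = [i for i in block if i not in drop_reason]
        if not surviving:
            continue
        n_correct = sum(trials[i].correct for i in surviving)
        if n_correct / len(surviving) < criteria.min_block_performance - 1e-12:
            for i in surviving:
                drop_reason[i] = "low_block"

    if criteria.require_history_trials > 0:
        for block in iter_blocks(trials):
            surviving = [i for i in block if i not in drop_reason]
            for i in surviving[: criteria.require_history_trials]:
                drop_reason[i] = "history"

    per_mouse: dict[str, list[int]] = {}
    for i, t in enumerate(trials):
        if i not in drop_reason:
            per_mouse.setdefault(t.mouse_id, []).append(i)
    for mouse, idxs in per_mouse.items():
        if len(idxs) < criteria.min_trials_per_mouse:
            for i in idxs:
                drop_reason[i] = "low_mouse"

    kept = [t for i, t in enumerate(trials) if i not in drop_reason]
    reason_field = {
        "maze_level": "excluded_maze_level",
        "opto": "excluded_opto_session",
        "bad_trial": "excluded_bad_trial",
        "low_block": "excluded_low_performance_block",
        "history": "excluded_history_warmup",
        "low_mouse": "excluded_low_trial_mouse",
    }
    for i, reason in drop_reason.items():
        setattr(ledger, reason_field[reason], getattr(ledger, reason_field[reason]) + 1)
        lvl = trials[i].maze_level
        ledger.per_level_excluded[lvl] = ledger.per_level_excluded.get(lvl, 0) + 1
    ledger.n_kept = len(kept)

    if not kept:
        raise NoTrialsError("no trials survive the selection criteria")
    return kept, ledger


def effective_durations(trial: TrialRecord, stem_length_cm: float = 300.0) -> tuple[float, float]:
    """Effective cue and delay durations of a trial, in cm of maze.

    Effective cue duration is the span from first to last tower (both sides
    pooled); effective delay is the stem length (300 cm) minus the last tower
    position.
    """
    positions = list(trial.towers_left) + list(trial.towers_right)
    if not positions:
        raise UndefinedStatisticError("trial has no towers; durations undefined")
    first, last = min(positions), max(positions)
    return last - first, stem_length_cm - last


def exclude_low_performance_bouts(
    trials: Sequence[TrialRecord],
    window_sigma_trials: float = 10.0,
    threshold: float = 0.55,
) -> tuple[list[TrialRecord], list[tuple[int, int]]]:
    """Drop bouts where Gaussian-smoothed running accuracy falls below threshold.

    Trials must be in session order.  Returns surviving trials and the list of
    removed (start, stop) index spans (half-open, in input coordinates).
    """
    if window_sigma_trials <= 0:
        raise ValidationError("window_sigma_trials must be positive")
    if not trials:
        raise NoTrialsError("no trials in input")
    outcomes = np.array([1.0 if t.correct else 0.0 for t in trials])
    smoothed = gaussian_filter1d(outcomes, sigma=window_sigma_trials, mode="nearest")
    below = smoothed < threshold
    kept = [t for t, b in zip(trials, below) if not b]
    spans: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(trials)))
    if not kept:
        raise NoTrialsError("no trials survive the running-performance threshold")
    return kept, spans


def mirror_trial(trial: TrialRecord) -> TrialRecord:
    """Swap left and right everywhere (used by symmetry tests and analyses)."""
    flip = {"L": "R", "R": "L"}
    return replace(
        trial,
        towers_left=trial.towers_right,
        towers_right=trial.towers_left,
        rewarded_side=flip[trial.rewarded_side],
        choice=flip[trial.choice],
    )
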