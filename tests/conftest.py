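import numpy as np
import pytest

from accumtowers.datamodel import MazeConfig, TrialRecord
from accumtowers.task_protocol import draw_towers


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(towers_left, towers_right, choice=None, index=0, mouse="m1", session="s000",
               block=0, level=11, **kwargs):
    """Construct a consistent TrialRecord from tower lists (+optional choice)."""
    nl, nr = len(towers_left), len(towers_right)
    rewarded = "R" if nr > nl else "L"
    if choice is None:
        choice = rewarded
    outcome = "correct" if choice == rewarded else "error"
    return TrialRecord(
        mouse_id=mouse,
        session_id=session,
        block_id=block,
        maze_level=level,
        trial_index=index,
        towers_left=tuple(towers_left),
        towers_right=tuple(towers_right),
        rewarded_side=rewarded,
        choice=choice,
        outcome=outcome,
        **kwargs,
    )


def draw_stimulus_trials(n, seed=0, config=None):
    """n stimulus-only trials from the task generator (choice = rewarded side)."""
    config = config or MazeConfig()
    gen = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        side = "R" if gen.uniform() < 0.5 else "L"
        tl, tr = draw_towers(config, side, gen)
        trials.append(make_trial(tuple(tl), tuple(tr), index=i))
    return trials


@pytest.fixture(scope="session")
def stimulus_trials_2k():
    return draw_stimulus_trials(2000, seed=7)
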