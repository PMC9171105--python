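"""Canonical worked-example logs used across tests and documentation."""

from __future__ import annotations

from pathlib import Path
from typing import Union

from ..agents import AgentParams, run_session
from ..task_model import (
    AttemptLog,
    BlockPosition,
    BoardLayout,
    Condition,
    SessionState,
    play_attempt,
)
from .serialization import write_log

# A fixed four-pair board used by the worked examples: sounds laid out
# explicitly so the fixtures are readable by eye.
_EXAMPLE_ASSIGNMENT = {
    (0, 0): "bee", (0, 2): "bee",
    (0, 1): "lion", (0, 3): "lion",
    (0, 4): "frog", (1, 0): "frog",
    (1, 1): "rooster", (1, 2): "rooster",
}


def example_board() -> BoardLayout:
    cond = Condition.four_pair()
    apertures = cond.default_apertures()
    assignment = {
        BlockPosition(*pos): sound for pos, sound in _EXAMPLE_ASSIGNMENT.items()
    }
    layout = BoardLayout(cond, apertures, assignment, seed=0)
    layout.validate()
    return layout


def _play(state: SessionState, moves) -> AttemptLog:
    for first, second in moves:
        play_attempt(state, BlockPosition(*first), BlockPosition(*second))
    return state.log


def score_example_log() -> AttemptLog:
    """Four attempts: both-new miss (0), one-old miss (-1), both-old miss
    (-2), then a match (+10) — cumulative score 7."""
    state = SessionState(example_board(), subject_id="example_score")
    return _play(
        state,
        [
            ((0, 0), (0, 1)),  # bee / lion: both new, no match -> 0
            ((0, 0), (0, 4)),  # bee / frog: one old, no match -> -1
            ((0, 1), (0, 4)),  # lion / frog: both old, no match -> -2
            ((0, 0), (0, 2)),  # bee / bee: match -> +10
        ],
    )


def anchor_example_log() -> AttemptLog:
    """Three attempts all starting at (0, 0) — anchor index 0 + 1 + 1 = 2."""
    state = SessionState(example_board(), subject_id="example_anchor")
    return _play(
        state,
        [
            ((0, 0), (0, 1)),
            ((0, 0), (0, 3)),
            ((0, 0), (0, 4)),
        ],
    )


def perfect_memory_log(seed: int = 1) -> AttemptLog:
    """A complete four-pair session of the perfect-memory agent (score 40)."""
    params = AgentParams(p_encode=1.0, p_forget=0.0, anchor_propensity=0.0,
                         policy="systematic_scan", seed=seed)
    return run_session(params, example_board(), subject_id="example_perfect")


def make_fixtures(directory: Union[str, Path]) -> dict[str, Path]:
    """Write the worked-example logs to ``directory``; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "score_example": directory / "score_example.csv",
        "anchor_example": directory / "anchor_example.csv",
        "perfect_memory": directory / "perfect_memory.csv",
    }
    write_log(score_example_log(), paths["score_example"])
    write_log(anchor_example_log(), paths["anchor_example"])
    write_log(perfect_memory_log(), paths["perfect_memory"])
    return paths
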