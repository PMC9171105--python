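"""Shared fixtures: boards, random legal play sequences, oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from audiomem.task_model import (
    AttemptLog,
    BoardLayout,
    Condition,
    SessionState,
    new_board,
    play_attempt,
)


@pytest.fixture
def four_pair_board() -> BoardLayout:
    return new_board(Condition.four_pair(), seed=7)


@pytest.fixture
def twelve_pair_board() -> BoardLayout:
    return new_board(Condition.twelve_pair(), seed=7)


def random_legal_log(
    layout: BoardLayout,
    rng: np.random.Generator,
    max_attempts: int | None = None,
    stop_prob: float = 0.0,
) -> AttemptLog:
    """Play uniformly random legal moves until complete (or early stop).

    Independent of the agents module: each attempt touches two distinct
    uniformly chosen in-play apertures.
    """
    state = SessionState(layout)
    while not state.is_complete():
        if max_attempts is not None and len(state.log.attempts) >= max_attempts:
            break
        if stop_prob and state.log.attempts and rng.random() < stop_prob:
            break
        in_play = state.in_play()
        i, j = rng.choice(len(in_play), size=2, replace=False)
        play_attempt(state, in_play[int(i)], in_play[int(j)])
    return state.log


# --- independent per-attempt index oracles (used across test modules) ------


def oracle_score(log: AttemptLog) -> int:
    """Score by per-attempt rule application over touch-count histories."""
    total = 0
    history: list = []
    for att in log:
        prior = lambda pos: sum(
            pos in (a.first, a.second) for a in history
        )
        if att.matched:
            total += 10
        else:
            total -= int(prior(att.first) > 0) + int(prior(att.second) > 0)
        history.append(att)
    return total


def oracle_anchor(log: AttemptLog) -> int:
    firsts = [a.first for a in log]
    return sum(int(a == b) for a, b in zip(firsts[1:], firsts[:-1]))


def oracle_number_of_attempts(log: AttemptLog) -> float:
    """Direct enumeration of discovery and match indices per pair."""
    per_pair = []
    for sound in log.condition.sounds:
        positions = set()
        d = m = None
        for att in log:
            for pos, s in ((att.first, att.first_sound),
                           (att.second, att.second_sound)):
                if s == sound:
                    positions.add(pos)
            if d is None and len(positions) == 2:
                d = att.index
            if att.matched and att.first_sound == sound:
                m = att.index
        assert m is not None, "oracle requires a complete session"
        per_pair.append(m - d)
    return sum(per_pair) / len(per_pair)
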