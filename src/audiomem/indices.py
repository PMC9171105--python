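"""Behavioral indices computed from an attempt log.

Three session-level indices quantify memory and exploration strategy:

``score``
    Cumulative points: a matching attempt adds +10 regardless of prior
    touches; a non-matching attempt subtracts 1 per block that was
    touched in an earlier attempt (0 / -1 / -2).
``number_of_attempts``
    For each pair, the number of attempts elapsed between the attempt
    that completed the discovery of both its positions and the attempt
    that matched it, averaged over pairs.
``audio_anchor``
    The number of attempts (from the second onward) that start at the
    same block as the immediately preceding attempt's first touch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .task_model import AttemptLog, BlockPosition, IllegalLogError


class IncompleteSessionError(ValueError):
    """Raised when an index requires a completed session."""


@dataclass(frozen=True)
class SessionIndices:
    """The index triple of one session plus the raw attempt count."""

    score: int
    number_of_attempts: float
    audio_anchor: int
    n_attempts_total: int


def compute_score(log: AttemptLog, *, validate: bool = True) -> int:
    """Cumulative score of a (possibly incomplete) legal play sequence.

    Each attempt contributes +10 when it matches a pair; otherwise 0 if
    both blocks are first-time touches, -1 if exactly one block was
    touched in an earlier attempt, -2 if both were.  A touch within the
    current attempt does not make a block "previously touched" for the
    same attempt.
    """
    if validate:
        log.validate()
    score = 0
    touched: set[BlockPosition] = set()
    for att in log:
        if att.matched:
            score += 10
        else:
            score -= (att.first in touched) + (att.second in touched)
        touched.update((att.first, att.second))
    return score


def compute_number_of_attempts(
    log: AttemptLog,
    *,
    validate: bool = True,
    inclusive: bool = False,
    partial: bool = False,
) -> float:
    """Mean attempts needed to match each pair once both positions are known.

    For pair ``P`` let ``d(P)`` be the index of the attempt at whose end
    both apertures of ``P`` have been revealed at least once, and
    ``m(P)`` the index of the attempt that matches ``P``.  The per-pair
    count is ``m(P) - d(P)`` (so a pair matched on the attempt that
    first reveals its second member counts 0); the index is the mean
    over pairs.

    Parameters
    ----------
    inclusive
        If true, count ``m(P) - d(P) + 1`` instead (the alternative
        inclusive convention).
    partial
        If true, pairs never matched are skipped with a warning instead
        of raising :class:`IncompleteSessionError`.
    """
    if validate:
        log.validate()
    discovery: dict[str, int] = {}
    match_at: dict[str, int] = {}
    seen: dict[str, set[BlockPosition]] = {}
    for att in log:
        for pos, sound in ((att.first, att.first_sound),
                           (att.second, att.second_sound)):
            seen.setdefault(sound, set()).add(pos)
            if len(seen[sound]) == 2 and sound not in discovery:
                discovery[sound] = att.index
        if att.matched:
            match_at[att.first_sound] = att.index

    expected = set(log.condition.sounds)
    missing = expected - set(match_at)
    if missing:
        if not partial:
            raise IncompleteSessionError(
                f"session incomplete: pairs never matched: {sorted(missing)}"
            )
        warnings.warn(
            f"partial session: skipping unmatched pairs {sorted(missing)}",
            stacklevel=2,
        )
    counted = sorted(expected & set(match_at))
    if not counted:
        raise IncompleteSessionError("no matched pairs to average over")
    offset = 1 if inclusive else 0
    counts = [match_at[s] - discovery[s] + offset for s in counted]
    return sum(counts) / len(counts)


def compute_audio_anchor(log: AttemptLog, *, validate: bool = True) -> int:
    """Count attempts starting at the previous attempt's first block."""
    if validate:
        log.validate()
    attempts = log.attempts
    return sum(
        attempts[t].first == attempts[t - 1].first
        for t in range(1, len(attempts))
    )


def compute_indices(
    log: AttemptLog,
    *,
    validate: bool = True,
    inclusive: bool = False,
    partial: bool = False,
) -> SessionIndices:
    """Bundle the three indices for one completed session."""
    if validate:
        log.validate()
    return SessionIndices(
        score=compute_score(log, validate=False),
        number_of_attempts=compute_number_of_attempts(
            log, validate=False, inclusive=inclusive, partial=partial
        ),
        audio_anchor=compute_audio_anchor(log, validate=False),
        n_attempts_total=len(log.attempts),
    )
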