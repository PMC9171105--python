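"""Board model and rules of the spatialized-sound pairing game.

The device is a 5x5 grid of sound-emitting blocks.  The centre block
(2, 2) is reserved for feedback sounds and is never selectable.  A
*condition* overlays a cardboard grid exposing a subset of blocks (the
apertures); each aperture hides one sound, and every sound occurs on
exactly two apertures.  One *attempt* is an ordered touch of two
distinct apertures; touching both apertures of a pair removes that pair
from play.  A session is complete once every pair has been matched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

GRID_SIZE = 5
CENTER = (2, 2)

#: Canonical sound sets for the two experimental conditions.
FOUR_PAIR_SOUNDS = ("bee", "lion", "frog", "rooster")
TWELVE_PAIR_SOUNDS = (
    "wolf", "dog", "crow", "cat", "elephant", "birds",
    "hen", "sheep", "donkey", "goose", "owl", "horse",
)


class GameError(Exception):
    """Base class for rule violations in the task model."""


class IllegalMoveError(GameError):
    """An attempt violated the rules (bad position, covered pair, ...)."""


class IllegalLogError(GameError):
    """An attempt log is not a legal play sequence."""


class SafetyCapExceeded(GameError):
    """A session did not terminate within the configured attempt cap."""


class BlockPosition(NamedTuple):
    """Zero-based (row, col) grid coordinate; row 0 is the top row."""

    row: int
    col: int

    def validate(self) -> None:
        if not (0 <= self.row < GRID_SIZE and 0 <= self.col < GRID_SIZE):
            raise IllegalMoveError(f"position {self!r} outside the 5x5 grid")
        if (self.row, self.col) == CENTER:
            raise IllegalMoveError(
                "the centre position (2, 2) is the feedback speaker and "
                "cannot be selected"
            )


def all_selectable_positions() -> list[BlockPosition]:
    """All 24 non-centre positions in row-major order."""
    return [
        BlockPosition(r, c)
        for r, c in itertools.product(range(GRID_SIZE), range(GRID_SIZE))
        if (r, c) != CENTER
    ]


@dataclass(frozen=True)
class Condition:
    """A difficulty condition: number of pairs, apertures and sound set.

    The two canonical conditions are :func:`Condition.four_pair` (8
    apertures) and :func:`Condition.twelve_pair` (24 apertures).  Custom
    toy conditions (e.g. 2 pairs on 4 apertures) are permitted for
    testing and exploration.
    """

    name: str
    n_pairs: int
    sounds: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if len(self.sounds) != self.n_pairs:
            raise ValueError(
                f"{self.name}: {self.n_pairs} pairs need {self.n_pairs} "
                f"distinct sounds, got {len(self.sounds)}"
            )
        if len(set(self.sounds)) != len(self.sounds):
            raise ValueError("sound labels must be distinct")
        if self.n_apertures > GRID_SIZE * GRID_SIZE - 1:
            raise ValueError("more apertures than selectable blocks")

    @property
    def n_apertures(self) -> int:
        return 2 * self.n_pairs

    @classmethod
    def four_pair(cls) -> "Condition":
        return cls("four_pair", 4, FOUR_PAIR_SOUNDS)

    @classmethod
    def twelve_pair(cls) -> "Condition":
        return cls("twelve_pair", 12, TWELVE_PAIR_SOUNDS)

    @classmethod
    def from_name(cls, name: str) -> "Condition":
        try:
            return {"four_pair": cls.four_pair, "twelve_pair": cls.twelve_pair}[name]()
        except KeyError:
            raise ValueError(f"unknown condition name: {name!r}") from None

    def default_apertures(self) -> tuple[BlockPosition, ...]:
        """First ``n_apertures`` non-centre positions in row-major order.

        The published grids are only shown pictorially; the default keeps
        the geometry deterministic while ``aperture_spec`` lets callers
        supply the exact physical arrangement.
        """
        return tuple(all_selectable_positions()[: self.n_apertures])


@dataclass(frozen=True)
class BoardLayout:
    """Apertures of one condition plus the hidden sound assignment."""

    condition: Condition
    apertures: tuple[BlockPosition, ...]
    assignment: dict[BlockPosition, str]
    seed: int

    def sound_at(self, pos: BlockPosition) -> str:
        try:
            return self.assignment[pos]
        except KeyError:
            raise IllegalMoveError(f"{pos!r} is not an aperture") from None

    def positions_of(self, sound: str) -> tuple[BlockPosition, BlockPosition]:
        pair = tuple(p for p in self.apertures if self.assignment[p] == sound)
        if len(pair) != 2:
            raise ValueError(f"sound {sound!r} not assigned to exactly two apertures")
        return pair  # type: ignore[return-value]

    def validate(self) -> None:
        cond = self.condition
        if len(self.apertures) != cond.n_apertures:
            raise ValueError(
                f"expected {cond.n_apertures} apertures, got {len(self.apertures)}"
            )
        if len(set(self.apertures)) != len(self.apertures):
            raise ValueError("duplicate apertures")
        for pos in self.apertures:
            pos.validate()
        counts: dict[str, int] = {}
        for pos in self.apertures:
            counts[self.assignment[pos]] = counts.get(self.assignment[pos], 0) + 1
        if sorted(counts) != sorted(cond.sounds) or set(counts.values()) != {2}:
            raise ValueError("every sound must occur on exactly two apertures")


def new_board(
    condition: Condition,
    seed: int,
    aperture_spec: Optional[Sequence[tuple[int, int]]] = None,
) -> BoardLayout:
    """Create a board with a seeded uniform assignment of pairs to apertures.

    Parameters
    ----------
    condition
        The difficulty condition to lay out.
    seed
        Seed for the assignment shuffle; identical seeds give identical
        layouts.
    aperture_spec
        Optional explicit aperture coordinates (ordered, distinct,
        non-centre).  Defaults to the condition's row-major layout.
    """
    if aperture_spec is None:
        apertures = condition.default_apertures()
    else:
        apertures = tuple(BlockPosition(r, c) for r, c in aperture_spec)
        if len(apertures) != condition.n_apertures:
            raise IllegalMoveError(
                f"aperture_spec has {len(apertures)} positions, condition "
                f"{condition.name!r} needs {condition.n_apertures}"
            )
        if len(set(apertures)) != len(apertures):
            raise IllegalMoveError("aperture_spec contains duplicates")
        for pos in apertures:
            pos.validate()
    rng = np.random.default_rng(seed)
    labels = [s for s in condition.sounds for _ in range(2)]
    order = rng.permutation(len(labels))
    assignment = {pos: labels[k] for pos, k in zip(apertures, order)}
    layout = BoardLayout(condition, apertures, assignment, seed)
    layout.validate()
    return layout


@dataclass(frozen=True)
class Attempt:
    """One turn: an ordered touch of two distinct apertures."""

    index: int  # 1-based
    first: BlockPosition
    second: BlockPosition
    first_sound: str
    second_sound: str
    matched: bool

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise IllegalLogError("an attempt must touch two distinct apertures")
        if self.matched != (self.first_sound == self.second_sound):
            raise IllegalLogError("matched flag inconsistent with revealed sounds")


@dataclass
class AttemptLog:
    """The ordered attempts of one session plus subject metadata."""

    condition: Condition
    attempts: list[Attempt] = field(default_factory=list)
    subject_id: Optional[str] = None
    group: Optional[str] = None
    age: Optional[float] = None

    def __len__(self) -> int:
        return len(self.attempts)

    def __iter__(self):
        return iter(self.attempts)

    @property
    def matched_sounds(self) -> set[str]:
        return {a.first_sound for a in self.attempts if a.matched}

    def is_complete(self) -> bool:
        return len(self.matched_sounds) == self.condition.n_pairs

    def validate(self) -> None:
        """Check the log is a legal play sequence.

        Raises :class:`IllegalLogError` on inconsistent labels, re-use of
        a matched aperture, repeated indices, or positions off the grid.
        """
        revealed: dict[BlockPosition, str] = {}
        covered: set[BlockPosition] = set()
        matched: set[str] = set()
        for i, att in enumerate(self.attempts, start=1):
            if att.index != i:
                raise IllegalLogError(
                    f"attempt {i}: index {att.index} out of sequence"
                )
            for pos, sound in ((att.first, att.first_sound),
                               (att.second, att.second_sound)):
                try:
                    pos.validate()
                except IllegalMoveError as exc:
                    raise IllegalLogError(f"attempt {i}: {exc}") from None
                if pos in covered:
                    raise IllegalLogError(
                        f"attempt {i}: aperture {pos!r} was already matched"
                    )
                if revealed.setdefault(pos, sound) != sound:
                    raise IllegalLogError(
                        f"attempt {i}: aperture {pos!r} changed sound from "
                        f"{revealed[pos]!r} to {sound!r}"
                    )
            if att.matched:
                if att.first_sound in matched:
                    raise IllegalLogError(
                        f"attempt {i}: pair {att.first_sound!r} matched twice"
                    )
                matched.add(att.first_sound)
                covered.update((att.first, att.second))


class SessionState:
    """Mutable state of one game session on a fixed layout."""

    def __init__(self, layout: BoardLayout, subject_id: Optional[str] = None,
                 group: Optional[str] = None, age: Optional[float] = None):
        layout.validate()
        self.layout = layout
        self.touched: set[BlockPosition] = set()
        self.matched_pairs: set[str] = set()
        self.log = AttemptLog(layout.condition, [], subject_id, group, age)

    @property
    def covered(self) -> set[BlockPosition]:
        """Apertures removed from play because their pair was matched."""
        return {
            p for p in self.layout.apertures
            if self.layout.assignment[p] in self.matched_pairs
        }

    def in_play(self) -> list[BlockPosition]:
        """Apertures still selectable, in layout order."""
        return [
            p for p in self.layout.apertures
            if self.layout.assignment[p] not in self.matched_pairs
        ]

    def is_complete(self) -> bool:
        return len(self.matched_pairs) == self.layout.condition.n_pairs


def play_attempt(
    state: SessionState, first: BlockPosition, second: BlockPosition
) -> tuple[SessionState, Attempt]:
    """Play one attempt, mutating ``state`` and returning the new record."""
    if state.is_complete():
        raise IllegalMoveError("session already complete")
    first = BlockPosition(*first)
    second = BlockPosition(*second)
    if first == second:
        raise IllegalMoveError("cannot touch the same aperture twice in one attempt")
    for pos in (first, second):
        pos.validate()
        if pos not in state.layout.assignment:
            raise IllegalMoveError(f"{pos!r} is not an aperture of this board")
        if state.layout.assignment[pos] in state.matched_pairs:
            raise IllegalMoveError(f"{pos!r} belongs to an already matched pair")
    s1 = state.layout.sound_at(first)
    s2 = state.layout.sound_at(second)
    attempt = Attempt(
        index=len(state.log.attempts) + 1,
        first=first,
        second=second,
        first_sound=s1,
        second_sound=s2,
        matched=(s1 == s2),
    )
    state.log.attempts.append(attempt)
    state.touched.update((first, second))
    if attempt.matched:
        state.matched_pairs.add(s1)
    return state, attempt


def is_complete(state: SessionState) -> bool:
    """True iff every pair of the condition has been matched."""
    return state.is_complete()
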