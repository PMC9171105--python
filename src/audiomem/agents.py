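"""Synthetic behavioral agents and cohort generation.

An agent plays the pairing game with three parameters that map
one-to-one onto the behavioral indices: ``p_encode`` (probability of
storing a heard sound's position), ``p_forget`` (per-attempt probability
of losing each stored position) and ``anchor_propensity`` (probability
of starting the next attempt at the previous attempt's first block).
The decision rule is:

1. if memory holds both positions of an unmatched pair, play that pair;
2. else pick the first touch: with probability ``anchor_propensity``
   re-touch the previous attempt's first block if it is still in play,
   otherwise per policy (``systematic_scan`` = lowest row-major
   untouched aperture, falling back to the lowest row-major unmatched
   one; ``uniform_random`` = uniform over unmatched apertures);
3. pick the second touch: if the partner of the first-revealed sound is
   in memory, play it; else per policy over the remaining unmatched
   apertures excluding the first.

A cohort emulates the study design: two groups of ``n_per_group``
subjects, each playing both difficulty conditions, with per-subject
parameters drawn from group-level distributions.  Group defaults are
calibration constants, not estimates of human parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .indices import SessionIndices, compute_indices
from .task_model import (
    AttemptLog,
    BlockPosition,
    BoardLayout,
    Condition,
    SafetyCapExceeded,
    SessionState,
    new_board,
    play_attempt,
)

POLICIES = ("systematic_scan", "uniform_random")
DEFAULT_SAFETY_CAP = 10_000


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one synthetic subject."""

    p_encode: float = 1.0
    p_forget: float = 0.0
    anchor_propensity: float = 0.0
    policy: str = "systematic_scan"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_encode", "p_forget", "anchor_propensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}, got {self.policy!r}")


MemoryState = dict[BlockPosition, str]


def _policy_choice(
    candidates: Sequence[BlockPosition],
    policy: str,
    rng: np.random.Generator,
) -> BlockPosition:
    if policy == "systematic_scan":
        return min(candidates)  # row-major order == tuple order
    return candidates[int(rng.integers(len(candidates)))]


def agent_step(
    memory: MemoryState,
    state: SessionState,
    params: AgentParams,
    rng: np.random.Generator,
) -> tuple[BlockPosition, BlockPosition]:
    """Choose the two touches of the next attempt (always a legal move)."""
    if state.is_complete():
        raise ValueError("session already complete")
    in_play = state.in_play()
    live_memory = {
        p: s for p, s in memory.items()
        if s not in state.matched_pairs and p in state.layout.assignment
    }

    # rule 1: a fully known unmatched pair
    by_sound: dict[str, list[BlockPosition]] = {}
    for pos in sorted(live_memory):
        by_sound.setdefault(live_memory[pos], []).append(pos)
    for sound in sorted(by_sound):
        if len(by_sound[sound]) == 2:
            first, second = by_sound[sound]
            return first, second

    # rule 2: first touch
    first: Optional[BlockPosition] = None
    if state.log.attempts and rng.random() < params.anchor_propensity:
        prev_first = state.log.attempts[-1].first
        if prev_first in in_play:
            first = prev_first
    if first is None:
        untouched = [p for p in in_play if p not in state.touched]
        if params.policy == "systematic_scan" and untouched:
            first = _policy_choice(untouched, params.policy, rng)
        else:
            first = _policy_choice(in_play, params.policy, rng)

    # rule 3: second touch — the agent hears the first sound before choosing
    first_sound = state.layout.sound_at(first)
    partner = next(
        (p for p in sorted(live_memory)
         if live_memory[p] == first_sound and p != first),
        None,
    )
    if partner is not None:
        return first, partner
    remaining = [p for p in in_play if p != first]
    untouched = [p for p in remaining if p not in state.touched]
    if params.policy == "systematic_scan" and untouched:
        second = _policy_choice(untouched, params.policy, rng)
    else:
        second = _policy_choice(remaining, params.policy, rng)
    return first, second


def update_memory(
    memory: MemoryState,
    attempt,
    params: AgentParams,
    rng: np.random.Generator,
) -> MemoryState:
    """Encode the attempt's touches, apply forgetting, purge matched sounds."""
    memory = dict(memory)
    for pos, sound in ((attempt.first, attempt.first_sound),
                       (attempt.second, attempt.second_sound)):
        if pos not in memory and rng.random() < params.p_encode:
            memory[pos] = sound
    if params.p_forget > 0.0:
        memory = {
            p: s for p, s in sorted(memory.items())
            if rng.random() >= params.p_forget
        }
    if attempt.matched:
        memory = {p: s for p, s in memory.items() if s != attempt.first_sound}
    return memory


def run_session(
    params: AgentParams,
    layout: BoardLayout,
    rng: Optional[np.random.Generator] = None,
    *,
    safety_cap: int = DEFAULT_SAFETY_CAP,
    subject_id: Optional[str] = None,
    group: Optional[str] = None,
    age: Optional[float] = None,
) -> AttemptLog:
    """Play a full session; deterministic given ``params.seed`` or ``rng``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = SessionState(layout, subject_id=subject_id, group=group, age=age)
    memory: MemoryState = {}
    while not state.is_complete():
        if len(state.log.attempts) >= safety_cap:
            raise SafetyCapExceeded(
                f"session exceeded the safety cap of {safety_cap} attempts"
            )
        first, second = agent_step(memory, state, params, rng)
        _, attempt = play_attempt(state, first, second)
        memory = update_memory(memory, attempt, params, rng)
    return state.log


@dataclass(frozen=True)
class GroupParams:
    """Means and spreads of the per-subject parameter draws for one group."""

    p_encode_mean: float
    p_encode_sd: float = 0.05
    p_forget_mean: float = 0.0
    p_forget_sd: float = 0.0
    anchor_mean: float = 0.0
    anchor_sd: float = 0.05
    policy: str = "uniform_random"


#: Calibration constants for the two synthetic groups (not estimates of
#: human parameters): the "sighted_like" group encodes well, forgets
#: moderately and anchors rarely; the "blind_like" group encodes and
#: retains worse and anchors often.  The nonzero forgetting rates are
#: what makes the harder condition costly enough that mean Score drops
#: below the easy condition, as observed in the study.
DEFAULT_GROUP_PARAMS = {
    "sighted_like": GroupParams(
        p_encode_mean=0.8, p_forget_mean=0.55, p_forget_sd=0.05,
        anchor_mean=0.1,
    ),
    "blind_like": GroupParams(
        p_encode_mean=0.35, p_forget_mean=0.7, p_forget_sd=0.05,
        anchor_mean=0.5,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort: 2 groups x 2 within-subject conditions."""

    n_per_group: int = 12
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    age_range: tuple[float, float] = (12.0, 54.0)
    conditions: tuple[str, ...] = ("four_pair", "twelve_pair")
    master_seed: int = 0
    safety_cap: int = DEFAULT_SAFETY_CAP
    aperture_specs: Optional[dict[str, list[tuple[int, int]]]] = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.group_params) != 2:
            raise ValueError("exactly two groups are required")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be ordered (lo, hi)")


def _truncated_normal(
    mean: float, sd: float, rng: np.random.Generator
) -> float:
    if sd == 0.0:
        return float(np.clip(mean, 0.0, 1.0))
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def draw_subject_params(
    gp: GroupParams, seed: int, rng: np.random.Generator
) -> AgentParams:
    """Draw one subject's parameters, truncated to [0, 1]."""
    return AgentParams(
        p_encode=_truncated_normal(gp.p_encode_mean, gp.p_encode_sd, rng),
        p_forget=_truncated_normal(gp.p_forget_mean, gp.p_forget_sd, rng),
        anchor_propensity=_truncated_normal(gp.anchor_mean, gp.anchor_sd, rng),
        policy=gp.policy,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[AttemptLog]]:
    """Simulate a full cohort; fully reproducible from ``master_seed``.

    Per-subject and per-session random streams are spawned from
    ``numpy.random.SeedSequence(master_seed)`` in a fixed order (groups
    sorted by name, subjects by index, conditions in spec order), so
    seeds never collide and the output is bit-reproducible.

    Returns a table with one row per subject x condition (columns:
    subject_id, group, age, condition, score, number_of_attempts,
    audio_anchor, n_attempts_total) and the raw attempt logs.
    """
    root = np.random.SeedSequence(spec.master_seed)
    n_cond = len(spec.conditions)
    n_subjects = 2 * spec.n_per_group
    children = root.spawn(n_subjects * (1 + n_cond))

    rows = []
    logs: list[AttemptLog] = []
    child_i = 0
    for g_i, group in enumerate(sorted(spec.group_params)):
        gp = spec.group_params[group]
        for s_i in range(spec.n_per_group):
            subject_id = f"{group}_{s_i + 1:02d}"
            subj_rng = np.random.default_rng(children[child_i])
            child_i += 1
            params = draw_subject_params(gp, seed=0, rng=subj_rng)
            age = float(subj_rng.uniform(*spec.age_range))
            for cond_name in spec.conditions:
                cond = Condition.from_name(cond_name)
                sess_ss = children[child_i]
                child_i += 1
                board_seed = int(sess_ss.generate_state(1)[0])
                spec_apertures = (
                    spec.aperture_specs.get(cond_name)
                    if spec.aperture_specs else None
                )
                layout = new_board(cond, board_seed, spec_apertures)
                log = run_session(
                    params,
                    layout,
                    np.random.default_rng(sess_ss),
                    safety_cap=spec.safety_cap,
                    subject_id=subject_id,
                    group=group,
                    age=age,
                )
                idx = compute_indices(log, validate=False)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "age": age,
                        "condition": cond_name,
                        "score": idx.score,
                        "number_of_attempts": idx.number_of_attempts,
                        "audio_anchor": idx.audio_anchor,
                        "n_attempts_total": idx.n_attempts_total,
                    }
                )
                logs.append(log)
    table = pd.DataFrame(rows)
    return table, logs
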