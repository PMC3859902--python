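"""Structure of the two-choice discrimination ("fruit box") task.

A session consists of 96 trials arranged in 8 blocks of 12. On each trial
one of 6 discriminative stimuli is shown and the subject responds LEFT or
RIGHT; three stimuli are rewarded for LEFT and three for RIGHT, and each
stimulus maps to a unique outcome identity. Contingencies are fixed for the
whole session; within every block each stimulus appears exactly twice, in
randomized order.

Stimuli and outcomes are abstract labels (``S1``..``S6``, ``O1``..``O6``);
fruit pictures are presentation-layer detail the model never sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

LEFT = "LEFT"
RIGHT = "RIGHT"
RESPONSES = (LEFT, RIGHT)

N_STIMULI = 6
N_BLOCKS = 8
TRIALS_PER_BLOCK = 12
REPEATS_PER_BLOCK = 2  # each stimulus appears twice per block
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK

STIMULI = tuple(f"S{i}" for i in range(1, N_STIMULI + 1))
OUTCOMES = tuple(f"O{i}" for i in range(1, N_STIMULI + 1))


@dataclass(frozen=True)
class ContingencyMap:
    """Fixed stimulus -> (correct response, outcome identity) assignments.

    Exactly half the stimuli are rewarded for LEFT and half for RIGHT, and
    ``outcome_of`` is a bijection between stimuli and outcome labels. The
    map is immutable for the lifetime of a session.
    """

    stimuli: tuple[str, ...]
    outcomes: tuple[str, ...]
    correct_response: Mapping[str, str]
    outcome_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.stimuli) != N_STIMULI or len(set(self.stimuli)) != N_STIMULI:
            raise ValueError(f"expected {N_STIMULI} distinct stimuli")
        if len(self.outcomes) != N_STIMULI or len(set(self.outcomes)) != N_STIMULI:
            raise ValueError(f"expected {N_STIMULI} distinct outcomes")
        object.__setattr__(
            self, "correct_response", MappingProxyType(dict(self.correct_response))
        )
        object.__setattr__(self, "outcome_of", MappingProxyType(dict(self.outcome_of)))
        if set(self.correct_response) != set(self.stimuli):
            raise ValueError("correct_response must cover every stimulus")
        n_left = sum(r == LEFT for r in self.correct_response.values())
        if n_left != N_STIMULI // 2:
            raise ValueError(
                f"{N_STIMULI // 2} stimuli must map to LEFT, got {n_left}"
            )
        if sorted(self.outcome_of) != sorted(self.stimuli) or sorted(
            self.outcome_of.values()
        ) != sorted(self.outcomes):
            raise ValueError("outcome_of must be a stimulus -> outcome bijection")

    def stimulus_index(self, stimulus: str) -> int:
        return self.stimuli.index(stimulus)


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled trial: its position, block and stimulus."""

    trial_index: int  # 1-based
    block: int  # 1-based; == ceil(trial_index / 12)
    stimulus: str

    def __post_init__(self) -> None:
        expected_block = (self.trial_index - 1) // TRIALS_PER_BLOCK + 1
        if self.block != expected_block:
            raise ValueError(
                f"trial {self.trial_index} belongs to block {expected_block}, "
                f"got {self.block}"
            )


@dataclass(frozen=True)
class Schedule:
    """An ordered 96-slot presentation schedule."""

    slots: tuple[TrialSlot, ...]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.slots)

    def block_slots(self, block: int) -> tuple[TrialSlot, ...]:
        return tuple(s for s in self.slots if s.block == block)


def make_contingency(seed: int) -> ContingencyMap:
    """Draw a counterbalanced contingency map.

    Which three stimuli are rewarded for LEFT and which outcome follows each
    stimulus are both uniform random draws, so that across subjects (seeds)
    every stimulus serves each role about equally often. Deterministic for a
    fixed seed.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    left_idx = set(rng.permutation(N_STIMULI)[: N_STIMULI // 2])
    correct = {
        s: (LEFT if i in left_idx else RIGHT) for i, s in enumerate(STIMULI)
    }
    outcome_perm = rng.permutation(N_STIMULI)
    outcome_of = {s: OUTCOMES[j] for s, j in zip(STIMULI, outcome_perm)}
    return ContingencyMap(STIMULI, OUTCOMES, correct, outcome_of)


def build_schedule(contingency: ContingencyMap, seed: int) -> Schedule:
    """Randomize the 8-block x 12-trial presentation order.

    Each block holds every stimulus exactly twice; blocks are shuffled
    independently and uniformly. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(N_STIMULI), REPEATS_PER_BLOCK)
    slots: list[TrialSlot] = []
    for block in range(1, N_BLOCKS + 1):
        order = rng.permutation(base)
        for pos, stim_idx in enumerate(order):
            trial_index = (block - 1) * TRIALS_PER_BLOCK + pos + 1
            slots.append(
                TrialSlot(trial_index, block, contingency.stimuli[stim_idx])
            )
    return Schedule(tuple(slots), seed=seed)


def validate_schedule(schedule: Schedule) -> list[str]:
    """Check schedule invariants; return a list of violations (empty = valid).

    Violations name the block and stimulus involved so a bad schedule can be
    traced to its construction.
    """
    violations: list[str] = []
    if len(schedule.slots) != N_TRIALS:
        violations.append(
            f"schedule has {len(schedule.slots)} slots, expected {N_TRIALS}"
        )
    for i, slot in enumerate(schedule.slots, start=1):
        if slot.trial_index != i:
            violations.append(
                f"slot {i} carries trial_index {slot.trial_index} (must be {i})"
            )
            break
    blocks: dict[int, list[str]] = {}
    for slot in schedule.slots:
        blocks.setdefault(slot.block, []).append(slot.stimulus)
    for block in range(1, N_BLOCKS + 1):
        stims = blocks.get(block, [])
        if len(stims) != TRIALS_PER_BLOCK:
            violations.append(
                f"block {block} has {len(stims)} trials, expected {TRIALS_PER_BLOCK}"
            )
        counts = pd.Series(stims).value_counts() if stims else pd.Series(dtype=int)
        for stimulus in STIMULI:
            c = int(counts.get(stimulus, 0))
            if c != REPEATS_PER_BLOCK:
                violations.append(
                    f"block {block}: stimulus {stimulus} appears {c} times, "
                    f"expected {REPEATS_PER_BLOCK}"
                )
    return violations


def schedule_to_frame(schedule: Schedule, contingency: ContingencyMap) -> pd.DataFrame:
    """Tabular view of a schedule (one row per trial)."""
    return pd.DataFrame(
        {
            "trial_index": [s.trial_index for s in schedule.slots],
            "block": [s.block for s in schedule.slots],
            "stimulus": [s.stimulus for s in schedule.slots],
            "correct_response": [
                contingency.correct_response[s.stimulus] for s in schedule.slots
            ],
        }
    )


def write_schedule(
    schedule: Schedule, contingency: ContingencyMap, path: str
) -> None:
    schedule_to_frame(schedule, contingency).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_schedule(path: str) -> tuple[Schedule, dict[str, str]]:
    """Load a schedule table; returns the schedule and its correct-response map."""
    df = pd.read_csv(path)
    slots = tuple(
        TrialSlot(int(r.trial_index), int(r.block), str(r.stimulus))
        for r in df.itertuples()
    )
    correct = dict(
        zip(df["stimulus"].astype(str), df["correct_response"].astype(str))
    )
    return Schedule(slots), correct
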