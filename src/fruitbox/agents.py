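"""Generative choice models: Q-learning agents and random responders.

The agent keeps one weight W in [0, 1] per (stimulus, response) pair —
12 weights for the 6-stimulus, two-response task. On each trial the
response is drawn from a softmax over the two weights of the presented
stimulus, with inverse-gain (exploration) parameter beta:

    P(LEFT) = exp(W_left / beta) / (exp(W_left / beta) + exp(W_right / beta))

Feedback is deterministic — the correct response always delivers the reward
(US = 1), the incorrect one nothing (US = 0) — and only the chosen pair's
weight is updated by the delta rule W <- W + alpha * (US - W).

The same model, replayed against observed choices, is the likelihood that
:mod:`fruitbox.fit` maximizes; generator and fitter must agree on the
initial weight ``w_init`` (default 0.5, the midpoint of the US range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import (
    LEFT,
    N_TRIALS,
    RESPONSES,
    RIGHT,
    ContingencyMap,
    Schedule,
)

TRIAL_COLUMNS = ("trial_index", "block", "stimulus", "response", "us", "correct")

DEFAULT_W_INIT = 0.5


@dataclass(frozen=True)
class AgentParams:
    """A subject's (learning rate, exploration) pair.

    alpha scales the prediction-error update; beta divides the weights
    inside the softmax, so small beta means exploitation and large beta
    exploration. Both are dimensionless.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")


@dataclass(frozen=True)
class SessionData:
    """One subject's ordered 96-trial record.

    ``trials`` is a DataFrame with columns trial_index, block, stimulus,
    response, us, correct — one row per trial, ordered 1..96. ``us`` (the
    delivered feedback) equals ``correct`` because feedback is deterministic.
    """

    subject_id: str
    schedule_seed: int
    agent_seed: int
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _choice_prob_left(w_left: float, w_right: float, beta: float) -> float:
    # stable two-option softmax: sigmoid of the scaled weight difference
    return float(expit((w_left - w_right) / beta))


def simulate_session(
    params: AgentParams,
    contingency: ContingencyMap,
    schedule: Schedule,
    seed: int,
    w_init: float = DEFAULT_W_INIT,
) -> SessionData:
    """Play a schedule with a Q-learning agent and record every trial.

    Responses are sampled from the softmax choice rule given the current
    weights; the chosen (stimulus, response) weight is then updated with the
    realized feedback. Deterministic for fixed (params, seeds).
    """
    if params.beta <= 0:
        raise ValueError("beta must be positive (degenerate softmax otherwise)")
    if not 0.0 <= w_init <= 1.0:
        raise ValueError("w_init must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_stim = len(contingency.stimuli)
    w = np.full((n_stim, 2), float(w_init))  # columns: LEFT, RIGHT
    rows = []
    for slot in schedule.slots:
        s = contingency.stimulus_index(slot.stimulus)
        p_left = _choice_prob_left(w[s, 0], w[s, 1], params.beta)
        r = 0 if rng.random() < p_left else 1
        response = RESPONSES[r]
        us = int(response == contingency.correct_response[slot.stimulus])
        w[s, r] += params.alpha * (us - w[s, r])
        rows.append((slot.trial_index, slot.block, slot.stimulus, response, us, us))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionData(
        subject_id="sim",
        schedule_seed=schedule.seed,
        agent_seed=seed,
        trials=trials,
    )


def simulate_random_session(
    schedule: Schedule, contingency: ContingencyMap, seed: int
) -> SessionData:
    """Play a schedule with a memoryless coin-flip responder (p = 0.5)."""
    rng = np.random.default_rng(seed)
    rows = []
    for slot in schedule.slots:
        response = RESPONSES[int(rng.random() < 0.5)]
        us = int(response == contingency.correct_response[slot.stimulus])
        rows.append((slot.trial_index, slot.block, slot.stimulus, response, us, us))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionData(
        subject_id="random",
        schedule_seed=schedule.seed,
        agent_seed=seed,
        trials=trials,
    )


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    """Stack sessions into the long interchange table (one row per trial).

    Columns: subject_id, trial_index, block, stimulus, response, correct.
    ``us`` is omitted because feedback is deterministic (us == correct).
    """
    frames = []
    for s in sessions:
        df = s.trials[["trial_index", "block", "stimulus", "response", "correct"]].copy()
        df.insert(0, "subject_id", s.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_sessions(df: pd.DataFrame) -> list[SessionData]:
    """Inverse of :func:`sessions_to_frame` (``us`` restored from ``correct``)."""
    required = {"subject_id", "trial_index", "block", "stimulus", "response", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    sessions = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        trials = sub.sort_values("trial_index").reset_index(drop=True)
        trials = trials[["trial_index", "block", "stimulus", "response", "correct"]].copy()
        trials.insert(4, "us", trials["correct"].astype(int))
        sessions.append(
            SessionData(
                subject_id=str(subject_id),
                schedule_seed=-1,
                agent_seed=-1,
                trials=trials,
            )
        )
    return sessions
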