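"""Grid-search maximum-likelihood fitting of the Q-learning choice model.

A subject's 96 binary choices are replayed trial by trial: at each trial the
model assigns a softmax probability to the response the subject actually
made, then updates the chosen (stimulus, response) weight with the delivered
feedback via the delta rule

    PE(t) = US(t) - W(t),        W(t+1) = W(t) + alpha * PE(t).

The session log-likelihood LLE = sum_t log p(choice_t) is evaluated on a
dense (alpha, beta) grid (default step 0.01 on both axes) and the maximizing
pair is reported. Fit quality is summarized by a pseudo-R^2 against the
random responder that picks LEFT/RIGHT with p = 0.5 on every trial:

    pseudo_R2 = 1 - LLE / r,     r = n_trials * ln(1/2),

which is 0 for a chance-level fit and 1 for perfect prediction. Because the
grid contains alpha = 0 and the initial weights are response-symmetric, the
fitted LLE can never fall below r, so pseudo-R^2 is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import DEFAULT_W_INIT, SessionData
from .task import RESPONSES

__all__ = [
    "FitGrid",
    "FitResult",
    "SessionFormatError",
    "update_weight",
    "choice_probabilities",
    "session_loglik",
    "fit_grid",
    "fit_sessions",
    "pseudo_r2",
]


class SessionFormatError(ValueError):
    """A trial table that cannot be replayed (bad stimulus, response or order)."""


@dataclass(frozen=True)
class FitGrid:
    """The (alpha, beta) search lattice.

    alpha spans [0, 1]; beta spans (0, 1] — beta = 0 is excluded because it
    degenerates the softmax into a step function with zero-probability
    events. Both axes must be strictly increasing.
    """

    alpha_values: np.ndarray
    beta_values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_values, dtype=float)
        b = np.asarray(self.beta_values, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
            raise ValueError("grid axes must be non-empty 1-D sequences")
        if np.any(np.diff(a) <= 0) or np.any(np.diff(b) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if a[0] < 0 or a[-1] > 1 or b[0] <= 0 or b[-1] > 1:
            raise ValueError("alpha in [0,1] and beta in (0,1] required")
        object.__setattr__(self, "alpha_values", a)
        object.__setattr__(self, "beta_values", b)

    @classmethod
    def default(cls, step: float = 0.01) -> "FitGrid":
        """alpha = 0, step, ..., 1; beta = step, 2*step, ..., 1."""
        n = int(round(1.0 / step))
        alpha = np.linspace(0.0, 1.0, n + 1)
        beta = np.linspace(step, 1.0, n)
        return cls(alpha, beta)


@dataclass(frozen=True)
class FitResult:
    """Grid-search ML estimate for one session."""

    alpha_hat: float
    beta_hat: float
    lle: float  # log-likelihood at the optimum, nats
    pseudo_r2: float
    n_trials: int


def update_weight(w: float, us: int, alpha: float) -> float:
    """Delta-rule update of the chosen pair's weight: w + alpha * (us - w).

    A convex combination of w and us, so weights initialized in [0, 1]
    stay there.
    """
    return w + alpha * (us - w)


def choice_probabilities(
    w_left: float, w_right: float, beta: float
) -> tuple[float, float]:
    """Two-option softmax with inverse-gain beta, computed stably.

    p_left = exp(w_left/beta) / (exp(w_left/beta) + exp(w_right/beta)),
    evaluated as a sigmoid of the scaled difference so no overflow occurs.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = (w_left - w_right) / beta
    # each side as its own sigmoid: 1 - sigmoid(z) would cancel catastrophically
    # for saturated margins (small beta), losing the tail probability entirely
    p_left = 1.0 / (1.0 + np.exp(-z))
    p_right = 1.0 / (1.0 + np.exp(z))
    return float(p_left), float(p_right)


def _stimulus_vocab(contingency) -> tuple[str, ...]:
    """Accept a ContingencyMap or any ordered stimulus collection."""
    return tuple(getattr(contingency, "stimuli", contingency))


def _session_arrays(
    session: SessionData, contingency
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Validate a session and encode it as (stimulus index, response index, us)."""
    trials = session.trials
    n = len(trials)
    expected = np.arange(1, n + 1)
    if not np.array_equal(trials["trial_index"].to_numpy(), expected):
        raise SessionFormatError(
            f"subject {session.subject_id}: trial_index must run 1..{n} without gaps"
        )
    stim_codes = {s: i for i, s in enumerate(_stimulus_vocab(contingency))}
    try:
        stim = np.array([stim_codes[s] for s in trials["stimulus"]], dtype=np.intp)
    except KeyError as err:
        bad = trials.index[~trials["stimulus"].isin(stim_codes)][0]
        raise SessionFormatError(
            f"subject {session.subject_id}, trial {int(trials['trial_index'].iloc[bad])}: "
            f"unknown stimulus {err.args[0]!r}"
        ) from None
    resp_codes = {r: i for i, r in enumerate(RESPONSES)}
    try:
        resp = np.array([resp_codes[r] for r in trials["response"]], dtype=np.intp)
    except KeyError as err:
        bad = trials.index[~trials["response"].isin(resp_codes)][0]
        raise SessionFormatError(
            f"subject {session.subject_id}, trial {int(trials['trial_index'].iloc[bad])}: "
            f"unknown response {err.args[0]!r}"
        ) from None
    us = trials["us"].to_numpy(dtype=float)
    if not np.isin(us, (0.0, 1.0)).all():
        raise SessionFormatError(
            f"subject {session.subject_id}: us must be 0 or 1 on every trial"
        )
    return stim, resp, us


def session_loglik(
    session: SessionData,
    contingency: ContingencyMap,
    alpha: float,
    beta: float,
    w_init: float = DEFAULT_W_INIT,
) -> tuple[float, np.ndarray]:
    """Sequential log-likelihood of an observed session at one (alpha, beta).

    Replays the session: at each trial the model probability of the response
    the subject actually made is recorded, then the chosen pair's weight is
    updated with the recorded feedback. Returns (lle, per-trial choice
    probabilities); lle <= 0 always.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    stim, resp, us = _session_arrays(session, contingency)
    n_stim = len(_stimulus_vocab(contingency))
    w = np.full((n_stim, 2), float(w_init))
    log_p = np.empty(len(stim))
    for t in range(len(stim)):
        s, r = stim[t], resp[t]
        z = (w[s, r] - w[s, 1 - r]) / beta  # chosen-minus-unchosen margin
        log_p[t] = -np.logaddexp(0.0, -z)  # log sigmoid(z), no underflow
        w[s, r] = update_weight(w[s, r], us[t], alpha)
    return float(log_p.sum()), np.exp(log_p)


def _weight_margin_by_alpha(
    stim: np.ndarray,
    resp: np.ndarray,
    us: np.ndarray,
    alphas: np.ndarray,
    n_stim: int,
    w_init: float,
) -> np.ndarray:
    """Per-trial weight margin of the chosen response, for every alpha at once.

    The weight trajectory depends on alpha but not beta, so the grid search
    factorizes: replay the session once per alpha (vectorized across the
    alpha axis) and record d(t) = W_chosen - W_unchosen before each update.
    Returns an (n_alpha, n_trials) array.
    """
    n_alpha, n_trials = alphas.size, stim.size
    w = np.full((n_alpha, n_stim, 2), float(w_init))
    d = np.empty((n_alpha, n_trials))
    for t in range(n_trials):
        s, r = stim[t], resp[t]
        chosen = w[:, s, r]
        d[:, t] = chosen - w[:, s, 1 - r]
        w[:, s, r] = chosen + alphas * (us[t] - chosen)
    return d


def fit_grid(
    session: SessionData,
    contingency: ContingencyMap,
    grid: FitGrid | None = None,
    w_init: float = DEFAULT_W_INIT,
) -> FitResult:
    """Exhaustive grid search for the ML (alpha, beta) of one session.

    Evaluates the session log-likelihood at every grid point and returns the
    maximizer; exact ties are broken toward the smallest beta, then the
    smallest alpha, so results are deterministic. The returned pseudo-R^2
    compares the optimum against the p = 0.5 random responder.
    """
    if grid is None:
        grid = FitGrid.default()
    stim, resp, us = _session_arrays(session, contingency)
    d = _weight_margin_by_alpha(
        stim, resp, us, grid.alpha_values, len(_stimulus_vocab(contingency)), w_init
    )
    # lle(alpha, beta) = sum_t log sigmoid(d_t(alpha) / beta)
    z = d[:, None, :] / grid.beta_values[None, :, None]  # (A, B, T)
    lle = -np.sum(np.logaddexp(0.0, -z), axis=2)  # (A, B)
    best = lle.max()
    ties = np.argwhere(lle == best)  # exact ties only (e.g. alpha = 0 row)
    order = np.lexsort((ties[:, 0], ties[:, 1]))  # smallest beta, then alpha
    ai, bi = ties[order[0]]
    return FitResult(
        alpha_hat=float(grid.alpha_values[ai]),
        beta_hat=float(grid.beta_values[bi]),
        lle=float(best),
        pseudo_r2=pseudo_r2(float(best), len(stim)),
        n_trials=len(stim),
    )


def fit_sessions(
    sessions,
    contingency=None,
    grid: FitGrid | None = None,
    w_init: float = DEFAULT_W_INIT,
):
    """Grid-fit a list of sessions; returns a per-subject fit table.

    Columns: subject_id, alpha_hat, beta_hat, lle, pseudo_r2, n_trials.
    When ``contingency`` is None the canonical S1..S6 vocabulary is assumed.
    """
    import pandas as pd

    from .task import STIMULI

    vocab = STIMULI if contingency is None else contingency
    rows = []
    for session in sessions:
        res = fit_grid(session, vocab, grid=grid, w_init=w_init)
        rows.append(
            {
                "subject_id": session.subject_id,
                "alpha_hat": res.alpha_hat,
                "beta_hat": res.beta_hat,
                "lle": res.lle,
                "pseudo_r2": res.pseudo_r2,
                "n_trials": res.n_trials,
            }
        )
    return pd.DataFrame(rows)


def pseudo_r2(lle: float, n_trials: int) -> float:
    """Improvement over the random responder, normalized: 1 - lle / r.

    r = n_trials * ln(1/2) is the log-likelihood of any binary choice
    sequence under the p = 0.5 coin-flip model. 0 means chance-level fit,
    1 perfect prediction; positive values mean better than chance.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if lle > 0:
        raise ValueError("log-likelihood must be <= 0")
    r = n_trials * np.log(0.5)
    return float(1.0 - lle / r)
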