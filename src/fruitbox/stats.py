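"""Behavioral summaries and group contrasts.

Block-wise and overall accuracy per session, two-sample contrasts of any
per-subject measure (permutation test on the mean difference by default,
with Welch's t and Mann-Whitney U available for parity with standard
practice), and a covariate screen correlating clinical variables against a
learning measure. Permutation p-values use seeded label shuffles and the
add-one estimator (1 + #extreme) / (n_perm + 1), which can never return 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agents import SessionData
from .fit import SessionFormatError
from .task import N_BLOCKS, N_TRIALS, TRIALS_PER_BLOCK

METHODS = ("permutation", "welch_t", "mann_whitney")
DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class BlockAccuracy:
    subject_id: str
    acc: np.ndarray  # 8 proportions, each k/12


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    method: str
    statistic: float
    p_value: float
    group_means: tuple[float, float]


def block_accuracy(session: SessionData) -> BlockAccuracy:
    """Proportion correct per 12-trial block."""
    trials = session.trials
    if len(trials) != N_TRIALS:
        raise SessionFormatError(
            f"subject {session.subject_id}: expected {N_TRIALS} trials, "
            f"got {len(trials)}"
        )
    acc = (
        trials.groupby("block")["correct"].sum().reindex(range(1, N_BLOCKS + 1))
        / TRIALS_PER_BLOCK
    )
    if acc.isna().any():
        raise SessionFormatError(
            f"subject {session.subject_id}: missing blocks "
            f"{list(acc.index[acc.isna()])}"
        )
    return BlockAccuracy(session.subject_id, acc.to_numpy(dtype=float))


def overall_accuracy(session: SessionData) -> float:
    """Proportion correct across all trials; equals the mean block accuracy."""
    return float(session.trials["correct"].mean())


def block_accuracy_matrix(sessions: list[SessionData]) -> pd.DataFrame:
    """Subjects x blocks accuracy table (columns block_1..block_8)."""
    rows = {
        s.subject_id: block_accuracy(s).acc for s in sessions
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"block_{b}" for b in range(1, N_BLOCKS + 1)]
    ).rename_axis("subject_id")


def _perm_mean_diff_p(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Two-sided permutation p for the difference of group means."""
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    # each row of idx is an independent uniform permutation of 0..n-1
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[idx]
    diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    p = (1 + np.sum(np.abs(diffs) >= abs(obs) - 1e-12)) / (n_perm + 1)
    return float(obs), float(p)


def compare_groups(
    values_a,
    values_b,
    method: str = "permutation",
    measure: str = "",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> ComparisonResult:
    """Two-sample contrast of a per-subject measure.

    ``permutation`` shuffles group labels and compares mean differences
    (two-sided); ``welch_t`` and ``mann_whitney`` delegate to scipy.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if method == "permutation":
        stat, p = _perm_mean_diff_p(a, b, n_perm, np.random.default_rng(seed))
    elif method == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        measure=measure,
        method=method,
        statistic=stat,
        p_value=p,
        group_means=(float(a.mean()), float(b.mean())),
    )


def perm_corr_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Pearson r of (x, y) with a two-sided permutation p (shuffling y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    n = x.size
    r_obs = float(zx @ zy / n)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = zy[idx] @ zx / n
    p = (1 + np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)) / (n_perm + 1)
    return r_obs, float(p)


def null_covariate_screen(
    cohort: pd.DataFrame,
    covariates: list[str],
    target: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate each covariate against a target measure.

    Returns one row per covariate with Pearson r and a permutation p;
    constant covariates are flagged and get r = NaN rather than an error,
    since a screen should report every variable it was asked about.
    """
    missing = [c for c in covariates + [target] if c not in cohort.columns]
    if missing:
        raise ValueError(f"columns not in cohort table: {missing}")
    rng = np.random.default_rng(seed)
    y = cohort[target].to_numpy(dtype=float)
    rows = []
    for cov in covariates:
        x = cohort[cov].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append(
                {"covariate": cov, "r": np.nan, "p_value": np.nan, "constant": True}
            )
            continue
        r, p = perm_corr_pvalue(x, y, n_perm, rng)
        rows.append({"covariate": cov, "r": r, "p_value": p, "constant": False})
    return pd.DataFrame(rows)
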