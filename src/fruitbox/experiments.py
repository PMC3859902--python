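"""Canned simulation experiments: parameter recovery and cohort replication.

These drive the whole pipeline end to end and are what the validation suite
and the reproduction script execute. Each experiment takes a single master
seed and derives all of its randomness from it, so results are exactly
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import AgentParams, simulate_random_session, simulate_session
from .brain import association_table
from .cohort import ROI_REGIONS, CohortSpec, cohort_to_frame, sample_cohort
from .fit import FitGrid, fit_grid, fit_sessions
from .stats import compare_groups
from .task import build_schedule, make_contingency

# published group-level generating values: (alpha, beta) means
CONTROL_PARAMS = (0.217, 0.70)
PD_PARAMS = (0.163, 0.85)


def _session_seeds(master_seed: int, n: int) -> list[np.ndarray]:
    return [
        np.random.default_rng(ss).integers(2**31, size=3)
        for ss in np.random.SeedSequence(master_seed).spawn(n)
    ]


def recovery_experiment(
    alpha: float,
    beta: float,
    n_sessions: int = 200,
    master_seed: int = 0,
    grid_step: float = 0.01,
    w_init: float = 0.5,
) -> pd.DataFrame:
    """Simulate agents at fixed (alpha, beta) and grid-fit every session.

    Every subject gets its own counterbalanced contingency, schedule and
    choice stream. Returns one row per session with the recovered
    parameters; recovery quality is summarized by the column means.
    """
    grid = FitGrid.default(grid_step)
    params = AgentParams(alpha, beta)
    rows = []
    for seeds in _session_seeds(master_seed, n_sessions):
        contingency = make_contingency(int(seeds[0]))
        schedule = build_schedule(contingency, int(seeds[1]))
        session = simulate_session(
            params, contingency, schedule, int(seeds[2]), w_init=w_init
        )
        res = fit_grid(session, contingency, grid=grid, w_init=w_init)
        rows.append(
            {
                "true_alpha": alpha,
                "true_beta": beta,
                "alpha_hat": res.alpha_hat,
                "beta_hat": res.beta_hat,
                "lle": res.lle,
                "pseudo_r2": res.pseudo_r2,
            }
        )
    return pd.DataFrame(rows)


def random_responder_experiment(
    n_sessions: int = 500, master_seed: int = 0, grid_step: float = 0.01
) -> np.ndarray:
    """Fit coin-flip responders; returns the fitted pseudo-R2 per session.

    The overfitting margin of the two-parameter model on 96 Bernoulli(0.5)
    trials: values are guaranteed >= 0 (the grid contains alpha = 0) and
    should be small.
    """
    grid = FitGrid.default(grid_step)
    out = np.empty(n_sessions)
    for i, seeds in enumerate(_session_seeds(master_seed, n_sessions)):
        contingency = make_contingency(int(seeds[0]))
        schedule = build_schedule(contingency, int(seeds[1]))
        session = simulate_random_session(schedule, contingency, int(seeds[2]))
        out[i] = fit_grid(session, contingency, grid=grid).pseudo_r2
    return out


def group_contrast_experiment(
    n_cohorts: int = 200,
    master_seed: int = 0,
    grid_step: float = 0.02,
    n_perm: int = 10_000,
) -> pd.DataFrame:
    """Replicate the control-vs-PD learning-rate contrast on synthetic cohorts.

    For each replicate: sample a default cohort (n = 11 controls, 17 PD),
    grid-fit every subject's session, and contrast recovered alpha between
    groups with a seeded permutation test. One row per cohort.
    """
    grid = FitGrid.default(grid_step)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_cohorts)
    rows = []
    for k, seed in enumerate(seeds):
        records = sample_cohort(CohortSpec(master_seed=int(seed % 2**31)))
        fits = fit_sessions([r.session for r in records], grid=grid)
        groups = np.array([r.group for r in records])
        a = fits["alpha_hat"].to_numpy()
        ctl, pdg = a[groups == "CONTROL"], a[groups == "PD"]
        res = compare_groups(ctl, pdg, n_perm=n_perm, seed=int(seed % 2**31))
        rows.append(
            {
                "cohort": k,
                "mean_alpha_control": ctl.mean(),
                "mean_alpha_pd": pdg.mean(),
                "direction_correct": ctl.mean() > pdg.mean(),
                "perm_p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def brain_behavior_experiment(
    n_cohorts: int = 200,
    master_seed: int = 0,
    n_perm: int = 10_000,
) -> pd.DataFrame:
    """Replicate the ROI association pattern across synthetic cohorts.

    For each replicate, sample a default cohort and run the marginal and
    partial association of each ROI with the PD group's generating learning
    rates (the coupling the generator encodes). One row per (cohort, region)
    with significance indicators at p < 0.05.
    """
    seeds = np.random.SeedSequence(master_seed).generate_state(n_cohorts)
    rows = []
    for k, seed in enumerate(seeds):
        records = sample_cohort(CohortSpec(master_seed=int(seed % 2**31)))
        df = cohort_to_frame(records).set_index("subject_id")
        pdg = df[df["group"] == "PD"]
        table = association_table(
            pdg[list(ROI_REGIONS)],
            pdg["true_alpha"],
            n_perm=n_perm,
            seed=int(seed % 2**31),
        )
        for rec in table.to_dict("records"):
            rows.append(
                {
                    "cohort": k,
                    "region": rec["region"],
                    "marginal_sig": rec["marginal_p"] < 0.05,
                    "partial_sig": rec["partial_p"] < 0.05,
                }
            )
    return pd.DataFrame(rows)
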