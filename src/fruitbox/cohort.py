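"""Synthetic cohorts: subjects with parameters, covariates, ROI values and sessions.

Stands in for a real patient study with a control group (n = 11) and a
Parkinson's-disease group (n = 17). Each subject receives:

* generating (alpha, beta) drawn from group-specific normal distributions
  truncated to the fitting grid's support (alpha in [0, 1], beta in (0, 1]);
  the default group means/SDs are the published control and PD values
  (alpha 0.217 (0.036) vs 0.163 (0.041); beta 0.70 (0.26) vs 0.85 (0.30));
* clinical covariates (disease duration, Hoehn & Yahr stage, UPDRS-III,
  dopamine dose equivalent, BDI) drawn independently of alpha, so their
  association with learning rate is null by construction;
* gray-matter values for three regions of interest, generated from a single
  latent driver: vmPFC carries the alpha coupling, while rIFG and NAcc are
  correlated bystanders with no direct alpha coupling — giving the
  partial-correlation analysis a recoverable ground truth;
* its own counterbalanced contingency map, randomized schedule, and a
  simulated 96-trial session played by its generating agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .agents import AgentParams, SessionData, simulate_session
from .task import build_schedule, make_contingency

ROI_REGIONS = ("vmPFC", "rIFG", "NAcc")

# clinical covariate -> (mean, sd, lower clip, upper clip); PD-cohort summary
# statistics, in the covariate's natural units
CLINICAL_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "disease_duration": (5.6, 5.4, 0.0, np.inf),  # years since diagnosis
    "hoehn_yahr": (2.1, 0.52, 1.0, 5.0),  # disease stage
    "updrs_iii": (29.2, 12.8, 0.0, 108.0),  # motor score
    "dde": (616.1, 453.1, 0.0, np.inf),  # dopamine dose equivalent, mg/day
    "bdi": (10.6, 6.9, 0.0, 63.0),  # depression inventory
}

_BETA_FLOOR = 1e-6  # beta = 0 degenerates the softmax; truncate just above


@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions and coupling structure for a synthetic cohort."""

    n_control: int = 11
    n_pd: int = 17
    alpha_mean_control: float = 0.217
    alpha_sd_control: float = 0.036
    alpha_mean_pd: float = 0.163
    alpha_sd_pd: float = 0.041
    beta_mean_control: float = 0.70
    beta_sd_control: float = 0.26
    beta_mean_pd: float = 0.85
    beta_sd_pd: float = 0.30
    roi_effect: float = 1.0  # coupling of the vmPFC latent to standardized alpha
    roi_cross_corr: float = 0.5  # correlation of bystander ROIs with vmPFC
    w_init: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_pd < 1:
            raise ValueError("group sizes must be >= 1")
        for name in ("alpha_mean_control", "alpha_mean_pd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "alpha_sd_control",
            "alpha_sd_pd",
            "beta_sd_control",
            "beta_sd_pd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.roi_cross_corr) < 1:
            raise ValueError("|roi_cross_corr| must be < 1")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"cohort": asdict(self)}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc["cohort"])


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: group, ground truth, covariates, ROI values, data."""

    subject_id: str
    group: str  # "CONTROL" or "PD"
    true_params: AgentParams
    clinical: dict[str, float]
    roi: dict[str, float]
    session: SessionData = field(repr=False)


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a full synthetic cohort and simulate every subject's session.

    Deterministic for a fixed ``master_seed``; each subject gets independent
    streams for contingency counterbalancing, schedule order and choices.
    """
    root = np.random.SeedSequence(spec.master_seed)
    ss_params, ss_clin, ss_roi, ss_sessions = root.spawn(4)
    rng_params = np.random.default_rng(ss_params)
    rng_clin = np.random.default_rng(ss_clin)
    rng_roi = np.random.default_rng(ss_roi)

    groups = ["CONTROL"] * spec.n_control + ["PD"] * spec.n_pd
    n = len(groups)
    alphas = np.concatenate(
        [
            _truncated_normal(
                spec.alpha_mean_control, spec.alpha_sd_control, 0.0, 1.0,
                spec.n_control, rng_params,
            ),
            _truncated_normal(
                spec.alpha_mean_pd, spec.alpha_sd_pd, 0.0, 1.0,
                spec.n_pd, rng_params,
            ),
        ]
    )
    betas = np.concatenate(
        [
            _truncated_normal(
                spec.beta_mean_control, spec.beta_sd_control, _BETA_FLOOR, 1.0,
                spec.n_control, rng_params,
            ),
            _truncated_normal(
                spec.beta_mean_pd, spec.beta_sd_pd, _BETA_FLOOR, 1.0,
                spec.n_pd, rng_params,
            ),
        ]
    )

    clinical = {
        name: _truncated_normal(mean, sd, lo, hi, n, rng_clin)
        for name, (mean, sd, lo, hi) in CLINICAL_COVARIATES.items()
    }
    roi = _sample_roi(alphas, spec, rng_roi)

    records: list[SubjectRecord] = []
    child_seeds = ss_sessions.spawn(n)
    for i, group in enumerate(groups):
        sid = f"{'ctl' if group == 'CONTROL' else 'pd'}{i + 1:03d}"
        seeds = np.random.default_rng(child_seeds[i]).integers(2**31, size=3)
        contingency = make_contingency(int(seeds[0]))
        schedule = build_schedule(contingency, int(seeds[1]))
        params = AgentParams(float(alphas[i]), float(betas[i]))
        session = simulate_session(
            params, contingency, schedule, int(seeds[2]), w_init=spec.w_init
        )
        session = SessionData(
            subject_id=sid,
            schedule_seed=session.schedule_seed,
            agent_seed=session.agent_seed,
            trials=session.trials,
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                true_params=params,
                clinical={k: float(v[i]) for k, v in clinical.items()},
                roi={k: float(roi[k][i]) for k in ROI_REGIONS},
                session=session,
            )
        )
    return records


def _sample_roi(
    alphas: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Single-latent-driver ROI structure.

    vmPFC = roi_effect * z(alpha) + N(0, 1); bystanders load on standardized
    vmPFC with weight roi_cross_corr and carry no direct alpha term, so any
    bystander-alpha correlation flows entirely through vmPFC and vanishes
    once vmPFC is partialled out. Values are rescaled to gray-matter-density
    -like units (0.45 +/- 0.05 per latent SD); correlations are unaffected.
    """
    n = alphas.size
    sd = alphas.std()
    z_alpha = (alphas - alphas.mean()) / sd if sd > 0 else np.zeros(n)
    vmpfc = spec.roi_effect * z_alpha + rng.standard_normal(n)
    v_sd = vmpfc.std()
    v = (vmpfc - vmpfc.mean()) / v_sd if v_sd > 0 else np.zeros(n)
    rcc = spec.roi_cross_corr
    latent = {
        "vmPFC": v,
        "rIFG": rcc * v + np.sqrt(1 - rcc**2) * rng.standard_normal(n),
        "NAcc": rcc * v + np.sqrt(1 - rcc**2) * rng.standard_normal(n),
    }
    return {k: 0.45 + 0.05 * x for k, x in latent.items()}


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject: group, generating params, covariates, ROI values."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "group": r.group,
            "true_alpha": r.true_params.alpha,
            "true_beta": r.true_params.beta,
        }
        row.update(r.clinical)
        row.update(r.roi)
        rows.append(row)
    return pd.DataFrame(rows)
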