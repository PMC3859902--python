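"""Structure-behavior association on region-of-interest (ROI) summary values.

Given per-subject gray-matter values for a few regions and a behavioral
measure (here, the recovered or generating learning rate), two questions are
asked: which regions correlate with the measure marginally, and which still
correlate once the other regions are held constant. The partial correlation
uses the residual method — regress both the target region and the measure on
the control regions (ordinary least squares with an intercept) and correlate
the residuals — which for a handful of regions is equivalent to the
inverse-correlation-matrix formula. Inference is by seeded permutation,
shuffling the measure (or its residuals) across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import DEFAULT_N_PERM, perm_corr_pvalue

COLLINEARITY_CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class AssociationResult:
    region: str
    partial_r: float
    partial_p: float
    controls: tuple[str, ...]
    collinear: bool = False


def _aligned(roi: pd.DataFrame, measure: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    if not roi.index.equals(measure.index):
        if set(roi.index) != set(measure.index):
            raise ValueError(
                "ROI table and measure cover different subjects: "
                f"{sorted(set(roi.index) ^ set(measure.index))}"
            )
        measure = measure.reindex(roi.index)
    values = roi.to_numpy(dtype=float)
    if not np.isfinite(values).all() or not np.isfinite(measure.to_numpy()).all():
        raise ValueError("ROI and measure values must be finite")
    if len(roi) < 4:
        raise ValueError("need at least 4 subjects for a correlation")
    return roi, measure.to_numpy(dtype=float)


def marginal_association(
    roi: pd.DataFrame,
    measure: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson r of each region with the measure, with permutation p.

    ``roi`` is a subjects x regions table indexed by subject id; ``measure``
    is a per-subject series on the same index.
    """
    roi, y = _aligned(roi, measure)
    rng = np.random.default_rng(seed)
    rows = []
    for region in roi.columns:
        r, p = perm_corr_pvalue(roi[region].to_numpy(dtype=float), y, n_perm, rng)
        rows.append({"region": region, "marginal_r": r, "marginal_p": p})
    return pd.DataFrame(rows)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def partial_association(
    roi: pd.DataFrame,
    measure: pd.Series,
    target_region: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> AssociationResult:
    """Correlation of one region with the measure, controlling for the rest.

    Both the target region and the measure are regressed on the remaining
    regions (with intercept); the Pearson correlation of the two residual
    vectors is the partial correlation, and its permutation p shuffles the
    measure residuals. Near-collinear control regions (design condition
    number above 1e8) or a target fully explained by the controls are
    flagged and reported with partial_r = NaN.
    """
    if target_region not in roi.columns:
        raise ValueError(f"unknown target region {target_region!r}")
    roi, y = _aligned(roi, measure)
    controls = tuple(c for c in roi.columns if c != target_region)
    if len(roi) <= len(controls) + 2:
        raise ValueError(
            f"need more than {len(controls) + 2} subjects to control for "
            f"{len(controls)} regions"
        )
    X = np.column_stack(
        [np.ones(len(roi))] + [roi[c].to_numpy(dtype=float) for c in controls]
    )
    target = roi[target_region].to_numpy(dtype=float)
    collinear = np.linalg.cond(X) > COLLINEARITY_CONDITION_LIMIT
    res_t = _residualize(target, X)
    res_y = _residualize(y, X)
    if collinear or res_t.std() < 1e-12 * max(1.0, np.abs(target).max()):
        return AssociationResult(
            region=target_region,
            partial_r=float("nan"),
            partial_p=float("nan"),
            controls=controls,
            collinear=True,
        )
    rng = np.random.default_rng(seed)
    r, p = perm_corr_pvalue(res_t, res_y, n_perm, rng)
    return AssociationResult(
        region=target_region, partial_r=r, partial_p=p, controls=controls
    )


def association_table(
    roi: pd.DataFrame,
    measure: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal and partial association for every region, one row per region."""
    marg = marginal_association(roi, measure, n_perm=n_perm, seed=seed)
    partial_rows = []
    for i, region in enumerate(roi.columns):
        res = partial_association(
            roi, measure, region, n_perm=n_perm, seed=seed + i + 1
        )
        partial_rows.append(
            {
                "region": region,
                "partial_r": res.partial_r,
                "partial_p": res.partial_p,
                "collinear": res.collinear,
            }
        )
    return marg.merge(pd.DataFrame(partial_rows), on="region")
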