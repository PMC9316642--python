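"""Stage 1: per-subject trajectory extraction.

Visit-level trait values are reduced to two numbers per subject — the level at
the subject's own mean age and the annual change rate — by weighted least
squares on centred age.  Weights are the inverse cross-sectional residual
variances per visit (heteroscedasticity across visits is the norm for
repeat-measured physiological traits), estimated by regressing the trait on
age, sex and height among the subjects observed at that visit.  Subjects with
fewer than ``min_visits`` (default 3) observations are excluded.  Trajectory
parameters are then mapped to normal scores by a rank-based inverse normal
transformation before any mixed-model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .simdata import LongitudinalCohort

__all__ = [
    "VisitWeights",
    "SubjectTrajectory",
    "estimate_visit_weights",
    "fit_subject_trajectories",
    "trajectories_frame",
    "inverse_normal_transform",
]

DEFAULT_WEIGHT_COVARIATES = ("age", "sex", "height")


@dataclass
class VisitWeights:
    """Inverse residual-variance weights per visit for one trait."""

    trait: str
    weights: dict[int, float]
    residual_vars: dict[int, float]
    n_obs: dict[int, int] = field(default_factory=dict)
    excluded_visits: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for j, w in self.weights.items():
            rv = self.residual_vars[j]
            if not (np.isfinite(w) and w > 0 and np.isclose(w, 1.0 / rv)):
                raise ValueError(f"weight for visit {j} is not 1/residual_var")

    def to_frame(self) -> pd.DataFrame:
        visits = sorted(self.weights)
        return pd.DataFrame(
            {
                "trait": self.trait,
                "visit": visits,
                "residual_var": [self.residual_vars[j] for j in visits],
                "weight": [self.weights[j] for j in visits],
                "n_obs": [self.n_obs.get(j, np.nan) for j in visits],
            }
        )


@dataclass
class SubjectTrajectory:
    subject_id: str
    trait: str
    beta0: float  # level at the subject's mean observed age
    beta1: float  # annual change rate
    n_visits_used: int
    mean_age: float


def estimate_visit_weights(
    cohort: LongitudinalCohort,
    trait: str,
    covariates: tuple[str, ...] = DEFAULT_WEIGHT_COVARIATES,
) -> VisitWeights:
    """Per-visit inverse residual variances from cross-sectional regressions.

    At each visit ``j``, the trait is regressed by OLS on an intercept plus
    ``covariates`` over all subjects observed at ``j`` (including subjects that
    later fail the minimum-visit filter — every observation informs the visit's
    error variance).  The residual variance uses the unbiased divisor
    ``n_j - p - 1``.  Visits with too few complete observations are excluded
    with a warning; a visit with zero residual variance is degenerate and
    raises.
    """
    if trait not in cohort.traits:
        raise ValueError(f"unknown trait {trait!r}")
    df = cohort.data
    weights: dict[int, float] = {}
    resvars: dict[int, float] = {}
    n_obs: dict[int, int] = {}
    excluded: list[int] = []
    p = len(covariates)
    for j, sub in df.groupby("visit"):
        sub = sub.dropna(subset=[trait, *covariates])
        nj = len(sub)
        if nj < p + 2:
            excluded.append(int(j))
            warnings.warn(
                f"visit {j}: only {nj} complete observations; excluded from weights",
                stacklevel=2,
            )
            continue
        X = np.column_stack(
            [np.ones(nj)] + [sub[c].to_numpy(dtype=float) for c in covariates]
        )
        y = sub[trait].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        s2 = rss / (nj - p - 1)
        if not np.isfinite(s2) or s2 <= 1e-10 * (1.0 + float(np.mean(y**2))):
            raise ValueError(f"visit {j}: degenerate (zero) residual variance")
        resvars[int(j)] = s2
        weights[int(j)] = 1.0 / s2
        n_obs[int(j)] = nj
    if not weights:
        raise ValueError("no visit had enough observations to estimate weights")
    return VisitWeights(
        trait=trait,
        weights=weights,
        residual_vars=resvars,
        n_obs=n_obs,
        excluded_visits=excluded,
    )


def fit_subject_trajectories(
    cohort: LongitudinalCohort,
    trait: str,
    weights: VisitWeights,
    min_visits: int = 3,
) -> list[SubjectTrajectory]:
    """Per-subject weighted regression of the trait on centred age.

    For each subject with at least ``min_visits`` non-missing observations,
    solves the two-parameter weighted least squares of ``y_ij`` on
    ``(1, age_ij - mean(age_i))`` with the visit weights.  Centring makes the
    two estimates orthogonal under equal weights, so ``beta0`` is the
    subject's (weighted) mean level and ``beta1`` the annual change rate.
    Subjects whose observed ages are all equal have a singular design and are
    dropped with a warning.
    """
    df = cohort.data.dropna(subset=[trait])
    out: list[SubjectTrajectory] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        if len(sub) < min_visits:
            continue
        visits = sub["visit"].to_numpy(dtype=int)
        missing_w = [int(j) for j in visits if int(j) not in weights.weights]
        if missing_w:
            raise ValueError(
                f"subject {sid}: no weight available for attended visit(s) {missing_w}"
            )
        ages = sub["age"].to_numpy(dtype=float)
        if np.ptp(ages) == 0:
            warnings.warn(f"subject {sid}: all ages equal; dropped", stacklevel=2)
            continue
        y = sub[trait].to_numpy(dtype=float)
        w = np.array([weights.weights[int(j)] for j in visits])
        mean_age = ages.mean()
        x = ages - mean_age
        # weighted normal equations for (1, x)
        sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
        swy, swxy = (w * y).sum(), (w * x * y).sum()
        det = sw * swxx - swx**2
        b0 = (swxx * swy - swx * swxy) / det
        b1 = (sw * swxy - swx * swy) / det
        out.append(
            SubjectTrajectory(
                subject_id=str(sid),
                trait=trait,
                beta0=float(b0),
                beta1=float(b1),
                n_visits_used=len(sub),
                mean_age=float(mean_age),
            )
        )
    if not out:
        raise ValueError("all subjects were filtered out; no trajectories estimated")
    return out


def trajectories_frame(trajs: list[SubjectTrajectory]) -> pd.DataFrame:
    """Tabular view: subject_id, trait, beta0, beta1, n_visits, mean_age."""
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in trajs],
            "trait": [t.trait for t in trajs],
            "beta0": [t.beta0 for t in trajs],
            "beta1": [t.beta1 for t in trajs],
            "n_visits": [t.n_visits_used for t in trajs],
            "mean_age": [t.mean_age for t in trajs],
        }
    )


def inverse_normal_transform(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    A value with (average, for ties) rank ``r`` among ``n`` maps to
    ``Phi^-1((r - c) / (n - 2c + 1))``.  Strictly rank-preserving on tie-free
    input; the transformed vector has mean ~0 and unit-normal margins.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; rank transform undefined")
    r = rankdata(v, method="average")
    return ndtri((r - c) / (v.size - 2 * c + 1))
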