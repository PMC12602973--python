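"""Multivariate outlier screening and feature/outcome scaling.

Outlier screening uses the classical Mahalanobis distance of the three
geometry features (P, L, S) against the chi-square quantile with 3 degrees of
freedom — the 0.95 quantile is 7.81, matching the published cutoff, which is
what pins the screening to the feature space rather than the joint
feature+outcome space.  Scaling (min-max on features, division by 100 on the
percent outcomes) maps training data into the operating range of the sigmoid
network; values outside [0, 1] on unseen data are deliberately NOT clipped so
the inverse transform stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from dvhpredict.synthetic import CaseRecord

_FEATURE_DIM = 3
_OUTCOME_DIVISOR = 100.0


@dataclass
class OutlierReport:
    """Outcome of one Mahalanobis screening pass."""

    threshold: float
    alpha: float
    removed_ids: list[str]
    retained_count: int
    distances: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "alpha": self.alpha,
            "removed_ids": list(self.removed_ids),
            "retained_count": self.retained_count,
            "distances": dict(self.distances),
        }


@dataclass
class ScalingParams:
    """Min-max bounds per feature plus the fixed percent→fraction divisor."""

    feature_min: np.ndarray
    feature_max: np.ndarray
    outcome_divisor: float = _OUTCOME_DIVISOR

    def to_dict(self) -> dict:
        return {
            "feature_min": [float(v) for v in self.feature_min],
            "feature_max": [float(v) for v in self.feature_max],
            "outcome_divisor": self.outcome_divisor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            feature_min=np.asarray(d["feature_min"], dtype=float),
            feature_max=np.asarray(d["feature_max"], dtype=float),
            outcome_divisor=float(d["outcome_divisor"]),
        )


def chi2_threshold(alpha: float, dims: int) -> float:
    """Squared-distance cutoff: inverse chi-square CDF at 1 - alpha, ``dims`` df."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if dims < 1:
        raise ValueError("dims must be a positive integer")
    return float(stats.chi2.ppf(1.0 - alpha, df=dims))


def squared_mahalanobis(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distances of rows of x from (mean, cov)."""
    centered = np.atleast_2d(x) - mean
    try:
        solved = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "feature covariance is singular; inspect the features for collinearity "
            "or add a ridge regularization before screening"
        ) from exc
    return np.einsum("ij,ji->i", centered, solved)


def mahalanobis_filter(
    cohort: Sequence[CaseRecord], alpha: float = 0.05
) -> tuple[list[CaseRecord], OutlierReport]:
    """Remove cases whose (P, L, S) squared Mahalanobis distance exceeds the cutoff.

    Distances use the classical sample mean and covariance of the whole input
    cohort (single pass, no robust re-estimation); removal is strict
    inequality against ``chi2_threshold(alpha, 3)``.
    """
    if len(cohort) <= _FEATURE_DIM + 1:
        raise ValueError("cohort too small for covariance estimation (need > dims + 1 cases)")
    feats = np.array([r.features() for r in cohort], dtype=float)
    mean = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False)
    d2 = squared_mahalanobis(feats, mean, cov)
    threshold = chi2_threshold(alpha, _FEATURE_DIM)
    keep = d2 <= threshold
    retained = [r for r, k in zip(cohort, keep) if k]
    report = OutlierReport(
        threshold=threshold,
        alpha=alpha,
        removed_ids=[r.case_id for r, k in zip(cohort, keep) if not k],
        retained_count=int(keep.sum()),
        distances={r.case_id: float(d) for r, d in zip(cohort, d2)},
    )
    return retained, report


def fit_scaler(cohort: Sequence[CaseRecord]) -> ScalingParams:
    """Min-max bounds of (P, L, S) over the given (training) cohort."""
    if len(cohort) == 0:
        raise ValueError("cannot fit a scaler on an empty cohort")
    feats = np.array([r.features() for r in cohort], dtype=float)
    fmin = feats.min(axis=0)
    fmax = feats.max(axis=0)
    degenerate = np.isclose(fmax, fmin)
    if degenerate.any():
        names = np.array(["P", "L", "S"])[degenerate]
        raise ValueError(f"degenerate (constant) feature range for: {', '.join(names)}")
    return ScalingParams(feature_min=fmin, feature_max=fmax)


def apply_scaler(
    cohort: Sequence[CaseRecord], params: ScalingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled design matrices: X via min-max, Y via division by 100."""
    feats = np.array([r.features() for r in cohort], dtype=float)
    outs = np.array([r.outcomes() for r in cohort], dtype=float)
    x = (feats - params.feature_min) / (params.feature_max - params.feature_min)
    y = outs / params.outcome_divisor
    return x, y


def scale_features(raw_features: np.ndarray, params: ScalingParams) -> np.ndarray:
    raw_features = np.atleast_2d(np.asarray(raw_features, dtype=float))
    return (raw_features - params.feature_min) / (params.feature_max - params.feature_min)


def invert_scaler(
    x: np.ndarray, y: np.ndarray, params: ScalingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`apply_scaler` (no clipping anywhere)."""
    feats = np.asarray(x) * (params.feature_max - params.feature_min) + params.feature_min
    outs = np.asarray(y) * params.outcome_divisor
    return feats, outs
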