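"""Mapping HRV fatigue features to a Brief Fatigue Inventory estimate (MBFI).

Two routes are implemented:

1. **Fitted linear mapping.**  Ordinary least squares of the self-reported
   BFI on the three features (sleep disorder ratio, mean sleep LF-HF,
   active disorder ratio — fractions on the 0-1 scale) with an intercept:

       MBFI = alpha * r_sleep + beta * mean_lfhf + gamma * r_active + eps

2. **Unit-weight mapping with group compensation.**  To avoid refitting
   weights for every cohort, all three weights are fixed at 1 (no
   intercept) and a per-group compensation factor — the group mean of
   (BFI - unit-weight MBFI) — is added.  Groups follow the clustering seen
   in the data: A (BFI = 0), B (0 < BFI <= 3), C (BFI > 3).

Either way a negative estimate is clipped to 0 (BFI is a 0-10 scale); the
unclipped value is kept for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .features import FatigueFeatures

__all__ = [
    "MappingWeights",
    "FatigueGroup",
    "CompensationTable",
    "MbfiEstimate",
    "compute_mbfi",
    "fit_weights",
    "assign_group",
    "unit_mbfi",
    "compensation_factors",
    "compensated_mbfi",
    "map_cohort",
    "severity_band",
]


class FatigueGroup(str, Enum):
    """BFI clusters used for compensation: A no fatigue, B mild, C moderate+."""

    A = "A"
    B = "B"
    C = "C"


@dataclass(frozen=True)
class MappingWeights:
    """Weight vector {alpha, beta, gamma, epsilon} with fit diagnostics."""

    alpha: float
    beta: float
    gamma: float
    epsilon: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "epsilon"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.epsilon])


@dataclass(frozen=True)
class MbfiEstimate:
    """A mapped BFI with its pre-clipping value retained for diagnostics."""

    value: float  # clipped at 0
    unclipped: float
    group: FatigueGroup | None = None


@dataclass(frozen=True)
class CompensationTable:
    """Per-group compensation factors CF_W = mean(BFI - unit-weight MBFI)."""

    factors: dict[FatigueGroup, float] = field(default_factory=dict)
    counts: dict[FatigueGroup, int] = field(default_factory=dict)

    def factor(self, group: FatigueGroup) -> float:
        if group not in self.factors:
            raise KeyError(f"no compensation factor for group {group.value}")
        return self.factors[group]


def _feature_matrix(features: Sequence[FatigueFeatures]) -> np.ndarray:
    return np.vstack([f.vector for f in features])


def compute_mbfi(features: FatigueFeatures, weights: MappingWeights) -> MbfiEstimate:
    """Evaluate the linear mapping for one patient and clip at zero."""
    vec = features.vector
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"features for {features.patient_id} contain non-finite values")
    raw = float(weights.alpha * vec[0] + weights.beta * vec[1] + weights.gamma * vec[2]
                + weights.epsilon)
    return MbfiEstimate(value=max(0.0, raw), unclipped=raw)


def fit_weights(
    features: Sequence[FatigueFeatures], bfi: Sequence[float]
) -> MappingWeights:
    """OLS fit of BFI on the three features with an intercept.

    Returns the weight vector and R^2 (computed on the unclipped fitted
    values).  A constant BFI vector yields zero slopes and R^2 = 0; a
    rank-deficient design raises ``ValueError``.
    """
    if len(features) != len(bfi):
        raise ValueError("features and bfi must have equal length")
    if len(features) < 5:
        raise ValueError(f"need >= 5 patients to fit 4 parameters, got {len(features)}")
    x = sm.add_constant(_feature_matrix(features), has_constant="add")
    y = np.asarray(bfi, dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix: feature columns are linearly dependent")
    res = sm.OLS(y, x).fit()
    const, alpha, beta, gamma = res.params
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
    if not np.isfinite(r2):  # constant response: nothing to explain
        r2 = 0.0
    return MappingWeights(alpha=float(alpha), beta=float(beta), gamma=float(gamma),
                          epsilon=float(const), r_squared=min(max(r2, 0.0), 1.0))


def assign_group(bfi: float) -> FatigueGroup:
    """Cluster a BFI score: A iff 0, C iff > 3, otherwise B."""
    if not 0.0 <= bfi <= 10.0:
        raise ValueError(f"BFI must be in [0, 10], got {bfi}")
    if bfi == 0.0:
        return FatigueGroup.A
    if bfi > 3.0:
        return FatigueGroup.C
    return FatigueGroup.B


def severity_band(bfi: float) -> str:
    """Conventional BFI severity label (none / mild < 3 / moderate 4-7 / severe > 7).

    The printed band edges leave [3, 4) unassigned; it is folded into
    "moderate" (the nearest band).  Note this labelling differs from the
    A/B/C clustering used for compensation.
    """
    if not 0.0 <= bfi <= 10.0:
        raise ValueError(f"BFI must be in [0, 10], got {bfi}")
    if bfi == 0.0:
        return "No"
    if bfi < 3.0:
        return "Mild"
    if bfi <= 7.0:
        return "Moderate"
    return "Severe"


def unit_mbfi(features: FatigueFeatures) -> float:
    """Unit-weight mapping: the plain sum of the three features (no shift)."""
    return float(features.vector.sum())


def compensation_factors(
    features: Sequence[FatigueFeatures], bfi: Sequence[float]
) -> CompensationTable:
    """Group-mean differences between BFI and the unit-weight MBFI.

    CF_W = (1 / N_W) * sum over group members of (BFI_P - MBFI_P), with the
    unit-weight, unclipped MBFI.  Adding CF_W to every member's MBFI
    centres each group's residuals at exactly zero (before clipping).
    """
    if len(features) != len(bfi):
        raise ValueError("features and bfi must have equal length")
    deltas: dict[FatigueGroup, list[float]] = {}
    for f, b in zip(features, bfi):
        deltas.setdefault(assign_group(b), []).append(b - unit_mbfi(f))
    factors = {g: float(np.mean(d)) for g, d in deltas.items()}
    counts = {g: len(d) for g, d in deltas.items()}
    return CompensationTable(factors=factors, counts=counts)


def compensated_mbfi(
    features: FatigueFeatures,
    table: CompensationTable,
    group: FatigueGroup,
) -> MbfiEstimate:
    """Unit-weight MBFI plus the group's compensation factor, clipped at 0."""
    raw = unit_mbfi(features) + table.factor(group)
    return MbfiEstimate(value=max(0.0, raw), unclipped=raw, group=group)


def map_cohort(
    features: Sequence[FatigueFeatures], bfi: Sequence[float]
) -> tuple[CompensationTable, list[MbfiEstimate]]:
    """Compensated unit-weight MBFI for a whole cohort (factors from the same cohort)."""
    table = compensation_factors(features, bfi)
    estimates = [
        compensated_mbfi(f, table, assign_group(b)) for f, b in zip(features, bfi)
    ]
    return table, estimates
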