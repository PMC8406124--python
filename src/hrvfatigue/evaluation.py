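"""Mapping-quality metrics: MAE/RMSE by fatigue group, error rate, correlations.

The error rate expresses the total MAE as a percentage of the BFI scale
width (10), e.g. MAE 0.3 -> 3%.  Feature-BFI correlations default to the
Pearson product-moment coefficient; Spearman (average ranks for ties) is
available for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .features import FatigueFeatures
from .mapping import FatigueGroup, MbfiEstimate, assign_group

__all__ = [
    "EvaluationReport",
    "mae",
    "rmse",
    "error_rate",
    "correlate",
    "evaluate_mapping",
]

#: width of the BFI scale (0-10) used by the error rate
BFI_SCALE_WIDTH = 10.0

FEATURE_NAMES = ("sleep_disorder_ratio", "mean_sleep_lfhf", "active_disorder_ratio")


def _paired(pred: Sequence[float], obs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pred and obs must be equal-length non-empty 1-D sequences")
    return p, o


def mae(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean absolute error between predicted and observed scores."""
    p, o = _paired(pred, obs)
    return float(np.abs(o - p).mean())


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root mean square error between predicted and observed scores."""
    p, o = _paired(pred, obs)
    return float(np.sqrt(((o - p) ** 2).mean()))


def error_rate(mae_total: float, scale_width: float = BFI_SCALE_WIDTH) -> float:
    """MAE as a percentage of the score scale width."""
    if scale_width <= 0:
        raise ValueError("scale_width must be positive")
    return mae_total / scale_width * 100.0


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Correlation coefficient between two equal-length sequences."""
    xv, yv = _paired(x, y)
    if xv.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a correlation")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("correlate requires finite values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined: one input has zero variance")
    if method == "pearson":
        return float(stats.pearsonr(xv, yv).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xv, yv).statistic)
    raise ValueError(f"unknown correlation method: {method!r}")


@dataclass(frozen=True)
class EvaluationReport:
    """Stratified mapping errors plus the feature-BFI correlation table."""

    group_mae: dict[str, float]
    group_rmse: dict[str, float]
    group_n: dict[str, int]
    total_mae: float
    total_rmse: float
    error_rate_pct: float
    correlations: dict[str, float] = field(default_factory=dict)
    correlation_method: str = "pearson"

    def to_dict(self) -> dict:
        return {
            "groups": {
                g: {"mae": self.group_mae[g], "rmse": self.group_rmse[g], "n": self.group_n[g]}
                for g in self.group_mae
            },
            "total": {"mae": self.total_mae, "rmse": self.total_rmse,
                      "n": sum(self.group_n.values())},
            "error_rate_pct": self.error_rate_pct,
            "correlations": dict(self.correlations),
            "correlation_method": self.correlation_method,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def format_table(self) -> str:
        """Plain-text error table (rows: groups then total; columns: MAE, RMSE)."""
        lines = [f"{'':8s}{'MAE':>8s}{'RMSE':>8s}{'n':>5s}"]
        for g in sorted(self.group_mae):
            lines.append(
                f"Group {g:2s}{self.group_mae[g]:8.2f}{self.group_rmse[g]:8.2f}"
                f"{self.group_n[g]:5d}"
            )
        n = sum(self.group_n.values())
        lines.append(f"{'Total':8s}{self.total_mae:8.2f}{self.total_rmse:8.2f}{n:5d}")
        return "\n".join(lines)


def evaluate_mapping(
    features: Sequence[FatigueFeatures],
    bfi: Sequence[float],
    estimates: Sequence[MbfiEstimate],
    correlation_method: str = "pearson",
) -> EvaluationReport:
    """Per-group and total MAE/RMSE of the mapped BFI, plus correlations.

    Errors are computed on the clipped estimates (clipping is part of the
    mapping and matters for the no-fatigue group, whose compensated values
    can go negative).
    """
    if not len(features) == len(bfi) == len(estimates):
        raise ValueError("features, bfi and estimates must align")
    obs = np.asarray(bfi, dtype=float)
    pred = np.array([e.value for e in estimates])
    groups = np.array([assign_group(b).value for b in obs])

    g_mae, g_rmse, g_n = {}, {}, {}
    for g in sorted(set(groups)):
        sel = groups == g
        g_mae[g] = mae(pred[sel], obs[sel])
        g_rmse[g] = rmse(pred[sel], obs[sel])
        g_n[g] = int(sel.sum())
    total_mae = mae(pred, obs)

    mat = np.vstack([f.vector for f in features])
    correlations = {
        name: correlate(mat[:, i], obs, method=correlation_method)
        for i, name in enumerate(FEATURE_NAMES)
    }
    return EvaluationReport(
        group_mae=g_mae,
        group_rmse=g_rmse,
        group_n=g_n,
        total_mae=total_mae,
        total_rmse=rmse(pred, obs),
        error_rate_pct=error_rate(total_mae),
        correlations=correlations,
        correlation_method=correlation_method,
    )
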