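"""ROC/AUC, RMSE/MAE and leave-one-factor-out sensitivity (RD index).

The ROC sweeps every distinct predicted score as a threshold; a point is
predicted positive when its score >= threshold. X = 1 - TN/(TN+FP) (false
positive rate) and Y = TP/(TP+FN) (true positive rate); AUC is the
trapezoidal area under the (X, Y) polyline and equals the Mann-Whitney
rank statistic.

The RD index quantifies how much the training AUC drops when one factor is
left out of the model:

    RD = 100 * (AUC_all - AUC_i) / AUC_all
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedStatisticError

__all__ = [
    "ConfusionCounts",
    "PredictionPairs",
    "SensitivityReport",
    "roc_curve",
    "error_metrics",
    "confusion_at",
    "sensitivity_rd",
    "run_sensitivity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return 1.0 - self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class PredictionPairs:
    """Observed binary outcomes with predicted scores in [0, 1]."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.observed, dtype=int)
        s = np.asarray(self.predicted, dtype=float)
        if y.shape != s.shape or y.ndim != 1:
            raise ParameterError("observed and predicted must be equal-length 1-D")
        if y.size < 1:
            raise ParameterError("need at least one prediction pair")
        if y.size and not np.isin(y, (0, 1)).all():
            raise ParameterError("observed values must be 0/1")
        object.__setattr__(self, "observed", y)
        object.__setattr__(self, "predicted", s)

    def __len__(self) -> int:
        return self.observed.size


def confusion_at(pairs: PredictionPairs, threshold: float = 0.5) -> ConfusionCounts:
    pos = pairs.predicted >= threshold
    y = pairs.observed.astype(bool)
    return ConfusionCounts(tp=int((pos & y).sum()), tn=int((~pos & ~y).sum()),
                           fp=int((pos & ~y).sum()), fn=int((~pos & y).sum()))


def roc_curve(pairs: PredictionPairs) -> tuple[np.ndarray, np.ndarray, float]:
    """(X, Y, AUC): FPR/TPR per distinct threshold plus the end points."""
    y = pairs.observed
    s = pairs.predicted
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("ROC undefined: only one class present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [y.size - 1]])
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(1 - y_sorted)[cut]
    x = np.concatenate([[0.0], fp / n_neg])
    yy = np.concatenate([[0.0], tp / n_pos])
    auc = float(np.trapezoid(yy, x))
    return x, yy, auc


def error_metrics(pairs: PredictionPairs) -> tuple[float, float]:
    """(RMSE, MAE) between observed and predicted."""
    resid = pairs.observed - pairs.predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return rmse, mae


def sensitivity_rd(auc_all: float, auc_excluded: float) -> float:
    """Relative decrease of AUC (percent of AUC_all) when a factor is
    excluded; negative when exclusion helps."""
    if auc_all <= 0:
        raise ParameterError(f"AUC_all must be > 0, got {auc_all}")
    return 100.0 * (auc_all - auc_excluded) / auc_all


@dataclass(frozen=True)
class SensitivityReport:
    auc_all: float  # percent scale
    factors: list[str]
    auc_excluded: np.ndarray  # percent scale
    rd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "excluded_factor": self.factors,
            "AUC_i_pct": self.auc_excluded,
            "RD_pct": self.rd,
        })


def run_sensitivity(features, trainer, seed: int = 0,
                    score: str = "oob") -> SensitivityReport:
    """Leave-one-factor-out retraining on identical rows and seed.

    ``features`` is a :class:`georisk.susceptibility.FeatureMatrix`;
    ``trainer`` maps (FeatureMatrix, seed) -> fitted model. AUC is measured
    on the training rows; by default via the forest's out-of-bag
    probabilities (``score="oob"``), because the in-sample scores of a
    deep bagged ensemble saturate at AUC 1 and leave Eq-style RD values
    uninformative. ``score="insample"`` uses plain predictions.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise ParameterError("sensitivity analysis needs >= 2 criteria")
    if score not in ("oob", "insample"):
        raise ParameterError(f"unknown score mode {score!r}")

    def train_auc(fm) -> float:
        model = trainer(fm, seed)
        if score == "oob" and hasattr(model, "oob_decision_function_"):
            probs = model.oob_decision_function_[:, 1]
            probs = np.where(np.isfinite(probs), probs, 0.5)
        else:
            probs = model.predict_proba(fm.x)[:, 1]
        _, _, auc = roc_curve(PredictionPairs(fm.y, probs))
        return 100.0 * auc

    auc_all = train_auc(features)
    failures = []
    auc_i = np.empty(len(cols))
    for k, name in enumerate(cols):
        try:
            auc_i[k] = train_auc(features.drop_column(name))
        except Exception as exc:  # noqa: BLE001 - reported collectively
            failures.append((name, str(exc)))
            auc_i[k] = np.nan
    if failures:
        raise UndefinedStatisticError(
            f"sensitivity retraining failed for: {failures}")
    rd = np.array([sensitivity_rd(auc_all, a) for a in auc_i])
    return SensitivityReport(auc_all, cols, auc_i, rd)
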