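import numpy as np
import pytest

from georisk.autocorrelation import AggregationUnits
from georisk.grid import StudyArea


@pytest.fixture
def small_area() -> StudyArea:
    """40 x 30 cell fully-masked frame, 100 m cells."""
    return StudyArea.rectangle(4000.0, 3000.0, 100.0)


@pytest.fixture
def unit_square() -> StudyArea:
    """Unit square on a 20 x 20 grid for scale-free tests."""
    return StudyArea.rectangle(1.0, 1.0, 0.05)


def make_units(counts: np.ndarray, cell: float = 1.0) -> AggregationUnits:
    """AggregationUnits from a dense count grid (all cells in-area)."""
    counts = np.asarray(counts, dtype=int)
    area = StudyArea(0.0, counts.shape[0] * cell, cell,
                     np.ones(counts.shape, dtype=bool))
    rows, cols = np.nonzero(area.mask)
    return AggregationUnits(area, counts[rows, cols], rows, cols)


def brute_force_morans_i(counts: np.ndarray, w: np.ndarray) -> float:
    """Direct double-loop evaluation of the global Moran statistic."""
    x = np.asarray(counts, dtype=float).ravel()
    n = x.size
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    den = ((x - xbar) ** 2).sum()
    return (n / s0) * (num / den)


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)
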