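"""Criterion-raster classification and frequency-ratio (FR) class weights.

For each class i of a binned criterion the FR weight is

    FR = F_i / P_i

with F_i the percentage of training presence points in class i and P_i the
percentage of valid study-area pixels in class i. Classes over-represented
among presences have FR > 1. Reclassifying a raster by its FR table yields
the weight surface consumed by the susceptibility model.

Class edges follow the left-closed convention: a pixel exactly on an inner
edge belongs to the upper class. Natural-breaks edges are found by exact
dynamic programming (Fisher-Jenks), minimizing within-class variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError
from .grid import CasePoints, CriterionRaster

__all__ = [
    "ClassScheme",
    "FRTable",
    "jenks_breaks",
    "classify_raster",
    "compute_fr",
    "fr_reclassify",
]


def jenks_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Exact Fisher-Jenks natural breaks.

    Returns k+1 edges ``[min, b_1, ..., b_{k-1}, max]`` minimizing the total
    within-class sum of squared deviations over all partitions of the sorted
    values into k contiguous classes. Inner edges are placed at the lower
    bound of each upper class so that the left-closed assignment convention
    reproduces the optimal partition.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    v = v[np.isfinite(v)]
    n = v.size
    if k < 2:
        raise ParameterError(f"need k >= 2 classes, got {k}")
    if np.unique(v).size < k:
        raise EstimationError(
            f"cannot form {k} classes from {np.unique(v).size} distinct values")

    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(lo: np.ndarray, hi: int) -> np.ndarray:
        # within-class SSE of v[lo:hi] for an array of lower bounds lo
        cnt = hi - lo
        s = c1[hi] - c1[lo]
        return (c2[hi] - c2[lo]) - s * s / cnt

    # cost[j] = best SSE of v[:j] using the current number of classes
    cost = np.concatenate(
        [[0.0], [sse(np.array([0]), j)[0] for j in range(1, n + 1)]])
    split = np.zeros((k, n + 1), dtype=int)
    for cls in range(1, k):
        new_cost = np.full(n + 1, np.inf)
        for j in range(cls + 1, n + 1):
            lo = np.arange(cls, j)
            total = cost[lo] + sse(lo, j)
            m = int(np.argmin(total))
            new_cost[j] = total[m]
            split[cls, j] = lo[m]
        cost = new_cost

    # backtrack class boundaries (index of first element of each class)
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    for cls in range(k - 1, 0, -1):
        bounds[cls] = split[cls, bounds[cls + 1]]
    bounds[0] = 0
    edges = np.empty(k + 1)
    edges[0] = v[0]
    edges[k] = v[-1]
    edges[1:k] = v[bounds[1:k]]  # lower bound of each upper class
    return edges


@dataclass(frozen=True)
class ClassScheme:
    """Bin edges for one criterion; classes are ``[e_i, e_{i+1})`` except
    the last, which is closed above."""

    criterion: str
    edges: np.ndarray
    method: str = "manual"

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.size < 3:
            raise ParameterError("need >= 2 classes (>= 3 edges)")
        if (np.diff(edges) <= 0).any():
            raise ParameterError("class edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_classes(self) -> int:
        return self.edges.size - 1

    def labels(self) -> list[str]:
        e = self.edges
        return [f"[{e[i]:g}, {e[i+1]:g})" for i in range(self.n_classes - 1)] + \
               [f"[{e[-2]:g}, {e[-1]:g}]"]

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class id per value (-1 for NaN); exact inner-edge hits go to the
        upper class, values beyond the outer edges clip to the end classes."""
        v = np.asarray(values, dtype=float)
        ids = np.digitize(v, self.edges[1:-1], right=False)
        ids = np.where(np.isfinite(v), ids, -1)
        return ids


@dataclass(frozen=True)
class FRTable:
    """Per-class presence share F_i (%), area share P_i (%) and FR weight."""

    criterion: str
    class_ids: np.ndarray
    class_labels: list[str]
    f_pct: np.ndarray
    p_pct: np.ndarray
    fr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "criterion": self.criterion,
            "class_id": self.class_ids,
            "class": self.class_labels,
            "F_pct": self.f_pct,
            "P_pct": self.p_pct,
            "FR": self.fr,
        })

    def lookup(self) -> dict[int, float]:
        return dict(zip(self.class_ids.tolist(), self.fr.tolist()))


def classify_raster(raster: CriterionRaster, method: str = "natural-breaks",
                    k: int = 5, edges: np.ndarray | None = None,
                    max_sample: int = 1000, seed: int = 0) -> ClassScheme:
    """Build a class scheme for a criterion raster.

    natural-breaks: exact Fisher-Jenks on the valid pixels (subsampled
    deterministically above ``max_sample`` for tractability).
    quantile: equal-count edges. manual: caller-supplied ``edges``.
    """
    if method == "manual":
        if edges is None:
            raise ParameterError("manual classification requires edges")
        return ClassScheme(raster.name, np.asarray(edges, float), "manual")
    if k < 2:
        raise ParameterError(f"need k >= 2 classes, got {k}")
    vals = raster.values[raster.valid]
    if np.unique(vals).size < k:
        raise EstimationError(
            f"raster {raster.name!r} has fewer than {k} distinct values")
    if method == "natural-breaks":
        if vals.size > max_sample:
            rng = np.random.default_rng(seed)
            vals = rng.choice(vals, size=max_sample, replace=False)
        e = jenks_breaks(vals, k)
    elif method == "quantile":
        e = np.quantile(vals, np.linspace(0, 1, k + 1))
        if (np.diff(e) <= 0).any():
            raise EstimationError("degenerate quantile edges (ties)")
    else:
        raise ParameterError(f"unknown classification method {method!r}")
    return ClassScheme(raster.name, e, method)


def compute_fr(presences: CasePoints, raster: CriterionRaster,
               scheme: ClassScheme) -> FRTable:
    """FR table from presence points and the classed raster.

    Uses whatever points are passed in; callers wanting the train-only
    convention pass ``points.train`` explicitly. Classes with zero area are
    dropped with a warning.
    """
    vals = raster.values[raster.valid]
    if vals.size == 0:
        raise EstimationError("raster has no valid pixels")
    pix_ids = scheme.assign(vals)
    pt_vals = raster.sample(presences.x, presences.y)
    ok = np.isfinite(pt_vals)
    if not ok.any():
        raise EstimationError("no presence point falls on valid raster area")
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} presence point(s) on nodata dropped",
                      stacklevel=2)
    pt_ids = scheme.assign(pt_vals[ok])

    ids = np.arange(scheme.n_classes)
    area_counts = np.array([(pix_ids == i).sum() for i in ids], dtype=float)
    pt_counts = np.array([(pt_ids == i).sum() for i in ids], dtype=float)
    empty = area_counts == 0
    if empty.any():
        warnings.warn(
            f"classes with zero area excluded: {ids[empty].tolist()}",
            stacklevel=2)
    keep = ~empty
    f_pct = 100.0 * pt_counts[keep] / pt_counts[keep].sum()
    p_pct = 100.0 * area_counts[keep] / area_counts[keep].sum()
    fr = f_pct / p_pct
    labels = [scheme.labels()[i] for i in ids[keep]]
    return FRTable(scheme.criterion, ids[keep], labels, f_pct, p_pct, fr)


def fr_reclassify(raster: CriterionRaster, fr: FRTable,
                  scheme: ClassScheme) -> CriterionRaster:
    """Replace each valid pixel by the FR weight of its class."""
    if fr.criterion != scheme.criterion:
        raise ParameterError("FR table and class scheme refer to different criteria")
    ids = scheme.assign(raster.values)
    table = fr.lookup()
    out = np.full(raster.values.shape, np.nan)
    valid = raster.valid
    unknown = sorted(set(np.unique(ids[valid]).tolist()) - set(table) - {-1})
    if unknown:
        raise ParameterError(
            f"pixel class(es) {unknown} missing from the FR table "
            f"(zero-area classes?)")
    for cid, weight in table.items():
        out[valid & (ids == cid)] = weight
    return raster.with_values(out, name=f"{raster.name}_fr")
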