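"""Global/local Moran's I and Getis-Ord G / Gi* on gridded case counts.

Case points are aggregated onto square cells; cluster statistics operate on
the resulting count vector with a configurable spatial-weights matrix.

Conventions
-----------
* Global Moran's I uses randomization (analytic) or conditional permutation
  inference; expected value under the null is -1/(n-1).
* Local Moran quadrant labels (H-H, H-L, L-H, L-L) compare a unit's
  deviation from the global mean with the weighted average deviation of its
  neighbors; only units with permutation p < alpha are labeled.
* The global G excludes i == j in both sums; Gi* uses self-inclusive
  weights and returns per-unit z-scores directly (hot if z >= +threshold,
  cold if z <= -threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .errors import (EstimationError, ParameterError, SamplingError,
                     UndefinedStatisticError)
from .grid import CasePoints, StudyArea

__all__ = [
    "AggregationUnits",
    "SpatialWeights",
    "AutocorrResult",
    "aggregate_points",
    "build_weights",
    "global_morans_i",
    "local_morans_i",
    "getis_ord",
]

Z_THRESHOLD = 1.959963984540054  # two-sided 5%


@dataclass(frozen=True)
class AggregationUnits:
    """Grid cells with a case count per cell."""

    area: StudyArea
    counts: np.ndarray  # flat, one entry per masked cell (row-major order)
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ParameterError("counts must be non-negative integers")

    @property
    def n_units(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        cs = self.area.cell_size
        x = self.area.x_min + (self.cols + 0.5) * cs
        y = self.area.y_max - (self.rows + 0.5) * cs
        return np.column_stack([x, y])

    def to_grid(self, values: np.ndarray | None = None) -> np.ndarray:
        """Scatter per-unit values (defaults to counts) back onto the grid."""
        out = np.full(self.area.shape, np.nan)
        v = self.counts if values is None else values
        out[self.rows, self.cols] = v
        return out


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse weights matrix with scheme metadata; w_ii = 0 unless
    explicitly self-inclusive."""

    matrix: sparse.csr_matrix
    scheme: str
    row_standardized: bool
    self_inclusive: bool = False

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ParameterError("weights matrix must be square")
        if (m.data < 0).any():
            raise ParameterError("negative spatial weights are not allowed")
        if not self.self_inclusive and m.diagonal().any():
            raise ParameterError("diagonal weights must be zero (w_ii = 0)")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


@dataclass(frozen=True)
class AutocorrResult:
    statistic: str
    index_value: float
    z_score: float | None
    p_value: float | None
    pattern: str | None
    local_values: np.ndarray | None = None
    local_z: np.ndarray | None = None
    local_p: np.ndarray | None = None
    labels: np.ndarray | None = None  # per-unit strings

    def to_dict(self) -> dict:
        return {
            "index": self.statistic,
            "index_value": float(self.index_value),
            "z_score": None if self.z_score is None else float(self.z_score),
            "p_value": None if self.p_value is None else float(self.p_value),
            "distribution_type": self.pattern,
        }


def aggregate_points(points: CasePoints, area: StudyArea,
                     cell: float | None = None) -> AggregationUnits:
    """Count points per grid cell (masked cells only).

    ``cell`` must be an integer multiple of the area's cell size; counts are
    reported on the coarsened grid. Points outside the mask are ignored; if
    every point falls outside, aggregation fails.
    """
    if cell is None:
        cell = area.cell_size
    if cell <= 0:
        raise ParameterError("aggregation cell size must be > 0")
    factor = cell / area.cell_size
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ParameterError(
            f"aggregation cell ({cell}) must be an integer multiple of the "
            f"raster cell ({area.cell_size})")
    factor = int(round(factor))
    if factor > 1:
        nr = -(-area.nrows // factor)
        nc = -(-area.ncols // factor)
        pad = np.zeros((nr * factor, nc * factor), dtype=bool)
        pad[:area.nrows, :area.ncols] = area.mask
        coarse_mask = pad.reshape(nr, factor, nc, factor).any(axis=(1, 3))
        area = StudyArea(area.x_min, area.y_max, cell, coarse_mask)

    inside = area.contains(points.x, points.y)
    if len(points) and not inside.any():
        raise SamplingError("all points fall outside the study area")
    row, col = area.point_to_cell(points.x[inside], points.y[inside])
    counts = np.zeros(area.shape, dtype=int)
    np.add.at(counts, (row, col), 1)
    rows, cols = np.nonzero(area.mask)
    return AggregationUnits(area, counts[rows, cols], rows, cols)


def build_weights(units: AggregationUnits, scheme: str = "queen",
                  row_standardize: bool = True,
                  band: float | None = None,
                  self_inclusive: bool = False) -> SpatialWeights:
    """Spatial weights between aggregation units.

    scheme: ``queen`` / ``rook`` contiguity (binary), ``inverse-distance``
    (1/d between unit centers), or ``distance-band`` (binary within
    ``band``, default 1.5 cell diagonals). Isolated units get a zero row
    and a warning in the result.
    """
    n = units.n_units
    if n < 2:
        raise ParameterError("need >= 2 units to build weights")
    rows, cols = units.rows, units.cols
    cs = units.area.cell_size

    if scheme in ("queen", "rook"):
        index = -np.ones(units.area.shape, dtype=int)
        index[rows, cols] = np.arange(n)
        if scheme == "queen":
            offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                       (0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        ii, jj = [], []
        nr, nc = units.area.shape
        for dr, dc in offsets:
            r2 = rows + dr
            c2 = cols + dc
            ok = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc)
            src = np.arange(n)[ok]
            dst = index[r2[ok], c2[ok]]
            keep = dst >= 0
            ii.append(src[keep])
            jj.append(dst[keep])
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        w = sparse.csr_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    elif scheme == "inverse-distance":
        centers = units.centers
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        with np.errstate(divide="ignore"):
            wdense = 1.0 / d
        np.fill_diagonal(wdense, 0.0)
        w = sparse.csr_matrix(wdense)
    elif scheme == "distance-band":
        if band is None:
            band = 1.5 * np.sqrt(2.0) * cs
        centers = units.centers
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        wdense = (d <= band).astype(float)
        np.fill_diagonal(wdense, 0.0)
        w = sparse.csr_matrix(wdense)
    else:
        raise ParameterError(f"unknown weights scheme {scheme!r}")

    if self_inclusive:
        w = (w + sparse.eye(n, format="csr")).tocsr()

    row_sums = np.asarray(w.sum(axis=1)).ravel()
    if (row_sums == 0).any():
        warnings.warn(
            f"{int((row_sums == 0).sum())} isolated unit(s) with no neighbors",
            stacklevel=2)
    if row_standardize:
        inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums),
                        where=row_sums > 0)
        w = sparse.diags(inv) @ w
    return SpatialWeights(w.tocsr(), scheme, row_standardize, self_inclusive)


def _check_counts(x: np.ndarray) -> None:
    if np.ptp(x) == 0:
        raise UndefinedStatisticError(
            "statistic undefined: counts are constant (zero variance)")


def _pattern(z: float, threshold: float = Z_THRESHOLD) -> str:
    if z > threshold:
        return "clustered"
    if z < -threshold:
        return "dispersed"
    return "random"


def _moran_stat(x: np.ndarray, w: sparse.csr_matrix) -> float:
    xd = x - x.mean()
    num = float(xd @ (w @ xd))
    den = float(xd @ xd)
    s0 = w.sum()
    return (len(x) / s0) * (num / den)


def global_morans_i(units: AggregationUnits, weights: SpatialWeights,
                    inference: str = "analytic", n_perm: int = 999,
                    seed: int = 0) -> AutocorrResult:
    """Global Moran's I with randomization or permutation inference."""
    x = units.counts.astype(float)
    _check_counts(x)
    w = weights.matrix
    if weights.self_inclusive:
        raise ParameterError("Moran's I requires w_ii = 0 weights")
    s0 = weights.s0
    if s0 <= 0:
        raise ParameterError("total weight must be > 0")
    n = units.n_units
    observed = _moran_stat(x, w)

    if inference == "analytic":
        # randomization-assumption moments (Cliff & Ord)
        wt = w.T.tocsr()
        s1 = 0.5 * float(((w + wt).power(2)).sum())
        ri = np.asarray(w.sum(axis=1)).ravel()
        ci = np.asarray(w.sum(axis=0)).ravel()
        s2 = float(((ri + ci) ** 2).sum())
        xd = x - x.mean()
        m2 = (xd**2).sum() / n
        b2 = ((xd**4).sum() / n) / m2**2
        e_i = -1.0 / (n - 1)
        a = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        b = b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        var = (a - b) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        if var <= 0:
            raise EstimationError("non-positive Moran variance; grid too small")
        z = (observed - e_i) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    elif inference == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for k in range(n_perm):
            sims[k] = _moran_stat(rng.permutation(x), w)
        sd = sims.std(ddof=1)
        z = (observed - sims.mean()) / sd if sd > 0 else np.inf
        n_extreme = int((sims >= observed).sum())
        p_one = (n_extreme + 1) / (n_perm + 1)
        p = 2.0 * min(p_one, 1.0 - p_one + 1.0 / (n_perm + 1))
        p = min(p, 1.0)
    else:
        raise ParameterError(f"unknown inference mode {inference!r}")
    return AutocorrResult("morans_i", observed, float(z), float(p), _pattern(z))


def local_morans_i(units: AggregationUnits, weights: SpatialWeights,
                   n_perm: int = 999, seed: int = 0,
                   alpha: float = 0.05) -> AutocorrResult:
    """Local Moran's I with conditional-permutation p-values and
    H-H / H-L / L-H / L-L labels for significant units."""
    x = units.counts.astype(float)
    _check_counts(x)
    if weights.self_inclusive:
        raise ParameterError("local Moran requires w_ii = 0 weights")
    n = units.n_units
    w = weights.matrix
    xd = x - x.mean()
    m2 = float(xd @ xd) / n
    lag = w @ xd
    local = xd * lag / m2

    # conditional permutation: hold x_i fixed, permute the remaining values
    # among the neighbors; one bank of shuffles shared across units
    rng = np.random.default_rng(seed)
    wl = w.tolil()
    degrees = np.array([len(r) for r in wl.rows])
    max_k = int(degrees.max()) if n else 0
    perm_bank = np.empty((n_perm, max_k), dtype=int)
    for r in range(n_perm):
        perm_bank[r] = rng.permutation(n - 1)[:max_k]
    p_local = np.empty(n)
    for i in range(n):
        idx = np.asarray(wl.rows[i], dtype=int)
        wv = np.asarray(wl.data[i], dtype=float)
        if idx.size == 0:
            p_local[i] = 1.0
            continue
        others = np.delete(xd, i)
        sims = (others[perm_bank[:, :idx.size]] * wv).sum(axis=1) * xd[i] / m2
        n_ge = int((sims >= local[i]).sum())
        p_one = (n_ge + 1) / (n_perm + 1)
        p_local[i] = min(2.0 * min(p_one, 1.0 - p_one + 1.0 / (n_perm + 1)), 1.0)

    labels = np.full(n, "not-significant", dtype=object)
    sig = p_local < alpha
    hi = xd > 0
    lag_hi = lag > 0
    labels[sig & hi & lag_hi] = "H-H"
    labels[sig & hi & ~lag_hi] = "H-L"
    labels[sig & ~hi & lag_hi] = "L-H"
    labels[sig & ~hi & ~lag_hi] = "L-L"
    labels[xd == 0] = "not-significant"

    global_i = _moran_stat(x, w)
    return AutocorrResult("local_morans_i", global_i, None, None, None,
                          local_values=local, local_p=p_local, labels=labels)


def _global_g_stat(x: np.ndarray, w: sparse.csr_matrix) -> float:
    num = float(x @ (w @ x)) - float((w.diagonal() * x * x).sum())
    tot = float(x.sum()) ** 2 - float((x * x).sum())
    return num / tot


def getis_ord(units: AggregationUnits, weights: SpatialWeights,
              mode: str = "local_Gi_star", n_perm: int = 999,
              seed: int = 0) -> AutocorrResult:
    """Getis-Ord statistics on the aggregated counts.

    ``global_G``: high/low-value concentration index over i != j pairs with
    permutation z/p. ``local_Gi_star``: per-unit z-scores with
    self-inclusive weights and hot/cold/not-significant labels.
    """
    x = units.counts.astype(float)
    if not x.any():
        raise UndefinedStatisticError("Getis-Ord undefined on all-zero counts")
    n = units.n_units
    w = weights.matrix

    if mode == "global_G":
        _check_counts(x)
        observed = _global_g_stat(x, w)
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for k in range(n_perm):
            sims[k] = _global_g_stat(rng.permutation(x), w)
        sd = sims.std(ddof=1)
        z = (observed - sims.mean()) / sd if sd > 0 else np.inf
        n_ge = int((sims >= observed).sum())
        p_one = (n_ge + 1) / (n_perm + 1)
        p = min(2.0 * min(p_one, 1.0 - p_one + 1.0 / (n_perm + 1)), 1.0)
        # high z: high values cluster together
        return AutocorrResult("getis_ord_G", observed, float(z), float(p),
                              _pattern(z))

    if mode != "local_Gi_star":
        raise ParameterError(f"unknown Getis-Ord mode {mode!r}")
    if not weights.self_inclusive:
        w = (w + sparse.eye(n, format="csr")).tocsr()
    xbar = x.mean()
    s = np.sqrt((x**2).sum() / n - xbar**2)
    wi = np.asarray(w.sum(axis=1)).ravel()
    s1i = np.asarray(w.power(2).sum(axis=1)).ravel()
    num = np.asarray(w @ x).ravel() - xbar * wi
    den = s * np.sqrt(np.maximum((n * s1i - wi**2) / (n - 1), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / den, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    labels = np.full(n, "not-significant", dtype=object)
    labels[z >= Z_THRESHOLD] = "hot"
    labels[z <= -Z_THRESHOLD] = "cold"
    gi = float(np.nan)
    return AutocorrResult("getis_ord_gi_star", gi, None, None, None,
                          local_z=z, local_p=p, labels=labels)
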