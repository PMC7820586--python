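"""Semivariogram estimation, variogram-model fitting, the spatial-dependence
index and ordinary kriging.

The empirical semivariogram is the classic Matheron estimator

    gamma(h) = 1 / (2 N(h)) * sum [Z(x_i) - Z(x_i + h)]^2

computed over omnidirectional lag bins, each pair counted once. Fitted
models use the practical-range convention (exponential and gaussian curves
reach 95% of their sill at ``range_``). The spatial-dependence (SD) index is
the nugget as a percentage of the total sill:

    SD = 100 * nugget / (nugget + partial_sill)

classified strong (< 25), moderate (25-75) or weak (> 75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

from .errors import EstimationError, FittingError, ParameterError
from .grid import CriterionRaster, StudyArea

__all__ = [
    "StationSamples",
    "EmpiricalVariogram",
    "VariogramModel",
    "empirical_semivariogram",
    "fit_variogram_model",
    "spatial_dependence_index",
    "ordinary_kriging",
    "SD_STRONG_MAX",
    "SD_WEAK_MIN",
]

SD_STRONG_MAX = 25.0
SD_WEAK_MIN = 75.0

_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class StationSamples:
    """Sparse monitoring-station measurements of one variable."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    variable_name: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if not (x.shape == y.shape == v.shape) or x.ndim != 1:
            raise ParameterError("x, y, values must be 1-D arrays of equal length")
        if x.size < 3:
            raise ParameterError(f"need >= 3 stations, got {x.size}")
        if not np.isfinite(v).all():
            raise ParameterError("station values contain missing/non-finite entries")
        coords = np.column_stack([x, y])
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ParameterError("station locations must be distinct")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def standardized(self) -> "StationSamples":
        """Zero-mean, unit-variance copy (population sd)."""
        v = self.values
        sd = v.std()
        if sd == 0:
            return StationSamples(self.x, self.y, v - v.mean(), self.variable_name)
        return StationSamples(self.x, self.y, (v - v.mean()) / sd, self.variable_name)


@dataclass(frozen=True)
class EmpiricalVariogram:
    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.lag_centers, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        n = np.asarray(self.pair_counts, dtype=int)
        if not (h.shape == g.shape == n.shape):
            raise ParameterError("lag_centers, gamma and pair_counts must align")
        if (np.diff(h) <= 0).any():
            raise ParameterError("lag_centers must be strictly increasing")
        if (g < 0).any() or (n < 0).any():
            raise ParameterError("gamma and pair_counts must be non-negative")
        object.__setattr__(self, "lag_centers", h)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "pair_counts", n)


@dataclass(frozen=True)
class VariogramModel:
    """Fitted nugget / partial-sill / range triple with its SD index."""

    family: str
    nugget: float
    partial_sill: float
    range_: float
    sd_index: float = field(init=False)
    sd_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ParameterError(
                "need nugget >= 0, partial_sill >= 0, range > 0; got "
                f"({self.nugget}, {self.partial_sill}, {self.range_})")
        sd, cls = spatial_dependence_index(self.nugget, self.partial_sill)
        object.__setattr__(self, "sd_index", sd)
        object.__setattr__(self, "sd_class", cls)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        """Model semivariance gamma(h); exactly 0 at h == 0."""
        h = np.asarray(h, dtype=float)
        r, c0, c1 = self.range_, self.nugget, self.partial_sill
        if self.family == "spherical":
            u = np.minimum(h / r, 1.0)
            structure = 1.5 * u - 0.5 * u**3
        elif self.family == "exponential":
            structure = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            structure = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        gamma = c0 + c1 * structure
        return np.where(h > 0, gamma, 0.0)

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill - gamma(h) for h > 0; sill at h = 0."""
        h = np.asarray(h, dtype=float)
        return np.where(h > 0, self.sill - self(h), self.sill)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": float(self.nugget),
            "partial_sill": float(self.partial_sill),
            "range": float(self.range_),
            "sd_index": float(self.sd_index),
            "sd_class": self.sd_class,
        }


def spatial_dependence_index(nugget: float, partial_sill: float) -> tuple[float, str]:
    """SD = 100 * nugget / (nugget + partial_sill), with its class label."""
    if nugget < 0 or partial_sill < 0:
        raise ParameterError("nugget and partial_sill must be non-negative")
    total = nugget + partial_sill
    if total == 0:
        raise EstimationError("SD index undefined: nugget + partial_sill == 0")
    sd = 100.0 * nugget / total
    if sd < SD_STRONG_MAX:
        cls = "strong"
    elif sd <= SD_WEAK_MIN:
        cls = "moderate"
    else:
        cls = "weak"
    return sd, cls


def empirical_semivariogram(samples: StationSamples, n_lags: int = 12,
                            max_lag: float | None = None) -> EmpiricalVariogram:
    """Omnidirectional Matheron estimator on equal-width lag bins.

    ``max_lag`` defaults to half the maximum inter-station distance. Bins
    with no pairs are dropped; if every bin is empty an
    :class:`EstimationError` is raised.
    """
    if n_lags < 1:
        raise ParameterError(f"n_lags must be >= 1, got {n_lags}")
    d = pdist(samples.coords)
    if max_lag is None:
        max_lag = 0.5 * d.max()
    if max_lag <= 0:
        raise ParameterError("max_lag must be > 0")
    sq_diff = pdist(samples.values[:, None], metric="sqeuclidean")

    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.digitize(d, edges[1:-1])  # bin 0..n_lags-1 for d <= max_lag
    inside = d <= max_lag
    gamma = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for b in range(n_lags):
        sel = inside & (idx == b)
        counts[b] = sel.sum()
        if counts[b]:
            gamma[b] = sq_diff[sel].sum() / (2.0 * counts[b])
    nonempty = counts > 0
    if not nonempty.any():
        raise EstimationError(
            f"no station pairs within max_lag={max_lag}; all {n_lags} bins empty")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers[nonempty], gamma[nonempty], counts[nonempty])


def _model_curve(family: str, h: np.ndarray, nugget: float, psill: float,
                 rng: float) -> np.ndarray:
    return VariogramModel(family, max(nugget, 0.0), max(psill, 0.0), max(rng, 1e-12))(h)


def fit_variogram_model(emp: EmpiricalVariogram, family: str = "spherical",
                        weighting: str = "cressie") -> VariogramModel:
    """Weighted least squares fit of (nugget, partial sill, range).

    ``weighting="cressie"`` (default) minimizes
    sum N(h) * (model - gamma)^2 / model^2, Cressie's weights, which keep
    pair counts but damp the poorly-determined long lags;
    ``weighting="pair_count"`` uses plain N(h) weights. The nugget is
    clamped at zero.
    """
    if family not in _FAMILIES:
        raise ParameterError(f"unknown variogram family {family!r}")
    if weighting not in ("cressie", "pair_count"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    h = emp.lag_centers
    g = emp.gamma
    if h.size < 3:
        raise EstimationError(f"need >= 3 non-empty lag bins, got {h.size}")
    w = np.sqrt(emp.pair_counts.astype(float))

    sill0 = max(g.max(), 1e-12)
    range0 = max(h[np.argmax(g >= 0.95 * sill0)], h[0])
    starts = [
        (0.0, sill0, range0),
        (0.5 * g[0], sill0, 0.5 * h.max()),
        (0.0, sill0, h.max()),
    ]

    def residuals(p):
        curve = _model_curve(family, h, *p)
        r = w * (curve - g)
        if weighting == "cressie":
            r = r / np.maximum(curve, 1e-9)
        return r

    best = None
    hmax = h.max()
    for p0 in starts:
        try:
            res = least_squares(
                residuals, p0,
                bounds=([0.0, 0.0, h[0] * 1e-3], [np.inf, np.inf, 10.0 * hmax]))
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FittingError(
            f"variogram fit did not converge (family={family}, "
            f"lags={h.tolist()}, gamma={g.tolist()})")
    nugget, psill, range_ = best.x
    nugget = max(float(nugget), 0.0)
    psill = max(float(psill), 0.0)
    if range_ <= 1.05 * h[0]:
        # structure below the first lag is indistinguishable from nugget
        nugget += psill
        psill = 0.0
        range_ = h[0]
    if nugget + psill == 0:
        # flat-zero empirical variogram: keep a token sill so SD is defined
        raise FittingError("degenerate fit: total sill is zero")
    return VariogramModel(family, nugget, psill, float(range_))


def ordinary_kriging(samples: StationSamples, model: VariogramModel,
                     area: StudyArea) -> CriterionRaster:
    """Ordinary-kriging prediction of the sampled variable on ``area``.

    Weights solve the standard (n+1)-system with a Lagrange multiplier, so
    they sum to one at every cell; predictions honor the data exactly at
    station cells. Masked cells become nodata.
    """
    n = len(samples)
    coords = samples.coords
    dmat = squareform(pdist(coords))
    if (dmat[~np.eye(n, dtype=bool)] == 0).any():
        dup = np.argwhere((dmat == 0) & ~np.eye(n, dtype=bool))
        pairs = sorted({tuple(sorted(p)) for p in dup.tolist()})
        raise ParameterError(f"duplicate station locations at index pairs {pairs}")

    a_mat = np.empty((n + 1, n + 1))
    a_mat[:n, :n] = model(dmat)
    np.fill_diagonal(a_mat[:n, :n], 0.0)
    a_mat[n, :n] = 1.0
    a_mat[:n, n] = 1.0
    a_mat[n, n] = 0.0

    gx, gy = area.cell_centers()
    tx = gx[area.mask]
    ty = gy[area.mask]
    d_to_stations = np.hypot(tx[None, :] - samples.x[:, None],
                             ty[None, :] - samples.y[:, None])
    b = np.empty((n + 1, tx.size))
    b[:n] = model(d_to_stations)
    b[n] = 1.0
    try:
        weights = np.linalg.solve(a_mat, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ParameterError(f"singular kriging system: {exc}") from exc

    pred = np.full(area.shape, np.nan)
    pred[area.mask] = samples.values @ weights[:n]
    return CriterionRaster(area, pred, samples.variable_name)
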