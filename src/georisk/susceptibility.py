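"""Presence/pseudo-absence assembly, random-forest training and the
5-class susceptibility map.

The classifier consumes FR-weight surfaces (one feature per criterion, the
FR value of the pixel's class at each point); probability is the fraction
of trees voting presence. The continuous probability raster is cut into
five ordinal classes (very-low ... very-high) with natural breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier

from .errors import AlignmentError, ParameterError, SamplingError
from .frequency_ratio import ClassScheme, jenks_breaks
from .grid import CasePoints, CriterionRaster, StudyArea

__all__ = [
    "FeatureMatrix",
    "SusceptibilityMap",
    "split_points",
    "sample_pseudo_absence",
    "extract_features",
    "train_random_forest",
    "predict_susceptibility",
    "classify_map",
    "CLASS_NAMES",
]

CLASS_NAMES = ("very-low", "low", "moderate", "high", "very-high")


@dataclass(frozen=True)
class FeatureMatrix:
    """Design matrix: one row per point, one FR-weight column per
    criterion, binary target."""

    x: np.ndarray
    y: np.ndarray  # labels
    columns: tuple[str, ...]
    partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if x.ndim != 2 or x.shape[0] != y.size:
            raise ParameterError("x must be 2-D with one row per label")
        if x.shape[1] != len(self.columns):
            raise ParameterError("column names must match feature count")
        if not np.isfinite(x).all():
            raise ParameterError("feature matrix contains missing values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.y.size

    def drop_column(self, name: str) -> "FeatureMatrix":
        if name not in self.columns:
            raise ParameterError(f"unknown feature column {name!r}")
        keep = [i for i, c in enumerate(self.columns) if c != name]
        return FeatureMatrix(self.x[:, keep], self.y,
                             tuple(self.columns[i] for i in keep),
                             self.partition)

    def in_partition(self, which: str) -> "FeatureMatrix":
        if self.partition is None:
            raise ParameterError("feature matrix carries no partition")
        sel = self.partition == which
        return FeatureMatrix(self.x[sel], self.y[sel], self.columns,
                             self.partition[sel])


@dataclass(frozen=True)
class SusceptibilityMap:
    probability: CriterionRaster
    classes: CriterionRaster | None = None
    breaks: np.ndarray | None = None
    class_names: tuple[str, ...] = CLASS_NAMES


def split_points(points: CasePoints, train_fraction: float = 0.7,
                 seed: int = 0, rounding: str = "round") -> CasePoints:
    """Seeded random train/test partition of a point set.

    ``rounding`` fixes the train count: ``round`` (default, banker-free
    half-up), ``floor`` or ``ceil`` of n * train_fraction.
    """
    if not 0 < train_fraction < 1:
        raise ParameterError(f"train_fraction must be in (0,1), got {train_fraction}")
    n = len(points)
    if n < 2:
        raise ParameterError("need >= 2 points to split")
    raw = n * train_fraction
    if rounding == "round":
        n_train = int(np.floor(raw + 0.5))
    elif rounding == "floor":
        n_train = int(np.floor(raw))
    elif rounding == "ceil":
        n_train = int(np.ceil(raw))
    else:
        raise ParameterError(f"unknown rounding rule {rounding!r}")
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    part = np.array(["test"] * n, dtype=object)
    part[rng.choice(n, size=n_train, replace=False)] = "train"
    return CasePoints(points.x, points.y, points.label, part)


def sample_pseudo_absence(presences: CasePoints, area: StudyArea, n: int,
                          min_distance: float = 0.0,
                          seed: int = 0) -> CasePoints:
    """n uniform label-0 points over the masked area, each at least
    ``min_distance`` from every presence point (exact point distances)."""
    if n < 1:
        raise ParameterError("need n >= 1 pseudo-absences")
    rows, cols = np.nonzero(area.mask)
    if rows.size == 0:
        raise SamplingError("empty study-area mask")
    tree = cKDTree(np.column_stack([presences.x, presences.y])) \
        if len(presences) and min_distance > 0 else None
    rng = np.random.default_rng(seed)
    cs = area.cell_size
    xs, ys = [], []
    remaining = n
    tries = 0
    while remaining > 0:
        batch = max(4 * remaining, 512)
        pick = rng.integers(0, rows.size, size=batch)
        x = area.x_min + (cols[pick] + rng.random(batch)) * cs
        y = area.y_max - (rows[pick] + rng.random(batch)) * cs
        if tree is not None:
            d, _ = tree.query(np.column_stack([x, y]), k=1)
            keep = d >= min_distance
            x, y = x[keep], y[keep]
        take = min(remaining, x.size)
        xs.append(x[:take])
        ys.append(y[:take])
        remaining -= take
        tries += 1
        if tries > 200 and remaining > 0:
            raise SamplingError(
                f"eligible area too small: {n - remaining}/{n} pseudo-absences "
                f"found at min_distance={min_distance}")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return CasePoints(x, y, np.zeros(n, dtype=int))


def extract_features(points: CasePoints,
                     fr_surfaces: list[CriterionRaster]) -> FeatureMatrix:
    """Sample every FR surface at the containing cell of each point.

    Points falling on nodata in any surface are dropped with a warning, so
    kept rows + dropped count equals the input point count.
    """
    if not fr_surfaces:
        raise ParameterError("need at least one FR surface")
    base = fr_surfaces[0].area
    for r in fr_surfaces[1:]:
        if not r.area.same_grid(base):
            raise AlignmentError(
                f"surface {r.name!r} is not aligned with {fr_surfaces[0].name!r}")
    cols = np.column_stack([r.sample(points.x, points.y) for r in fr_surfaces])
    ok = np.isfinite(cols).all(axis=1)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} point(s) on nodata dropped",
                      stacklevel=2)
    part = None if points.partition is None else points.partition[ok]
    return FeatureMatrix(cols[ok], points.label[ok],
                         tuple(r.name for r in fr_surfaces), part)


def train_random_forest(features: FeatureMatrix, n_trees: int = 100,
                        seed: int = 0,
                        oob_score: bool = True) -> tuple[RandomForestClassifier, dict[str, float]]:
    """Bagged decision-tree ensemble with sqrt-p feature subsampling.

    Returns the fitted model and per-criterion importances normalized to
    sum to one. With ``oob_score`` the model also carries out-of-bag class
    probabilities (used by the sensitivity analysis, where in-sample scores
    of an interpolating forest would be uninformative).
    """
    if len(features) < 10:
        raise ParameterError("need >= 10 training rows")
    if np.unique(features.y).size < 2:
        raise ParameterError("training labels must contain both classes")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed,
        oob_score=oob_score, n_jobs=1)
    model.fit(features.x, features.y)
    imp = model.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    importances = dict(zip(features.columns, imp.tolist()))
    return model, importances


def predict_susceptibility(model: RandomForestClassifier,
                           fr_surfaces: list[CriterionRaster]) -> SusceptibilityMap:
    """Per-pixel presence probability over the shared grid; nodata
    propagates wherever any surface is invalid."""
    if model.n_features_in_ != len(fr_surfaces):
        raise ParameterError(
            f"model expects {model.n_features_in_} features, got "
            f"{len(fr_surfaces)} surfaces")
    base = fr_surfaces[0].area
    for r in fr_surfaces[1:]:
        if not r.area.same_grid(base):
            raise AlignmentError(f"surface {r.name!r} grid mismatch")
    stack = np.stack([r.values for r in fr_surfaces], axis=-1)
    valid = np.isfinite(stack).all(axis=-1) & base.mask
    prob = np.full(base.shape, np.nan)
    if valid.any():
        prob[valid] = model.predict_proba(stack[valid])[:, 1]
    raster = CriterionRaster(base, prob, "susceptibility")
    return SusceptibilityMap(raster)


def classify_map(prob: CriterionRaster, k: int = 5,
                 max_sample: int = 2000, seed: int = 0) -> SusceptibilityMap:
    """Cut the probability raster into k ordinal classes by natural breaks.

    Class ids are 1..k (monotone in probability); nodata stays NaN.
    """
    vals = prob.values[prob.valid]
    if np.unique(vals).size < k:
        raise ParameterError(
            f"near-constant raster: fewer than {k} distinct probabilities")
    sample = vals
    if sample.size > max_sample:
        sample = np.random.default_rng(seed).choice(vals, max_sample,
                                                    replace=False)
    breaks = jenks_breaks(sample, k)
    breaks[0] = min(breaks[0], vals.min())
    breaks[-1] = max(breaks[-1], vals.max())
    scheme = ClassScheme("susceptibility", breaks, "natural-breaks")
    ids = scheme.assign(prob.values).astype(float) + 1.0
    ids[~prob.valid] = np.nan
    names = CLASS_NAMES if k == 5 else tuple(f"class-{i+1}" for i in range(k))
    classes = prob.with_values(ids, "susceptibility_class")
    return SusceptibilityMap(prob, classes, breaks, names)
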