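"""Study-area grids, rasters and labeled point sets.

All coordinates live in one abstract projected CRS (map units ~ meters).
Rasters are north-up, row-major, origin at the upper-left corner. A point
falls in cell (row, col) by the half-open convention
``[x0, x0 + w) x (y0 - h, y0]`` so boundary points are never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ParameterError

__all__ = ["StudyArea", "CriterionRaster", "CasePoints"]


@dataclass(frozen=True)
class StudyArea:
    """Rectangular grid frame with an in-area boolean mask.

    Parameters
    ----------
    x_min, y_max : float
        Upper-left corner of the grid in map units.
    cell_size : float
        Side of the square cells, map units per pixel.
    mask : ndarray of bool, shape (nrows, ncols)
        True for cells inside the study area.
    """

    x_min: float
    y_max: float
    cell_size: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ParameterError(f"cell_size must be > 0, got {self.cell_size}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ParameterError("mask must be a non-empty 2-D boolean array")
        if mask.size < 2:
            raise ParameterError("degenerate 1-cell grid")
        if not mask.any():
            raise ParameterError("mask must contain at least one in-area cell")
        object.__setattr__(self, "mask", mask)

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.mask.shape[0]

    @property
    def ncols(self) -> int:
        return self.mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def x_max(self) -> float:
        return self.x_min + self.ncols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max)."""
        return (self.x_min, self.x_max, self.y_min, self.y_max)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def rectangle(cls, width: float, height: float, cell_size: float,
                  x_min: float = 0.0, y_max: float | None = None) -> "StudyArea":
        """Fully-masked rectangular area of the given size."""
        ncols = int(round(width / cell_size))
        nrows = int(round(height / cell_size))
        if ncols < 1 or nrows < 1:
            raise ParameterError("extent must be strictly positive in both axes")
        if y_max is None:
            y_max = nrows * cell_size
        return cls(x_min, y_max, cell_size, np.ones((nrows, ncols), dtype=bool))

    # -- coordinate transforms -------------------------------------------
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinates, each of shape (nrows, ncols)."""
        cs = self.cell_size
        x = self.x_min + (np.arange(self.ncols) + 0.5) * cs
        y = self.y_max - (np.arange(self.nrows) + 0.5) * cs
        return np.meshgrid(x, y)

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices for points; may fall outside [0, n)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        # y on the bottom edge of a cell belongs to the cell below: (y0-h, y0]
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        """True for points inside the masked area."""
        row, col = self.point_to_cell(x, y)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.zeros_like(ok)
        out[ok] = self.mask[row[ok], col[ok]]
        return out

    def same_grid(self, other: "StudyArea") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.x_min, other.x_min)
                and np.isclose(self.y_max, other.y_max)
                and np.isclose(self.cell_size, other.cell_size))


@dataclass(frozen=True)
class CriterionRaster:
    """One gridded environmental variable; NaN marks nodata cells."""

    area: StudyArea
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.area.shape:
            raise AlignmentError(
                f"raster {self.name!r}: values shape {values.shape} does not "
                f"match area grid {self.area.shape}")
        values = values.copy()
        values[~self.area.mask] = np.nan
        object.__setattr__(self, "values", values)

    @property
    def valid(self) -> np.ndarray:
        return self.area.mask & np.isfinite(self.values)

    def sample(self, x, y) -> np.ndarray:
        """Value of the containing cell per point; NaN outside the grid."""
        row, col = self.area.point_to_cell(x, y)
        ok = ((row >= 0) & (row < self.area.nrows)
              & (col >= 0) & (col < self.area.ncols))
        out = np.full(row.shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def with_values(self, values: np.ndarray, name: str | None = None) -> "CriterionRaster":
        return CriterionRaster(self.area, values, self.name if name is None else name)


@dataclass(frozen=True)
class CasePoints:
    """Point set with presence (1) / pseudo-absence (0) labels and an
    optional train/test partition."""

    x: np.ndarray
    y: np.ndarray
    label: np.ndarray
    partition: np.ndarray | None = None  # elements in {"train", "test"} or None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        label = np.asarray(self.label, dtype=int)
        if not (x.shape == y.shape == label.shape):
            raise ParameterError("x, y and label must have identical length")
        if label.size and not np.isin(label, (0, 1)).all():
            raise ParameterError("labels must be 0 or 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "label", label)
        if self.partition is not None:
            part = np.asarray(self.partition, dtype=object)
            if part.shape != x.shape:
                raise ParameterError("partition must match point count")
            bad = set(np.unique(part)) - {"train", "test"}
            if bad:
                raise ParameterError(f"unknown partition labels: {sorted(bad)}")
            object.__setattr__(self, "partition", part)

    def __len__(self) -> int:
        return self.x.size

    def subset(self, idx) -> "CasePoints":
        part = None if self.partition is None else self.partition[idx]
        return CasePoints(self.x[idx], self.y[idx], self.label[idx], part)

    @property
    def presences(self) -> "CasePoints":
        return self.subset(self.label == 1)

    @property
    def absences(self) -> "CasePoints":
        return self.subset(self.label == 0)

    def in_partition(self, which: str) -> "CasePoints":
        if self.partition is None:
            raise ParameterError("points carry no train/test partition")
        return self.subset(self.partition == which)

    @property
    def train(self) -> "CasePoints":
        return self.in_partition("train")

    @property
    def test(self) -> "CasePoints":
        return self.in_partition("test")

    @staticmethod
    def concatenate(parts: list["CasePoints"]) -> "CasePoints":
        has_part = all(p.partition is not None for p in parts)
        return CasePoints(
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.label for p in parts]),
            np.concatenate([p.partition for p in parts]) if has_part else None,
        )
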