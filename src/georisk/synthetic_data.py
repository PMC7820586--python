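"""Synthetic study areas, criterion surfaces, station samples and case
points with known statistical structure.

Criterion surfaces are stationary Gaussian random fields with a spherical
covariance (unit total variance split between a nugget fraction and a
spatially structured component), generated by circulant embedding / FFT so
the realized variogram matches the requested nugget fraction and range.

Case points come from an inhomogeneous Poisson-type process: the
log-intensity is a linear combination of the driver criteria and points are
drawn by thinning (accept/reject against the normalized intensity), which
is exact for any bounded intensity. With all driver coefficients zero the
pattern reduces to complete spatial randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SamplingError
from .geostatistics import StationSamples
from .grid import CasePoints, CriterionRaster, StudyArea

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "generate_criterion_field",
    "sample_stations",
    "generate_cases",
    "generate_criteria",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of one synthetic study."""

    seed: int = 0
    n_criteria: int = 13
    n_cases: int = 872
    driver_indices: tuple[int, ...] = (0, 1, 2)
    driver_coefficients: tuple[float, ...] = (1.5, 1.2, 1.0)
    spatial_range: tuple[float, ...] | float = 4000.0
    nugget_fraction: tuple[float, ...] | float = 0.1
    station_count: int = 20
    station_noise_sd: float = 0.05
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_cases < 10:
            raise ParameterError("n_cases must be >= 10")
        if self.n_criteria < 1:
            raise ParameterError("n_criteria must be >= 1")
        if len(self.driver_indices) != len(self.driver_coefficients):
            raise ParameterError("one coefficient per driver index required")
        if any(i < 0 or i >= self.n_criteria for i in self.driver_indices):
            raise ParameterError("driver_indices must lie in [0, n_criteria)")
        if not all(np.isfinite(self.driver_coefficients)):
            raise ParameterError("driver coefficients must be finite")
        for r in np.atleast_1d(self.spatial_range):
            if r <= 0:
                raise ParameterError("spatial ranges must be > 0")
        for f in np.atleast_1d(self.nugget_fraction):
            if not 0 <= f <= 1:
                raise ParameterError("nugget fractions must be in [0, 1]")

    def range_for(self, k: int) -> float:
        r = np.atleast_1d(self.spatial_range)
        return float(r[k % r.size])

    def nugget_for(self, k: int) -> float:
        f = np.atleast_1d(self.nugget_fraction)
        return float(f[k % f.size])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_criteria": self.n_criteria,
            "n_cases": self.n_cases,
            "driver_indices": list(self.driver_indices),
            "driver_coefficients": list(self.driver_coefficients),
            "spatial_range": np.atleast_1d(self.spatial_range).tolist(),
            "nugget_fraction": np.atleast_1d(self.nugget_fraction).tolist(),
            "station_count": self.station_count,
            "station_noise_sd": self.station_noise_sd,
            "train_fraction": self.train_fraction,
        }


def default_scenario(seed: int = 0) -> tuple[StudyArea, SyntheticScenario]:
    """Paper-scale default: ~10 km x 7.3 km frame on 100 m cells,
    13 criteria of which 3 drive the case intensity, 872 cases, 70/30."""
    area = StudyArea.rectangle(10_000.0, 7_300.0, 100.0)
    return area, SyntheticScenario(seed=seed)


def _spherical_corr(h: np.ndarray, range_: float) -> np.ndarray:
    u = np.minimum(h / range_, 1.0)
    return 1.0 - 1.5 * u + 0.5 * u**3


def generate_criterion_field(area: StudyArea, range_: float,
                             nugget_fraction: float, seed: int,
                             name: str = "") -> CriterionRaster:
    """Zero-mean, unit-variance Gaussian random field on the area grid.

    Theoretical variogram: gamma(h) = f + (1 - f) * sph(h; range_) for
    h > 0, where f is the nugget fraction. Deterministic per seed.
    """
    if range_ <= 0:
        raise ParameterError(f"range must be > 0, got {range_}")
    if not 0 <= nugget_fraction <= 1:
        raise ParameterError(f"nugget_fraction must be in [0, 1], got {nugget_fraction}")
    nr, nc = area.shape
    if nr * nc < 2:
        raise ParameterError("degenerate 1-cell grid")
    cs = area.cell_size
    rng = np.random.default_rng(seed)

    structured = 1.0 - nugget_fraction
    if structured > 0:
        # circulant embedding: pad so the torus wrap never reaches the range
        pad = int(np.ceil(range_ / cs)) + 1
        pr = int(2 ** np.ceil(np.log2(nr + pad)))
        pc = int(2 ** np.ceil(np.log2(nc + pad)))
        fr = np.minimum(np.arange(pr), pr - np.arange(pr)) * cs
        fc = np.minimum(np.arange(pc), pc - np.arange(pc)) * cs
        h = np.hypot(fr[:, None], fc[None, :])
        cov = _spherical_corr(h, range_)
        lam = np.fft.fft2(cov).real
        lam = np.maximum(lam, 0.0)  # clamp tiny negative eigenvalues
        noise = rng.standard_normal((pr, pc)) + 1j * rng.standard_normal((pr, pc))
        spec = np.sqrt(lam / (pr * pc)) * noise
        smooth = np.fft.fft2(spec).real[:nr, :nc]
        values = np.sqrt(structured) * smooth
    else:
        values = np.zeros((nr, nc))
    if nugget_fraction > 0:
        values = values + np.sqrt(nugget_fraction) * rng.standard_normal((nr, nc))
    return CriterionRaster(area, values, name)


def generate_criteria(area: StudyArea, scenario: SyntheticScenario,
                      prefix: str = "criterion") -> list[CriterionRaster]:
    """One field per criterion, each with its own derived seed."""
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.n_criteria)
    out = []
    for k, ss in enumerate(seeds):
        sub_seed = int(ss.generate_state(1)[0])
        out.append(generate_criterion_field(
            area, scenario.range_for(k), scenario.nugget_for(k),
            sub_seed, name=f"{prefix}_{k:02d}"))
    return out


def sample_stations(raster: CriterionRaster, n: int, noise_sd: float,
                    seed: int) -> StationSamples:
    """n distinct in-mask cell-center samples of the raster, with optional
    additive Gaussian measurement noise."""
    if n < 3:
        raise ParameterError(f"need n >= 3 stations, got {n}")
    valid = raster.valid
    rows, cols = np.nonzero(valid)
    if n > rows.size:
        raise SamplingError(
            f"requested {n} stations but only {rows.size} valid cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False)
    r, c = rows[pick], cols[pick]
    cs = raster.area.cell_size
    x = raster.area.x_min + (c + 0.5) * cs
    y = raster.area.y_max - (r + 0.5) * cs
    values = raster.values[r, c]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return StationSamples(x, y, values, raster.name)


def generate_cases(area: StudyArea, criteria: list[CriterionRaster],
                   scenario: SyntheticScenario) -> CasePoints:
    """Presence points by thinning an inhomogeneous point process.

    log-intensity(s) = sum_k coefficient_k * driver_k(s); candidate points
    are uniform over the masked area (cell + in-cell jitter) and accepted
    with probability intensity / max(intensity). Exactly ``n_cases`` points
    are returned; all carry label 1 and no partition.
    """
    if not area.mask.any():
        raise SamplingError("empty study-area mask")
    for r in criteria:
        if not r.area.same_grid(area):
            raise ParameterError(f"criterion {r.name!r} is not on the area grid")
    log_int = np.zeros(area.shape)
    for idx, coef in zip(scenario.driver_indices, scenario.driver_coefficients):
        if idx >= len(criteria):
            raise ParameterError(f"driver index {idx} out of range")
        log_int += coef * np.nan_to_num(criteria[idx].values)
    log_int -= log_int[area.mask].max()
    accept_p = np.exp(log_int)  # in (0, 1], max 1 on the mask

    rows, cols = np.nonzero(area.mask)
    rng = np.random.default_rng(scenario.seed)
    cs = area.cell_size
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    remaining = scenario.n_cases
    guard = 0
    while remaining > 0:
        batch = max(4 * remaining, 1024)
        pick = rng.integers(0, rows.size, size=batch)
        u = rng.random(batch)
        keep = u < accept_p[rows[pick], cols[pick]]
        jx = rng.random(batch)
        jy = rng.random(batch)
        r, c = rows[pick[keep]], cols[pick[keep]]
        x = area.x_min + (c + jx[keep]) * cs
        y = area.y_max - (r + jy[keep]) * cs
        take = min(remaining, x.size)
        xs.append(x[:take])
        ys.append(y[:take])
        remaining -= take
        guard += 1
        if guard > 10_000:
            raise SamplingError("thinning failed to accept enough points "
                                "(intensity nearly zero everywhere)")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return CasePoints(x, y, np.ones(x.size, dtype=int))
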