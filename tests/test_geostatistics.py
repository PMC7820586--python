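import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from georisk.errors import EstimationError, ParameterError
from georisk.geostatistics import (EmpiricalVariogram, StationSamples,
                                   VariogramModel, empirical_semivariogram,
                                   fit_variogram_model, ordinary_kriging,
                                   spatial_dependence_index)
from georisk.grid import StudyArea
from georisk.synthetic_data import generate_criterion_field, sample_stations

# printed (criterion, nugget, partial sill, SD%) reference rows
SD_REFERENCE = [
    ("distance_to_street", 0.0, 0.90347, 0.0),
    ("pressure", 0.020703, 1.14351, 1.77),
    ("wind_speed", 0.0723, 0.746103, 8.83),
    ("humidity", 0.04172, 0.968473, 4.12),
    ("temperature", 0.04508, 0.85825, 4.99),
    ("distance_to_park", 0.0, 1.041133, 0.0),
    ("pm25", 0.0, 0.73868, 0.0),
    ("pm10", 0.0, 0.824453, 0.0),
    ("so2", 0.193513, 1.36949, 12.38),
    ("no2", 0.028775, 1.107712, 2.53),
    ("co", 0.11694, 0.877, 11.76),
    ("o3", 0.079762, 1.17747, 6.34),
    ("rainfall", 0.0, 0.080033, 0.0),
]


class TestStationSamples:
    def test_requires_three_points(self):
        with pytest.raises(ParameterError):
            StationSamples([0, 1], [0, 1], [1.0, 2.0])

    def test_rejects_duplicates(self):
        with pytest.raises(ParameterError):
            StationSamples([0, 0, 1], [0, 0, 1], [1.0, 2.0, 3.0])

    def test_rejects_missing_values(self):
        with pytest.raises(ParameterError):
            StationSamples([0, 1, 2], [0, 1, 2], [1.0, np.nan, 3.0])

    def test_standardized(self):
        s = StationSamples([0, 1, 2, 3], [0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0])
        z = s.standardized()
        assert z.values.mean() == pytest.approx(0.0)
        assert z.values.std() == pytest.approx(1.0)


class TestEmpiricalSemivariogram:
    def test_single_pair(self):
        # two points with value difference d in one bin: gamma = d^2 / 2
        s = StationSamples([0.0, 1.0, 10.0], [0.0, 0.0, 10.0], [1.0, 4.0, 1.0])
        emp = empirical_semivariogram(s, n_lags=1, max_lag=2.0)
        assert emp.pair_counts.tolist() == [1]
        assert emp.gamma[0] == pytest.approx(9.0 / 2.0)

    def test_constant_values(self):
        s = StationSamples([0, 1, 2, 3], [0, 0, 0, 0], [5.0] * 4)
        emp = empirical_semivariogram(s, n_lags=3, max_lag=3.0)
        assert np.all(emp.gamma == 0.0)

    def test_collinear_brute_force(self):
        # exhaustive C(5,2) oracle with independent binning arithmetic
        xs = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        vals = np.array([2.0, 3.5, -1.0, 0.5, 4.0])
        n_lags, max_lag = 4, 6.0
        width = max_lag / n_lags
        gamma_oracle = np.zeros(n_lags)
        counts_oracle = np.zeros(n_lags)
        for i in range(5):
            for j in range(i + 1, 5):
                d = abs(xs[i] - xs[j])
                if d > max_lag:
                    continue
                b = min(int(d // width), n_lags - 1)
                counts_oracle[b] += 1
                gamma_oracle[b] += (vals[i] - vals[j]) ** 2
        keep = counts_oracle > 0
        gamma_oracle[keep] /= 2.0 * counts_oracle[keep]

        s = StationSamples(xs, np.zeros(5), vals)
        emp = empirical_semivariogram(s, n_lags=n_lags, max_lag=max_lag)
        assert emp.pair_counts.tolist() == counts_oracle[keep].tolist()
        np.testing.assert_allclose(emp.gamma, gamma_oracle[keep], atol=1e-12)

    def test_empty_bins_error(self):
        s = StationSamples([0, 100, 200], [0, 0, 0], [1.0, 2.0, 3.0])
        with pytest.raises(EstimationError):
            empirical_semivariogram(s, n_lags=2, max_lag=1.0)

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(7)
        s = StationSamples(rng.random(30), rng.random(30), rng.random(30))
        emp = empirical_semivariogram(s, n_lags=5)
        shifted = StationSamples(s.x, s.y, s.values + 17.3)
        scaled = StationSamples(s.x, s.y, s.values * 3.0)
        np.testing.assert_allclose(
            empirical_semivariogram(shifted, n_lags=5).gamma, emp.gamma)
        np.testing.assert_allclose(
            empirical_semivariogram(scaled, n_lags=5).gamma, 9.0 * emp.gamma)


class TestFitVariogram:
    def test_noiseless_spherical_recovery(self):
        true = VariogramModel("spherical", 0.1, 0.9, 0.3)
        h = np.linspace(0.02, 0.6, 15)
        emp = EmpiricalVariogram(h, true(h), np.full(15, 40))
        m = fit_variogram_model(emp, "spherical")
        assert m.nugget == pytest.approx(0.1, rel=0.01)
        assert m.partial_sill == pytest.approx(0.9, rel=0.01)
        assert m.range_ == pytest.approx(0.3, rel=0.01)

    def test_flat_variogram_classified_weak(self):
        h = np.linspace(0.02, 0.6, 12)
        emp = EmpiricalVariogram(h, np.full(12, 1.0), np.full(12, 40))
        m = fit_variogram_model(emp)
        assert m.nugget == pytest.approx(1.0, abs=1e-6)
        assert m.partial_sill == pytest.approx(0.0, abs=1e-6)
        assert m.sd_index > 75
        assert m.sd_class == "weak"

    def test_needs_three_bins(self):
        emp = EmpiricalVariogram([1.0, 2.0], [0.5, 0.6], [3, 3])
        with pytest.raises(EstimationError):
            fit_variogram_model(emp)

    @pytest.mark.parametrize("family", ["exponential", "gaussian"])
    def test_other_families_noiseless(self, family):
        true = VariogramModel(family, 0.05, 0.95, 0.4)
        h = np.linspace(0.02, 1.0, 20)
        emp = EmpiricalVariogram(h, true(h), np.full(20, 40))
        m = fit_variogram_model(emp, family)
        assert m.range_ == pytest.approx(0.4, rel=0.05)

    def test_simulated_range_recovery(self):
        # one-realization recovery study; statistics frozen by seed
        area = StudyArea.rectangle(10_000.0, 7_300.0, 100.0)
        ok = 0
        n_rep = 20
        for seed in range(n_rep):
            f = generate_criterion_field(area, 3000.0, 0.0, seed=seed)
            s = sample_stations(f, 200, 0.0, seed=1000 + seed)
            emp = empirical_semivariogram(s, n_lags=15, max_lag=6000.0)
            m = fit_variogram_model(emp, "spherical")
            ok += abs(m.range_ - 3000.0) / 3000.0 <= 0.25
        assert ok >= 0.8 * n_rep


class TestSpatialDependenceIndex:
    @pytest.mark.parametrize("name,nugget,psill,sd_printed", SD_REFERENCE)
    def test_printed_reference_rows(self, name, nugget, psill, sd_printed):
        sd, _ = spatial_dependence_index(nugget, psill)
        assert sd == pytest.approx(sd_printed, abs=0.01)

    def test_classes(self):
        assert spatial_dependence_index(0.193513, 1.36949) == (
            pytest.approx(12.380846, abs=1e-5), "strong")
        assert spatial_dependence_index(0.0, 0.90347)[1] == "strong"
        assert spatial_dependence_index(1.0, 0.0) == (100.0, "weak")
        assert spatial_dependence_index(0.11694, 0.8771)[0] == pytest.approx(
            11.76, abs=0.01)
        assert spatial_dependence_index(1.0, 1.0)[1] == "moderate"

    def test_undefined_when_both_zero(self):
        with pytest.raises(EstimationError):
            spatial_dependence_index(0.0, 0.0)

    @given(nugget=st.floats(0.0, 1e3), psill=st.floats(0.0, 1e3),
           k=st.floats(1e-3, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, nugget, psill, k):
        if nugget + psill < 1e-9:  # undefined / underflow region
            return
        sd, cls = spatial_dependence_index(nugget, psill)
        sd_k, cls_k = spatial_dependence_index(k * nugget, k * psill)
        assert sd_k == pytest.approx(sd, abs=1e-9)
        assert cls_k == cls


class TestOrdinaryKriging:
    @pytest.fixture
    def model(self):
        return VariogramModel("spherical", 0.05, 0.95, 2.0)

    def test_exact_at_station_cells(self, model):
        area = StudyArea.rectangle(5.0, 5.0, 1.0)
        s = StationSamples([0.5, 2.5, 4.5], [0.5, 2.5, 4.5], [1.0, -2.0, 3.0])
        kr = ordinary_kriging(s, model, area)
        np.testing.assert_allclose(kr.sample(s.x, s.y), s.values, atol=1e-10)

    def test_constant_field(self, model):
        area = StudyArea.rectangle(5.0, 5.0, 1.0)
        s = StationSamples([0.5, 2.5, 4.5], [0.5, 1.5, 4.5], [7.0, 7.0, 7.0])
        kr = ordinary_kriging(s, model, area)
        np.testing.assert_allclose(kr.values[kr.valid], 7.0, atol=1e-9)

    def test_equidistant_symmetry(self, model):
        area = StudyArea.rectangle(3.0, 3.0, 1.0)
        # stations mirror-symmetric about the center column; third far away
        s = StationSamples([0.5, 2.5, 1.5], [1.5, 1.5, 2.5], [2.0, 6.0, 4.0])
        kr = ordinary_kriging(s, model, area)
        center = kr.sample([1.5], [1.5])[0]
        assert center == pytest.approx((2.0 + 6.0) / 2.0, abs=1e-9)

    def test_weights_sum_to_one(self, model):
        # adding a constant to the data shifts every prediction by it
        area = StudyArea.rectangle(6.0, 4.0, 1.0)
        rng = np.random.default_rng(3)
        s = StationSamples(rng.uniform(0, 6, 8), rng.uniform(0, 4, 8),
                           rng.random(8))
        shifted = StationSamples(s.x, s.y, s.values + 100.0)
        a = ordinary_kriging(s, model, area).values
        b = ordinary_kriging(shifted, model, area).values
        np.testing.assert_allclose(b - a, 100.0, atol=1e-8)

    def test_masked_cells_are_nodata(self, model):
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        area = StudyArea(0, 4, 1.0, mask)
        s = StationSamples([0.5, 2.5, 3.5], [0.5, 2.5, 1.5], [1.0, 2.0, 3.0])
        kr = ordinary_kriging(s, model, area)
        assert np.isnan(kr.values[0, 0])
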