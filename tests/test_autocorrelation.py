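import numpy as np
import pytest

from conftest import brute_force_morans_i, make_units

from georisk.autocorrelation import (AggregationUnits, SpatialWeights,
                                     aggregate_points, build_weights,
                                     getis_ord, global_morans_i,
                                     local_morans_i)
from georisk.errors import (ParameterError, SamplingError,
                            UndefinedStatisticError)
from georisk.grid import CasePoints, StudyArea
from scipy import sparse


class TestAggregatePoints:
    def test_single_point(self, small_area):
        pts = CasePoints([150.0], [250.0], [1])
        units = aggregate_points(pts, small_area)
        assert units.total == 1
        assert (units.counts > 0).sum() == 1

    def test_total_preserved_872(self, small_area):
        rng = np.random.default_rng(0)
        pts = CasePoints(rng.uniform(0, 4000, 872), rng.uniform(0, 3000, 872),
                         np.ones(872, int))
        units = aggregate_points(pts, small_area, cell=500.0)
        assert units.total == 872

    def test_boundary_convention_counts_once(self):
        area = StudyArea.rectangle(2.0, 2.0, 1.0)
        # point exactly on the interior cross: x=1 goes right, y=1 goes down
        pts = CasePoints([1.0], [1.0], [1])
        units = aggregate_points(pts, area)
        grid = units.to_grid()
        assert np.nansum(grid) == 1
        assert grid[1, 1] == 1

    def test_all_points_outside(self, small_area):
        pts = CasePoints([-10.0, -20.0], [-10.0, -20.0], [1, 1])
        with pytest.raises(SamplingError):
            aggregate_points(pts, small_area)

    def test_non_multiple_cell_rejected(self, small_area):
        pts = CasePoints([10.0], [10.0], [1])
        with pytest.raises(ParameterError):
            aggregate_points(pts, small_area, cell=250.0)


class TestBuildWeights:
    def test_queen_center_has_8(self):
        units = make_units(np.zeros((3, 3), int))
        w = build_weights(units, "queen", row_standardize=False)
        # center unit index 4 in row-major order
        assert w.matrix[4].getnnz() == 8

    def test_rook_center_has_4(self):
        units = make_units(np.zeros((3, 3), int))
        w = build_weights(units, "rook", row_standardize=False)
        assert w.matrix[4].getnnz() == 4

    def test_inverse_distance_symmetric(self):
        units = make_units(np.arange(9).reshape(3, 3))
        w = build_weights(units, "inverse-distance", row_standardize=False)
        dense = w.matrix.toarray()
        np.testing.assert_allclose(dense, dense.T)
        assert np.all(np.diag(dense) == 0)

    def test_row_standardization(self):
        units = make_units(np.zeros((3, 3), int))
        w = build_weights(units, "queen", row_standardize=True)
        np.testing.assert_allclose(
            np.asarray(w.matrix.sum(axis=1)).ravel(), 1.0)

    def test_negative_weights_rejected(self):
        m = sparse.csr_matrix(np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(ParameterError):
            SpatialWeights(m, "manual", False)


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        counts = np.indices((4, 4)).sum(axis=0) % 2
        units = make_units(counts)
        w = build_weights(units, "rook", row_standardize=False)
        res = global_morans_i(units, w)
        assert res.index_value == pytest.approx(-1.0, abs=1e-12)
        assert res.pattern == "dispersed"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(4.0, size=(5, 5))
        if np.ptp(counts) == 0:  # pragma: no cover
            counts[0, 0] += 1
        units = make_units(counts)
        w = build_weights(units, "queen", row_standardize=True)
        res = global_morans_i(units, w)
        oracle = brute_force_morans_i(counts, w.matrix.toarray())
        assert res.index_value == pytest.approx(oracle, abs=1e-12)

    def test_halfplane_clustered(self):
        counts = np.zeros((4, 4), int)
        counts[:2] = 8
        units = make_units(counts)
        res = global_morans_i(units, build_weights(units, "queen"))
        oracle = brute_force_morans_i(
            counts, build_weights(units, "queen").matrix.toarray())
        assert res.index_value == pytest.approx(oracle, abs=1e-12)
        assert res.index_value > 0
        assert res.pattern == "clustered"

    def test_permutation_agrees_with_analytic(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(5.0, size=(6, 6))
        units = make_units(counts)
        w = build_weights(units, "queen")
        analytic = global_morans_i(units, w, inference="analytic")
        perm = global_morans_i(units, w, inference="permutation",
                               n_perm=999, seed=11)
        assert perm.index_value == pytest.approx(analytic.index_value)
        assert abs(perm.p_value - analytic.p_value) < 0.1

    def test_permutation_reproducible(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(5, 5))
        units = make_units(counts)
        w = build_weights(units, "queen")
        a = global_morans_i(units, w, inference="permutation", seed=5)
        b = global_morans_i(units, w, inference="permutation", seed=5)
        assert a.p_value == b.p_value
        assert a.z_score == b.z_score

    def test_constant_counts_error(self):
        units = make_units(np.full((3, 3), 4))
        w = build_weights(units, "queen")
        with pytest.raises(UndefinedStatisticError):
            global_morans_i(units, w)

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (3.0, 10.0), (0.5, -1.0)])
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(9)
        counts = rng.poisson(6.0, size=(5, 5))
        units = make_units(counts)
        w = build_weights(units, "queen")
        base = global_morans_i(units, w).index_value
        x = units.counts.astype(float)
        xt = a * x + b
        # evaluate the statistic directly on transformed values
        xd = xt - xt.mean()
        s0 = w.s0
        transformed = (units.n_units / s0) * float(
            xd @ (w.matrix @ xd)) / float(xd @ xd)
        assert transformed == pytest.approx(base, rel=1e-12)


class TestLocalMoran:
    def test_quadrant_labels(self):
        counts = np.zeros((5, 5), int)
        counts[:, :2] = 9          # high half
        counts[2, 4] = 9           # lone high cell among lows
        units = make_units(counts)
        w = build_weights(units, "queen")
        res = local_morans_i(units, w, n_perm=499, seed=0)
        grid_labels = np.array(res.labels).reshape(5, 5)
        assert grid_labels[2, 0] == "H-H"          # high among highs
        assert grid_labels[2, 4] == "H-L"          # high among lows

    def test_sum_identity(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5.0, size=(5, 5))
        units = make_units(counts)
        w = build_weights(units, "queen")
        res = local_morans_i(units, w, n_perm=99, seed=0)
        glob = global_morans_i(units, w)
        assert res.local_values.sum() == pytest.approx(
            glob.index_value * w.s0, rel=1e-10)


class TestGetisOrd:
    def test_uniform_counts_no_spots(self):
        units = make_units(np.full((4, 4), 3))
        w = build_weights(units, "distance-band", row_standardize=False,
                         self_inclusive=True)
        res = getis_ord(units, w, mode="local_Gi_star")
        np.testing.assert_allclose(res.local_z, 0.0, atol=1e-12)
        assert all(l == "not-significant" for l in res.labels)

    def test_planted_block_hot(self):
        counts = np.zeros((5, 5), int)
        counts[:2, :2] = 20
        units = make_units(counts)
        w = build_weights(units, "distance-band", row_standardize=False,
                         self_inclusive=True)
        res = getis_ord(units, w, mode="local_Gi_star")
        grid_z = np.array(res.local_z).reshape(5, 5)
        labels = np.array(res.labels).reshape(5, 5)
        assert labels[0, 0] == "hot"
        assert labels[1, 1] == "hot"
        assert labels[4, 4] != "hot"
        # brute-force z at the block corner
        x = units.counts.astype(float)
        n = x.size
        wdense = w.matrix.toarray()
        xbar = x.mean()
        s = np.sqrt((x**2).sum() / n - xbar**2)
        i = 0
        wi = wdense[i].sum()
        s1 = (wdense[i] ** 2).sum()
        z_oracle = (wdense[i] @ x - xbar * wi) / (
            s * np.sqrt((n * s1 - wi**2) / (n - 1)))
        assert grid_z[0, 0] == pytest.approx(z_oracle, abs=1e-12)

    def test_global_g_three_unit_hand_oracle(self):
        # x = (1, 2, 3); w pairs only between units 0 and 1 ->
        # num = w01*x0*x1 + w10*x1*x0 = 4; den = 2*(2 + 3 + 6) = 22
        counts = np.array([[1, 2, 3]])
        area = StudyArea(0, 1, 1.0, np.ones((1, 3), bool))
        rows, cols = np.nonzero(area.mask)
        units = AggregationUnits(area, counts[rows, cols], rows, cols)
        w = SpatialWeights(sparse.csr_matrix(np.array(
            [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])),
            "manual", False)
        res = getis_ord(units, w, mode="global_G", seed=0)
        assert res.index_value == pytest.approx(4.0 / 22.0, abs=1e-12)

    def test_all_zero_counts_error(self):
        units = make_units(np.zeros((3, 3), int))
        w = build_weights(units, "queen")
        with pytest.raises(UndefinedStatisticError):
            getis_ord(units, w, mode="local_Gi_star")
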