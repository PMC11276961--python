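import numpy as np
import pytest
from scipy import stats

from rangeshift.grid import cell_area_grid
from rangeshift.maps import RangeMap, SuitabilityMap
from rangeshift.metrics import tss_at_threshold
from rangeshift.ranges import (binarize, centroid_shift, compute_rer,
                               compute_rsi, expanding_range, mss_threshold,
                               paired_t_test, range_area, range_dynamics)

from conftest import make_grid


def suit_map(values, **kw):
    return SuitabilityMap(make_grid(values, **kw), "sp", "current")


def range_from_cells(cells, shape=(1, 8), scenario="current", **kw):
    vals = np.zeros(shape)
    for c in cells:
        vals[(0, c) if np.isscalar(c) else c] = 1.0
    return RangeMap(make_grid(vals, **kw), "sp", scenario, 0.5)


class TestBinarize:
    def test_extremes_and_monotonicity(self):
        rng = np.random.default_rng(0)
        s = suit_map(rng.random((4, 5)))
        assert binarize(s, 0.0).grid.values.sum() == 20
        hi = np.nextafter(s.grid.values.max(), 1.0)
        assert binarize(s, hi).grid.values.sum() == 0
        low = binarize(s, 0.3).grid.values
        high = binarize(s, 0.6).grid.values
        assert np.all(high <= low)

    def test_mss_binarization_reproduces_selection_confusion(self):
        rng = np.random.default_rng(5)
        sp = np.clip(rng.normal(0.7, 0.2, 50), 0, 1)
        sa = np.clip(rng.normal(0.3, 0.2, 60), 0, 1)
        t = mss_threshold(sp, sa)
        m = tss_at_threshold(sp, sa, t)
        # binarizing the same scores at t yields exactly those rates
        assert np.mean(sp >= t) == pytest.approx(m.sensitivity)
        assert np.mean(sa < t) == pytest.approx(m.specificity)

    def test_nodata_propagates(self):
        mask = np.array([[True, False], [True, True]])
        s = SuitabilityMap(make_grid([[0.9, 0.1], [0.2, 0.8]], mask=mask),
                           "sp", "current")
        r = binarize(s, 0.5)
        assert not r.grid.mask[0, 1]


class TestAreas:
    def test_empty_full_additive(self):
        areas = cell_area_grid(make_grid(np.zeros((1, 8))))
        empty = range_from_cells([])
        full = range_from_cells(range(8))
        left = range_from_cells([0, 1, 2])
        right = range_from_cells([5, 6])
        assert range_area(empty, areas) == 0.0
        assert range_area(full, areas) == pytest.approx(areas.values.sum())
        both = range_from_cells([0, 1, 2, 5, 6])
        assert range_area(both, areas) == pytest.approx(
            range_area(left, areas) + range_area(right, areas))

    def test_misaligned_rejected(self):
        areas = cell_area_grid(make_grid(np.zeros((2, 2))))
        r = range_from_cells([0], shape=(1, 8))
        with pytest.raises(ValueError):
            range_area(r, areas)


class TestIndices:
    def test_rer_arithmetic_and_error(self):
        assert compute_rer(1.0, 1.0) == 1.0
        assert compute_rer(1.0, 2.36) == pytest.approx(2.36)
        assert compute_rer(2.0, 5.0) > 1
        with pytest.raises(ValueError, match="RER"):
            compute_rer(0.0, 1.0)

    def test_rsi_identical_disjoint_fractional(self):
        areas = cell_area_grid(make_grid(np.zeros((1, 8))))
        cur = range_from_cells([0, 1])
        fut_same = range_from_cells([0, 1], scenario="F")
        assert compute_rsi(cur, fut_same, areas) == pytest.approx(1.0)
        fut_disjoint = range_from_cells([4, 5], scenario="F")
        assert compute_rsi(cur, fut_disjoint, areas) == 0.0
        # one row at fixed latitude → equal cell areas → count arithmetic:
        # RC=2, RF=4, RS=1 → RSI = 2·1/(2+4) = 1/3
        fut = range_from_cells([1, 4, 5, 6], scenario="F")
        assert compute_rsi(cur, fut, areas) == pytest.approx(1 / 3)

    def test_expanding_range_set_identities(self):
        cur = range_from_cells([0, 1, 2])
        fut = range_from_cells([2, 3, 4], scenario="F")
        exp = expanding_range(cur, fut)
        assert np.array_equal(np.flatnonzero(exp.grid.values[0]), [3, 4])
        same = expanding_range(cur, range_from_cells([0, 1, 2], scenario="F"))
        assert same.grid.values.sum() == 0
        empty_cur = range_from_cells([], scenario="current")
        assert np.array_equal(expanding_range(empty_cur, fut).grid.values,
                              fut.grid.values)
        # expanding ∪ (current ∩ future) = future, disjointly
        inter = cur.grid.values * fut.grid.values
        assert np.array_equal(exp.grid.values + inter, fut.grid.values)

    def test_range_accounting_identity(self):
        rng = np.random.default_rng(9)
        shape = (6, 9)
        cur = RangeMap(make_grid((rng.random(shape) > 0.5).astype(float)),
                       "sp", "current", 0.5)
        fut = RangeMap(make_grid((rng.random(shape) > 0.4).astype(float)),
                       "sp", "F", 0.5)
        areas = cell_area_grid(cur.grid)
        dyn = range_dynamics(cur, fut, areas)
        assert dyn.rf_area_km2 == pytest.approx(
            dyn.rs_area_km2 + dyn.expanding_area_km2, rel=1e-12)
        assert dyn.rs_area_km2 <= min(dyn.rc_area_km2, dyn.rf_area_km2)
        assert 0 <= dyn.rsi <= 1


class TestCentroid:
    def test_identical_ranges_zero_shift(self):
        cur = range_from_cells([2, 3], shape=(3, 6))
        fut = range_from_cells([2, 3], shape=(3, 6), scenario="F")
        areas = cell_area_grid(cur.grid)
        d, _ = centroid_shift(cur, fut, areas)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_shift_on_equator(self):
        # single-cell ranges with centres 1° apart straddling the equator
        g = make_grid(np.zeros((1, 3)), west=0.0, north=0.5, cellsize=1.0)
        cur = RangeMap(g.copy_with(np.array([[1.0, 0, 0]])), "sp", "c", 0.5)
        fut = RangeMap(g.copy_with(np.array([[0, 1.0, 0]])), "sp", "F", 0.5)
        areas = cell_area_grid(g)
        d, bearing = centroid_shift(cur, fut, areas)
        assert d == pytest.approx(6371 * np.pi / 180, rel=1e-6)
        assert bearing == pytest.approx(90.0, abs=1e-6)

    def test_distance_symmetric_empty_rejected(self):
        cur = range_from_cells([0], shape=(2, 4))
        fut = range_from_cells([(1, 3)], shape=(2, 4), scenario="F")
        areas = cell_area_grid(cur.grid)
        d1, _ = centroid_shift(cur, fut, areas)
        d2, _ = centroid_shift(fut, cur, areas)
        assert d1 == pytest.approx(d2)
        with pytest.raises(ValueError, match="empty"):
            centroid_shift(range_from_cells([], shape=(2, 4)), fut, areas)


class TestPairedT:
    def test_textbook_example_matches_distribution_oracle(self):
        cur = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        fut = np.array([12.0, 15.0, 9.5, 17.0, 12.0])
        t, p = paired_t_test(cur, fut)
        d = cur - fut
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(d) - 1)
        assert t == pytest.approx(t_hand, rel=1e-10)
        assert p == pytest.approx(p_hand, rel=1e-10)

    def test_antisymmetry_and_degenerate(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(8), rng.random(8)
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        with pytest.raises(ValueError, match="variance"):
            paired_t_test(x, x + 3.0)
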