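import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cloq
from cloq.geometry import (
    EARTH_RADIUS_KM,
    KM_PER_MILE,
    arc_distance,
    build_neighbors,
    neighbor_count_within,
    radius_coverage,
)
from oracles import brute_neighbors, brute_radius_coverage

coord = st.tuples(
    st.floats(-180, 180, allow_nan=False), st.floats(-89.9, 89.9, allow_nan=False)
)


class TestArcDistance:
    def test_identity(self):
        assert arc_distance(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_quarter_circumference(self):
        # 90 degrees of longitude along the equator is a quarter circle
        assert arc_distance(0.0, 0.0, 90.0, 0.0) == pytest.approx(
            math.pi / 2 * EARTH_RADIUS_KM, rel=1e-12
        )

    @settings(deadline=None, max_examples=50)
    @given(p=coord, q=coord)
    def test_symmetry_and_nonnegativity(self, p, q):
        d_pq = arc_distance(p[0], p[1], q[0], q[1])
        d_qp = arc_distance(q[0], q[1], p[0], p[1])
        assert d_pq == d_qp
        assert d_pq >= 0.0

    @settings(deadline=None, max_examples=50)
    @given(p=coord, q=coord, r=coord)
    def test_triangle_inequality(self, p, q, r):
        d = lambda a, b: arc_distance(a[0], a[1], b[0], b[1])
        assert d(p, r) <= d(p, q) + d(q, r) + 1e-9

    @pytest.mark.parametrize("bad", [(float("nan"), 0.0), (200.0, 0.0), (0.0, 95.0)])
    def test_invalid_coordinates_rejected(self, bad):
        with pytest.raises(ValueError):
            arc_distance(bad[0], bad[1], 0.0, 0.0)

    def test_mile_constant(self):
        assert KM_PER_MILE == 1.609344

    @pytest.mark.parametrize(
        "p,q,expected_km",
        [
            # reference values from R geosphere::distHaversine, r = 6371.0088 km
            ((-71.06, 42.36), (-93.61, 41.59), 1860.629287397),
            ((-93.61, 41.59), (-104.0, 39.74), 899.549296900),
            ((-157.86, 21.31), (-149.90, 61.22), 4480.538539187),
            ((-149.90, 61.22), (-71.06, 42.36), 5420.190115253),
        ],
    )
    def test_against_independent_reference(self, p, q, expected_km):
        assert arc_distance(p[0], p[1], q[0], q[1]) == pytest.approx(
            expected_km, abs=1e-6
        )


class TestBuildNeighbors:
    def test_collinear_middle_point_nearest(self):
        # equatorial points at 0, 1, 3 degrees: the middle point is closer
        # to the one at the origin
        lon = np.array([0.0, 1.0, 3.0])
        nb = build_neighbors(lon, np.zeros(3), k=1)
        idx, _, w = nb.neighbors_of(1)
        assert idx.tolist() == [0]
        assert w.tolist() == [1.0]

    def test_k_equals_n_minus_one_full_weight(self):
        rng = np.random.default_rng(3)
        lon, lat = rng.uniform(-10, 10, 8), rng.uniform(-10, 10, 8)
        nb = build_neighbors(lon, lat, k=7)
        for i in range(8):
            idx, _, w = nb.neighbors_of(i)
            assert sorted(idx.tolist()) == [j for j in range(8) if j != i]
            assert np.all(w == 1.0)

    def test_equidistant_tie_gets_half_weight(self):
        lon = np.array([0.0, 1.0, -1.0])
        nb = build_neighbors(lon, np.zeros(3), k=1)
        idx, _, w = nb.neighbors_of(0)
        assert sorted(idx.tolist()) == [1, 2]
        assert np.allclose(w, 0.5)
        assert w.sum() == 1.0

    def test_k_clamped_with_warning(self, caplog):
        lon = np.array([0.0, 1.0, 2.0])
        with caplog.at_level("WARNING"):
            nb = build_neighbors(lon, np.zeros(3), k=10)
        assert nb.k_effective == 2
        assert any("clamped" in r.message for r in caplog.records)

    def test_single_point_is_structural_error(self):
        with pytest.raises(ValueError):
            build_neighbors(np.array([0.0]), np.array([0.0]), k=1)

    def test_duplicate_coordinates_zero_bandwidth_flagged(self):
        lon = np.array([0.0, 0.0, 1.0])
        nb = build_neighbors(lon, np.zeros(3), k=1)
        assert nb.bandwidths[0] == 0.0
        assert nb.zero_bandwidth[0] and nb.zero_bandwidth[1]
        assert not nb.zero_bandwidth[2]
        # self never in own list even with duplicates
        for i in range(3):
            idx, _, _ = nb.neighbors_of(i)
            assert i not in idx

    @pytest.mark.parametrize("seed,n,k", [(0, 20, 1), (1, 50, 4), (2, 120, 7),
                                          (3, 200, 17), (4, 60, 59)])
    def test_matches_bruteforce_oracle_exactly(self, seed, n, k):
        """Indices, distances and tie weights agree with an O(N^2) sort."""
        rng = np.random.default_rng(seed)
        lon = rng.uniform(-100, -95, n)
        lat = rng.uniform(35, 40, n)
        # inject duplicates so zero-distance ties are exercised
        lon[5], lat[5] = lon[4], lat[4]
        nb = build_neighbors(lon, lat, k)
        expected = brute_neighbors(lon, lat, k)
        for i in range(n):
            idx, d, w = nb.neighbors_of(i)
            e_idx, e_d, e_w = expected[i]
            assert idx.tolist() == e_idx.tolist()
            assert d.tolist() == e_d.tolist()
            assert w.tolist() == e_w.tolist()

    def test_order_independence(self):
        rng = np.random.default_rng(7)
        lon = rng.uniform(-100, -95, 40)
        lat = rng.uniform(35, 40, 40)
        nb1 = build_neighbors(lon, lat, 4)
        perm = rng.permutation(40)
        nb2 = build_neighbors(lon[perm], lat[perm], 4)
        inv = np.empty(40, dtype=int)
        inv[perm] = np.arange(40)
        for i in range(40):
            idx1, d1, w1 = nb1.neighbors_of(i)
            idx2, d2, w2 = nb2.neighbors_of(inv[i])
            assert sorted(perm[idx2].tolist()) == sorted(idx1.tolist())
            assert sorted(d2.tolist()) == sorted(d1.tolist())

    def test_weights_sum_to_k(self):
        rng = np.random.default_rng(11)
        lon = rng.uniform(-100, -95, 60)
        lat = rng.uniform(35, 40, 60)
        for k in (1, 3, 10):
            nb = build_neighbors(lon, lat, k)
            for i in range(60):
                _, d, w = nb.neighbors_of(i)
                assert w.sum() == k
                assert np.all(np.diff(d) >= 0)


class TestRadiusCoverage:
    def test_two_points_within_radius(self):
        lon = np.array([0.0, 1.0 / 111.19])  # ~1 km apart on the equator
        lat = np.zeros(2)
        assert radius_coverage(lon, lat, lon, lat, 2.0) == 1.0
        assert radius_coverage(lon, lat, lon, lat, 0.5) == 0.0

    def test_grid_matches_bruteforce(self):
        # 10 equatorial points ~100 km apart; radius 150 km covers all
        lon = np.arange(10) * (100.0 / (math.pi / 180.0 * EARTH_RADIUS_KM))
        lat = np.zeros(10)
        got = radius_coverage(lon, lat, lon, lat, 150.0)
        assert got == brute_radius_coverage(lon, lat, lon, lat, 150.0)

    def test_random_sets_match_bruteforce(self):
        rng = np.random.default_rng(5)
        lon = rng.uniform(-98, -96, 30)
        lat = rng.uniform(36, 38, 30)
        rlon = rng.uniform(-98, -96, 40)
        rlat = rng.uniform(36, 38, 40)
        for radius in (10.0, 50.0, 120.0):
            got = radius_coverage(lon, lat, rlon, rlat, radius)
            assert got == brute_radius_coverage(lon, lat, rlon, rlat, radius)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            radius_coverage(np.array([]), np.array([]), np.array([0.0]),
                            np.array([0.0]), 1.0)

    def test_neighbor_counts(self):
        lon = np.array([0.0, 1.0 / 111.19, 10.0])
        lat = np.zeros(3)
        counts = neighbor_count_within(lon, lat, lon, lat, 2.0)
        assert counts.tolist() == [1.0, 1.0, 0.0]
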