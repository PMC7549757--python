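import math

import numpy as np
import pytest

import cloq
from cloq import (
    KernelSpec,
    LabeledPointSet,
    LocalCLQEngine,
    classify_clq,
    clq_table,
    global_clq,
    local_clq,
)
from cloq.core import (
    CLASS_STRONG_CLUSTERING,
    CLASS_STRONG_SEGREGATION,
    CLASS_WEAK_CLUSTERING,
    CLASS_WEAK_SEGREGATION,
)
from cloq.geometry import _haversine_km, build_neighbors
from conftest import random_instance
from oracles import brute_global_clq


def make_data(lon, lat, labels):
    return LabeledPointSet(np.asarray(lon, float), np.asarray(lat, float),
                           np.asarray(labels))


class TestGlobalCLQ:
    def test_five_point_attraction_example(self):
        # A at 0, 2.1, 10 deg; B at 1, 3 deg on the equator.  Each A's
        # nearest neighbor is a B, so the observed share is 1 against an
        # expected share of 2/4 -> CLQ = 2.
        data = make_data([0.0, 1.0, 2.1, 3.0, 10.0], [0.0] * 5,
                         ["A", "B", "A", "B", "A"])
        nbrs = build_neighbors(data.lon, data.lat, 1)
        est = global_clq(data, nbrs, "A", "B")
        assert est.value == pytest.approx(2.0, abs=1e-12)
        assert est.descriptive_class == CLASS_STRONG_CLUSTERING

    def test_single_category_self_clq_is_one(self):
        rng = np.random.default_rng(0)
        data = make_data(rng.uniform(-10, 10, 30), rng.uniform(-10, 10, 30),
                         ["NH"] * 30)
        for k in (1, 5, 29):
            nbrs = build_neighbors(data.lon, data.lat, k)
            assert global_clq(data, nbrs, "NH", "NH").value == 1.0

    def test_self_pair_with_single_point_errors(self):
        data = make_data([0.0, 1.0, 2.0], [0.0] * 3, ["A", "B", "B"])
        nbrs = build_neighbors(data.lon, data.lat, 1)
        with pytest.raises(ValueError):
            global_clq(data, nbrs, "A", "A")

    def test_absent_category_errors(self):
        data = make_data([0.0, 1.0], [0.0, 0.0], ["A", "B"])
        nbrs = build_neighbors(data.lon, data.lat, 1)
        with pytest.raises(ValueError):
            global_clq(data, nbrs, "C", "A")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        """Exact agreement with explicit full-matrix counting, N <= 100."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 101))
        lon, lat, labels = random_instance(rng, n)
        k = int(rng.integers(1, min(8, n - 1)))
        data = make_data(lon, lat, labels)
        nbrs = build_neighbors(lon, lat, k)
        for a in "AB":
            for b in "AB":
                expected = brute_global_clq(lon, lat, labels, a, b, k)
                assert global_clq(data, nbrs, a, b).value == pytest.approx(
                    expected, abs=1e-12
                )

    def test_normalization_identity(self):
        """Sum_B CLQ_A->B * N_B'/(N-1) == 1: the k neighbor slots of each
        focal point are fully allocated across categories."""
        rng = np.random.default_rng(4)
        lon, lat, labels = random_instance(rng, 200, ("A", "B", "C", "D"))
        data = make_data(lon, lat, labels)
        for k in (1, 4, 17):
            nbrs = build_neighbors(lon, lat, k)
            for a in "ABCD":
                total = 0.0
                for b in "ABCD":
                    n_b = data.count(b) - (1 if a == b else 0)
                    total += global_clq(data, nbrs, a, b).value * n_b / (data.n - 1)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_range_bound(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lon, lat, labels = random_instance(rng, 60)
            data = make_data(lon, lat, labels)
            nbrs = build_neighbors(lon, lat, 3)
            for a in "ABC":
                for b in "ABC":
                    v = global_clq(data, nbrs, a, b).value
                    n_b = data.count(b) - (1 if a == b else 0)
                    assert 0.0 <= v <= (data.n - 1) / n_b + 1e-12

    def test_asymmetry_when_rare_a_sits_among_b(self):
        # a tight B cluster hosting two A points, plus far-away B outliers:
        # A always sees B neighbors, B mostly sees B
        rng = np.random.default_rng(1)
        lon_b = np.concatenate([rng.normal(0, 0.01, 20), [30.0, 40.0, 50.0]])
        lat_b = np.concatenate([rng.normal(0, 0.01, 20), [0.0, 0.0, 0.0]])
        lon_a = rng.normal(0, 0.01, 2)
        lat_a = rng.normal(0, 0.01, 2)
        data = make_data(np.r_[lon_a, lon_b], np.r_[lat_a, lat_b],
                         ["A"] * 2 + ["B"] * 23)
        nbrs = build_neighbors(data.lon, data.lat, 3)
        ab = global_clq(data, nbrs, "A", "B").value
        ba = global_clq(data, nbrs, "B", "A").value
        assert ab != ba

    def test_random_labeling_mean_near_one(self):
        """Averaged over random relabelings, the global CLQ is centered on 1."""
        from cloq.significance import PermutationPlan, mc_pvalue_global

        rng = np.random.default_rng(2)
        lon, lat, labels = random_instance(rng, 150, ("A", "B"))
        data = make_data(lon, lat, labels)
        nbrs = build_neighbors(lon, lat, 4)
        res = mc_pvalue_global(data, nbrs, "A", "B",
                               PermutationPlan(n_permutations=1000, seed=5))
        se = res.null_sd / math.sqrt(res.n_permutations)
        assert abs(res.null_mean - 1.0) < 3 * se


class TestCLQTable:
    def test_grid_shape_and_same_resolution(self):
        rng = np.random.default_rng(6)
        lon, lat, labels = random_instance(rng, 120, ("NH", "acute_care"))
        data = make_data(lon, lat, labels)
        ests = clq_table(data, ["NH"], ["acute_care", cloq.SAME], [1, 4])
        assert len(ests) == 4
        same = [e for e in ests if e.to_category == "NH"]
        assert len(same) == 2  # SAME resolved to the from-category

    def test_empty_k_list(self):
        data = make_data([0.0, 1.0], [0.0, 0.0], ["A", "B"])
        assert clq_table(data, ["A"], ["B"], []) == []


class TestLocalCLQ:
    def test_two_term_hand_oracle(self):
        # focal A at origin; B at 0.1 and 0.2 deg east; far A at 1 deg.
        # k=2: bandwidth is the distance to the 2nd neighbor (B at 0.2).
        lon = np.array([0.0, 0.1, 0.2, 1.0])
        lat = np.zeros(4)
        data = make_data(lon, lat, ["A", "B", "B", "A"])
        est = local_clq(data, 0, "B", k=2)

        d = _haversine_km(np.zeros(3), np.zeros(3), lon[1:], lat[1:])
        b = d[1]
        w = np.exp(-0.5 * (d / b) ** 2)
        expected = (w[:2].sum() / w.sum()) / (2 / 3)
        assert est.value == pytest.approx(expected, rel=1e-12)
        assert est.bandwidth_km == b

    def test_equidistant_neighbors_reduce_to_box_ratio(self):
        # focal at the pole-free center of a symmetric cross: all four
        # neighbors equidistant, so gaussian weighting is constant
        lon = np.array([0.0, 0.3, -0.3, 0.0, 0.0])
        lat = np.array([0.0, 0.0, 0.0, 0.3, -0.3])
        data = make_data(lon, lat, ["A", "B", "B", "A", "A"])
        est = local_clq(data, 0, "B", k=4)
        # 2 of 4 equidistant neighbors are B; expected share 2/4
        assert est.value == pytest.approx((2 / 4) / (2 / 4), rel=1e-9)

    def test_zero_bandwidth_falls_back_to_positive_distance(self, caplog):
        lon = np.array([0.0, 0.0, 0.5, 1.0])
        lat = np.zeros(4)
        data = make_data(lon, lat, ["A", "B", "B", "A"])
        with caplog.at_level("WARNING"):
            est = local_clq(data, 0, "B", k=1)
        assert est.value > 0
        assert any("zero bandwidth" in r.message for r in caplog.records)

    def test_box_kernel_variant(self):
        lon = np.array([0.0, 0.1, 0.2, 1.0])
        data = make_data(lon, np.zeros(4), ["A", "B", "B", "A"])
        est = local_clq(data, 0, "B", k=2, kernel=KernelSpec("box", 2))
        assert est.value == pytest.approx((2 / 2) / (2 / 3), rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, CLASS_STRONG_SEGREGATION),
            (0.06, CLASS_STRONG_SEGREGATION),
            (0.499999, CLASS_STRONG_SEGREGATION),
            (0.50, CLASS_WEAK_SEGREGATION),
            (0.86, CLASS_WEAK_SEGREGATION),
            (1.00, CLASS_WEAK_SEGREGATION),  # boundary goes to the lower class
            (1.000001, CLASS_WEAK_CLUSTERING),
            (1.26, CLASS_WEAK_CLUSTERING),
            (1.50, CLASS_WEAK_CLUSTERING),
            (1.51, CLASS_STRONG_CLUSTERING),
            (6.85, CLASS_STRONG_CLUSTERING),
        ],
    )
    def test_descriptive_classes(self, value, expected):
        assert classify_clq(value) == expected

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_clq(bad)


class TestKernelSpec:
    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            KernelSpec("triangular", 4)

    def test_rejects_bad_rank(self):
        with pytest.raises(ValueError):
            KernelSpec("box", 0)
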