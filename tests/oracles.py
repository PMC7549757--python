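"""Independent brute-force oracles for the neighbor and CLQ machinery.

Everything here is deliberately naive — full O(N^2) distance matrices,
explicit Python loops, direct transcription of the defining formulas — and
shares nothing with the package implementation except the haversine
distance function itself (distances must agree bit-for-bit for exact tie
comparisons to be meaningful).
"""

from __future__ import annotations

import numpy as np

from cloq.geometry import _haversine_km


def full_distance_matrix(lon, lat) -> np.ndarray:
    # row-vectorized so numpy uses the same SIMD kernels as the package
    # (scalar libm calls can differ from the vector path by one ulp,
    # which would spoil exact tie comparisons)
    n = len(lon)
    d = np.empty((n, n))
    for i in range(n):
        d[i] = _haversine_km(lon[i], lat[i], np.asarray(lon), np.asarray(lat))
    return d


def brute_neighbors(lon, lat, k):
    """Per-point (indices, distances, weights) by exhaustive distance sort.

    Ties at the k-th rank share the remaining slots equally; output sorted
    by (distance, index).  Returns a list of 3-tuples of arrays.
    """
    n = len(lon)
    k_eff = min(k, n - 1)
    d = full_distance_matrix(lon, lat)
    out = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (d[i, j], j))
        dists = [d[i, j] for j in others]
        d_k = dists[k_eff - 1]
        closer = [j for j in others if d[i, j] < d_k]
        tied = [j for j in others if d[i, j] == d_k]
        tie_w = (k_eff - len(closer)) / len(tied)
        keep = [j for j in others if d[i, j] <= d_k]
        w = [1.0 if d[i, j] < d_k else tie_w for j in keep]
        out.append(
            (
                np.array(keep, dtype=np.int64),
                np.array([d[i, j] for j in keep]),
                np.array(w),
            )
        )
    return out


def brute_global_clq(lon, lat, labels, a_cat, b_cat, k) -> float:
    """Global CLQ_A→B straight from the definition, no shared code paths."""
    labels = np.asarray(labels)
    n = len(lon)
    k_eff = min(k, n - 1)
    nbrs = brute_neighbors(lon, lat, k)
    n_b = int(np.sum(labels == b_cat))
    n_b_adj = n_b - 1 if a_cat == b_cat else n_b
    a_idx = [i for i in range(n) if labels[i] == a_cat]
    total = 0.0
    for i in a_idx:
        idx, _, w = nbrs[i]
        total += sum(wi for j, wi in zip(idx, w) if labels[j] == b_cat)
    return (total / len(a_idx) / k_eff) / (n_b_adj / (n - 1))


def brute_radius_coverage(lon, lat, ref_lon, ref_lat, radius_km) -> float:
    """Exhaustive pair check; one zero-distance match per point is self."""
    covered = 0
    for i in range(len(lon)):
        d = [
            _haversine_km(lon[i], lat[i], ref_lon[j], ref_lat[j])
            for j in range(len(ref_lon))
        ]
        within = [x for x in d if x <= radius_km]
        if 0.0 in within:
            within.remove(0.0)
        if within:
            covered += 1
    return covered / len(lon)
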