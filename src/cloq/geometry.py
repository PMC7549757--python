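"""Great-circle geometry and adaptive nearest-neighbor machinery.

All coordinates are unprojected WGS84 longitude/latitude in decimal degrees;
all distances are great-circle (arc) kilometers on a sphere of radius
:data:`EARTH_RADIUS_KM`.  Miles appear only at the command-line boundary.

The central object is :class:`NeighborStructure`: for every point of a point
set, the ``k`` nearest *other* points by arc distance, with ties at the k-th
rank resolved by fractional inclusion weights so that each point's weights
always sum to exactly ``k`` (or ``N - 1`` when ``k`` exceeds it).  This makes
every downstream statistic deterministic and invariant to the input ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.neighbors import BallTree

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: International mile, km.
KM_PER_MILE = 1.609344


class GeoPoint(NamedTuple):
    """A WGS84 longitude/latitude pair (degrees east, degrees north)."""

    lon: float
    lat: float


def validate_coordinates(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Coerce lon/lat to float arrays and check finiteness and range.

    Raises
    ------
    ValueError
        If any coordinate is non-finite or outside [-180, 180] / [-90, 90].
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.shape != lat.shape:
        raise ValueError("lon and lat must have the same shape")
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise ValueError("lon must lie in [-180, 180] and lat in [-90, 90]")
    return lon, lat


def arc_distance(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Uses the haversine formulation for numerical stability at small
    separations.  Accepts scalars or broadcastable arrays; returns the same
    shape.  Symmetric, non-negative, and zero only for identical coordinates.
    """
    lon1, lat1 = validate_coordinates(lon1, lat1)
    lon2, lat2 = validate_coordinates(lon2, lat2)
    return _haversine_km(lon1, lat1, lon2, lat2)


def _haversine_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance, km.  No validation; radians math."""
    lam1, phi1 = np.radians(lon1), np.radians(lat1)
    lam2, phi2 = np.radians(lon2), np.radians(lat2)
    s = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    # clip guards sqrt of tiny negative round-off for antipodal-ish pairs
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


@dataclass
class NeighborStructure:
    """Per-point nearest neighbors with tie-weighted adaptive bandwidths.

    Stored in CSR-like flat form: the neighbors of point ``i`` occupy the
    slice ``indptr[i]:indptr[i+1]`` of ``indices``, ``distances`` and
    ``weights``.  ``bandwidths[i]`` is the arc distance to the k-th nearest
    neighbor (the adaptive bandwidth b_i).

    Invariants (enforced at build time, checked by the test suite):

    * a point never appears in its own neighbor list;
    * distances are non-decreasing within each slice;
    * weights within a slice sum to ``min(k, N - 1)`` exactly;
    * ``bandwidths[i] == 0`` only when duplicate coordinates reach rank k
      (then ``zero_bandwidth[i]`` is set).
    """

    k: int
    n_points: int
    indptr: np.ndarray
    indices: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    bandwidths: np.ndarray
    zero_bandwidth: np.ndarray = field(repr=False)

    @property
    def k_effective(self) -> int:
        """The rank actually used: ``min(k, n_points - 1)``."""
        return min(self.k, self.n_points - 1)

    def neighbors_of(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (indices, distances, weights) for point ``i``."""
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return self.indices[sl], self.distances[sl], self.weights[sl]

    @property
    def row_ids(self) -> np.ndarray:
        """Focal-point index for every flat neighbor entry."""
        return np.repeat(
            np.arange(self.n_points), np.diff(self.indptr)
        )


def build_neighbors(lon, lat, k: int) -> NeighborStructure:
    """Build the k-nearest-neighbor structure over a lon/lat point set.

    Neighbors are ranked by arc distance.  All points tied at the k-th
    distance share the remaining inclusion slots equally, so the result does
    not depend on the input ordering.  Duplicate coordinates are kept as
    distinct points; only the self-pair is excluded.

    Parameters
    ----------
    lon, lat : array-like, degrees
    k : int
        Adaptive bandwidth rank (>= 1).  Clamped to ``N - 1`` with a logged
        warning when it exceeds it.
    """
    lon, lat = validate_coordinates(lon, lat)
    n = lon.size
    if n < 2:
        raise ValueError("need at least 2 points to build neighbors")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, n - 1)
    if k_eff != k:
        logger.warning("k=%d exceeds N-1=%d; clamped", k, n - 1)

    x = np.column_stack([np.radians(lat), np.radians(lon)])
    tree = BallTree(x, metric="haversine")

    # Query with padding, recompute distances with our own haversine so tie
    # detection is bit-identical to a brute-force oracle, and expand until we
    # are certain no tie at rank k is truncated.
    kq = min(n, k_eff + 1 + 8)
    while True:
        _, idx = tree.query(x, k=kq)
        d = _haversine_km(lon[:, None], lat[:, None], lon[idx], lat[idx])
        # drop exactly one self entry per row (duplicates stay)
        self_pos = idx == np.arange(n)[:, None]
        keep = np.ones_like(self_pos)
        has_self = self_pos.any(axis=1)
        first_self = np.where(has_self, self_pos.argmax(axis=1), kq - 1)
        keep[np.arange(n), first_self] = False  # rows w/o self drop the last
        idx_ns = idx[keep].reshape(n, kq - 1)
        d_ns = d[keep].reshape(n, kq - 1)
        # re-sort by (our distance, index): deterministic, order-independent
        order = np.lexsort((idx_ns, d_ns), axis=1)
        idx_ns = np.take_along_axis(idx_ns, order, axis=1)
        d_ns = np.take_along_axis(d_ns, order, axis=1)
        if kq >= n:
            break
        # rank-k distance must be strictly below the last candidate, else a
        # tie group might extend beyond what we fetched
        if np.all(d_ns[:, k_eff - 1] < d_ns[:, -1]):
            break
        kq = min(n, kq * 2)

    d_k = d_ns[:, k_eff - 1]
    closer = d_ns < d_k[:, None]
    tied = d_ns == d_k[:, None]
    n_closer = closer.sum(axis=1)
    n_tied = tied.sum(axis=1)
    tie_w = (k_eff - n_closer) / n_tied

    keep_mask = closer | tied
    counts = keep_mask.sum(axis=1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    w = np.where(closer, 1.0, np.where(tied, tie_w[:, None], 0.0))

    nbrs = NeighborStructure(
        k=k,
        n_points=n,
        indptr=indptr,
        indices=idx_ns[keep_mask],
        distances=d_ns[keep_mask],
        weights=w[keep_mask],
        bandwidths=d_k.copy(),
        zero_bandwidth=(d_k == 0.0),
    )
    if nbrs.zero_bandwidth.any():
        logger.warning(
            "%d point(s) have zero bandwidth at rank k=%d (duplicate "
            "coordinates)", int(nbrs.zero_bandwidth.sum()), k_eff,
        )
    return nbrs


def radius_coverage(
    lon, lat, ref_lon, ref_lat, radius_km: float, *, exclude_self: bool = True
) -> float:
    """Fraction of query points with >= 1 reference point within a radius.

    With ``exclude_self`` (the default, for when the reference set equals or
    contains the query set) one zero-distance match per query point is
    discounted as the self-pair; additional coincident points still count.

    Parameters
    ----------
    lon, lat : query coordinates, degrees
    ref_lon, ref_lat : reference coordinates, degrees
    radius_km : float, > 0
    """
    lon, lat = validate_coordinates(lon, lat)
    ref_lon, ref_lat = validate_coordinates(ref_lon, ref_lat)
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    if lon.size == 0 or ref_lon.size == 0:
        raise ValueError("query and reference sets must be non-empty")

    tree = BallTree(
        np.column_stack([np.radians(ref_lat), np.radians(ref_lon)]),
        metric="haversine",
    )
    x = np.column_stack([np.radians(lat), np.radians(lon)])
    hits = tree.query_radius(x, r=radius_km / EARTH_RADIUS_KM)
    covered = 0
    for i, h in enumerate(hits):
        m = h.size
        if exclude_self and m:
            d0 = _haversine_km(lon[i], lat[i], ref_lon[h], ref_lat[h])
            if np.any(d0 == 0.0):
                m -= 1
        if m > 0:
            covered += 1
    return covered / lon.size


def neighbor_count_within(
    lon, lat, ref_lon, ref_lat, radius_km: float, *, exclude_self: bool = True
) -> np.ndarray:
    """Per-query-point count of reference points within ``radius_km``."""
    lon, lat = validate_coordinates(lon, lat)
    ref_lon, ref_lat = validate_coordinates(ref_lon, ref_lat)
    tree = BallTree(
        np.column_stack([np.radians(ref_lat), np.radians(ref_lon)]),
        metric="haversine",
    )
    x = np.column_stack([np.radians(lat), np.radians(lon)])
    hits = tree.query_radius(x, r=radius_km / EARTH_RADIUS_KM)
    out = np.empty(lon.size, dtype=float)
    for i, h in enumerate(hits):
        m = h.size
        if exclude_self and m:
            d0 = _haversine_km(lon[i], lat[i], ref_lon[h], ref_lat[h])
            if np.any(d0 == 0.0):
                m -= 1
        out[i] = m
    return out
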