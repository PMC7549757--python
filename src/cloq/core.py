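"""Global and geographically weighted local colocation quotients.

The colocation quotient CLQ_A→B measures how strongly points of category A
are attracted to points of category B inside a marked (categorical) point
pattern.  With N points overall, N_B of category B, and n_aB the
(tie-weighted) number of B points among the k nearest neighbors of an
A point ``a``:

    CLQ_A→B = [ (1/N_A) Σ_a n_aB / k ] / [ N_B' / (N - 1) ]

where N_B' = N_B - 1 when A = B (a point cannot be its own neighbor) and
N_B otherwise.  Values above 1 indicate attraction (clustering) of A toward
B, below 1 segregation, and 1 the absence of spatial dependence.  The
quotient is asymmetric: CLQ_A→B need not equal CLQ_B→A.

Local quotients replace the flat ("box") neighbor weighting with a Gaussian
kernel scaled by the focal point's adaptive bandwidth (the distance to its
k-th nearest neighbor), describing the spatial variability of association
around each individual point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import BallTree

from .geometry import (
    EARTH_RADIUS_KM,
    NeighborStructure,
    _haversine_km,
    build_neighbors,
    validate_coordinates,
)

logger = logging.getLogger(__name__)

#: Provider category codes used in the CMS facility tables.
CATEGORIES = ("IRF", "NH", "hh_care", "acute_care", "crit_care", "hospice", "LTCH")

#: Post-acute provider categories (focal categories of the analyses).
POST_ACUTE_CATEGORIES = ("hh_care", "hospice", "IRF", "LTCH", "NH")

#: Hospital categories (target categories of the analyses).
HOSPITAL_CATEGORIES = ("acute_care", "crit_care")

#: Sentinel resolving a from-category to itself in table requests.
SAME = "SAME"

CLASS_STRONG_SEGREGATION = "moderate-to-strong segregation"
CLASS_WEAK_SEGREGATION = "weak-to-moderate segregation"
CLASS_WEAK_CLUSTERING = "weak-to-moderate clustering"
CLASS_STRONG_CLUSTERING = "moderate-to-strong clustering"

#: The four descriptive classes, ordered from strongest segregation to
#: strongest clustering.
DESCRIPTIVE_CLASSES = (
    CLASS_STRONG_SEGREGATION,
    CLASS_WEAK_SEGREGATION,
    CLASS_WEAK_CLUSTERING,
    CLASS_STRONG_CLUSTERING,
)

#: Gaussian kernel weights below this are truncated for performance.
GAUSSIAN_TRUNCATION = 1e-9


@dataclass
class LabeledPointSet:
    """A marked point pattern: lon/lat coordinates plus one label each."""

    lon: np.ndarray
    lat: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.lon, self.lat = validate_coordinates(self.lon, self.lat)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.lon.shape:
            raise ValueError("labels and points must have equal length")

    @property
    def n(self) -> int:
        return self.lon.size

    def census(self) -> dict[str, int]:
        """Point count per category."""
        cats, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(cats.tolist(), counts.tolist()))

    def count(self, category: str) -> int:
        return int(np.sum(self.labels == category))

    def subset(self, mask) -> "LabeledPointSet":
        return LabeledPointSet(self.lon[mask], self.lat[mask], self.labels[mask])


@dataclass(frozen=True)
class KernelSpec:
    """Neighbor weighting: flat ``box`` or adaptive-bandwidth ``gaussian``."""

    kind: str = "box"
    k: int = 4

    def __post_init__(self):
        if self.kind not in ("box", "gaussian"):
            raise ValueError(f"unknown kernel kind: {self.kind!r}")
        if self.k < 1:
            raise ValueError("kernel rank k must be >= 1")


@dataclass
class CLQEstimate:
    """A global colocation quotient with its provenance and significance."""

    from_category: str
    to_category: str
    k: int
    kernel: str
    value: float
    n_from: int
    n_to: int
    descriptive_class: str = field(default="")
    p_value: float | None = None
    n_permutations: int | None = None

    def __post_init__(self):
        if not self.descriptive_class:
            self.descriptive_class = classify_clq(self.value)


@dataclass
class LocalCLQEstimate:
    """A per-point colocation quotient toward a target category."""

    index: int
    to_category: str
    value: float
    bandwidth_km: float
    descriptive_class: str = field(default="")
    p_value: float | None = None

    def __post_init__(self):
        if not self.descriptive_class:
            self.descriptive_class = classify_clq(self.value)


def classify_clq(value: float) -> str:
    """Map a CLQ value to one of the four descriptive classes.

    ``[0, 0.50)`` moderate-to-strong segregation, ``[0.50, 1.00]``
    weak-to-moderate segregation, ``(1.00, 1.50]`` weak-to-moderate
    clustering, ``(1.50, ∞)`` moderate-to-strong clustering.  The boundary
    1.00 belongs to the segregation class.
    """
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"CLQ value must be finite and non-negative, got {value}")
    if value < 0.50:
        return CLASS_STRONG_SEGREGATION
    if value <= 1.00:
        return CLASS_WEAK_SEGREGATION
    if value <= 1.50:
        return CLASS_WEAK_CLUSTERING
    return CLASS_STRONG_CLUSTERING


def _n_to_adjusted(data: LabeledPointSet, a_cat: str, b_cat: str) -> int:
    n_b = data.count(b_cat)
    return n_b - 1 if a_cat == b_cat else n_b


def category_neighbor_sums(
    nbrs: NeighborStructure, labels: np.ndarray, category: str
) -> np.ndarray:
    """Tie-weighted count of ``category`` neighbors for every point."""
    mask = (labels[nbrs.indices] == category).astype(float)
    return np.bincount(
        nbrs.row_ids, weights=nbrs.weights * mask, minlength=nbrs.n_points
    )


def global_clq(
    data: LabeledPointSet,
    nbrs: NeighborStructure,
    a_cat: str,
    b_cat: str,
) -> CLQEstimate:
    """Global CLQ_A→B with a box kernel over the k nearest neighbors.

    ``nbrs`` must be built over the full point set of ``data`` (all
    categories), the population from which neighbors are drawn.
    """
    if nbrs.n_points != data.n:
        raise ValueError("neighbor structure does not match the point set")
    n_a = data.count(a_cat)
    if n_a < 1:
        raise ValueError(f"category {a_cat!r} absent from data")
    n_b_adj = _n_to_adjusted(data, a_cat, b_cat)
    if n_b_adj < 1:
        raise ValueError(
            f"CLQ {a_cat}->{b_cat} undefined: fewer than "
            f"{2 if a_cat == b_cat else 1} target point(s)"
        )
    k_eff = nbrs.k_effective
    n_ab = category_neighbor_sums(nbrs, data.labels, b_cat)
    observed = float(np.mean(n_ab[data.labels == a_cat])) / k_eff
    expected = n_b_adj / (data.n - 1)
    return CLQEstimate(
        from_category=a_cat,
        to_category=b_cat,
        k=nbrs.k,
        kernel="box",
        value=observed / expected,
        n_from=n_a,
        n_to=data.count(b_cat),
    )


def clq_table(
    data: LabeledPointSet,
    from_categories,
    to_specs,
    k_values,
    *,
    neighbor_cache: dict[int, NeighborStructure] | None = None,
) -> list[CLQEstimate]:
    """One global CLQ per (from, to, k) triple; ``SAME`` resolves each
    from-category to itself.  Neighbor structures are built once per k and
    reused (pass ``neighbor_cache`` to share across calls).
    """
    if neighbor_cache is None:
        neighbor_cache = {}
    out: list[CLQEstimate] = []
    for k in k_values:
        if k not in neighbor_cache:
            neighbor_cache[k] = build_neighbors(data.lon, data.lat, k)
        nbrs = neighbor_cache[k]
        for a_cat in from_categories:
            for to_spec in to_specs:
                b_cat = a_cat if to_spec == SAME else to_spec
                out.append(global_clq(data, nbrs, a_cat, b_cat))
    return out


class LocalCLQEngine:
    """Computes Gaussian-kernel local CLQs toward a target category.

    Bandwidths are adaptive: b_i is the arc distance from the focal point to
    its k-th nearest neighbor within the analyzed point set.  Weights
    w_ij = exp(-0.5 (d_ij / b_i)^2) are evaluated over all other points,
    truncated below :data:`GAUSSIAN_TRUNCATION`; the statistic is the
    weighted share of target-category neighbors over the expected share
    N_B' / (N - 1).

    A zero bandwidth (duplicate coordinates through rank k) falls back to
    the smallest positive neighbor distance, with a logged warning.
    """

    def __init__(self, data: LabeledPointSet, k: int):
        self.data = data
        self.k = k
        self.nbrs = build_neighbors(data.lon, data.lat, k)
        self._tree = BallTree(
            np.column_stack([np.radians(data.lat), np.radians(data.lon)]),
            metric="haversine",
        )
        # exp(-0.5 r^2) < 1e-9 beyond r = sqrt(2 ln 1e9) bandwidths
        self._trunc_radii = np.sqrt(-2.0 * np.log(GAUSSIAN_TRUNCATION))

    def bandwidth(self, i: int) -> float:
        b = float(self.nbrs.bandwidths[i])
        if b == 0.0:
            _, dists, _ = self.nbrs.neighbors_of(i)
            pos = dists[dists > 0]
            if pos.size == 0:
                d_all = _haversine_km(
                    self.data.lon[i], self.data.lat[i], self.data.lon, self.data.lat
                )
                pos = d_all[d_all > 0]
            if pos.size == 0:
                raise ValueError("all points coincide; local CLQ undefined")
            b = float(pos.min())
            logger.warning(
                "point %d has zero bandwidth at rank %d; falling back to "
                "smallest positive neighbor distance %.6f km", i, self.k, b,
            )
        return b

    def _neighborhood(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices (excluding self) and Gaussian weights around point ``i``."""
        b = self.bandwidth(i)
        r_km = self._trunc_radii * b
        (hit,) = self._tree.query_radius(
            np.array([[np.radians(self.data.lat[i]), np.radians(self.data.lon[i])]]),
            r=r_km / EARTH_RADIUS_KM,
        )
        hit = hit[hit != i]
        d = _haversine_km(
            self.data.lon[i], self.data.lat[i], self.data.lon[hit], self.data.lat[hit]
        )
        w = np.exp(-0.5 * (d / b) ** 2)
        keep = w >= GAUSSIAN_TRUNCATION
        return hit[keep], w[keep]

    def local_clq(
        self, i: int, b_cat: str, labels: np.ndarray | None = None
    ) -> LocalCLQEstimate:
        """Local CLQ of point ``i`` toward category ``b_cat``.

        ``labels`` overrides the data labels (used by permutation tests;
        the geometry and bandwidth stay fixed).
        """
        labels = self.data.labels if labels is None else labels
        n_b_adj = int(np.sum(labels == b_cat)) - (1 if labels[i] == b_cat else 0)
        if n_b_adj < 1:
            raise ValueError(f"local CLQ toward {b_cat!r} undefined: no targets")
        hit, w = self._neighborhood(i)
        share = float(np.sum(w * (labels[hit] == b_cat)) / np.sum(w))
        expected = n_b_adj / (self.data.n - 1)
        return LocalCLQEstimate(
            index=i,
            to_category=b_cat,
            value=share / expected,
            bandwidth_km=self.bandwidth(i),
        )

    def local_clq_many(self, indices, b_cat: str) -> list[LocalCLQEstimate]:
        return [self.local_clq(int(i), b_cat) for i in indices]


def local_clq(
    data: LabeledPointSet,
    index: int,
    b_cat: str,
    k: int,
    kernel: KernelSpec | None = None,
) -> LocalCLQEstimate:
    """Local colocation quotient of one focal point toward ``b_cat``.

    Convenience wrapper; for many focal points build a
    :class:`LocalCLQEngine` once and reuse it.  A ``box`` kernel reduces to
    the focal point's tie-weighted neighbor share n_aB / k over the expected
    share.
    """
    kernel = kernel or KernelSpec("gaussian", k)
    if kernel.kind == "gaussian":
        return LocalCLQEngine(data, k).local_clq(index, b_cat)
    nbrs = build_neighbors(data.lon, data.lat, k)
    n_b = data.count(b_cat)
    n_b_adj = n_b - 1 if data.labels[index] == b_cat else n_b
    if n_b_adj < 1:
        raise ValueError(f"local CLQ toward {b_cat!r} undefined: no targets")
    idx, _, w = nbrs.neighbors_of(index)
    n_ab = float(np.sum(w * (data.labels[idx] == b_cat)))
    value = (n_ab / nbrs.k_effective) / (n_b_adj / (data.n - 1))
    return LocalCLQEstimate(
        index=index,
        to_category=b_cat,
        value=value,
        bandwidth_km=float(nbrs.bandwidths[index]),
    )
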