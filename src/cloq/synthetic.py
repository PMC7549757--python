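"""Synthetic marked point patterns with known clustering/segregation.

The generator emulates the urban-concentration structure of facility
location data: a handful of "city" centers placed uniformly in a lon/lat
rectangle, around which a configurable fraction of each category's points
aggregates (a Neyman–Scott-style cluster process), the remainder falling
uniformly over the region.  Cross-category attraction θ_{A→B} plants a
fraction of B points directly next to already-placed A points, giving a
known, tunable colocation signal; with all cluster fractions and θ at zero
the pattern is completely spatially random with random labels (the CSR
null).

Planar kilometer offsets are converted to degrees by dividing by
111.32 km/deg (and cos(lat) for longitude), adequate at the regional scale
of these benchmarks.  All coordinates are clipped to the configured region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabeledPointSet
from .facility_io import DialectConfig, FacilityTable, write_facilities
from .significance import permute_labels

KM_PER_DEG = 111.32

__all__ = ["CategorySpec", "SyntheticConfig", "generate_pattern", "relabel_csr",
           "write_pattern"]


@dataclass(frozen=True)
class CategorySpec:
    """One category of the synthetic pattern.

    ``cluster_fraction`` (φ) is the probability that a point of the category
    sits near a city center rather than uniformly in the region; ``sigma_km``
    is its isotropic displacement scale around its anchor.
    """

    name: str
    n: int
    cluster_fraction: float = 0.0
    sigma_km: float = 5.0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("category count must be >= 0")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.sigma_km <= 0:
            raise ValueError("sigma_km must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model for benchmark point patterns.

    ``cross_attraction`` maps ``(A, B)`` to θ_{A→B}: the probability that a
    B point is planted within ``sigma_km`` of category B from a randomly
    chosen, previously placed A point.  Categories are placed in listed
    order, so attraction sources must precede their targets.
    """

    categories: tuple[CategorySpec, ...]
    lon_range: tuple[float, float] = (-96.5, -90.0)
    lat_range: tuple[float, float] = (40.3, 43.6)
    n_centers: int = 6
    seed: int = 0
    cross_attraction: dict = field(default_factory=dict)

    def __post_init__(self):
        if sum(c.n for c in self.categories) == 0:
            raise ValueError("the pattern must contain at least one point")
        names = [c.name for c in self.categories]
        order = {n: i for i, n in enumerate(names)}
        for (a, b), theta in self.cross_attraction.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError("cross-attraction θ must lie in [0, 1]")
            if a not in order or b not in order:
                raise ValueError(f"unknown category in attraction pair ({a}, {b})")
            if order[a] >= order[b]:
                raise ValueError(
                    f"attraction source {a!r} must be listed before target {b!r}"
                )


def _offset(rng, lon, lat, sigma_km, displacement):
    if displacement == "gaussian":
        dx, dy = rng.normal(0.0, sigma_km, size=(2,) + np.shape(lon))
    elif displacement == "uniform_disc":
        r = sigma_km * np.sqrt(rng.uniform(size=np.shape(lon)))
        ang = rng.uniform(0, 2 * np.pi, size=np.shape(lon))
        dx, dy = r * np.cos(ang), r * np.sin(ang)
    else:
        raise ValueError(f"unknown displacement kind: {displacement!r}")
    new_lat = lat + dy / KM_PER_DEG
    new_lon = lon + dx / (KM_PER_DEG * np.cos(np.radians(lat)))
    return new_lon, new_lat


def generate_pattern(
    config: SyntheticConfig,
    seed: int | None = None,
    *,
    displacement: str = "gaussian",
) -> LabeledPointSet:
    """Draw one labeled point pattern from the generative model.

    Deterministic for a fixed config and seed (``seed`` overrides
    ``config.seed`` when given).  ``displacement`` selects ``gaussian``
    (default) or ``uniform_disc`` offspring offsets.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo_lon, hi_lon = config.lon_range
    lo_lat, hi_lat = config.lat_range

    centers_lon = rng.uniform(lo_lon, hi_lon, size=config.n_centers)
    centers_lat = rng.uniform(lo_lat, hi_lat, size=config.n_centers)

    attraction_by_target: dict[str, list[tuple[str, float]]] = {}
    for (a, b), theta in config.cross_attraction.items():
        attraction_by_target.setdefault(b, []).append((a, theta))

    placed_lon: list[np.ndarray] = []
    placed_lat: list[np.ndarray] = []
    placed_lab: list[np.ndarray] = []

    def _anchor_pool(name):
        mask = np.concatenate(placed_lab) == name
        return (
            np.concatenate(placed_lon)[mask],
            np.concatenate(placed_lat)[mask],
        )

    for spec in config.categories:
        if spec.n == 0:
            continue
        u = rng.uniform(size=spec.n)
        lon = np.empty(spec.n)
        lat = np.empty(spec.n)
        # partition points into: attracted to a source category, clustered
        # around a city center, or uniform background
        thresholds = []
        acc = 0.0
        for a, theta in attraction_by_target.get(spec.name, []):
            acc += theta
            thresholds.append((a, acc))
        assigned = np.zeros(spec.n, dtype=bool)
        prev = 0.0
        for a, hi in thresholds:
            pick = (~assigned) & (u >= prev) & (u < hi)
            prev = hi
            if pick.any():
                src_lon, src_lat = _anchor_pool(a)
                if src_lon.size == 0:
                    raise ValueError(f"no placed {a!r} points to attract {spec.name!r}")
                j = rng.integers(src_lon.size, size=int(pick.sum()))
                lon[pick], lat[pick] = _offset(
                    rng, src_lon[j], src_lat[j], spec.sigma_km, displacement
                )
            assigned |= pick
        clustered = (~assigned) & (u < prev + spec.cluster_fraction)
        if clustered.any():
            j = rng.integers(config.n_centers, size=int(clustered.sum()))
            lon[clustered], lat[clustered] = _offset(
                rng, centers_lon[j], centers_lat[j], spec.sigma_km, displacement
            )
        assigned |= clustered
        uniform = ~assigned
        lon[uniform] = rng.uniform(lo_lon, hi_lon, size=int(uniform.sum()))
        lat[uniform] = rng.uniform(lo_lat, hi_lat, size=int(uniform.sum()))

        placed_lon.append(lon)
        placed_lat.append(lat)
        placed_lab.append(np.full(spec.n, spec.name, dtype=object))

    lon = np.clip(np.concatenate(placed_lon), lo_lon, hi_lon)
    lat = np.clip(np.concatenate(placed_lat), lo_lat, hi_lat)
    labels = np.concatenate(placed_lab).astype(str)
    return LabeledPointSet(lon, lat, labels)


#: CMS-like provider mix at roughly 1/20 scale: relative category
#: frequencies follow the national provider censuses, with urban clustering
#: and planted attraction of the hospital-adjacent post-acute categories
#: (inpatient rehabilitation, long-term care hospitals) toward acute care.
_CMS_LIKE_MIX = (
    # (name, n, cluster_fraction, sigma_km)
    ("acute_care", 160, 0.7, 6.0),
    ("crit_care", 67, 0.1, 10.0),
    ("hh_care", 557, 0.6, 10.0),
    ("hospice", 241, 0.5, 10.0),
    ("IRF", 58, 0.2, 3.0),
    ("LTCH", 19, 0.2, 3.0),
    ("NH", 769, 0.5, 10.0),
)


def cms_like_config(seed: int = 0, scale: float = 1.0) -> SyntheticConfig:
    """A ready-made config emulating the national facility pattern.

    Category counts follow the relative abundance of the CMS provider
    types at about one-twentieth of the national census (``scale``
    rescales them); acute care hospitals are strongly urban-clustered,
    critical access hospitals mostly dispersed, and IRF/LTCH points are
    planted near acute care hospitals.
    """
    return SyntheticConfig(
        categories=tuple(
            CategorySpec(name, max(2, int(round(n * scale))),
                         cluster_fraction=phi, sigma_km=sig)
            for name, n, phi, sig in _CMS_LIKE_MIX
        ),
        cross_attraction={("acute_care", "IRF"): 0.7,
                          ("acute_care", "LTCH"): 0.6},
        lon_range=(-104.0, -90.0),
        lat_range=(37.0, 45.0),
        n_centers=12,
        seed=seed,
    )


def relabel_csr(data: LabeledPointSet, seed=None) -> LabeledPointSet:
    """Random-labeling draw: locations fixed, labels uniformly permuted."""
    return permute_labels(data, seed)


def write_pattern(
    data: LabeledPointSet,
    path,
    state: str | None = None,
    dialect: DialectConfig | None = None,
) -> FacilityTable:
    """Write a pattern as an S1-dialect facility table (optional state code)."""
    import pandas as pd

    df = pd.DataFrame(
        {"category": data.labels, "lon": data.lon, "lat": data.lat}
    )
    if state is not None:
        df["state"] = state
    table = FacilityTable(df, provenance={"source": "synthetic"})
    write_facilities(table, path, dialect)
    return table
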