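"""Orchestration of the facility colocation analyses.

Three analyses over a facility table:

* ``run_global_grid`` — the nationwide grid: global CLQ of every post-acute
  category toward acute care hospitals, critical access hospitals, and its
  own category, across a set of adaptive bandwidths (default k = 1, 4, 17
  with k = 4 as the reference), with Monte Carlo random-labeling p-values.
* ``run_state_local`` — per-facility Gaussian-kernel local CLQs within one
  state (adaptive rank n = 10 by default) toward a target hospital
  category, summarized as shares of the four descriptive classes.
* ``run_coverage`` — the fraction of each hospital category with at least
  one other hospital within a 10-mile radius, plus the mean neighbor count
  for acute care hospitals.

Every run is deterministic for a fixed input, configuration and seed, and
writes a manifest (configuration, seed, input checksum) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import facility_io
from .core import (
    HOSPITAL_CATEGORIES,
    POST_ACUTE_CATEGORIES,
    SAME,
    DESCRIPTIVE_CLASSES,
    LabeledPointSet,
    LocalCLQEngine,
    classify_clq,
    global_clq,
)
from .facility_io import FacilityTable, filter_contiguous, filter_state, to_geojson
from .geometry import KM_PER_MILE, build_neighbors, neighbor_count_within, radius_coverage
from .significance import PermutationPlan, mc_pvalue_global

logger = logging.getLogger(__name__)

#: Target hospital category per example state in the state-level analyses.
STATE_TARGETS = {"MA": "acute_care", "IA": "crit_care"}


@dataclass
class AnalysisConfig:
    """Shared knobs of the analysis pipelines."""

    k_values: tuple[int, ...] = (1, 4, 17)
    main_k: int = 4
    local_n: int = 10
    n_permutations: int = 999
    seed: int = 0
    radius_miles: float = 10.0
    contiguous: bool = True
    coverage_reference: str = "hospitals"  # or "all"

    def __post_init__(self):
        if any(k < 1 for k in self.k_values):
            raise ValueError("k values must be positive")
        if self.main_k not in self.k_values:
            raise ValueError("main_k must be among k_values")


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: AnalysisConfig, extra: dict) -> None:
    manifest = {"config": asdict(config), **extra}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _prepare(table: FacilityTable, config: AnalysisConfig) -> LabeledPointSet:
    if config.contiguous:
        table = filter_contiguous(table)
    return table.to_labeled_point_set()


def run_global_grid(
    table: FacilityTable,
    config: AnalysisConfig | None = None,
    *,
    out_dir=None,
    with_pvalues: bool = True,
) -> pd.DataFrame:
    """The Table-2-shaped grid of global CLQs.

    One row per (post-acute category) × (acute_care | crit_care | same type)
    × k, with the CLQ value, its descriptive class, and (optionally) the
    Monte Carlo two-sided p-value.  Categories absent from the data are
    reported as unavailable rows; the run continues.
    """
    config = config or AnalysisConfig()
    data = _prepare(table, config)
    logger.info("global grid over %d facilities; census %s", data.n, data.census())

    rows = []
    for k in config.k_values:
        nbrs = build_neighbors(data.lon, data.lat, k)
        for a_cat in POST_ACUTE_CATEGORIES:
            for to_spec in (*HOSPITAL_CATEGORIES, SAME):
                b_cat = a_cat if to_spec == SAME else to_spec
                row = {
                    "from": a_cat,
                    "to": to_spec.lower() if to_spec == SAME else b_cat,
                    "k": k,
                    "kernel": "box",
                }
                try:
                    est = global_clq(data, nbrs, a_cat, b_cat)
                except ValueError as exc:
                    logger.warning("row unavailable: %s", exc)
                    row.update(
                        value=np.nan, descriptive_class="", p_value=np.nan,
                        status="unavailable",
                    )
                    rows.append(row)
                    continue
                p = np.nan
                if with_pvalues:
                    plan = PermutationPlan(
                        n_permutations=config.n_permutations,
                        seed=_pair_seed(config.seed, k, a_cat, b_cat),
                    )
                    p = mc_pvalue_global(data, nbrs, a_cat, b_cat, plan).p_value
                row.update(
                    value=est.value,
                    descriptive_class=est.descriptive_class,
                    p_value=p,
                    status="ok",
                )
                rows.append(row)
    report = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "global_clq.csv", index=False, float_format="%.6f")
        _write_table2_json(report, out_dir / "global_clq.json")
        _write_manifest(
            out_dir, config,
            {"analysis": "global-grid", "n_facilities": data.n,
             "census": data.census(), "provenance": table.provenance},
        )
    return report


def _pair_seed(seed: int, k: int, a_cat: str, b_cat: str) -> int:
    key = f"{seed}:{k}:{a_cat}:{b_cat}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _write_table2_json(report: pd.DataFrame, path: Path) -> None:
    """Structured output mirroring the provider × target × k grid."""
    grid: dict = {}
    for _, r in report.iterrows():
        grid.setdefault(r["from"], {}).setdefault(r["to"], {})[f"k={r['k']}"] = (
            None if r["status"] != "ok" else {
                "clq": round(float(r["value"]), 6),
                "class": r["descriptive_class"],
                "p_value": None if pd.isna(r["p_value"]) else float(r["p_value"]),
            }
        )
    Path(path).write_text(json.dumps(grid, indent=2, sort_keys=True) + "\n")


def run_state_local(
    table: FacilityTable,
    state: str,
    config: AnalysisConfig | None = None,
    *,
    target: str | None = None,
    polygon=None,
    out_dir=None,
) -> dict:
    """Local CLQ classification shares for one state.

    Computes the Gaussian-kernel local CLQ of every post-acute facility in
    the state toward the target hospital category (acute care for MA,
    critical access for IA, by default), using adaptive bandwidths of rank
    ``local_n`` built within the state subset, and reports the share of
    facilities in each of the four descriptive classes.
    """
    config = config or AnalysisConfig()
    target = target or STATE_TARGETS.get(state.upper(), "acute_care")
    sub = filter_state(table, state=state if polygon is None else None,
                       polygon=polygon)
    if len(sub) == 0:
        raise ValueError(f"no records for state {state!r}")
    data = sub.to_labeled_point_set()
    if data.n < config.local_n + 1:
        raise ValueError(
            f"state {state!r} has {data.n} facilities; need at least "
            f"{config.local_n + 1} for adaptive rank n={config.local_n}"
        )
    if data.count(target) == 0:
        raise ValueError(f"target category {target!r} absent in state {state!r}")

    engine = LocalCLQEngine(data, config.local_n)
    focal = np.flatnonzero(np.isin(data.labels, POST_ACUTE_CATEGORIES))
    est = engine.local_clq_many(focal, target)

    per_facility = pd.DataFrame(
        {
            "index": [e.index for e in est],
            "category": data.labels[focal],
            "lon": data.lon[focal],
            "lat": data.lat[focal],
            "to": target,
            "local_clq": [e.value for e in est],
            "bandwidth_km": [e.bandwidth_km for e in est],
            "descriptive_class": [e.descriptive_class for e in est],
        }
    )
    counts = per_facility["descriptive_class"].value_counts()
    n_focal = len(per_facility)
    shares = _rounded_shares(
        {cls: int(counts.get(cls, 0)) for cls in DESCRIPTIVE_CLASSES}, n_focal
    )
    result = {
        "state": state.upper(),
        "target": target,
        "n_local": config.local_n,
        "kernel": "gaussian",
        "n_post_acute": n_focal,
        "n_facilities_state": data.n,
        "class_shares_pct": shares,
        "weak_to_moderate_pct": round(
            shares["weak-to-moderate segregation"]
            + shares["weak-to-moderate clustering"], 1
        ),
        "segregation_pct": round(
            shares["moderate-to-strong segregation"]
            + shares["weak-to-moderate segregation"], 1
        ),
        "clustering_pct": round(
            shares["weak-to-moderate clustering"]
            + shares["moderate-to-strong clustering"], 1
        ),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_facility.to_csv(
            out_dir / f"local_clq_{state.upper()}.csv", index=False,
            float_format="%.6f",
        )
        focal_table = FacilityTable(
            sub.df.iloc[focal][["category", "lon", "lat"]].reset_index(drop=True)
        )
        gj = to_geojson(
            focal_table,
            per_facility[["local_clq", "bandwidth_km", "descriptive_class"]],
        )
        (out_dir / f"local_clq_{state.upper()}.geojson").write_text(
            json.dumps(gj) + "\n"
        )
        (out_dir / f"local_shares_{state.upper()}.json").write_text(
            json.dumps(result, indent=2, sort_keys=True) + "\n"
        )
        _write_manifest(
            out_dir, config,
            {"analysis": "state-local", "state": state.upper(), "target": target,
             "provenance": sub.provenance},
        )
    return result


def _rounded_shares(counts: dict[str, int], total: int) -> dict[str, float]:
    """Percentages to one decimal via largest-remainder, summing to 100.0."""
    raw = {k: 1000.0 * v / total for k, v in counts.items()}
    floors = {k: int(np.floor(r)) for k, r in raw.items()}
    short = 1000 - sum(floors.values())
    order = sorted(raw, key=lambda k: (raw[k] - floors[k], counts[k]), reverse=True)
    for k in order[:short]:
        floors[k] += 1
    return {k: floors[k] / 10.0 for k in counts}


def run_coverage(
    table: FacilityTable,
    config: AnalysisConfig | None = None,
    *,
    out_dir=None,
) -> dict:
    """Hospital coverage within the radius (default 10 miles).

    For each hospital category: the fraction of its facilities with at
    least one other hospital within the radius, and the complementary
    isolated fraction.  The reference set is all hospitals
    (``coverage_reference="hospitals"``) or every facility (``"all"``).
    Also reports the mean within-radius neighbor count for acute care
    hospitals.
    """
    config = config or AnalysisConfig()
    data = _prepare(table, config)
    radius_km = config.radius_miles * KM_PER_MILE

    if config.coverage_reference == "hospitals":
        ref_mask = np.isin(data.labels, HOSPITAL_CATEGORIES)
    else:
        ref_mask = np.ones(data.n, dtype=bool)
    ref_lon, ref_lat = data.lon[ref_mask], data.lat[ref_mask]

    result = {
        "radius_miles": config.radius_miles,
        "reference": config.coverage_reference,
        "categories": {},
    }
    for cat in HOSPITAL_CATEGORIES:
        m = data.labels == cat
        if not m.any():
            result["categories"][cat] = None
            continue
        frac = radius_coverage(
            data.lon[m], data.lat[m], ref_lon, ref_lat, radius_km
        )
        entry = {
            "n": int(m.sum()),
            "covered_fraction": round(frac, 4),
            "isolated_fraction": round(1.0 - frac, 4),
        }
        if cat == "acute_care":
            counts = neighbor_count_within(
                data.lon[m], data.lat[m], ref_lon, ref_lat, radius_km
            )
            entry["mean_neighbors_within_radius"] = round(float(counts.mean()), 2)
        result["categories"][cat] = entry

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "coverage.json").write_text(
            json.dumps(result, indent=2, sort_keys=True) + "\n"
        )
        _write_manifest(
            out_dir, config,
            {"analysis": "coverage", "n_facilities": data.n,
             "provenance": table.provenance},
        )
    return result
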