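# cloq

Colocation-quotient analysis of categorical geographic point patterns,
built around the spatial association between **post-acute care services**
(home health care, nursing homes, inpatient rehabilitation facilities,
long-term care hospitals, hospice) and **hospitals** (acute care and rural
critical access) in the United States.

Given a table of facility locations with one provider category per row,
`cloq` answers: are facilities of category A spatially attracted to, or
segregated from, facilities of category B — overall, and facility by
facility?

## The statistic

For a marked point pattern with N points, N_B of category B, the global
**colocation quotient** of A toward B is

```
CLQ_A→B = [ (1/N_A) Σ_{a∈A} n_aB / k ] / [ N_B′ / (N − 1) ]
```

where `n_aB` is the number of category-B points among the k nearest
neighbors of point `a` (neighbors ranked by great-circle distance;
equidistant ties share the remaining inclusion slots fractionally), and
`N_B′ = N_B − 1` when A = B so that a point is never its own neighbor.
CLQ > 1 means attraction (clustering), CLQ < 1 segregation, and 1 no
spatial dependence.  The quotient is asymmetric: CLQ_A→B ≠ CLQ_B→A in
general.

The **local** variant replaces the flat box weighting with a Gaussian
kernel `w_ij = exp(−½ (d_ij / b_i)²)` whose bandwidth `b_i` is the focal
point's adaptive k-th nearest-neighbor distance, yielding one quotient per
facility.  Values are summarized in four descriptive bands: < 0.50
(moderate-to-strong segregation), 0.50–1.00 (weak-to-moderate
segregation), 1.01–1.50 (weak-to-moderate clustering), > 1.50
(moderate-to-strong clustering).

Significance comes from **Monte Carlo random labeling**: locations stay
fixed, category labels are permuted (M = 999 by default), and the
two-sided p-value uses the add-one permutation estimator.

All distances are arc (great-circle) kilometers on a sphere of radius
6371.0088 km, since coordinates are unprojected longitude/latitude.

## Worked example

```python
import numpy as np
from cloq import LabeledPointSet, build_neighbors, global_clq

# five facilities on the equator: A at 0°, 2.1°, 10°; B at 1°, 3°
data = LabeledPointSet(
    lon=np.array([0.0, 1.0, 2.1, 3.0, 10.0]),
    lat=np.zeros(5),
    labels=np.array(["A", "B", "A", "B", "A"]),
)
nbrs = build_neighbors(data.lon, data.lat, k=1)
est = global_clq(data, nbrs, "A", "B")
print(est.value, est.descriptive_class)
```

prints

```
2.0 moderate-to-strong clustering
```

Every A point's nearest neighbor is a B, so the observed B share among
A-neighbors is 1.0 against an expected share of 2/4 — a colocation
quotient of 2.0.

## Analysis pipeline

The numbered scripts under `analysis/` run the full study on a synthetic
CMS-like pattern (or on the real table if `data/s1_facilities.txt` is
present):

```
python analysis/01_simulate.py      # generate the benchmark facility table
python analysis/02_global_grid.py   # global CLQ grid, k = 1 / 4 / 17, MC p-values
python analysis/03_state_local.py   # per-facility local CLQs and class shares
python analysis/04_coverage.py      # 10-mile hospital coverage check
python analysis/05_calibration.py   # test size under CSR; theta recovery
```

Outputs land in `results/` (CSV, JSON, GeoJSON).  The same operations are
available as a CLI (`cloq global-grid`, `cloq state-local`,
`cloq coverage`, `cloq simulate`; see `cloq --help`).

Running step 02 on the synthetic benchmark prints, among others:

```
   IRF -> acute_care CLQ  2.52  moderate-to-strong clustering *
  LTCH -> acute_care CLQ  2.77  moderate-to-strong clustering *
  LTCH -> crit_care  CLQ  0.37  moderate-to-strong segregation
```

— the planted structure (inpatient rehabilitation and long-term care
hospitals seeded next to acute care hospitals, far from dispersed rural
critical access hospitals) recovered and flagged significant.

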