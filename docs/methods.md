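# Methods

## The model

`cloq` treats a facility directory as a *marked point pattern*: N point
locations on the sphere, each carrying one categorical mark (provider
type).  The scientific question is directional spatial association
between marks — does category A aggregate around category B? — which the
colocation quotient (CLQ) answers through nearest-neighbor composition
rather than distances, making it robust to the strongly uneven density of
facilities (dense metropolitan cores, sparse rural plains).

### Global CLQ

With `n_aB` the count of B points among the k nearest neighbors of an A
point `a`,

    CLQ_A→B = [ (1/N_A) Σ_a n_aB / k ] / [ N_B′ / (N − 1) ].

The denominator is the expected B share among any point's neighbors under
random labeling, with `N_B′ = N_B − 1` when A = B: a point cannot be its
own neighbor, and this correction makes CLQ_A→A equal exactly 1 for a
single-category population at any k (verified exactly in the tests).
The quotient is bounded by `0 ≤ CLQ_A→B ≤ (N−1)/N_B′` and satisfies the
allocation identity `Σ_B CLQ_A→B · N_B′/(N−1) = 1`, because each focal
point's k neighbor slots are fully distributed across categories — a
strong internal consistency check, asserted to 1e−9.

Neighbors are drawn from the **full** multi-category population, not just
the two categories under comparison: the reference universe is the whole
facility system, and restricting it would change the null.  (A restricted
two-category population can be had by subsetting the input table.)

### Ranks, ties, bandwidths

The adaptive bandwidth is a *distance rank*: the neighborhood of a point
is its k nearest other points, however far away they are.  Rank k = 4 is
the reference for the national analysis (chosen to mirror the average of
~4 hospital neighbors within the 10-mile radius that covers most of the
population), with k = 1 (most conservative) and k = 17 (≈ cube root of
the hospital count, the near-equal-coverage rule of thumb) as sensitivity
brackets.

Ties at the k-th distance share the remaining inclusion slots equally as
fractional weights, so every point's weights sum to exactly k and the
result is invariant to input ordering.  Duplicate coordinates (distinct
certifications at one address are common in CMS data) are kept as
distinct points at distance zero; only the self-pair is excluded.  If
duplicates persist through rank k the bandwidth is zero, which is flagged
and, for Gaussian kernels, replaced by the smallest positive neighbor
distance.

### Local CLQ

The geographically weighted local quotient of focal point `i` toward B is

    LCLQ_i→B = [ Σ_{j≠i} w_ij 1(m_j = B) / Σ_{j≠i} w_ij ] / [ N_B′ / (N − 1) ],
    w_ij = exp(−½ (d_ij / b_i)²),

with `b_i` the adaptive rank-k distance of the focal point.  Weights below
1e−9 are truncated (beyond ≈ 6.4 bandwidths), which bounds the
neighborhood query without affecting the quotient at reporting precision.
State-level analyses use rank n = 10 within the state subset (states are
analyzed in isolation), classify each post-acute facility's quotient
toward the state's hospital target (acute care in Massachusetts, critical
access in Iowa), and report class shares rounded to one decimal by
largest remainder so they always sum to 100.0%.

### Descriptive classes

CLQ values map to four bands: [0, 0.50) moderate-to-strong segregation,
[0.50, 1.00] weak-to-moderate segregation, (1.00, 1.50] weak-to-moderate
clustering, (1.50, ∞) moderate-to-strong clustering.  The printed class
limits leave (1.00, 1.01) unassigned for continuous values; the boundary
1.00 is assigned to the segregation side here, and 1.005 would fall in
the clustering band.

### Significance

The null is *random labeling conditional on locations*: the label vector
is uniformly permuted, geometry fixed.  Because the neighbor structure
never changes, each permutation costs one sparse recount, so M = 999
permutations (default; M = 199 in the bulk studies) are cheap even at
national scale.  p-values use the add-one estimator
`p_tail = (1 + #{sim beyond obs}) / (M + 1)` doubled and capped at 1 for
two-sidedness.  The permuted labels are drawn from the *sorted* label
multiset, which makes p-values byte-reproducible under reordering of the
input rows.  The count statistic is discrete, so ties between simulated
and observed values occur and the test is mildly conservative (measured
size ≈ 0.046 at α = 0.05; see calibration below).  Local p-values carry
no multiple-testing adjustment — local classes are descriptive — and the
reports say so.

## Geometry

Distances are great-circle kilometers by the haversine formula (stable at
small separations) on the IUGG mean sphere, R = 6371.0088 km; the test
suite pins this against an independent geodesic implementation
(R `geosphere::distHaversine`) to 1e−6 km.  One mile = 1.609344 km
wherever the 10-mile coverage radius appears.  Nearest-neighbor queries go
through a BallTree with the haversine metric; candidate distances are then
recomputed with the package's own formula so that tie detection and the
exhaustive-search test oracle agree bit for bit, and the candidate list is
expanded until the rank-k tie group is provably complete.

## Input handling

The reader accepts comma- or tab-delimited text with columns `type`,
`g_lon`, `g_lat` (configurable), drops rows with invalid coordinates or
unknown category codes (counted in provenance, logged), and keeps
duplicates.  The contiguous-US filter uses the state column when one
exists and otherwise a bounding box (lon −125…−66, lat 24.5…49.5);
state selection uses the state column or a caller-supplied polygon
(shapely), since the published facility table carries no state codes.
Coordinates are taken as-is; no geocoding.

## Synthetic generator

The generator emulates the urban concentration of the facility system: a
few "city" centers uniform in a lon/lat rectangle; each category-c point
is, with probability φ_c, displaced from a random center by an isotropic
Gaussian of scale σ_c km (uniform-disc option for boundary sensitivity),
otherwise uniform over the region.  Cross-attraction θ_{A→B} plants that
fraction of B points next to already-placed A points — a direct, tunable
colocation signal.  Kilometer offsets convert to degrees via 111.32 km/deg
(with cos(lat) for longitude), adequate at regional scale; points are
clipped to the region.  With φ = θ = 0 the pattern is completely spatially
random with random labels, the null of the significance test.

The ready-made `cms_like_config` mix scales the national provider censuses
by ~1/20 (e.g. 769 nursing homes, 160 acute care, 67 critical access, 19
long-term care hospitals) over a ~1200 × 900 km region with 12 centers,
strong urban clustering of acute care, dispersed critical access
hospitals, and planted IRF/LTCH attraction toward acute care — enough
structure for every analysis to produce interpretable output at seconds of
runtime.

What the generator does **not** emulate: population-density covariates,
coastlines and state borders, road networks, and the empirical spacing
distribution of real facilities.  Green tests therefore demonstrate
correctness of the statistics and calibration of the test, not agreement
with any published national estimate; that agreement is checked separately
when the real facility table is supplied (see `data/README.md`).

## Calibration

Two standing studies (`cloq.calibration`, exercised by the test suite and
`analysis/05_calibration.py`):

* **Size**: 500 CSR patterns (n = 300, two categories 150/150, k = 4,
  M = 199) give a rejection rate of ≈ 0.046 at α = 0.05 and a KS distance
  from uniformity of ≈ 0.05 — the mild conservatism expected from ties in
  a discrete permutation statistic.
* **Power/recovery**: sweeping θ ∈ {0, 0.2, …, 0.8} (N = 400, 20
  replicates per θ) and ranking the attracted pair's global CLQ gives
  Spearman ρ typically 0.90–0.95.  The sweep uses rank k = 1 and a 1-km
  planting scale: attraction is planted pairwise at sub-kilometer
  (co-located facility) scale, so the first-ranked neighbor carries the
  signal undiluted, whereas larger k mixes in background points and blurs
  the ranking.

## Numerical and design choices

* Earth radius fixed at the IUGG mean (6371.0088 km) for reproducibility.
* Exact floating-point equality defines distance ties; only genuinely
  identical coordinates tie in practice, and both the implementation and
  the test oracle evaluate distances through the same vectorized kernels.
* `k ≥ N` is clamped to N − 1 with a warning; a single point is an error.
* Monte Carlo seeds for the grid derive per (k, A, B) pair from the run
  seed by hashing, so adding or removing grid rows never shifts another
  row's p-value.
* Analysis problem sizes (≈ 1 900 synthetic facilities nationally, 500
  calibration replicates) were chosen so a full reproduction runs in well
  under a minute on one core while keeping Monte Carlo noise far below the
  effects of interest.

## Known limitations

* CLQ values at third-decimal precision depend on the distance constant
  and tie policy, which published analyses rarely state; cross-software
  agreement is expected to ~0.01–0.05, not to machine precision.
* The two-sided doubled p-value is conservative for discrete statistics;
  one-sided tail probabilities are returned alongside for users who need
  them.
* Local quotients at small bandwidth ranks are noisy; the state pipeline
  refuses subsets with fewer than n + 1 facilities, and national-scale
  local maps are out of scope.
* State analyses need either a state column or a boundary polygon; no
  boundary data ships with the package.
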