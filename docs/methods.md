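# Methods

This note documents, in the package's own terms, the algorithms implemented
in `trajscale`, the parameter defaults and their units, the behaviour of the
synthetic generators, and the numerical conventions that matter for
reproducing results exactly.

## 1. Data model and geometry

Input trajectories are per-individual time series of GPS fixes
(longitude/latitude in decimal degrees, UTC timestamps). `read_fixes`
normalises arbitrary CSV dialects via a column map (Movebank naming is the
default), coerces timestamps to timezone-aware UTC, drops rows with
unparseable timestamps or coordinates outside [-180, 180] × [-90, 90], sorts
stably by (individual, time), and removes duplicate timestamps (first kept).
A `ReadReport` records every drop.

All distances are great-circle (haversine) distances on a sphere of radius
6 371 008.8 m (the IUGG mean Earth radius). At the sub-kilometre scales of
stop detection and clustering, the difference from ellipsoidal geodesics is
far below GPS noise.

## 2. Stop detection

Parameters: spatial threshold **δ = 150 m**, dwell threshold **τ = 18 min**
(both strictly positive; these defaults match the gull analysis).

The detector is a single forward scan. The first unassigned fix becomes the
*anchor* of a candidate stop. Subsequent fixes are assigned to the candidate
while their distance to the anchor is **strictly less than δ**; the first fix
at distance ≥ δ breaks the candidate. The candidate's dwell time is the span
from the anchor to the last assigned fix, and the candidate is emitted as a
stop iff dwell **> τ** (strict). Scanning restarts at the breaking fix
whether or not the candidate was emitted; a trailing candidate at the end of
the trajectory is emitted under the same dwell rule. A stop's location is the
unweighted mean of its member coordinates.

Consequences worth knowing:

- Candidate segmentation depends only on δ, so for fixed δ the number of
  stops is non-increasing in τ (`sensitivity_sweep` exposes the δ × τ grid).
- Stops are disjoint, time-ordered, and contain ≥ 2 fixes (a 1-fix candidate
  has zero dwell).
- Because the anchor is the *first* point of the candidate, a fix that lands
  near the edge of a true stay (e.g. the last fix of an inbound transit) can
  seed an off-centre anchor, occasionally splitting one physical stay into
  two contiguous detected stops. The downstream clustering step re-merges
  these into one stay region, so region-level results are unaffected.

`match_planted_stops` scores detected against ground-truth stops: a pair
matches when the centroids are within δ **and** the time intervals overlap;
precision and recall over the match sets are returned (empty sets count as
perfect by convention).

## 3. Stay regions

Parameters: clustering radius **ϵ = 400 m** for the gull data (200 m for the
denser human comparison data), minimum region size **min_stops = 2**.

Stop centroids are clustered per individual with DBSCAN
(`min_samples = 2`, haversine metric, ϵ expressed in radians on the
6 371 008.8 m sphere). With `min_samples = 2` DBSCAN is exactly the
connected components of the ϵ-ball graph — two stops are linked when they lie
within ϵ — which is the property the test suite verifies against an
independent BFS oracle. Components smaller than `min_stops` are discarded as
noise unless `keep_singletons` is set. A complete-linkage alternative
(`linkage="complete"`, scipy hierarchical clustering cut at ϵ) is provided
for the stricter reading in which *all* pairwise distances within a region
must be below ϵ.

Region identifiers are dense integers assigned in order of first visit.
Each surviving stop becomes one `Visit(region_id, t_start, t_end)`;
`region_count_by_month` reports distinct regions per individual-month.

## 4. Temporal aggregation

Two symbolisation schemes turn visits into sequences:

- **NTB (network time bins)**, default bin width **1 hour**, anchored at the
  top of the UTC hour containing the first visit. Each bin's symbol is the
  region with the largest dwell overlap in that bin; ties go first to the
  region with more visits in the whole sequence, then to the smaller region
  id. Bins with no overlap get the gap symbol **−1**. Self-transitions are
  kept (the same region may fill consecutive bins).
- **NP (next place)**: the regions in visit order with consecutive
  duplicates collapsed, so the sequence has no self-transitions and no gaps.

Gap symbols advance time in growth curves but never count as locations, and
are excluded from rank-frequency statistics.

## 5. Mobility metrics

- **Visitation frequency**: region visit shares sorted into a rank curve
  (ties broken by region id); Zipf exponent ζ from `f_r ~ r^-ζ`.
- **Distinct-location growth**: `S(t)` = number of distinct regions seen in
  the first *t* symbols; growth exponent μ from `S(t) ~ t^μ`.
- **Radius of gyration**: the (optionally weighted) root-mean-square
  great-circle distance of a point set from its weighted mean-coordinate
  centroid, in metres. For symbolic sequences the weights are symbol
  occurrence counts.
- **Exponent fitting**: ordinary least squares of log₁₀ y on log₁₀ x
  (`scipy.stats.linregress`) over the positive finite points, requiring ≥ 3
  points. The reported exponent is the absolute slope (ζ and μ are both
  quoted positive); the signed slope, intercept, and R² are retained. A
  constant curve fits exponent 0 exactly.
- **Population curves**: per-individual curves are aligned at x = 1, padded
  with NaN to the longest, and averaged pointwise; monthly ζ and μ are fitted
  on these population-averaged curves, not on individual fits.

## 6. Group statistics

Per individual-month observables: top-rank frequency `f_1` (for the f_r
family), monthly radius of gyration, and the terminal distinct-location count
(for the S(t) family), each under both NTB and NP. Three groupings are
compared — breeding (months **April–June**) vs non-breeding, male vs female,
and study vs comparison population — with the two-sample Kolmogorov–Smirnov
test and the Kruskal–Wallis test. Cells with fewer than 2 values on either
side are marked untestable. Significance marks: ✓ for p < 0.05, * for
p < 0.1, — otherwise. Degenerate Kruskal–Wallis inputs (all values tied)
are reported as p = 1.

## 7. EPR model and synthetic data

**EPR walker** (`simulate_epr`): parameters ρ ∈ (0, 1] (default **0.6**) and
γ ≥ 0 (default **0.6**). The first step always explores. Afterwards a step
explores a new location with probability min(1, ρ·S^−γ) where S is the
current number of known locations, otherwise returns to a previously visited
location chosen proportionally to visit counts, **excluding the current
location** so the emitted sequence has no self-transitions. When S = 1 and
the walker does not explore, it must re-visit its only location; such forced
self-visits are counted in the truth bookkeeping but collapse out of the
emitted sequence. The model predicts μ = 1/(1+γ); at γ = 1, ρ = 0.6 and 10⁵
steps the fitted μ lies within 0.05 of 0.5.

**Raw-GPS generator** (`simulate_raw_gps`): renders an itinerary of `Stay`
and `Transit` episodes as fixes sampled at a nominal **2-minute** interval
with uniform ±30 % jitter, plus isotropic Gaussian position noise
(default σ = **20 m**) applied in the local tangent plane. Stays emit noisy
fixes at the stay location and are returned as planted ground-truth stops;
transits interpolate along the great-circle chord at the given speed.
`make_planted_itinerary` builds a random-walk itinerary of well-separated
stays (≥ 1 km apart, dwell 30–90 min by default); `make_epr_itinerary`
renders an EPR visit sequence spatially so that the whole pipeline can be
validated closed-loop.

**Study population** (`make_study_population`): a gull-like cohort (default
**11 individuals, 4 female / 7 male**, months January–November of one year).
Breeding months (April–June) use a confined regime (γ = 1.5, 5 km home
radius); other months a roaming regime (γ = 0.6, 15 km). `make_archetypes`
produces two deterministic symbolic profiles — a "stationary" individual with
a steep Zipf profile (ζ = 3, f₁ ≈ 0.84) and a "roamer" (ζ = 0.8 over 30
locations) — used to check that fitted ζ orders individuals correctly.

These generators emulate sampling irregularity, GPS noise, stay/transit
structure, and seasonal regime shifts. They do **not** emulate missing-data
bursts, altitude, device-specific error distributions, tides or diel
rhythms, or central-place trip structure beyond what the EPR itinerary
induces.

## 8. Pipeline, determinism, and problem sizes

`run_pipeline` (YAML-configurable, also `trajscale run`) splits each
individual's track by calendar month and runs stages read → stops → regions
→ sequences → metrics → exponents → significance, writing CSV tables, a
markdown significance grid, and a JSON run log; failures are tagged with the
stage name. All randomness flows from explicit seeds and outputs are written
with fixed float formatting, so identical config + seed gives byte-identical
files.

The problem sizes used in the test suite and the acceptance script (1000
random trajectories for the stop-detector oracle, 500 instances for the
clustering oracle, 20 planted stays, 10⁵ EPR steps, an 11-bird × 11-month
population) are this package's own verification choices, sized to finish in
seconds to tens of seconds on one CPU while leaving negligible Monte-Carlo
slack around the tested tolerances.

## 9. Limitations

- OLS on log-log curves is a pragmatic exponent estimator, not a rigorous
  power-law fit (no MLE, no cutoff selection); exponents from short monthly
  curves (tens of points) carry substantial uncertainty.
- The spherical-distance approximation and tangent-plane noise model are
  adequate at study scales (< 100 km) but not for global-scale data.
- Stop detection is threshold-based and sensitive to fix rate; very sparse
  sampling (interval approaching τ) degrades recall.
- Significance tests treat individual-months as independent samples,
  ignoring repeated measures on the same individual.
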