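# Methods

## Accessibility model

The package measures potential spatial accessibility: how much provider
capacity a town's population could reach, discounted by travel effort and
by competition from other towns. Demand is located at population-weighted
town centroids; supply is provider head count at facility sites; travel
effort is a precomputed route-distance matrix in km. Coordinates are planar
(projected, km) and are never used to derive distances — the scoring
consumes route distances as given, so any travel-cost model (road network,
travel time) can be substituted upstream. A missing distance pair means
unreachable, so sparse matrices are valid input.

**Distance decay.** Utilization propensity falls with distance in three
travel bands: weight 1 within 3 km (reachable on foot), 3/d from 3 to
15 km (a short drive), 15/d² from 15 to 30 km (a long drive), and 0 beyond
30 km. Bands are closed on the right — d = 15 km takes the 3/d branch
(0.2), d = 15 + ε the 15/d² branch (≈0.067) — so the kernel is continuous
at the first edge and drops discontinuously at the second and third. The
edges are configurable (`DecayParams`); for edges (e₁,…,e_h) band r ≥ 2
uses e_{r−1}/d^{r−1}, which keeps the first transition continuous and
reproduces the default kernel exactly.

**Two-step FCA (A1).** Step 1 assigns each facility j a
supply-to-demand ratio R_j = S_j / Σ_k P_k f(d_kj) over the demand points
within its 30-km catchment; step 2 accumulates A_i = c · Σ_j R_j f(d_ij)
over the facilities within the demand point's catchment, with c = 10,000
by default (scores are providers per 10,000 persons; the scale is
configurable).

**Three-step FCA (A2–A4).** Plain 2SFCA overstates demand: every town
loads every reachable facility in full. The three-step variants first
split each town's demand across the competing facilities in its catchment
with a choice probability

  w_ij = m_j f(d_ij) / Σ_{k ∈ catchment(i)} m_k f(d_ik),

where the facility mass m_j is capacity S_j (A2), the public 1–5 rating
V_j (A3), or the product V_j·S_j (A4) — the last reflecting that patients
weigh both a facility's size and its online reputation. The weights are
applied symmetrically: they deflate the demand each facility sees in
step 1 (load_j = Σ_k w_kj P_k f(d_kj)) and scale the ratios accumulated in
step 2 (A_i = c · Σ_j w_ij R_j f(d_ij)). Symmetric application yields an
exact conservation law — Σ_i P_i A_i / c equals the total capacity of
facilities with nonzero weighted demand — which the test suite checks to
1e-6 relative error on 100 random landscapes (observed: ~1e-16).

The choice probability is normalized once over the whole 30-km catchment
rather than per distance band: the bands enter only through f, and a
single normalization is what makes the weights a probability distribution
(they must sum to 1 per demand point, verified to 1e-9).

**Regional average (A0).** For contrast with the catchment methods, A0
divides the capacity located inside each administrative region by the
region's population, ignoring distance and forbidding cross-region use.
Regions with zero population but resident facilities are an undefined
ratio: scored 0 with a warning rather than an error. A related but
distinct quantity, the county-level crude density (total county capacity /
total county population), is exposed as `county_density`; note it does not
equal the county mean of town-level A0 scores (an unweighted mean of
ratios), and published county tables sometimes mix the two.

**Degenerate facilities.** A facility whose weighted reachable demand is
zero (nothing within 30 km, or only zero-population towns) has no defined
R_j; it is flagged, logged, and excluded from step 2 rather than aborting
the run.

## Equity assessment

Scores are summarized per county and nationally: mean, median, sample SD
(ddof = 1; 0 for singleton groups), min, max, and median−mean. A negative
median−mean flags a right-skewed county where more than half the towns sit
below the county average — concentrated access.

**Lorenz/Gini.** Units are sorted ascending by score (ties broken by id
for reproducibility); the Lorenz x-axis cumulates population shares and
the y-axis cumulates resource-volume shares A_i·P_i. Cumulating A_i·P_i
rather than A_i follows the income-Gini analogy the measure is built on:
A_i plays per-capita income, so the curve must track the resource mass
held by the poorest x fraction of *people*. An unweighted variant (uniform
unit shares) is available behind `weighted=False` for sensitivity; the
weighted form is the default everywhere. G is twice the area between the
diagonal and the curve, integrated by the trapezoidal rule on the curve's
vertices with no smoothing, clipped to [0,1]. A distribution with zero
total resource is defined as G = 0. The trapezoidal form equals the
population-weighted mean-absolute-difference formula
G = Σ_i Σ_j p_i p_j |a_i − a_j| / (2ā) exactly; the suite verifies the two
routes agree to 1e-9 on 50 random instances of up to 50 units.

Gini values are read on the conventional five-band scale: < 0.2 highly
equitable, 0.2–0.3 equitable, 0.3–0.4 bearable, 0.4–0.6 median inequality
(both ends inclusive), > 0.6 high inequality. Boundary values at
0.2/0.3/0.4 go to the band they open.

**Quintiles.** For choropleth output, units are classed 1–5 by percentile
rank (class k covers ((k−1)·20%, k·20%]); tied scores share the class of
their common (maximum) rank. All-equal scores carry no information: every
unit is assigned class 1 with a degenerate-distribution warning. Fewer
than five units are ranked individually. Classes map to the conventional
colors red / orange / green / light blue / dark blue.

**Prioritization.** Counties are staged for resource improvement from the
summaries of one method (A4 is the intended one): stage 1 = negative
median−mean *and* Gini category median/high inequality; stage 2 = negative
median−mean and county mean below the national mean, excluding stage 1;
stage 3 = any remaining county with negative median−mean; otherwise none.

## Synthetic landscapes

`generate_landscape` draws an island-scale system for testing and method
work: county seats scatter around a handful of Gaussian urban clusters and
towns around their county seat (county sd 40 km, town sd 12 km, in a
150 × 350 km extent); town populations are log-normal (μ = 8.75, σ = 1.0,
≈ 10,400 elderly per town); each facility picks a host town with
probability proportional to a kernel population density (10-km Gaussian
window) raised to γ (default 1.5), so resources concentrate in metros, and
is jittered 3 km around it; capacities are 1 + Poisson(0.73) providers;
ratings are Normal(3.72, 0.66) clipped to [1, 5]. The defaults were
calibrated once to the published national aggregates of the system the
generator emulates — ≈ 350 towns in 19 counties, 658 facilities,
≈ 1,140 providers, ≈ 3.6 M elderly, rating mean 3.72 / SD 0.66 — and are
not tuned further.

Route distances default to Euclidean × 1.3 (a scalar detour factor, so
routes exceed straight lines); pairs beyond 60 km are omitted, keeping the
table sparse. An optional `distance_model="network"` routes through a
random geometric graph (sites within 20 km linked, edge lengths Euclidean
times a lognormal wiggle ≥ 1, shortest paths by Dijkstra), which produces
more realistic heterogeneous detours and genuinely unreachable pairs. All
randomness flows through `numpy.random.default_rng` (PCG64), so a seed
fixes the landscape across platforms.

What the generator does **not** emulate: real administrative geography and
boundary shapes, coastline constraints, within-county rating structure,
travel times or mode choice, and any correlation between rating and
capacity. Passing tests therefore demonstrate the estimators' internal
correctness and invariances (conservation, normalization, equivalences) on
realistically sized and clustered inputs — not agreement with any real
registry.

Scoring a real-scale landscape (≈ 350 × 658, ≈ 43,000 distance pairs) takes
under a second; the property suites run on ~50-town/20-facility landscapes
(100 seeds) and ≤ 50-unit Gini instances, sizes at which the brute-force
oracles stay exact and fast.

## Numerical choices

* Accumulation in float64 throughout; dense (n_demand × n_facility) decay
  matrices (≈ 230k entries at full scale) rather than sparse algebra.
* Weight denominators are only zero for empty catchments (capacity > 0 and
  rating ≥ 1 by type invariant); such rows simply get no weights.
* Lorenz vertices guard the final coordinate to exactly (1, 1) against
  cumulative-sum drift; Gini is clipped to [0, 1].
* Ties in every sort are broken by unit id so output files are stable.
* Sample (n−1) SD is used in summaries, matching common spreadsheet
  practice; population-weighted Gini is the default, the unweighted
  variant is a flag.

## Known limitations

* A0's within-region attribution needs facility `region_id` to match a
  demand region; orphan facilities are logged and dropped from A0 only.
* The three-step weights assume choice depends on capacity/rating/distance
  only; no congestion feedback or iterative equilibrium is modelled.
* Gini on very small counties (2–3 towns) is reported as computed, but a
  two-town Gini is hard to interpret; the category labels matter more at
  realistic county sizes.
* GeoJSON output uses the planar km coordinates as-is; reprojection to
  geographic coordinates is the caller's responsibility.
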