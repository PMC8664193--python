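# Methods

## Routing model

The road network is an undirected graph over junction nodes in planar
meter coordinates. Each edge carries a length `l` (m) and speed limit `v`
(km/h); its weight is the travel time `t = (l/1000)/v × 60` minutes.
Travel times are symmetric: one-way restrictions, turn penalties, traffic
and elevation are out of scope. Inputs are assumed pre-projected; no
geodesic math is performed. When building a graph from LineString
features, endpoints within a merge tolerance (default 1 m) collapse into
one junction and duplicate edges keep the smaller travel time.

Facilities and area centroids are snapped to the closest junction by
Euclidean distance (ties to the lowest node id) so that routes always
traverse whole segments. Area demand points are population-weighted
centroids: the count-weighted mean of the centers of populated grid cells
intersecting the area polygon, falling back to the geometric centroid
(flagged unweighted) when no populated cell intersects. The weighted mean
was chosen over the alternative reading — the single maximum-population
cell — because it varies smoothly with the population surface and
degrades gracefully to the geometric centroid; the argmax-cell variant
can be emulated by passing a single cell.

Closest-facility times are computed with one Dijkstra pass per facility
(equivalent to multi-source Dijkstra while retaining which facility
attains the minimum); exact ties go to the lowest facility id for
reproducibility. Areas unreachable from every facility are excluded from
all statistics with a logged warning rather than assigned infinite times.
Roads supplied as a border buffer are routable but flagged, and buffer
areas are excluded from reported statistics, which removes the border
effect of ignoring facilities just outside a study region.

## Time composition

Fixed components (minutes) attach to the *area's* urban/densely-populated
/rural class:

| constant | urban & dense | rural |
|---|---|---|
| activation (call → dispatch) | 1.4 | 2.9 |
| on-scene | 13.5 | 15.1 |

`RT = station travel + activation`, `TT = emergency-department travel`,
`TPT = RT + TT + on-scene`. An area is inside the golden hour iff
`TPT < 60` strictly — exactly 60 counts as outside, reading "below one
hour" literally. All constants are overridable through `TimeConstants`.

Quintiles are rank-based per measure: values are stably sorted (ties
resolve by area-id order) and ranks split into five contiguous blocks
whose sizes differ by at most one, the 5th quintile holding the longest
times. Each measure is classified independently, since the underserviced
subset differs between measures.

## Synthetic regions

The generator emulates the structure of a mixed urban/rural Scandinavian
region at reduced scale; all randomness flows from one seed, so regions
are bit-reproducible. Defaults (the study conditions used throughout the
tests and the acceptance script):

- **Extent and population.** 100 km × 100 km at a mean density of 107
  inhabitants/km² (≈1.07 M people), on a 1 km population grid. Density is
  a sum of exponential kernels (e-folding 6 km) around 5 urban cores (one
  major, four minor at weight 0.45) with multiplicative lognormal noise
  (σ = 0.6). This reproduces the urban/rural density contrast
  qualitatively, not any real geography.
- **Road network.** A perturbed lattice of ~1,600 junctions (jitter 18%
  of spacing), 6% of lattice edges dropped, 12% of cells given a diagonal
  shortcut, circuity factor 1.2, speed classes 50/70/90/110 km/h with
  weights 0.35/0.30/0.20/0.15; any disconnected component is re-bridged
  to the nearest node, so the graph is always connected.
- **Areas.** 500 Voronoi cells of seed points drawn
  population-proportionally (so areas hold DeSO-like comparable
  population), clipped to the extent.
- **Municipalities and area types.** Municipalities are 6 × 6 blocks of
  the extent. A grid cell is *rural* when it belongs to the low-density
  prefix holding share `1 − urban_fraction` (default 0.35) of the
  population. A municipality is rural when ≥ 50% of its population is
  rural; it is urban when < 20% is rural *and* its agglomeration — the
  connected component of adjacent low-rural-share blocks it belongs to —
  exceeds 500,000 residents after rescaling the miniature region's
  population to full size (4.3 M); otherwise it is densely populated. The
  commute-time criterion of the official classification is accepted as a
  parameter and defaulted to satisfied, since commute data has no
  synthetic counterpart. Under the defaults this yields roughly a quarter
  urban, half densely populated and a fifth rural areas, the mix of the
  emulated region type.
- **Covariates.** Per-area draws from normal distributions whose means
  depend on area type: older-adult share 0.15 (urban) → 0.30 (rural),
  sd 0.05; highly educated share 0.45 → 0.25, sd 0.06; median income
  310,000 → 250,000 SEK/yr, sd 25,000; densely populated areas take the
  midpoint. Shares are clipped to [0.01, 0.99].
- **Facilities.** 24 ambulance stations and 5 emergency departments
  (≈1/5 of the emulated region's 118 and 25, matching the 1/5 area
  count), placed in grid cells sampled proportionally to population.
  A municipality "has a station" when one falls inside its block.

What the generator does **not** emulate: real geography or network
topology, one-way streets, traffic variation, spatially autocorrelated
covariate noise within a type, ambulance availability, or hospital
capability differences. Passing tests therefore demonstrate the
correctness and statistical calibration of the *methods*, not empirical
claims about any real region.

`simulate_access_times` additionally draws integer access times from an
NB2 generative model (`μ = exp(Xβ)`, gamma-Poisson mixing) over the
generated covariates. It exists so that effects absent from routed
geometry — notably a true rural × older-adults interaction — can be
injected with known coefficients and recovered by the disparity models.
The injected interaction magnitude used in tests (4.0 on the log scale,
with dispersion 0.1) was chosen by a power calculation: with ~100–240
rural areas and older-share sd 0.05, the interaction Wald z is ≈5–7,
comfortably detectable, while the rural main effect (truth 0) stays near
zero.

## Statistics

- **Pearson screen.** Covariate pairs with |r| ≥ 0.6 are flagged and the
  later-priority member dropped (priority defaults to column order);
  constant columns are flagged as undefined. The RT–TT correlation uses
  the standard two-sided Pearson test.
- **ANOVA/Tukey.** One-way ANOVA across area types with Tukey HSD
  adjusted p-values from the studentized range distribution; group means
  and SDs are reported alongside.
- **NB2 regression.** Log link, `Var = μ + αμ²`. Minutes are rounded to
  the nearest integer before fitting so the count likelihood is well
  defined — the pragmatic counterpart of applying a count model to
  continuous skewed times. The dispersion α is estimated by profile
  maximum likelihood (bounded search on log α ∈ [log 1e-8, log 50],
  IRLS GLM fit per evaluation), which is the joint MLE and remains
  well-behaved at the Poisson boundary α → 0. Coefficient p-values are
  two-sided Wald tests. `AIC = 2k − 2ℓ` and `BIC = k ln n − 2ℓ` count
  k = coefficients + dispersion. Income enters in raw currency units by
  default (its coefficient then prints as ~0.000); an `income_scale`
  flag rescales it, which multiplies only that coefficient.
- **Design matrices.** Urban is the reference area type and the
  alphabetically first region the reference region. On restricted
  subsamples (quintile-5 models) indicator columns can degenerate: a
  missing reference type is re-referenced to the first present type,
  zero-variance dummies are dropped, and indicator columns aliased by the
  subset's composition are pruned via rank-revealing QR. Substantive
  covariates are never pruned — genuine collinearity among them raises an
  error naming the terms.

## Numerical choices and edge cases

- Snapping and facility ties break deterministically by lowest id.
- `assign_quintiles` requires ≥ 5 values; all-equal inputs split into
  balanced groups by stable order.
- Degenerate (zero-area) polygons and empty facility sets raise errors;
  an empty facility file is writable but rejected on read.
- Seeds: every stochastic component (region generation, simulations)
  takes an explicit integer seed; identical config + seed reproduces
  outputs byte for byte, including serialized regions (floats are written
  with full repr precision and read back with round-trip parsing).

## Problem sizes

The default pipeline (500 areas, 1,600 junctions, 29 facilities, 9
disparity models) runs in about a second on one CPU. The test suite's
calibration studies use 100 replicates of n = 2,000 NB2 simulations for
coverage/bias, 100 random graphs of ≤ 50 nodes against a Floyd–Warshall
oracle, and one 2,520-area region for quintile bookkeeping (5th-quintile
models then have exactly n = 504). These sizes were chosen to make the
statistical checks sharp while keeping a full run interactive.

## Known limitations

- The NB2 count treatment of continuous minutes discards sub-minute
  information; it mirrors the standard practice for overdispersed skewed
  wait times rather than a measurement model.
- Coefficient standard errors condition on the profiled dispersion
  (the usual GLM-with-estimated-theta convention); α itself is reported
  without a standard error.
- Municipality blocks are square and administrative regions are vertical
  bands — deliberate simplifications of political geography.
- ANOVA assumes homoskedastic groups; with the generator's strong
  between-type variance differences the F test is conventional rather
  than exact, matching the method being reproduced.
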