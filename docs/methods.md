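# Methods

## The model

The forecasting chain treats vegetation type (the Ecological Response
Unit, ERU) as the carrier of breeding habitat.  Each ERU has a climate
envelope: the mean x̄ and inter-annual standard deviation s of each of
five climate variables over the ERU's extent in the pre-1990 reference
period.  The vulnerability of an ERU at a location whose projected 2090
value of one variable is `Val` is the standardized departure

    VS = |x̄ − Val| / (2 s),

zero at the envelope centre, 1 at two inter-annual SDs.  Per-variable
scores are combined into an aggregate by their mean (a `max` combination
is available by flag).  The multi-variable combination is a genuine design
choice here — the envelope methodology this package follows does not fix
it — and the mean was chosen as the symmetric, least-surprising option.

Projection asks, per cell, which envelopes still admit the projected
climate: envelope E admits the cell when |Val_v − x̄_v(E)| ≤ k·s_v(E) for
*every* variable, with k = 2 by default so that admission coincides with
per-variable VS ≤ 1.  All admitting ERUs form the candidate set (envelope
overlap routinely yields more than one).  If no envelope admits the cell,
the single least-departed envelope (minimum aggregate VS) is the
candidate.  Ecological transition rules then filter the set:

* a shrub-lifeform type may only transition to shrubland, grassland or
  desert types (site factors, shrub recruitment strategies and fire
  perpetuate shrub dominance), never to woodland or forest;
* woodland and forest types may transition to anything the envelopes
  admit, including grassland/shrubland at their lower ecotone;
* riparian types are never produced: riparian vegetation is controlled by
  hydrology rather than the regional climate envelope, so riparian cells
  persist as themselves with an undefined (NaN) vulnerability;
* if filtering empties the set, the current type persists — cells are
  never projected to "no vegetation".

The *most-likely* future type is the allowed candidate with minimal
aggregate VS; exact ties break by taxonomy order (the fixed order of the
default ERU table), making the projection fully deterministic.

Habitat rendering intersects a species profile (ERU set × model-zone set,
with an optional distinct 2090 zone set for species expected to expand
northward) with either the current ERU layer or the projection.  The
default projected rendering is *inclusive* — a cell counts if any
candidate belongs to the profile — which deliberately errs toward
commission; *most-likely* rendering uses the single best type.  Inclusive
always contains most-likely.

## Statistics

Model validation draws, per iteration, n cells uniformly **with
replacement** from the woodland-and-forest sampling region (optionally
restricted to the species' model zones) and counts how many fall in the
habitat mask; 500 iterations by default.  Sampling cells rather than
continuous points is exact, scale-consistent and oracle-checkable; per-
iteration captures are Binomial(n, q) with q the habitat share of the
sampling region.  Two summaries are reported: the count of iterations
equaling or outperforming the observed capture, and a one-tailed pooled
two-proportion z-test of the observed proportion against the aggregated
null draw, with continuity correction c = (1/n₁ + 1/n₂)/2 applied only
when it shrinks the excess.  The parametric form of "a one-tailed z-test
with continuity correction" is underdetermined; the pooled test against
the aggregated null is one defensible reading, and the exceedance count is
always reported alongside so conclusions never rest on the parametric form
alone.  With habitat a random half of the sampling region and records
drawn from the same null, the test rejects at α = 0.05 in about 4–6% of
replicates (slightly conservative, as expected for a corrected discrete
test).

Change in record capture between current and projected habitat uses the
McNemar test on the paired in/out states: χ² = (b−c)²/(b+c) on the
discordant counts, replaced by the continuity-corrected
(|b−c|−1)²/(b+c) whenever **any** cell of the 2×2 table is below 5.  That
any-cell trigger is deliberate (it is the rule the workflow this package
reproduces states); the more common b+c-only trigger is available via
`correction_rule="discordant"`.  p-values are the upper tail of χ²₁ and
are displayed to 4 decimals (χ² to 2) in table output.

## Geometry

The landscape is a raster of square cells; coordinates are planar metres,
cell (0, 0) top-left with its centre at the origin, row-major indices.
"Dissolved polygons" become connected components of habitat cells, rook
(shared-edge) adjacency by default as the closest analogue of polygon
dissolve, queen available for sensitivity.  Patch SD uses the sample
(n−1) denominator and is 0 for a single patch; an empty mask reports
absent (not zero) min/max/mean/SD.  Buffering marks every cell whose
centre lies within the Euclidean distance of a habitat-cell centre;
membership is decided on squared integer cell offsets, so cells at
exactly the buffer distance are included without floating-point
ambiguity (a 1 km buffer on a single 100 m cell is a 317-cell disc).
Detection-point thinning keeps points greedily in input order whenever
they are at least 250 m from every point already kept; the
order-dependence is documented behaviour.

## The synthetic world

The generator emulates the structural features the analysis depends on,
not any real geography:

* **Elevation**: a base east-west ramp plus seeded Gaussian hills,
  min-max rescaled to 700–3520 m and then skewed hypsometrically
  (u → u²) so cell area decays with elevation the way montane terrain
  does — basins broad, summits scarce.  Without that skew, habitat would
  not contract upslope.
* **Vegetation**: twelve contiguous elevation bands of at most 250 m
  width, desert scrub through alpine tundra.  A seeded 30% of cells
  within 25 m of a band boundary flip across it (fuzzy ecotones); a
  sinuous one-cell riparian corridor threads the valleys below 2600 m.
  Model zones are four vertical slabs Z1–Z4.
* **Climate**: five placeholder variables, each linear in elevation with
  its own lapse rate and intercept, plus seeded Gaussian spatial noise of
  4 m elevation equivalent, truncated at ±4 SD.  Warming is *equivalent
  uplift*: the warmed surface at elevation h equals the unwarmed surface
  at h − Δ, default Δ = 300 m (the regional observed upslope vegetation
  shift of ~15 m per decade, compounded over a century).  One knob moves
  all variables coherently and directly expresses the upslope-shift
  hypothesis.
* **Envelopes**: x̄ is the spatial mean over the ERU's cells; s is a
  config input of 175 m elevation equivalent per variable (no time series
  exists in the synthetic world, so the inter-annual SD cannot be
  estimated).  175 m is derived, not tuned: the 2-SD admission window
  (350 m) must exceed the maximum possible within-ERU spread — band width
  (250 m) + ecotone jitter (2×25 m) + truncated noise (2×16 m) = 332 m —
  which makes the zero-warming recovery identity (every cell's current
  type among its candidates) hold *by construction*, for every seed.
  The truncation of the noise field exists precisely to keep that
  guarantee deterministic.
* **Occurrences/territories**: a commission fraction (default 15%) of
  points falls outside the habitat, preferentially (60%) in riparian
  cells within 1 km of habitat — mirroring the empirical pattern that
  most off-model records sit in riparian corridors nestled within
  woodland — with Gaussian positional error (50 m SD) on occurrence
  records and none on territory centres.  Records coarser than 1 km
  precision are never emitted (such records are excluded from
  validation).

What the synthetic world does **not** emulate: real envelope geometry in
climate space (variables here are collinear through elevation, so
envelope overlap is structured along the gradient rather than arbitrary),
disturbance (fire), hydrology, latitudinal gradients within zones, and
any spatial autocorrelation in occurrence sampling effort.  Passing tests
therefore demonstrate the correctness of the operations and the internal
consistency of the chain, not the realism of any particular regional
forecast.

A consequence of the recovery guarantee worth stating plainly: because
2s (350 m) is of the same order as the default uplift (300 m), the
*inclusive* rendering loses little area — the admission margin at the
lower habitat edge offsets most of the shift.  The upslope contraction
appears directly in the *most-likely* rendering, and inclusive extent
still decreases monotonically as the offset grows.

## Defaults and numerical choices

| parameter | default | units | why |
|---|---|---|---|
| grid | 200×200 × 100 m | cells, m | patch/buffer structure at seconds-scale runtime |
| warming offset Δ | 300 | m uplift | ~15 m/decade over a century |
| inter-annual SD | 175 | m equiv. | recovery-identity bound, see above |
| admission k | 2 | SD | coheres with the 2s of the VS denominator |
| aggregation | mean | – | symmetric default; max by flag |
| buffer | 1000 | m | spatial uncertainty of mapping and records |
| connectivity | rook | – | polygon-dissolve analogue; queen by flag |
| iterations | 500 | – | matches the reference validation design |
| commission | 0.15 / 0.6 riparian | – | off-model records mostly riparian |

Degenerate inputs are reported as absent rather than coerced: empty masks
yield no patch statistics, zero current extent yields no percent change,
b + c = 0 yields no McNemar statistic, and a pooled proportion of 0 or 1
short-circuits the z-test to the exact degenerate comparison with a flag.

The packaged CSV fixtures under `owlshift/data/` carry the published
regional worked examples (per-species extents, capture counts, the
148-territory transition table, and the eight-species profile table used
by the synthetic pipeline).  The taxonomy simplification that desert
scrub types carry lifeform "herb" keeps the shrub lifeform as an exact
marker of the upland-shrubland classes the shrub transition rule applies
to.

## Known limitations

* The desert-lowland side of the gradient is carried for completeness but
  its envelopes share the synthetic construction; no claim is made about
  desert-type envelope quality.
* Only one species profile table ships; the CSV is user-editable and its
  reading of the generalized profile descriptions is deliberately
  conservative (pinyon-juniper and Madrean pinyon-oak are excluded from
  the flammulated and northern saw-whet profiles).
* Whether published projected-capture figures used inclusive or
  most-likely rendering is not recoverable; both modes are first-class.
* No exact-binomial McNemar variant and no multiple-testing correction
  are provided (none is applied in the workflow this reproduces).
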