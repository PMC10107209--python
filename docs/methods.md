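# Methods

## The estimation problem

Tracking studies publish, for each tagged bird, the country where it was
tagged on the breeding grounds and the country where it spent most of the
nonbreeding season. Pooling such *migration records* across studies gives a
sparse, biased sample of how bird *populations* — all conspecifics breeding
in one European country — distribute themselves across sub-Saharan Africa.
This package turns a record table into **migratory links**: directional
edges (species, breeding country → nonbreeding country), each with a
**strength**, the percentage of the population's individuals assigned to
that nonbreeding country. Links and strengths then feed country-, species-
and flyway-level syntheses, knowledge-gap percentages, and a coverage-based
list of priority species × country combinations for future tracking.

## Model and procedure

1. **Retention filter.** Records are grouped by population; populations
   with fewer than `min_records_per_population` records (default 3) are
   excluded. Below that, a multinomial strength estimate is quantized too
   coarsely to be meaningful.
2. **Observed links.** One link per distinct (species, breeding country,
   nonbreeding country) triple; its record count is the number of
   individuals on the triple.
3. **Inferred links.** The sample underestimates the true link set, but
   some missing links are geometrically predictable. For each observed
   destination country, we take the area-weighted centroid of the species'
   nonbreeding range clipped to that country, computed in an equal-area
   projection. The minimum convex polygon (MCP) of these centroids is then
   tested against every other country holding a positive-area slice of the
   nonbreeding range: any such country whose in-range slice intersects the
   MCP (a boundary touch counts) gains an *inferred* link. One observed
   country yields no inference (there is no "between"); two degenerate the
   MCP to the segment joining the centroids, and intersection is tested
   against that segment.
4. **Interpolated counts.** An inferred link needs an expected record
   count before strengths can be computed. We transfer record *density*:
   for each observed country sharing a boundary with the inferred country,
   density = records ÷ area of the species' nonbreeding range within that
   country (km², equal-area); the inferred count is the mean neighbour
   density × the inferred country's in-range area. When no observed country
   shares a boundary, the two observed countries with nearest range
   centroids stand in, which guarantees the formula is total (hull vertices
   are always observed countries). Counts stay fractional — rounding would
   break strength normalization asymmetrically.
5. **Strengths.** strength = 100 × record count ÷ total records (observed
   or interpolated) across all links of the population. Strengths are
   stored at full precision and sum to 100 per population by construction;
   the `--round 1` CLI flag reproduces one-decimal presentation tables.

### Aggregations

* **Population shares.** A species' share of its European (or subregional)
  population in a country is 100 × national size ÷ scope total, from the
  national breeding-population table. No such table exists for Africa, so
  African "shares" use the fraction of the species' nonbreeding range (or
  subregional range) in each country, measured in the equal-area plane.
* **Species importance.** Each tracked population contributes
  strength/100 × (its share of the European population) to every African
  country it links to. Importances therefore sum exactly to the tracked
  share of the European population — tracked mass is conserved, only
  redistributed.
* **Knowledge gaps.** A species is present in a European country when the
  population table holds a positive size there, and in an African country
  when its nonbreeding range overlaps with positive area (a boundary touch
  does not count). It is tracked for a country when any link, observed or
  inferred, touches that country. gap % = 100 × (present − tracked) ÷
  present.
* **Priorities.** For each species with a decreasing European trend and
  each subregion: starting from the summed shares of already-tracked
  countries, untracked countries are added greedily, largest share first
  (ties by country code), until cumulative coverage reaches
  `coverage_threshold_pct` (default 50) or the subregion is exhausted. The
  greedy rule is the natural reading of "countries needed to complement
  existing studies", is deterministic, and reproduces the published
  turtle-dove example (France + UK cover 25.1%; Spain alone is added).
  Species × country combinations are deduplicated across subregional runs.
* **Effort curves.** Links gained per population versus records collected
  are fit with a saturating Michaelis–Menten curve, links = a·n/(b+n), by
  least squares; the model family is a package choice (only "nonlinear
  regression" toward an asymptote is implied by the source analyses) and
  is isolated behind one function. The fit reports whether the curve
  reaches 95% of its asymptote within the observed effort range
  (equivalently max n ≥ 19·b). A predictor with no variation is an error;
  constant link counts fit cleanly with b → 0 and are surfaced through the
  saturation flag.
* **Trends.** Cumulative studies/links per year. A link is dated by the
  earliest publication year among the studies contributing records to its
  population; inferred links carry no records, so they inherit the same
  population date. Studies without a year are excluded with a warning.

## Geometry and numerics

* All inputs are WGS84 lon/lat. Areas and centroids are computed after a
  cylindrical equal-area (Lambert) transform on the authalic sphere
  (R = 6 371 007.18 m): x = R·λ, y = R·sin φ. The transform is exactly
  area-preserving on the sphere, so area *ratios* (the only way areas
  enter the analysis) are unbiased; no external projection library is
  needed.
* Invalid polygons (self-intersecting rings are routine in published range
  maps) are repaired by zero-width buffering on ingest, with a logged
  warning; repair preserves enclosed area to ~1e-9 relative.
* "In range" means positive area in the equal-area plane, not mere
  intersection, so boundary-touching slivers never create presences or
  inferred links; the MCP intersection test itself is the permissive
  `intersects` (touching the hull counts).
* Ties in orderings are always broken by country code; all outputs are
  sorted, making every table byte-reproducible.

## The synthetic world

Real inputs (records compiled from the literature, national boundary
polygons, published range maps, national population estimates) are large
and license-encumbered, so tests and validation run on a generator that
emulates their statistical structure:

* Two rectangular continents placed at realistic latitudes (Europe
  36–60° N, Africa 34° S–12° N, so latitudinal area distortion is real),
  tessellated into contiguous countries via Voronoi cells of seeded
  points, with subregions assigned by quadrant. Defaults: 12 European and
  16 African countries.
* 24 species (18 landbirds, 6 raptors — the real system's ≈3:1 ratio).
  Breeding ranges are unions of ≥1 European countries; nonbreeding ranges
  are unions of contiguous African countries with occasional dropped
  members ("holes", p = 0.15) so inference has both positives and
  excluded-by-range negatives to find.
* National population sizes are log-normal (median ≈ 10⁴, σ_log = 1.5);
  each species is "decreasing" with probability 38/118, the decreasing
  fraction of the real species list.
* True connectivity per population is a Dirichlet(1) draw over the
  countries its nonbreeding range overlaps, so truth support never
  escapes the range.
* Records are sampled i.i.d. from the truth (multinomially). A population
  is tracked with probability 0.5 scaled by subregional effort bias
  (western/central Europe 1.5×, northern 1×, eastern 0.4×) and group bias
  (raptors 1.3×), mirroring the documented geographic and body-size biases
  of the real literature. Tracked sample sizes are negative-binomial
  (mean 8, dispersion 1.2 — matching the ~8.6–11.1 records per retained
  population of the real dataset) with substantial mass below 3, so the
  retention filter is genuinely exercised. Study years (raptors from 1996,
  landbirds from 2009), devices (raptors PTT/GPS, landbirds mostly GLS)
  and occasional missing years (p = 0.02) are attached synthetically.
* One root seed is split hierarchically (world / species / records), so
  redrawing records never perturbs the geography, and identical seeds give
  byte-identical output files.

What the generator does **not** emulate: positional error of geolocators,
nonbreeding-season mortality, within-country habitat structure, partial
range coverage inside a country (synthetic ranges are unions of whole
countries), or real coastline/border geometry. Passing tests therefore
demonstrate correctness of the estimator and its geometry on
well-structured inputs, not robustness to classification errors upstream
of the record table.

## Validation

* Every geometric operation is checked against closed forms (spherical
  band areas, analytic centroids) and against independent oracles that
  restate the projection and compute hulls with Qhull rather than the
  package's own path; inference must match the exhaustive brute-force
  hull-intersection oracle exactly on 100 seeded worlds.
* The strength estimator is validated end to end by a recovery experiment:
  sample n records per population from known truth, run the full engine,
  compare estimated to true strengths. At n = 500 the median (over ≥200
  replicate trials) of the per-population maximum absolute error stays
  within 5 percentage points and all true-support countries are recovered;
  at n = 3 errors of tens of points are expected and observed — the
  small-sample caveat that applies equally to real 3-bird populations.
* Problem sizes in the default test battery (5–8 countries per continent,
  3–6 species, 100 worlds, 25 × 10 recovery trials per n) were chosen to
  exercise every code path at desk scale; the whole suite runs in seconds.

## Known limitations

* The interpolation formula for inferred-link counts is a documented
  package decision (mean neighbour density × area); it sits behind a
  single function so an alternative can be swapped in.
* Strengths inherit all sampling biases of the record table; nothing here
  reweights for unrepresentative tagging effort.
* The reverse direction — how important a European breeding country is to
  an African country's nonbreeding community — is deliberately not
  computed: tracking is initiated in Europe, so African-side
  representativeness is too poor for that inference.
* Country-level aggregation treats national populations as closed;
  cross-border natal dispersal is assumed negligible at this scale.
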