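# Methods

## The analysis

The pipeline operationalizes a range-overlay biogeography analysis: given
species range multipolygons, two disjoint focal forest regions and a set
of named dispersal corridors bridging them, it computes, per species, (a)
co-occurrence in both regions, (b) range continuity, (c) the subset of
corridors overlapped, and, per dataset, (d) habitat-preference and
sequence-availability classes, (e) a route × habitat independence test and
(f) richness rasters. Two inclusion criteria gate the species list, in
this order: occurrence in both focal regions, then forest association (at
least one forest habitat record). Excluded species are logged with the
failing stage, so every input species is accounted for exactly once.

## Geometry and areas

Coordinates are WGS84 decimal degrees, longitude first. Every geometry is
cleaned once at ingest: `shapely.make_valid` with even-odd polygon repair
(a bow-tie becomes two triangles), non-areal debris discarded, parts
unioned and normalized. Already-valid input passes through with its area
preserved to machine precision. Input crossing ±180° is rejected; the
supported domain is a single hemisphere-scale window, which covers the
continental study systems this is built for.

Areas are evaluated on the world cylindrical equal-area plane
x = Rλ, y = R sin φ with R = 6371.0088 km (the WGS84 mean radius). For a
lon/lat rectangle this reproduces the spherical quadrangle area
R²·Δλ·(sin φ₂ − sin φ₁) exactly, which the tests use as an independent
oracle. No ellipsoidal (geodesic) areas: the sphere-vs-ellipsoid error is
a few tenths of a percent, far below any decision threshold here, and the
closed form keeps every synthetic-world area exact.

Route membership is binary on overlap area: species s is attributed to
corridor r iff area(range_s ∩ corridor_r) > τ. The default τ = 0 km²
means any strictly positive overlap counts — boundary contact of zero
area does not. τ is exposed (config/`--tau`) to suppress sliver
artifacts in digitized maps; raising it can only remove routes
(monotonicity is a tested invariant). Membership is deliberately *not* a
fraction of range or corridor area; the raw overlap areas are recorded
per species for users who want their own rule.

Continuity merges the range's connected components by single linkage at
gap ≤ ε (distance measured on the same equal-area plane; exact at the
equator, slightly compressed east–west away from it), then asks whether
any merged cluster overlaps both focal regions by > τ. Default ε = 0 km:
only genuinely touching parts form a cluster. ε > 0 exists because
digitized range maps fragment artificially; 10–50 km is a reasonable
scale for that artifact. Species with an empty route set are reported as
unrouted ("none"); no extra distance criterion defines "extremely
disjunct" — the empty set is the operational definition.

## Habitat classes

The three-class scale is computed from structured habitat records
(species, IUCN-style habitat code, suitability, major importance), where
level-1 code 1 is Forest:

1. **SF** — every record is forest;
2. **PF** — non-forest records exist but all are Marginal, *or* forest is
   the only habitat flagged as of major importance;
3. **G** — otherwise.

Unknown suitability is treated as Suitable and unknown major importance
as No, both of which push borderline species toward G, the most common
class — a conservative default. Because the historical labels for the
real compilation were assigned from free-text habitat accounts, a
per-species override CSV is accepted and wins over the rule; the rule
exists to make new datasets auditable, the overrides to preserve
fidelity to expert judgement.

## Availability bins and per-order means

Counts of public nucleotide records are binned by closed integer
intervals: none = {0}, low = [1, b₁], regular = [b₁+1, b₂], intermediate
= [b₂+1, b₃], high = [b₃+1, ∞), with shipped breaks (b₁, b₂, b₃) =
(22, 74, 225). For a new dataset, `quantile_breaks` computes quartiles of
the *positive* counts by linear order-statistic interpolation (quantile p
at position 1 + p(n−1)) and floors them to integers; the convention is
fixed because several quantile definitions exist and only one set of
integer intervals can be reproduced. Per-order mean sequence counts
include zero-count species by default (the availability summaries cover
the full species list); a flag excludes them.

## The chi-square test

The route × habitat table has one row per non-empty route combination in
the fixed order E, C, W, E+C, E+W, C+W, E+C+W and columns SF, PF, G.
Unrouted species are excluded by default (`include_unrouted` adds a
"none" row). Rows or columns with zero marginal totals are dropped before
testing — expected counts of zero make the statistic undefined — and the
dropped labels are recorded and logged.

The test itself: E_ij = (row total)(col total)/N, X² = Σ (O−E)²/E,
df = (r−1)(c−1) on the post-drop matrix, p = Q(df/2, X²/2) with Q the
regularized upper incomplete gamma function. No Yates correction at any
size: the conventional default applies the correction only to 2×2
tables, and uniform behaviour across table sizes was chosen over
emulating that special case. The minimum expected count is reported and
a warning is flagged below 5; the actionable response is the Monte-Carlo
mode, which permutes per-individual column labels under fixed margins
(seeded, add-one p estimator, default 2000 replicates).

On the reference compilation's printed seven count-triples (N = 123) the
implementation computes X² = 36.5673, df = 12, p = 0.000262. The
historically reported statistic for this comparison is 35.255 (df = 12,
p = 0.0004); the difference is consistent with one or two cells differing
between the printed text and the underlying species table. The package
always reports the value computed from its input counts and never
substitutes the historical number.

## Rasters

Pixel membership is a center-point test (boundary counts as inside),
matching the dominant rasterization default in desktop GIS toolchains;
richness is the integer cellwise sum over species, optionally restricted
to one route combination. Default resolution 0.5°, default extent the
padded bounding box of the inputs, anchored exactly at (xmin, ymax).
Output is the ESRI ASCII grid format — plain text, self-georeferencing,
readable by any GIS. Pixel-count × pixel-area agrees with the polygon's
equal-area measure within 5% once a range spans ≥ 20 pixels per
dimension (a tested property); coarser ranges are edge-dominated and
their grids should be read qualitatively.

## The synthetic world

The generator emulates the *structure* of the study inputs, not their
cartography: two rectangular focal regions flanking a gap, three disjoint
corridor bands crossing the gap into both regions (pairwise clearance
≥ c_min, default 100 km), a neutral latitude band free of corridors, and
an ecoregion mosaic tiling each corridor (for corridor-construction
tests). Everything is an axis-aligned rectangle, so every expected
overlap has a closed form.

Species labels are drawn first — route combination, continuity, habitat
class, taxonomic order, sequence count — and the geometry is then
constructed to realize them: full gap-bridging slabs per member corridor
for continuous species (region blobs welded to the first slab), half-gap
slabs plus an isolated far-side blob for disjunct routed species, and two
isolated blobs for unrouted species. Clearances from non-member corridors
hold by construction, so route and continuity recovery is exact (a tested
invariant at n = 500), not statistical.

Default distributions are the reference compilation's empirical
frequencies: the eight route-combination proportions (19, 4, 3, 30, 4,
13, 50, 4 of 127), habitat given combination from the 7 × 3 table,
disjunct probability 10/123 for routed species (unrouted species are
always disjunct), nine taxonomic orders with the compilation's species
counts, and per-order negative-binomial sequence counts with the
compilation's means and dispersion 0.5 — small enough that variance far
exceeds the mean, reproducing the long low-availability tail alongside
high-mean orders. What the generator does **not** emulate: real coastline
complexity, holes, shared range boundaries, spatial autocorrelation of
richness, or taxonomy — so passing tests certify the pipeline's logic and
arithmetic, not the cartographic robustness of any particular real
dataset.

## Calibration checks

Type-I behaviour and power of the pipeline's chi-square are checked on
100 simulated replicates each at n = 240 species with a uniform
route-combination distribution: those sizes keep every expected cell near
or above 5, the regime where the asymptotic reference distribution is
trustworthy, while staying fast enough to run routinely. Under habitat
independent of route (class probabilities 0.2/0.3/0.5 everywhere) the
test must not reject in ≥ 90% of replicates; under a strong dependence
(each combination concentrated 0.9 on one class) it must reject in
≥ 90%. These are coarse sanity bands, not a full size/power study.

## Known limitations

- Equal-area distances (continuity ε) degrade away from low latitudes;
  the tool is built for tropical two-biome systems.
- Corridors are static polygons, not resistance surfaces; no least-cost
  or connectivity modelling.
- The asymptotic p-value is unreliable exactly where real compilations
  live (sparse route × habitat cells); use the Monte-Carlo mode when the
  warning fires.
- Antimeridian-crossing data are not supported.
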