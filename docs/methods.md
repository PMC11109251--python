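# Methods

## The model

The unit of assessment is the **3D realm**: the intersection of a 2D
marine ecoregion with one depth band of either the benthic domain (the
seafloor) or the pelagic domain (the water column). Depth is the only
vertical coordinate; within a band no ecological heterogeneity is
modelled. Two schemes are built in:

| domain  | bands (m, positive-down) |
|---------|--------------------------|
| benthic | euphotic 0–30 · upper mesophotic 30–60 · lower mesophotic 60–150 · rariphotic 150–300 · upper bathyal 300–1000 · lower bathyal 1000–3500 · abyssal 3500–6000 · hadal >6000 |
| pelagic | epipelagic 0–200 · mesopelagic 200–1000 · bathypelagic 1000–3500 · abyssopelagic 3500–6000 · hadopelagic >6000 |

Bands are **deep-inclusive half-open intervals (shallow, deep]**. The
boundary convention is not ecologically meaningful but guarantees that
benthic classification is an exhaustive partition of positive depths —
a 30 m seabed is euphotic, a 30.001 m seabed upper mesophotic. The
mesophotic is always carried as its upper/lower subdivision. The
pelagic scheme defaults to five bands; `default_pelagic_scheme(
merge_deepest=True)` merges abysso- and hadopelagic into a four-band
variant used in some depictions of the zonation. A cell "contains" a
pelagic band whenever the band's shallow bound lies above the seabed,
so pelagic membership is nested in depth.

Depths are positive-down everywhere in the API; rasters store
*elevation* (negative below sea level, GEBCO-style) and are negated on
ingest. Cells with elevation ≥ 0 are land and excluded from every
tally; no separate land polygon layer is used.

## Grid geometry

Areas are computed per grid cell as height × width of a cylindrical
strip: height = resolution × 60 arc-minutes × 1852 m (constant), width
= 2πR cos φ / n_cells with R = 6378 km, evaluated at the **cell-center
latitude** (the choice of latitude is free at the sub-0.01% level; the
center minimizes strip bias). `n_cells` defaults to 360°/resolution so
coarse test grids stay self-consistent; at 0.004166° this gives the
canonical 86,400 cells and a 463 m cell height. The two constants are
mutually inconsistent at the 0.2% level (1852 m per arc-minute implies
R ≈ 6367 km, not 6378 km); both are kept as stated because the formula
is a published convention, and the acceptance suite bounds the total
error against an exact spherical-quadrilateral area
R²·Δλ·(sin φ₂ − sin φ₁) at < 0.5% for |φ| ≤ 85°. The strip formula is
not trusted poleward of that; none of the shipped analyses go there.

Cells are half-open, [west, east) × [south, north), so a point on a
shared edge belongs to exactly one cell. Point-to-cell lookup is
nearest-cell (floor division), emulating raster extraction at the data
resolution.

## Protection

Overlap flattening dissolves all polygons of each IUCN category into
one layer, then subtracts the union of all higher-priority layers,
walking the order Ia > Ib > II > III > IV > V > VI > Unknown. This is
the sequential-difference construction used to de-duplicate
protected-area databases; it is order-independent, idempotent, and
conserves the union. "Not Applicable/Reported/Assigned" categories are
mapped to Unknown on read. OECMs carry their reported category and
compete in the same ordering as MPAs in the "all" assessment — the
simplest consistent extension, since the flattening semantics ("a point
keeps its highest protection") do not depend on the designation kind.
The strict ("Ia_Ib") assessment filters to MPAs of category Ia/Ib
*before* flattening, so an OECM with a nominal Ia category never counts
as strict protection.

Cell membership is decided by the cell-center point; coverage error is
therefore at most one cell-area quantum per polygon boundary crossing.
Records without a real polygon boundary are not representable:
buffering a point to its reported area would fabricate bathymetric
coverage. Geometry validity is repaired with `make_valid` on ingest and
failures raise rather than drop records. An optional simplification
tolerance (e.g. 0.01°) can be applied before flattening.

A protected cell protects the benthic band of its own seabed and every
pelagic band of its column; realm coverage is Eq. above
(protected area / realm area × 100).

## Fishing

Two attribution rules:

* **impacted** — all realms in the surface-to-seabed column at the
  event location (one benthic band, ≥1 pelagic bands). Motivated by
  vertical connectivity: migrations, trophic cascades, by-catch,
  debris. Under this rule summed benthic effort equals total event
  hours exactly.
* **targeted** — benthic gears target the seabed band; pelagic gears
  target the pelagic bands whose open interval overlaps
  (gear min, min(gear max, seabed)). The open-interval logic matches
  the band convention: a gear reaching exactly 200 m does not select
  the mesopelagic. When a pelagic gear's minimum depth reaches the
  seabed (a catalog/bathymetry inconsistency) the event is attributed
  to the pelagic band containing the seabed — the deepest band the
  gear can reach once clipped to the column — with a warning; an empty
  attribution is never returned, so no effort silently disappears.

An event targeting several pelagic bands contributes its **full hours
to each band** by default (pressure is a per-realm intensity, not a
partition of effort); `split_hours=True` divides hours equally instead.
Gears absent from the catalog, and gears marked unspecified
("trawlers", "purse seines", generic "fishing" — labels that mix
benthic and pelagic operation), are reported under an `unspecified`
band/domain with effort only. The gear-depth catalog ships as an
editable CSV; the default ranges (drifting longline 0–400 m, midwater
trawl 30–1000 m, …) are typical figures from gear descriptions and
should be reviewed against the user's fleet.

Pressure = effort / realm area (h km⁻² yr⁻¹). Inter-annual variability
is summarized as mean ± t(df = n−1) · sd/√n at 95% confidence.

## Prioritization

Fishing categories are quartiles (inclusive linear-interpolation
quantiles, the numpy default) of the unweighted realm-level pressure
distribution, ties resolved downward (identical pressures are all
category 1). Coverage categories are fixed right-inclusive bins tied to
the 2030 targets: 0–10/10–20/20–30/>30% for total coverage (30%
target), 0–2.5/2.5–5/5–10/>10% for strict coverage (10% target). The
1–16 score is `(fishing_cat − 1) × 4 + (5 − coverage_cat)` — a
bijection onto the 4 × 4 grid that grows with pressure and with
protection deficit; only the 1–16 range is externally meaningful, the
cell order within it is this package's convention.

The four profiles use the median realm pressure and the halfway point
to the 2030 target (20% total, 5% strict). Ties: a realm exactly at the
median counts as high-fished and exactly at halfway counts as past
halfway (≥/≥), so the profiles partition the realm set for any
thresholds, including the discrete synthetic data where exact hits
occur.

The regression is OLS of log₁₀ coverage on log₁₀ pressure with Pearson
r and a two-sided p. Realms with zero coverage or pressure have no
logarithm and are dropped (counted in `n_dropped`); a pseudo-offset
option adds a constant to both variables instead. The result reports
slope, r, r², and p separately — a signed "R²" is never emitted, since
a coefficient of determination cannot be negative. Orientation
(coverage as response) is a convention; the Pearson r and p are
symmetric in it.

## Synthetic seascapes

The generator emulates the statistical structure of the real inputs,
not their geography:

* **Bathymetry** — a western land margin, then depth increasing
  eastward log-uniformly from 5 m to the 200 m shelf break over 25
  columns and on to 7500 m, times a smooth log-normal noise field
  (σ = 0.05, correlation length 6 cells). The log-uniform profile gives
  every benthic band a substantial cell count on the default 100 × 100
  grid at 0.05°, chosen so a full pipeline run takes well under a
  second while one cell is ≲0.1% of any realm.
* **Ecoregions** — latitudinal strips split at cell edges; coastal
  strips span from the coast through the last column containing any
  cell ≤200 m (so coastal ecoregions contain the entire shelf, the way
  coastal ecoregions are defined to reach the 200 m isobath), offshore
  strips tile the rest.
* **Protected areas** — per-band coverage targets are met by selecting
  contiguous cell runs (rows in seeded random order) and emitting
  cell-aligned rectangles, so ground-truth coverage is exact by
  construction. Default targets anchor on reported global coverages
  where such figures exist (euphotic 15%, abyssal 5.8%) and otherwise
  are set so the seascape exercises every branch of the downstream
  classification: rariphotic gaps, well-protected lightly fished deep
  realms, and one well-protected heavily fished band (lower
  mesophotic 25%) so that all four priority profiles occur. The
  category mix leans to VI/Unknown (as real coverage does), 15% of
  records are OECMs, and 20% of rectangles receive a second,
  conflicting designation to exercise flattening without changing the
  union.
* **Fishing** — seven gears with log-depth niches
  (weight ∝ exp(−decay·|ln d − ln d₀|)): trawling concentrated over
  shallow seabeds, drifting longlines and midwater trawls over deep
  water, and generic labels carrying the unspecified share. Hours are
  log-normal (median 2 h, σ = 1 — strictly positive and heavy-tailed
  like real effort), 2000 events per year for 2018–2020. Unspecified
  hours are rescaled to 45% of the total, matching the share of
  depth-ambiguous gear labels in public AIS effort data.

Hours are quantized to 1/64 h so that every effort sum is exact in
floating point regardless of summation order; this is what makes
"pipeline equals ground truth *exactly*" and "shuffling events changes
nothing" testable as equalities. Ground-truth tallies restate the band
bounds, ecoregion assignment, and cell-area formula locally and touch
none of the analysis modules.

What the generator does **not** emulate: realistic coastline or
seamount geometry, spatial autocorrelation of fishing within a gear
beyond the depth niche, vessel-level behaviour, multi-polygon protected
areas, or category co-location patterns. Passing recovery tests
therefore demonstrates the correctness of the bookkeeping (overlay,
flattening, attribution, aggregation), not the realism of any
ecological conclusion drawn from real data.

## Numerical choices and degenerate inputs

* Band classification uses `searchsorted` on the deep bounds
  (side="left"), realizing the (shallow, deep] convention exactly.
* Cell widths are clamped to exactly 0 at |φ| = 90° where cos is only
  zero to rounding.
* Flattening compares geometries through shapely/GEOS; union-area
  conservation is verified to 1e-9 relative tolerance in tests.
* Events on a cell edge resolve by the half-open cell convention; land
  or off-grid events are excluded and counted, never silently dropped.
* Zero-area realms produce no rows anywhere (absence, not zeros).
* An empty event table yields an empty pressure table; a single year
  yields a mean with an undefined (NaN) confidence interval; fewer than
  three usable realms make the regression undefined (raised, and
  recorded as such in the pipeline log).

## Test and verification sizes

The shipped suites run the generator at its default 100 × 100 grid with
6000 events (20 seeds in the end-to-end acceptance test), 100 random
polygon sets × 1500 sample points for the flattening oracle, and 20
replicates × 50 realms for regression recovery — sizes at which the
whole suite completes in seconds while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The cylindrical-strip area formula degrades near the poles; use an
  equal-area projection there instead (out of scope here).
* Coverage is cell-center based: very small or very thin protected
  areas (relative to the grid) are under- or over-counted by up to one
  cell each.
* The targeted attribution inherits the gear catalog's depth ranges;
  the defaults are literature-typical, not fleet-calibrated.
* Depth-unspecified effort (45% by default, mirroring public data)
  cannot be placed in a realm and is reported separately; targeted-mode
  pressures are therefore lower bounds.
* Ecoregion and protected-area geometries are treated in geographic
  lon/lat degrees throughout; no reprojection is offered.
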