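# Methods

## The model

The package implements a composite-indicator screening model for the
salinisation risk of coastal drinking-water sources.  Risk is treated
as the product interaction of exposure (cyclone landfall incidence,
elevation, geomorphology), sensitivity (population density) and
resilience (September rainfall, fresh-groundwater availability).  Each
variable is reduced to an ordinal score s ∈ {1, 2, 3} by a fixed step
function, and the six scores combine as

    CVI = sqrt(a·b·c·d·e·f / 6).

The multiplicative form makes the index sensitive to coincident
adversity: one high score triples the product, three high scores
multiply it 27-fold, whereas an arithmetic mean would move by the same
increment each time.  `compare_aggregators` quantifies the difference:
the two aggregators are strongly rank-correlated over the 729-point
score space but order many pairs differently, and the product index
spreads the upper tail much further.  All six variables carry equal
weight; differential weighting is deliberately out of scope because any
choice would be subjective at this screening scale.

Assumptions worth keeping in view: the variables are treated as
independent contributions even though elevation and geomorphology are
correlated on real coasts; the ordinal reduction discards within-class
variation (a cell at 0.1 m and one at 1.9 m both score 3); and the
index is relative — it ranks segments, it does not predict salinity
concentrations or case counts.

## Classification thresholds

All boundaries live in `ClassifierThresholds` and are echoed into the
run manifest.  Defaults: cyclone landfalls < 5 / 5–10 / > 10 over the
full record; elevation ≤ 2 m high, ≥ 5 m low (2 m is a typical tidal
amplitude, surge heights rarely exceed 5 m); population < 100 /
100–500 / > 500 people/km²; September rainfall > 300 mm low — about
the amount that fills a household's jars and tanks for the months after
the monsoon (300 mm on 15–20 m² of roof is 4 500–6 000 l at unit runoff
coefficient; `harvest_volume` exposes the coefficient because real
systems lose roughly 10 % of gross yield) — 150–300 mm moderate,
< 150 mm high.  Edge conventions: the moderate bands of cyclone,
population and rainfall are closed (5, 10, 100, 500, 150, 300 all
moderate); elevation places 2.0 m in the high class and 5.0 m in the
low class.  Exactly 5.0 m is read as low: the low class is defined as
"at or above the maximum plausible surge height".

CVI classes are decided on the integer product: LOW ≤ 18 < MODERATE
≤ 64 < HIGH.  18 and 64 are the products of the two pivotal
combinations whose CVI values (1.73, 3.27) are the quoted limits; both
limit combinations close their own class.  A dedicated test proves the
integer rule identical to float comparison against sqrt(18/6) and
sqrt(64/6) on all 729 combinations.

## Grid and geometry

The lattice is anchored at (0°, 0°): row = floor(lat/0.5),
col = floor(lon/0.5), with half-open bounds [min, min + 0.5).  A
clipped coastline piece lying entirely on a cell's upper lon/lat edge
is assigned to the neighbouring cell, so lengths are never double
counted and the per-class totals conserve the full coastline length
(verified to 0.1 %).  A cell touching the coastline only at a vertex
has zero length and is not coastal.  Lengths and distances are
great-circle on a sphere of radius 6 371 km (111.19 km/degree);
clipping is planar in lon/lat, which at half-degree scale introduces
sub-0.01 % error.  Registration of the lattice is a package choice —
the alternative (coast-following hand-delineated cells) is not
reproducible from data.

## Cyclone incidence

Track records (storm id, timestamp, lon, lat, Saffir–Simpson category;
category may be blank) are grouped per storm and time-sorted.  Storms
whose maximum category is below 1, or never recorded, are excluded.  A
landfall is the first intersection of each sea→land transition of the
track polyline with the land-polygon boundary, interpolated linearly
between the bracketing 6-hourly fixes; the category at landfall is the
last at-sea fix's (falling back to the storm maximum when that fix is
uncategorised).  Successive landfalls of one storm closer than 1° are
merged so a skimming track counts once.  Incidence is per storm per
cell: an event increments every coastal cell whose centre lies within
the impact half-width (default 1.0° of arc — an isotropic stand-in for
the ~2° storm footprint, touching ~4 half-degree elements along a
straight coast).  Footprint shape and per-storm counting are config-
exposed since the original procedure is stated only as "about 2°,
4 elements".  `count_incidence` is verified against a brute-force
(event × cell) double loop.

## Scenarios

A scenario is {population multiplier, elevation offset, rainfall
multiplier}; cyclone incidence, geomorphology and groundwater category
are held fixed (no robust basis for projecting them at this scale).
Built-ins: 2050 = (×1.40, −0.2 m, ×1.05), 2100 = (×1.35, −0.6 m,
×1.10), both relative to the baseline year — the 2100 population
multiplier is *not* compounded on 2050, matching the demographic
projections the constants come from.  Sea-level rise enters as a plain
offset on the representative cell elevation; no inundation remodelling
is attempted.  Consequences, proved as properties: elevation and
population scores can only move toward higher vulnerability, rainfall
only toward lower, and applying a scenario then its inverse recovers
the baseline to 1e−9.

## Exposure summaries

Coastline length per class is an exact sum of per-cell lengths.
Exposed population per class is density × land area within a buffer
(default 30 km) of the coastline, with the buffered land area sampled
on a 0.05° sub-grid: a sub-cell contributes its spherical area when its
centre is on land and within the buffer, distance being measured on a
local equirectangular plane (longitude scaled by cos lat) — adequate to
well under a kilometre at 30 km range.  The estimate is resolution-
configurable, monotone in the buffer, and conserves class totals.

## Synthetic worlds

`generate_world` emulates the statistical structure of the real input
stack (elevation model, gridded population and rainfall, groundwater-
salinity map, track archive) on a ~8°-long, gently sinuous
near-meridional coastline at ~90°E, 10–18°N, alternating deltaic
segments (delta-plain landform; elevation drawn from −0.5–1.9 m;
population 505–2 500 /km²; mostly saline groundwater; 8 aimed landfalls
per cell over the record) with beach/cliff segments (5.1–45 m,
2–95 /km², fresher groundwater, 1.5 landfalls per cell).  Segment-class
probabilities and draw ranges are defaults of the spec dataclass.

Two deliberate constructions make ground truth exact rather than
probabilistic.  First, every attribute draw stays strictly inside one
classifier band with a margin of at least one output-precision unit
from each boundary, so the intended score of every variable is
recovered by the classifiers with certainty; classifier boundary
behaviour is exercised by dedicated unit tests instead.  Second,
cyclone ground truth is computed by the generator's own brute-force
distance loop over the aimed landfall points, a path independent of the
track-parsing / landfall-detection / counting code it validates; storm
counts per cell are Poisson with segment-class rates, and category-0
plus uncategorised storms are added to exercise the exclusion rules.
All randomness flows from one integer seed through split RNG streams,
giving bit-identical worlds per seed.

What the generator does not emulate: real storm climatology (tracks
are straight west-east crossings), tides, surge physics, spatial
autocorrelation of rainfall and population beyond the segment
structure, and mixed-class cells.  Passing the recovery tests therefore
certifies the pipeline's bookkeeping and classification logic, not the
realism of any particular map; the headline map magnitudes of any real
assessment depend entirely on the real input rasters and archive, which
are out of scope here.

## Problem sizes and numerical choices

The default test suite and the acceptance script run synthetic worlds
of 16 half-degree cells with ~90 storms, five seeds for the recovery
property — sizes at which every oracle (dense lattice sampling,
brute-force counting, per-cell recomputation) is exact and fast; the
full suite completes in a few seconds.  Enumeration analyses always use
the complete 729-point score space.  CVI is reported to 2 decimal
places in outputs with full precision kept internally; class decisions
never pass through the rounded value.  Degenerate inputs fail loudly:
empty coastlines, negative densities/rainfall/buffers, unknown
categories, non-finite elevations and partially attributed grids all
raise with the offending item named.
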