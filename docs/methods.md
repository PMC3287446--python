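# Methods

## Model and scope

`dui` treats a biodiversity data portal as a usage log plus a dataset
inventory. The basic observable is an *event*: at a timestamp, an
anonymized visitor key touched some records of a dataset by searching,
viewing, downloading, or taxonomy-downloading them, or viewed metadata
only. Indicators are computed for *units* — datasets, publishers,
countries, regions, ad-hoc species slices, or the world — over an analysis
window, and normalized by the unit's stored-record number r(u) and dataset
number N(u). The package computes; it does not scrape: live portal access,
IP geolocation and citation analysis are out of scope.

## Counting conventions

These conventions are centralized here because each one silently changes
every downstream number:

- **Windows are half-open** `[start, end)`. Events on a boundary belong to
  the following window, so partitioning a window never double-counts
  (asserted by an additivity test).
- **Bounces** — metadata-view events, plus search/view events touching
  zero records — are removed before any counting. The bounce fraction is
  reported but used nowhere else.
- **Searched records s(u)** merge search and view events; **downloaded
  records d(u)** merge download and taxonomy-download events. Downloads
  are counted whether or not a search precedes them in the log.
- **Sessions** split on an inter-event gap **≥ 30 minutes** (the rule is
  "at least 30 minutes", so exactly 30 minutes splits). A visitor key's
  first session is a unique search; each later session is loyal. Keys are
  opaque; no prefix coarsening is attempted.
- **Record number r(u)**: when every member dataset carries record ids,
  cross-dataset duplicates are counted once (national totals can be
  smaller than the sum over publishers); otherwise the plain sum is
  returned with `deduplicated=False`. No heuristic duplicate detection is
  attempted — only id equality.
- **r(u) snapshot convention** defaults to `end_of_window` (a fixed
  denominator per unit across a time series). With a single inventory
  snapshot, all conventions coincide.
- **Publisher size classes** from N(u): the verbal ranges overlap at their
  boundaries, so the half-open convention small < 10 ≤ medium ≤ 100 <
  large ≤ 300 < ultra_large is fixed in one constant table.
- **Zero denominators** make a ratio undefined (`None`), never 0, NaN or
  infinity; unique-record scores are unavailable (`None`) when the log
  carries no record ids.
- **Display rounding** is decimal half-up (via `decimal`, not `round()`,
  whose banker's rounding disagrees exactly at printed ties): two
  decimals, three for the usage balance, which is reported as a ratio by
  default with an opt-in percent rendering.

## Relative indices and the crown indicator

The relative index divides a unit's impact factor d/r by the baseline
aggregate's Σdᵢ/Σrᵢ over the n baseline units. The ratio-of-sums form is
deliberate: it weights large datasets more than averaging per-unit ratios
would, and it yields the identity that the r-weighted mean of member
indices is exactly 1 (a regression test). By default the baseline includes
the unit itself (the world contains everything); an exclude-self option
exists on the CLI.

Two input-rounding modes are provided. `full` (default) divides
full-precision impact factors. `paper` rounds each absolute impact factor
half-up to two decimals before dividing and rounds the index to two
decimals; this is the mode consistent with two-decimal printed tables
(6.50/0.32 = 20.31, where full precision gives 19.99). The package keeps
both because reproducing a printed table and doing new analysis are
different tasks.

The Usage Crown Indicator is implemented in the CPP/FCSm-style
ratio-of-sums form `UCI = d(u) / Σ_{s=1..p} r_s·U_s` with
`U_s = Σᵢd_{s,i} / Σᵢr_{s,i}` over the reference units. Only the p species
with r_s > 0 enter the sum. Species present in a profile but absent from
the baseline are a hard error: silently skipping them would change p and
bias the index. Species stocked nowhere are omitted from the baseline with
a warning (their expected rate is undefined, not zero). Two exact
identities follow and are asserted to 1e-12: UCI of the union of all
reference units is 1, and a single-species unit's UCI is its UIF over the
global species UIF.

## Synthetic generator

The generator emulates the portal-log structure the indicators assume, at
desk scale (defaults: 20 publishers, ~100 datasets, ~1e5 records, ~1e4 raw
events; seconds to run). What it models:

- heavy-tailed datasets-per-publisher (truncated Zipf) and
  records-per-dataset (truncated lognormal, σ = 2) — the long-tail
  structure, calibrated so the top decile of datasets holds > 50% of
  records;
- per-dataset species profiles via Dirichlet(0.3) draws over a global
  species list, so units have distinct, concentrated species mixes;
- sessionized visitor arrival: short exponential in-session gaps with
  occasional ≥ 30-minute pauses, so loyal-search logic is exercised;
- a 0.66 bounce fraction (metadata-only events);
- search events retrieving lognormal record counts (mean ≈ 28, matching
  the observed 18–50 per event) and download events following searches
  with probability 0.014 (matching observed usage balances of 0.9–1.8%)
  with lognormal sizes (mean ≈ 337, matching the observed 190–900);
  a tenth of downloads are taxonomy downloads;
- record ids ("dataset:index") always generated and partitioned over
  species in sorted order, so unique-record scores and species-level
  download attribution are exactly testable.

Randomness derives from one root seed; each consumer (inventory, species,
timing, events) draws from a named substream, so adding a consumer never
perturbs existing output, and a fixed seed is byte-reproducible. The
generator also returns the exact per-unit counts it injected (s, d, S, D,
U, I, n per dataset, publisher, country, region and world), which the test
suite requires the counting pipeline to match exactly over a spread of
seeded configurations.

What it does **not** model — and therefore what passing tests cannot show
about real logs: crawler/robot traffic beyond bounces, diurnal or seasonal
cycles, visitor-side popularity dynamics (dataset choice is proportional
to size only), record updates during a window, cross-dataset duplicate
records, or malformed log lines (exercised by separate parser fixtures).

## Numerical and degenerate-input choices

Counts are exact integers throughout; only final indicators are floats.
Rank-table ties break by unit id for reproducibility. The Gini coefficient
uses the standard sorted-sum formula and is checked against an O(n²)
pairwise-difference oracle; all-zero value vectors make both tail
statistics undefined rather than zero. Empty event files produce all-zero
reports with a warning, not an error. Snapshot manifests digest all inputs
with SHA-256, and a re-run under an existing snapshot label with changed
inputs fails loudly rather than silently recomputing.

## Known limitations

- Species names are opaque controlled strings; no synonym resolution, so a
  species split across names fragments its baseline rate.
- Duplicate detection needs explicit record ids; without them national
  aggregates overcount shared records (flagged, not corrected).
- Unique-record scores (U, I) require per-event record ids, which real
  portal logs expose only internally.
- Indicators carry no uncertainty estimates; a one-month window and a
  six-month window are compared only at the user's risk, as the worked
  examples themselves illustrate.
- The test-scale study (tens of publishers, ~1e5 records) is three orders
  of magnitude below a full network; properties asserted here are exact
  identities and calibrations, not performance claims at network scale.
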