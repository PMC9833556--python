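# Methods

## The analysis

The package answers one question: what fraction of a fish stock's
surveyed distribution falls inside each state's regulatory unit, and how
has that fraction changed since the historical period used to set quota
shares? The chain is: grid the EEZ → interpolate survey CPUE per
stock × year × season → construct per-state regulatory units → allocate
each gridded surface to states → period means, percent changes, contrasts
and running means.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes,
not any particular coastline.

* **Geography.** A rectangular EEZ east of a straight meridian coastline,
  subdivided latitudinally into equal state strips. Defaults: 11 states
  over 33.8–45.2° N, EEZ 3° wide, strips 0.2° wide. The strip width is
  deliberately wider than the statutory ~3 nm (~0.05°) so that a 0.3°
  analysis grid resolves at least one column of coastal cells per state;
  with literal-width strips the fishing-ports design would assign
  port-less states regulatory units containing no whole grid cell.
  Rectangles keep every geometric quantity analytically checkable
  (areas by the shoelace formula, distances in closed form).
* **Stock field.** Expected CPUE is an axis-aligned Gaussian bump
  (kg/ha). Its centre latitude advances by `drift` °/yr and sits
  `seasonal_offset`° further poleward in fall than in spring. Defaults for
  the bundled study: centre (−72.5, 37.0), drift 0.1 °/yr over 1980–2019,
  fall offset 1.5° (a seasonal migration of the magnitude scup-like
  stocks show between southern New England in spring and the Gulf of
  Maine in fall), spreads (1.0°, 1.5°), peak 50 kg/ha.
* **Observation model.** Stations are uniform in the EEZ (150 per
  year-season in the study); observed CPUE multiplies the expectation by
  LogNormal(0, `noise_sd`) with `noise_sd` = 0.6 — median-unbiased,
  strictly positive, right-skewed, the simplest model with trawl-like
  dispersion. Real surveys differ in ways this model does not capture:
  stratified-random (not uniform) station design, true zero catches,
  multimodal and depth-structured distributions, and gear/vessel changes.
  Passing tests therefore demonstrate correctness of the *computations*,
  not realism of any particular CPUE field.
* **Ports and landings.** Ports sit on the coastline at uniform random
  latitudes within each state's band (3 per state in the study). Annual
  landings of a stock at a port are proportional to the stock's expected
  CPUE averaged over a 0.5° neighborhood of the port and over both
  seasons, times LogNormal(0, 0.3) — so landings concentrate where the
  stock currently is, which is what makes the port-selection step
  meaningfully stock- and period-dependent.

One integer seed drives each generator call; a pipeline run derives all
generator seeds from the single config seed, and reruns are
byte-identical.

## Gridding

Cells of the regular lon/lat grid (default 0.3°) belong to the analysis
domain when their centre lies inside (or on the boundary of) the EEZ
polygon. Cell-centre membership, rather than area-overlap weighting, is
used everywhere — it matches the gridded-matrix treatment and keeps every
geometric step verifiable by independent per-centre tests.

## Regulatory-unit designs

**State-waters expansion.** Every strip is dilated symmetrically by one
common radius, the smallest (to 1e-3°, found by doubling then bisection)
for which the union of dilated strips covers the EEZ; dilations are
clipped to the EEZ. Because a point lies in the dilation of a polygon by
r exactly when its distance to the polygon is ≤ r, cell membership is
evaluated with the exact distance test instead of a discretized buffer
(the covering-radius search still uses polygon buffers, quad_segs = 16).
Cells claimed by k states take weight 1/k. Cells claimed by none —
possible only within the radius-search tolerance — fall to the state(s)
at minimum centre-to-strip distance, ties split equally. The dilation
mechanics are this package's choice: for rectangular geographies the
design reduces to the intuitive perpendicular extension of state bands,
but with symmetric overlap zones shared between neighbours.

**Fishing-ports buffering.** Per stock, per-port landings are averaged
over the landings period (period total divided by the number of period
years); ports with zero average are excluded from the universe, then
`round(threshold × n)` ports (half-up, floor 1; default threshold 0.25)
with the largest averages are selected, ties broken by total landings
across all stocks, then port name — deterministic across platforms. A
circular buffer (config radius; the bundled study uses 0.75°, roughly a
day-trip range) around each selected port, clipped to the EEZ, is
attributed to the port's state; membership again uses the exact distance
test. Every state additionally keeps the cells of its statutory waters,
so port-less states retain their coastal strip. Cells in buffers of k
distinct states take weight 1/k; cells in no buffer have no owner, so
this design can leave part of the EEZ unallocated.

Buffers and distances are planar in degree space; the synthetic
geography is defined in the same space, so no projection step exists to
disagree with. For real-coastline use a geodesic treatment would be the
first extension to make.

**Threshold sensitivity.** The sweep reports, per threshold and state,
both the owned-cell count and the summed cell weights. Only the count is
guaranteed monotone in the threshold: a state's owned set can only grow
with more of its own ports, but newly shared cells split their weight,
so weighted totals may dip.

## Interpolation

Stations of one stock × year × season are Delaunay-triangulated in raw
lon/lat; each cell centre inside the triangulation gets the unique linear
interpolant of the containing triangle (barycentric weights, via
scipy's LinearNDInterpolator). Values are therefore bounded by the input
CPUE range (so non-negativity is inherited) and linear fields are
reproduced exactly. Centres outside the convex hull are missing — the
survey is silent there — and missing cells count as zero CPUE in all
downstream sums, which keeps proportions well-defined and treats
unsurveyed area as holding no observed stock.

Repeat tows at one site (positions within 1e-9°) are merged by mean CPUE
before triangulating. Groups with fewer than three distinct sites, or
with all sites collinear, cannot support a triangulation; batch
interpolation skips them with a logged warning and a row in the skip
report, and period means simply exclude those years rather than imputing
them.

## Allocation statistics

Shares are held as fractions internally and become percentages only at
I/O boundaries, which avoids double-scaling in the change statistic.

* `α_s = Σ_c w(c,s)·cpue(c) / Σ_c cpue(c)`; the denominator includes
  cells owned by no state, so `Σ_s α_s + unallocated = 1` exactly.
* `Δα = (α_cur − α_ref)/|α_ref| · 100`, a *relative* percent change.
  A zero reference share makes Δα undefined; undefined values are carried
  as NaN and propagate through contrasts — never silently 0 or ∞.
* `Δα_reg = Δα_fp − Δα_sw` is computed on the spring surveys.
  `Δα_seas = Δα_f − Δα_s` is computed under one unit design, state-waters
  expansion by default, because it gives every state a defined reference
  share; the long-format outputs retain all method × season combinations
  for anyone wanting the other pairing.
* Running means are trailing windows (default 10 years) labelled by
  their final calendar year and emitted only for complete windows;
  calendar gaps (skipped interpolations) break the window.
* The quota comparison reports `α·100 − quota%` per
  state × stock × method × season using current-period mean shares. A
  table of current MAFMC quota percentages ships with the package for
  real-stock comparisons; synthetic runs, lacking an external quota,
  synthesize a baseline from reference-period spring state-waters shares
  normalized to 100 — i.e., "quota as if set from the historical
  distribution" — so the comparison measures drift since the reference
  period.

### Sign behaviour of the seasonal contrast

For a state at the leading (poleward) edge of a shifting stock, the
share α(c) as a function of the stock's centre latitude c is increasing
and log-concave (Gaussian tail masses are log-concave, and the grid
weights only smooth this). The relative growth rate d log α/dc is then
decreasing in c, so the season whose centre sits further poleward (fall,
under a positive fall offset) always shows the *smaller* relative change:
`Δα_seas = Δα_f − Δα_s ≤ 0` for the northernmost state, structurally,
under this generative model — the bundled study measures it strongly
negative. A positive fall-vs-spring signal for a northern state does
appear in the *proportions themselves* (its fall share exceeds its spring
share in every year), and in percentage-point differences of shares; it
cannot appear in differences of relative changes while the reference
shares are positive and the field is unimodal. Users comparing seasons
should decide which of the two contrasts answers their question.

## Numerical choices

* Covering-radius search tolerance 1e-3°; orphan-cell tie tolerance
  1e-12°.
* Duplicate-station snap tolerance 1e-9° (below survey position
  precision).
* Weight normalization and conservation are exact to 1e-12 in tests;
  interpolation oracle agreement to 1e-9.
* Port-count rounding is half-up with floor 1, so a selection is never
  empty.
* All tie-breaks (port ranking, orphan cells, equidistant states) are
  deterministic.

## Problem sizes

The bundled study runs 11 states, a 10 × 38 cell grid (0.3°), 40 years ×
2 seasons × 150 stations (12 000 survey records), 33 ports and a
five-point threshold sweep; it completes in about a second. The demo
configuration (2 states, 2 stocks, 20 years, 0.5° grid) exists for quick
smoke runs. Both scale linearly in years × seasons (one triangulation
each) and in grid cells.

## Known limitations

* Planar degree-space geometry; no geodesic buffering or real coastlines.
* The observation model has no true zeros, so reference-period shares are
  never exactly zero in synthetic runs, whereas real survey data would
  produce undefined Δα cells for fringe states.
* Unimodal single-stock fields; no depth structure, no onshore–offshore
  seasonal component (longitudinal offsets would be a one-line extension
  of the scenario type).
* The fishing-ports design depends on a buffer radius for which no
  principled default exists; it is a required configuration parameter.
* Missing-as-zero is a modelling decision, not a fact; surfaces with
  large unsurveyed areas understate shares of states whose units lie
  outside the survey hull.
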