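# Methods

## The measurement model

Each cytometer event carries a PI (propidium-iodide) DNA fluorescence, a
projected cell area, a gradient-RMS-like focus metric, and — on imaging
instruments — counts of nuclei, pyrenoids and accumulation bodies. PI
fluorescence is taken proportional to nuclear DNA content with
multiplicative noise: a cell of true content `c` (multiples of the haploid
amount) measures `F = F_1C · c · exp(ε)`, `ε ~ N(0, σ²)` with
`σ = sqrt(ln(1 + CV²))` so that the lognormal coefficient of variation is
exactly the configured CV. Multiplicative noise is the standard
description of cytometry peak width (peaks at higher content are
proportionally wider), and it is what makes the gating scale-covariant:
multiplying all fluorescences by k > 0 scales every gate boundary by k and
leaves compositions unchanged.

## The ploidy model behind the simulator

Stages map to DNA content as: vegetative 1C; mitotic S uniform on (1, 2);
mitotic dividing 2C; zygote 2C; meiotic S (replicating zygote) uniform on
(2, 4); dyad, triad and tetrad 4C. Dyads/triads/tetrads are simulated as
single 4C objects because the meiotic divisions are nuclear before they
are cytoplasmic: the whole product passes the detector as one event with
2–4 nuclei. The uniform within-S distribution is a simplicity choice — the
gating rules are agnostic to the within-S shape. Cell area scales as
`c^(2/3)` (volume to projected area) with independent lognormal noise of
the same CV; the exponent only needs to make coincident aggregates
(whose area and fluorescence are *sums* of two cells) separable from large
singlets.

Canonical morphology per stage (nuclei / pyrenoids / accumulation bodies):
vegetative and mitotic-S 1/1/1, mitotic dividing 2/2/1 (the accumulation
body stays single through mitosis), zygote and meiotic-S 1/2/2 (two merged
cytoplasms), dyad 2/2/2, triad 3/2/2, tetrad 4/2/2. Each observed count is
independently perturbed ±1 with probability `morphology_error_rate`
(default 0.01 — visual scoring of confocal/IFC images is occasionally
wrong), floored at 0 (1 for lobes).

Artifacts: debris has content uniform on (0.1, 0.7) (fragments well below
1C); aggregates are sums of two independently drawn non-artifact cells
(fluorescence, area and counts all summed); unfocused events are ordinary
cells whose focus metric is drawn from a low support (default [0, 20]
versus [40, 80] for focused events, with a configurable overlap).

Default study conditions: 40,000 events (the lower end of a typical
acquisition), 1.5% of cells in sexual stages with most of that mass in the
above-2C stages (zygote 0.05%, meiotic S 0.3%, dyad 0.4%, triad 0.35%,
tetrad 0.4%), a ~8% 2C mitotic compartment, noise CV 0.05, 1% debris, 1%
aggregates, 2% unfocused. The CV default is a stand-in — instrument CVs
for the PI channel are rarely reported — and is deliberately prominent in
the configuration. What the simulator does **not** emulate: time-course
kinetics, instrument drift, spectral spillover, cell-cycle correlations
between neighbouring events, or realistic image morphology (counts are
generated directly, not segmented). Passing recovery tests therefore
demonstrates the correctness of the gating/classification logic under the
stated noise model, not performance on any particular instrument's raw
data.

## Gating

1. **Focus filter.** Events with focus metric below threshold are removed.
   The automatic threshold is the deepest between-mode valley of a
   64-bin, 5-bin-smoothed histogram; a split bin qualifies only if each
   side holds ≥ 1% of events and the smaller flanking maximum is at least
   twice the valley density (so shoulders and tail stragglers do not
   split a unimodal distribution). If no valley qualifies the distribution
   is treated as unimodal and the 10th percentile is used — a deliberate,
   conservative trim when no unfocused mode is visible; pass an explicit
   threshold when the data are known to be all-focused.
2. **Singlet filter.** The singlet trend of area against fluorescence is a
   straight line on log–log axes. Its slope is the median pairwise slope
   over point pairs whose fluorescence differs by ≥ 1.5× — within one
   ploidy peak, both axes vary only by independent measurement noise, so
   cluster-internal pairs carry no slope information and would bias any
   all-pairs robust fit toward zero; cross-ploidy pairs carry the trend.
   Pairs are taken from a deterministic x-sorted stride of ≤ 1000 points.
   The intercept is the median residual. Events whose residual exceeds
   `residual_cutoff` (default 3.0) MAD-scaled units on the *high-area*
   side are aggregates (a two-cell aggregate sits ~26% above the trend,
   versus a residual SD of ~1.2 × CV). With fewer than 20 events the fit
   is refused.
3. **1C peak.** Highest-count bin of a 256-bin linear histogram on
   [0, max], ties toward lower fluorescence, refined by a quadratic
   through the bin and its neighbours; an isolated spike (empty
   neighbours) returns the mean of its in-bin values, exact for noise-free
   data.
4. **Delineation.** The 1C region is `[peak − w, peak + w]`. The peak SD
   is estimated as FWHM/2.355 from the 3-bin-smoothed histogram and
   `w = 6 σ̂` by default. The multiplier is chosen for the *2C* gate: the
   2C region is constrained to the same width as 1C, but under
   multiplicative noise the 2C peak has twice the 1C SD, so covering
   ±3 σ of the 2C peak requires a half-width of 6 σ in 1C units. (A bare
   FWHM gate, ±1.18 σ, would capture only ~76% of a Gaussian-like peak
   and ~50% of the 2C peak — visibly wrong on a histogram and fatal for
   stage recall.) The geometric mean of events inside the 1C region is
   computed in a single pass (no iterative re-delineation); the 2C region
   of identical width is centred at twice it; S is the open interval
   between; the hyper region runs to the brightest event. A 2C region
   overlapping 1C raises a degenerate-gating error rather than guessing.
5. **Assignment.** Half-open `[low, high)` intervals, with the hyper upper
   endpoint closed so the brightest event is gated; events below the 1C
   region are sub-1C debris and are excluded from the composition
   denominator (the three reported percentages then sum to 100).

Invariants asserted on every constructed gate template: boundary ordering,
1C/2C width equality, and 2C centre = 2 × geometric mean (both to 1e-9
relative tolerance).

## Stage classification

First matching rule wins: (1) 4 nuclei → tetrad; (2) 3 nuclei → triad;
(3) hyper gate + 2 nuclei → dyad; (4) hyper + 1 nucleus → meiotic S;
(5) 2C + 1 nucleus + 2 pyrenoids + 2 accumulation bodies → zygote;
(6) 2C + 2 nuclei + 1 accumulation body → mitotic dividing; (7) S or 2C +
1 nucleus + ≤1 pyrenoid + ≤1 accumulation body → mitotic S; (8) 1C + 1
nucleus → vegetative; (9) otherwise unclassified. Nuclear count outranks
gate membership for triads/tetrads because multi-nuclei objects are
identified by their nuclei wherever they fall on the DNA axis. Any count a
rule needs that is absent makes the rule inapplicable — missing morphology
degrades to *unclassified* rather than guessing. The tetrad label encodes
the two-step-meiosis interpretation; a two-round asynchronous mitosis
cannot be excluded on these features alone, and downstream users should
carry that caveat.

The sexual fraction counts zygotes, meiotic-S cells, dyads, triads and
tetrads over the gated denominator; the gate-level (>2C–4C) percentage —
the DNA-content-only sex metric — is always reported alongside and is, by
construction, identical to the gate composition's value.

## Statistics

Summaries use the sample SD (n−1). Z-scores are `(x − mean)/SD`. The
Kruskal–Wallis H uses pooled mid-ranks and the tie correction
`1 − Σ(t³−t)/(N³−N)`; p-values come from the upper chi-square tail with
k−1 degrees of freedom (for df = 2 this equals `exp(−H/2)`, used as a test
anchor), with an exact permutation variant for pooled n ≤ 12. An
all-identical pooled sample yields H = 0, p = 1.

For the packaged sample table, the (>2C–4C) percentages are standardized
before grouping. The default standardizes the 20 samples **pooled**; since
the rank test is invariant under monotone transforms, this is equivalent
to testing the raw percentages. A per-instrument variant (Z-scores within
the IFC and sorting arms separately, then pooled) is available via
`standardization="within_method"`; it removes the between-instrument scale
difference but also equates the two arms' spreads, and on this table it
shifts the time-of-day p-value from 0.037 to 0.058. Because the
standardization grouping is a genuine analysis choice, both variants are
first-class and every report names the one used. Diel grouping: 06:00 →
P1, 12:00 → P2, 18:00 and 00:00 → P3; off-schedule times map to the
nearest sampling time with a warning.

## Numerical and testing choices

* Determinism: one `numpy` generator seeded from the config drives every
  draw in a fixed order; identical (seed, config) gives bitwise-identical
  events, truth tables and JSON reports.
* Zero-noise configurations short-circuit the noise draw (`exp(0) = 1`),
  so degenerate-distribution tests are exact.
* Per-stage recall benchmarks use discrete-ploidy mixtures (no S-phase
  stages): S-phase DNA content is uniform on an interval *abutting* the
  1C/2C gates, so for any finite gate width a boundary sliver of S-phase
  cells necessarily lands in the adjacent gate — near-perfect per-stage
  recall is a property of the boundary, not of the classifier, and is
  only meaningful for stages whose content maps to a single gate.
* Gate-fraction recovery benchmarks place the configured sexual fraction
  in the above-2C stages, because the recovered quantity is the (>2C–4C)
  gate fraction and 2C-resident zygotes cannot appear in it by design;
  the morphology-confirmed sexual fraction is the metric that counts
  zygotes.
* Simulation sizes in the tests (2,000–40,000 events; a 3 × 3 CV ×
  prevalence grid at 40,000) are chosen to keep the full suite in the
  tens of seconds while leaving binomial tolerances (3 SDs, floored at
  0.5 percentage points) meaningful.

## Known limitations

* Single-channel DNA analysis: no compensation or spillover handling.
* The aggregate filter assumes a dominant singlet population; samples that
  are mostly aggregates would defeat the median-based trend.
* The automatic focus threshold trims 10% on genuinely unimodal data; use
  an explicit threshold for all-focused inputs.
* Event tables are CSV only (column-mapped); proprietary instrument
  workspaces must be exported to per-event tables first.
* The packaged sample table's published source prints "(< 2C–4C)" in one
  column head where the surrounding text reads "(> 2C–4C)"; the fixture
  treats this as a typographical inconsistency and uses the latter
  meaning. One sample row (6) sums to 98.4 rather than ~100 and is
  transcribed as printed.
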