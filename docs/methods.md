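# Methods

## The instrument and its scoring model

The hierarchical mapping technique presents a respondent with two
concentric-circle canvases. The respondent self-selects their five most
important relationships (from a 17-role menu with a write-in option — the
"child" category only arrives as a write-in) and drags one icon per
relationship onto each canvas.

* **Emotional diagram.** The centre is the self; radial pixel distance is
  the attachment-strength score, 0 (centre) to 700 (outside the third
  ring), lower = stronger. Scores to different figures are independent,
  which is what permits whole-network ("morphology") metrics that ordinal
  ranking scales cannot support.
* **Physical diagram.** The centre is home; the three rings anchor 10, 250
  and 500 miles; compass directions are marked, so the diagram is a genuine
  2-D map of where figures live relative to home *and to each other*.

All derived metrics are deterministic functions of the placement
coordinates, three pixel thresholds, and the ring calibration.

### Thresholds (pixels)

| parameter | default | meaning |
|---|---|---|
| `clear_cut_px` | 60 | inner-circle radius; a figure at or inside it is a clear-cut attachment figure (boundary inclusive) |
| `primary_tol_px` | 15 | figures within this distance of the top-rated figure share primacy, up to three |
| `hierarchy_gap_px` | 18 | one icon radius — the smallest visually clear difference in closeness, used for hierarchy classification |

The 15 px and 18 px cut-offs serve different constructs (multi-primary
identification vs. hierarchy shape) and are deliberately kept as separate,
individually configurable parameters rather than unified.

### Hierarchy classification

With sorted strengths `d1 <= d2 <= d3 <= ...` and gap `g`:
monotropic iff `d2 - d1 > g`; shared primary iff `d2 - d1 <= g` and
`d3 - d2 > g`; distributed otherwise. The three printed class descriptions
do not explicitly cover networks where both successive gaps are small but
`d3 - d1 > g`; the chained rule assigns these to *distributed*, which keeps
the classes exhaustive and mutually exclusive for every network of at least
three figures (property-tested over 10,000 random strength vectors). The
binary "hierarchy" code used in the regressions maps monotropic to 1 and
the other two classes to 0, monotropy being the only unambiguous hierarchy.
The class is undefined (an error, not a default) below three figures.

### Calibration and the mile map

Ring pixel radii are not part of the instrument's printed output, so they
are configuration, not constants. Defaults: emotional rings at 60/380/700 px
(the inner ring identified with the 60 px clear-cut radius, the outer edge
at the 700 px score ceiling); physical rings at 233/466/700 px (equal
spacing). An alternative tradition puts the middle physical ring at 150
miles rather than 250; this implementation uses 250, consistent with the
distance-band tabulation, and the anchor triple is configurable.

Pixels map to miles by piecewise-linear interpolation through
(0, R1, R2, R3) → (0, 10, 250, 500), extrapolating past R3 at the last
segment's slope. This is the simplest monotone map exact at every anchor;
it is invertible, and the round trip is tested to 1e-9.

Between-figure distances are computed **in the mile plane**: each placement
keeps its bearing from home while its radius is mapped to miles, and pairs
are differenced there. Converting pixel-space chords directly would be
dimensionally meaningless because the radial scale is nonlinear; the
mile-plane construction makes centre distances and pairwise distances
commensurable, and makes density rotation-invariant (tested). Screen
convention: canvas y grows downward, so north is −y in pixels; the mile
plane flips it so +y is north, +x east.

Placements beyond the 700 px canvas radius are retained and flagged
(a warning plus a `beyond_canvas` predicate), never clipped — "outside the
third circle" is a legitimate score, and the >500-mile band extends past
the outer ring through the extrapolation.

### Composition conventions

Boundary values count as inside (`<=`) at every cut-off. Ties at identical
strength break by a fixed canonical role order
(partner, mother, father, sibling, friend, child, other), then
alphabetically, so primary sets are deterministic. Raw role labels are
normalised by a configurable alias table ("daughter" → child, "sister" →
sibling, unknown write-ins → other). Centrality averages over all placed
roles even when fewer than five were placed; the number placed is recorded.
Emotional (attachment) density is deliberately not computed: respondents
never place figures relative to each other on the emotional diagram.

## The synthetic-participant generator

The generator emulates the *structure* of the study sample so every
pipeline stage is testable without raw data:

* **Demographics.** Age-group sizes 288/304/276/62 per 930, with
  within-group gender, romantic-status and parental-status probabilities
  from the same table; ages uniform within bin, capped at 80.
* **Roster.** Always five roles: a romantic partner iff not single; a child
  only for parents, with probability `sigmoid(-0.5 + 0.05 (age - 45))` —
  calibrated once so about 38% of parents list a child and the
  point-biserial age–child-listing correlation is ≈ 0.22; remaining slots
  drawn without replacement from mother/father/sibling/friend/other.
* **Emotional placements.** Each network draws a hierarchy-class target from
  the mixture (default 69.8/17.2/13.0%) and a clear-cut-count target
  (default 8.2/30.3/33.3/18.2/5.2/4.8% over 0–5). Sorted radii are sampled
  *constructively* inside per-position feasible intervals that realise both
  targets exactly, with bounded retries; a genuinely infeasible pair
  triggers a redraw of the count from its distribution truncated to
  feasible values. Recovery by the scoring pipeline is therefore exact per
  network (tested), and any aggregate deviation from the mixture is pure
  sampling noise in the target draws. Roles attach to sorted radii through
  a weighted preference ordering (Gumbel perturbation of log-weights) that
  makes romantic partners the modal primary figure. Bearings are uniform.
* **Physical placements.** Per role, a distance band is drawn from that
  role's band frequencies (the "other" role borrows the friend profile, as
  it has no printed row); miles are uniform within the band, with the open
  top band truncated at 3,000 miles (continental scale, configurable);
  pixels come from the inverse calibration map; bearings are uniform.

Determinism: one run seed feeds a `numpy.random.SeedSequence`, which spawns
one substream per participant, so individual records are stable under
partial regeneration and full runs are byte-reproducible.

**What the generator does not emulate:** role-specific age trends in
attachment strength, the correlation structure between emotional and
physical placements, status effects on the hierarchy mixture (exposed as
optional logit shifts, default off), recruitment bias, or attention-check
failures. Tests passing on synthetic cohorts therefore validate the
*scoring and tabulation machinery*, not substantive claims about real
attachment networks.

## Statistical machinery

Pearson correlation (two-sided p via the t transform on n − 2 df), one-way
ANOVA (between/within sums of squares; F = t² for two groups, tested), and
the block-sequential OLS are implemented directly on numpy, with
scipy.stats and statsmodels serving as independent oracles in the test
suite. The sequential model puts age and the two status dummies (parental
0 = no child / 1 = child; romantic 0 = no partner / 1 = partner) in block 1
and all pairwise products of the *centered* block-1 columns in block 2;
standardized β is the raw coefficient times sd(x)/sd(y), taken from the
block-1 fit for main effects and the full fit for interactions. R² is
non-decreasing across blocks by construction (tested).

Constant and collinear predictors are dropped before fitting and recorded
on the result — this is the expected behaviour on per-role subsamples,
where the romantic dummy is constant among partner-raters and the parental
dummy among child-raters, and it reproduces the reduced three-predictor
models those outcomes require. Degrees of freedom are always computed from
the rows actually used. p-values are unadjusted by default, matching
common practice for these tables; a Benjamini–Hochberg helper is available
for users who want q-values. Per-role analyses use listwise deletion, i.e.
only participants who placed that role.

## Problem sizes and numerical choices

Simulation-based tests use 2,000 networks (mixture/count/band recovery,
judged at three binomial standard errors) and up to 10,000 random vectors
for the classification property suite; the acceptance script simulates
2,000 networks. These sizes put the Monte-Carlo error well inside the
tolerances being checked while keeping any run to a few seconds. Interval
sampling in the constructive sampler uses an epsilon of 1e-6 px at open
boundaries; rank decisions in the regression use a 1e-8 singular-value
tolerance; report files are written with a fixed six-decimal float format
so reruns are byte-identical.

## Known limitations

* Exact reproduction of the study's data-dependent coefficients and means
  is out of reach without the raw placements; the package reproduces the
  printed *arithmetic* (percentages from counts) through its own
  tabulation code paths and checks everything else by oracle equivalence
  and parameter recovery.
* The socioeconomic-status composite and survey-delivery concerns
  (recruitment, attention checks) are out of scope.
* The chained hierarchy rule's treatment of the `d3 - d1 > g` corner case
  is a documented convention, not an empirically validated choice.
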