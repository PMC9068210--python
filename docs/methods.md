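# Methods

## The staging model

Functional (erupted) teeth pass through four ordinal wear/maturity stages:

| stage | defining criteria |
|-------|-------------------|
| F1 | no or slight denticle wear, pulp cavity open at the tip |
| F2 | worn denticles, slightly concave lingual wear facet |
| F3 | extensive wear, concave facet, plus a root-resorption depression or a replacement bud |
| F4 | polished denticles, highly concave facet, plus a broken pulp cavity or an emerged successor |

Unerupted replacement teeth pass through three: R1 (crown tip only), R2
(crown complete), R3 (crown apex at the base of the functional crown).

`stage_functional_tooth` treats the descriptions as conjunctions and
returns the highest stage whose criteria are met, with wear and facet as
ordinal thresholds (worsening either can never lower the stage) and
explicit conflict detection (e.g. heavy wear with an open pulp cavity is
contradictory, since open cavities mark newly erupted teeth). A tooth
exceeding F1 but not reaching F2 is conservatively staged F1.

Both ladders unify onto one 7-step maturity score, R1=1 … R3=3,
F1=4 … F4=7. Placing all R-stages below all F-stages encodes that an
unerupted successor is younger than any erupted tooth; it is what lets a
Zahnreihe descend from an old functional tooth onto the replacement tooth
of a more caudal position. The published analyses plot both tooth kinds on
a single "replacement stage" axis without stating its numeric coding; the
1..7 ladder is the unique order-preserving choice consistent with the run
memberships they list, but the specific integer values are a convention
of this package.

## Zahnreihe segmentation

Each staged tooth is a point (position, score); a position undergoing
replacement contributes two points. Segmentation is greedy and
rostral→caudal: start a run at the rostral-most unassigned point and
repeatedly extend it to the nearest caudal unassigned point with a
strictly lower score. Two rules matter:

* **Gap tolerance** (`allow_gap`, default 1) applies only to *empty*
  positions — empty alveoli or unrecorded positions. A position that has
  points but offers no eligible candidate terminates the run: maturity
  descends tooth by tooth along a wave, so an ineligible occupied position
  marks the boundary with the next wave. (Allowing runs to skip occupied
  positions lets them capture the next wave's replacement teeth and
  systematically inflates the estimated spacing at true Z < 2.)
* **Functional first**: where a position offers both a functional and a
  replacement candidate, the functional point is consumed first.

Runs of length ≥ 2 become Zahnreihen; leftover single points are
*exceptions*, reported but excluded from spacing estimation. Runs are
indexed rostral→caudal by first position; when two runs start at the same
position (one functional-led, one replacement-led), the lower-scoring run
is indexed first, because at any shared maturity level it sits more
rostrally. Without this tie-break, adjacent-pair offsets can come out
negative at observation times where both wave phases straddle stage-bin
boundaries.

Equal scores never continue a run (strict descent). Under these rules the
greedy partition is minimal: each occupied position holds at most one
functional (score 4–7) and one replacement (score 1–3) point, runs can
only link consecutive occupied positions, and case analysis of the
resulting layered graph shows the greedy local choice always achieves the
per-boundary maximum matching. The test suite confirms equality with an
exhaustive minimum-run-cover oracle on random small rows.

## Z-spacing

For each adjacent pair of Zahnreihen, the spacing is the mean positional
offset at every integer maturity level shared by both runs' score ranges;
a run's position at a level is read off by exact match or linear
interpolation between its points. Pairs with disjoint score ranges are
skipped and flagged. The quadrant's mean spacing is the arithmetic mean
over pairs; it is undefined with fewer than two runs. This score-matched
construction yields position-unit values, is symmetric in stage, and
returns exactly 2.0 for pure alternation.

Pooled summaries (e.g. a taxon mean across quadrants) use
`aggregate_mean_spacing`: arithmetic mean with decimal half-up rounding to
2 places, the convention used for published Z-spacing summaries.

Regional means split pairs at the row midpoint: a pair is rostral when its
midpoint position is ≤ half the row length. The wave direction is called
from the mean spacing with a band of ±`eps` (default 0.05) around 2.0
treated as alternation; above the band → rostral-to-caudal, below →
caudal-to-rostral, undefined → undetermined.

## Replacement ratios and ontogeny

`replacement_ratio` counts functional and replacement records per
quadrant (empty alveoli and remnants never count) and returns RT/FT.
`ontogenetic_series` orders specimens by ascending skull length (cm) and
flags whether the ratio is non-increasing along the ordering (ties
allowed); sides are pooled by default, since published ontogenetic tables
mix sides — `per_side` is available for symmetry checks.

## The wave simulator

The generative model embeds the wave pattern in continuous time: the
replacement cycle of the tooth family at position p has phase

    phase(p) = frac(t/cycle − p/Z)   ∈ [0, 1)

so families exactly Z positions apart are in phase and more caudal
families lag (rostral teeth are more mature within a wave). Phase is
discretized by five cumulative stage-duration weights into the observable
states {F1}, {F2}, {F3, R1}, {F4, R2}, {F4, R3}: late functional wear
co-occurs with a developing successor, exactly as in the staging criteria
(a bud is an F3 criterion, an emerged successor an F4 criterion).

Parameters and defaults:

* `n_positions` (13) — alveolar positions; 13 matches a typical maxilla
  of the packaged taxa.
* `z_true` (2.5) — true Z-spacing, position units.
* `cycle` (1.0), `t` (0.0) — cycle duration and observation time
  (arbitrary units; only t/cycle matters).
* `stage_weights` (0.2 each) — relative durations of the five phase bins.
  No empirical stage-duration data exist, so equal weights are the
  neutral default; recovery behaviour under unequal weights is
  exploratory.
* `noise_p` (0) — probability a point's maturity score is perturbed ±1.
  The perturbation is clipped to the tooth kind's score band (functional
  4–7, replacement 1–3) so simulated quadrants always satisfy the
  dentition invariants.
* `missing_p` (0) — probability a position is recorded as an empty
  alveolus.
* `seed` — all randomness flows through one `numpy` generator.

What the simulator emulates: integer-position sampling of a periodic
maturity wave, co-occurring functional/replacement records, empty alveoli,
ordinal observation error. What it does not: tooth-size growth, jaw
growth, remnant formation, resorption geometry, position-dependent cycle
length, or multi-generation replacement (at most one successor per
position, as in the packaged taxa). Passing recovery tests therefore show
the estimator inverts this idealized wave model, not that real dentitions
satisfy its assumptions.

`run_recovery_experiment` draws the observation time uniformly over one
cycle per replicate (randomized t avoids aliasing at integer Z), simulates
with independent sub-seeds, runs the full pipeline, and reports the mean
estimate, bias and RMSE per true Z, counting replicates with undetermined
spacing separately. At the default study conditions (n = 16 positions,
200 replicates, zero noise) bias is within ±0.05 for Z ∈ [1.5, 3.5];
the residual negative bias at large Z comes from row-edge truncation of
terminal runs and from occasional plateau breaks (strict descent splits a
wave when two of its positions round to the same score). Noise
degradation is summarized by the grid-mean RMSE, which rises
monotonically over noise 0 → 0.1 → 0.2.

## Fixtures

Five packaged CSV fixtures transcribe the published specimen data: the
staged right maxilla of IVPP V18638; the four-skull *Yinlong* ontogenetic
series; per-quadrant counts for CT-studied ceratopsians; the six jaw
quadrants of the *Chaoyangsaurus* holotype; and the *Hualianceratops*
left dentary. Conventions:

* Count-only fixtures carry `stage=NA`; empty alveoli are explicit
  `empty_alveolus` rows so functional counts never silently include them;
  unpreserved quadrants are absent, not zero.
* Damaged elements carry `incomplete=true` (counts are minima).
* Values published only as counts get synthetic within-row positions,
  tagged `provenance=derived`; only counts are asserted on such rows.
  The V18638 stage values are likewise tagged: per-tooth stages were
  published only graphically, and the packaged values are the
  reconstruction consistent with the listed run memberships and the
  stated open pulp cavities of M3 and M9.
* Where the published tables and text disagree (some alveolus counts of
  the mid-sized *Yinlong* skulls; the holotype's dentary replacement
  count), the fixture follows the tabulated counts and the header comment
  records the discrepancy.
* Second-generation replacement teeth of *Liaoceratops* are labelled
  "(2nd)" and placed at their own synthetic positions, preserving record
  counts while keeping at most one replacement record per position.

## Numerical choices and degenerate inputs

* Direction band `eps = 0.05`: published usage treats 2.0 as exact;
  the band absorbs float noise in interpolated spacings.
* Spacing interpolation is linear in position along a run; levels are
  matched only over the shared integer score range.
* Fewer than two Zahnreihen → mean spacing `None` → direction
  `undetermined`; empty point sets → empty report; a region with no
  pairs → regional mean `None`; zero functional teeth → replacement
  ratio is an error, not infinity.
* `aggregate_mean_spacing` uses decimal half-up rounding (not banker's)
  on the shortest-repr decimal of the mean.
* Fractional Z with `frac()` at exact bin edges: the phase-to-bin map
  uses right-closed cumulative edges and clamps round-off at 1.0 into the
  last bin.

## Known limitations

* Z-spacing estimates from short rows (≲ 10 positions) carry edge bias
  of order −0.05 to −0.2 at Z ≥ 3; report row lengths alongside spacings
  when comparing taxa.
* The estimator assumes at most one replacement generation per position;
  dentitions with stacked successors (dental batteries) are out of scope.
* Premaxillary rows of the packaged taxa are count-only; no premaxillary
  Zahnreihen are computed.
* Absolute replacement rate in days is not estimable from these data and
  is not attempted.
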