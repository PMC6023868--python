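# Methods

## The assay being modelled

A subject zebrafish (alone or in a shoal of up to 15) leaves a holding area,
crosses a circular decision zone ~46 cm in diameter, and commits to one of
two destination arms of a Y-maze (arms 46 × 23 cm; the 20 cm water depth is
ignored — analysis is 2D, as in overhead video tracking).  Conspecific
silhouettes are projected into the zone: *leaders* head ballistically for a
target arm chosen at random per trial, *distractors* wander.  The design
crosses coherency *C* ∈ {0, 0.33, 0.67, 1} (leader fraction; 0.66 and 0.67
are synonyms for 40 of 60 silhouettes), relative leader speed Δv ∈ {1, 10}
(× 3.5 cm·s⁻¹ baseline, one body length per second), and shoal size
N ∈ {1, 5, 10, 15}.  Responses are the arm choice (accuracy), the time to
act T_A (gate opening → arm entry, which includes social recruitment in the
holding area) and the decision time T_D (zone entry → arm entry).

Coordinates: origin at the decision-zone centre, cm units, holding arm
along −y, destination arms at ±120° from it.  The holding area is a
rectangle abutting the zone along −y (its exact shape is not critical; only
the gate side matters for scoring).  A decision is the first crossing from
the decision zone into an arm; later re-entries are ignored because the
assay scores one choice per trial.

## Stimulus simulator

- Distractor turning: wrapped Cauchy centred on the current heading.  The
  30° spread is read as the circular standard deviation, so the
  concentration (= mean resultant length) is ρ = exp(−σ²/2) ≈ 0.8719.  The
  wrapped Cauchy has no linear moments; the circular SD is the standard
  reading of a "standard deviation" for a circular distribution.
- Time step 1/60 s (60 fps refresh); per-step displacement is
  speed × dt exactly, so a Δv = 10 leader covers 35 cm·s⁻¹.
- Boundary: a silhouette that leaves its visible region fades at
  (speed / baseline) × dt per frame — the fade constant is fixed so a
  baseline-speed silhouette vanishes in 1 s, preserving the stated
  proportionality to speed — then respawns uniformly inside the zone with
  the same role, keeping both the silhouette count and the leader fraction
  constant at every frame.  Distractors keep their heading on respawn;
  leaders re-aim at the trial's target arm (the target is trial-constant).
- Leader visible region: the zone disc, optionally extended 13.8 cm back
  toward the holding arm (a capsule) for the group-size experiment, where
  mass leader disappearance at an arm entrance was a concern.  The
  group-size experiment also reduces the silhouette count; 20 is the
  default (the count was shown to have no discernible effect, and no exact
  number is on record).
- In the C = 0 null condition all silhouettes are distractors moving at the
  treatment speed (`null_fast`), so the speed manipulation exists in the
  null cells without any directional information.

## Generative fish model

The live recordings are replaced by the minimal generative structure whose
output carries the analysed patterns; it is not a locomotion model.

**Departures (time to act).**  Each fish leaves the holding area with
hazard `latency_rate × (1 + social_hazard_boost × n_departed)`.  Defaults:
`latency_rate = 0.05 s⁻¹` (median solitary departure ≈ 14 s, a realistic
holding-area latency) and `social_hazard_boost = 15`.  With strong social
amplification the subject's median departure approaches the first-departure
time of the pooled process, Exp(N·λ), whose median scales as N⁻¹; boost 15
puts the fitted exponent near −0.9 over N ∈ {1, 5, 10, 15}, inside the
observed power-law range.  With boost 0 the model collapses to i.i.d.
exponential latencies (the null social model).  A
`subject_rate_multiplier > 1` biases the subject toward the front half of
the decision order; the default is 1 (exchangeable fish).

**Choices.**  P(correct) combines a visual-cue weight with logistic social
feedback in N_c, the signed tally of companions that decided first
(correct − incorrect):

    P = clip( w + (1 − w) · 1/(1 + exp(−a(N_c − b))) )

The cue weight w is solved so a solitary fish (N_c = 0) follows the target
arm with exactly `p_follow_fast = 0.85` (Δv = 10) or `p_follow_slow = 0.44`
(Δv = 1), the observed solitary rates; the logistic defaults a = 0.52,
b = 0.07 are the reported slow-cue fit.  For p_follow_slow = 0.44 the
solved w is slightly negative (−0.1) — the clip keeps probabilities valid.
At C = 0 there is no cue; "correct" means matching the program's random arm
designation and the social term is scaled by 2 × 0.25, which yields the
25 % two-independent-choices chance level when feedback is flat and lets
social feedback still operate in null cells (this generalisation to group
null cells never arises in the emulated group design, which fixes
C = 0.67).

**Choice scheduling and the speed–accuracy trade-off.**  Transit times T_D
are gamma-distributed with mean ± SD 2.6 ± 2 s when correct and
1.3 ± 0.8 s when incorrect.  Solitary fish draw their outcome first
(N_c = 0) and their transit conditioned on it — the full trade-off, which
is where the assay measures it (rank-sum on solitary transit times).  In
groups, conditioning every fish's transit on its own outcome would let the
outcome shift the fish's own crossing time and hence its own measured N_c,
biasing the fitted social slope (measured attenuation: â ≈ 0.33 for a
generating slope of 0.5).  Group trials therefore draw the crossing
schedule first — transit times from the correctness-marginal mixture — and
then commit each fish in crossing order with P(correct) evaluated at the
exact tally of earlier crossers, the same tally the social ledger
reconstructs.  This makes P(correct | N_c) exactly logistic by
construction, while a time–accuracy correlation still emerges in groups
through social drift (later crossers face larger tallies) and weakens as
shoals grow — matching the observed decay of that correlation with group
size.  Ties in crossing times are broken by fish id.

**Trajectories.**  Tracks at 10 Hz exist so the kinematics module has
realistic input: stationary in the holding area until departure, a straight
approach (holding position 3 cm behind the zone boundary), a tapered
sinusoidal meander along the entry→arm chord whose traversal time equals
the drawn T_D (the implied transit speed, ~4–9 body lengths·s⁻¹, is a brisk
crossing rather than the 1 FL·s⁻¹ cruising speed), then 1–2 s into the
chosen arm.  Segment boundaries snap to the frame grid so decision
extraction recovers the scheduled times exactly; the stored decision
records are re-derived from the tracks to guarantee agreement.  Trials are
censored at 120 s; non-deciders sit in the holding area and are excluded
from median T_A by default (inclusion at the censoring time is available
behind a flag, since the original treatment of non-deciders is ambiguous).

**What the generator does not emulate:** hydrodynamics, body shape,
pairwise spacing and collision avoidance, learning across trials, within-
zone exploration loops, or any dependence of departure rate on the stimulus
itself (decision *speed* was unaffected by the visual treatments in the
assay, so departures are treatment-independent here).  Passing tests
therefore show that the analysis chain recovers the statistical structure
the generator encodes — not that real fish follow these mechanisms.

## Statistics

- `exact_binomial_test`: exact two-sided p by the small-likelihood method
  (point probabilities ≤ P(X = k)·(1 + 10⁻⁷) are summed), the convention of
  mainstream statistical software; it reproduces the assay's printed
  p-values (0.268, 0.419, 0.14, 0.585) from the printed counts.  The
  printed P = 0.002 for the 46/8 solitary follow split is not reproducible
  from any obvious binomial null (p0 = 0.5 gives ~2×10⁻⁸); the proportion
  0.85 is used as the anchor instead.
- `sat_comparison`: Mann–Whitney U (pairs with x > y plus half ties), exact
  for combined n ≤ 20 without ties, otherwise tie-corrected normal
  approximation.
- `logistic_social_fit`: ML logistic fit via logit p = β₀ + β₁·N_c with
  a = β₁, b = −β₀/β₁ (delta-method SE for b); complete separation is
  flagged as non-convergence, never silently reported.  N_c levels with a
  single observation can be merged into their nearest populated level
  (`merge_singletons`), the package's alternative to dropping such rows
  for rank deficiency; the number of affected rows is reported.
- `powerlaw_fit`: OLS of log(median T_A) on log(N); needs ≥3 distinct
  positive group sizes.
- `accuracy_regression`: fixed-effects logistic regression (Wald z) with
  optional within-subject permutation p-values — outcomes are shuffled
  within each subject's block, preserving subject-level accuracy while
  breaking factor association.  This is the deliberate substitute for
  random-effects mixed models, which are out of scope; mixed-model test
  statistics are therefore not comparable quantities here.
- Multiple-comparison adjustment, where requested, defaults to Holm (the
  original adjustment method is unstated).
- α = 0.05 throughout.

## Numerical and size choices

- Wrapped-Cauchy sampling by inverse CDF; MRL checks use
  SE = sqrt((1 − ρ²)/(2n)).
- Per-trial RNG streams are spawned from the master seed keyed by trial
  index, so adding trials never perturbs existing ones and runs are
  byte-reproducible.
- Turning arcs use sin(θ) of the full angle even for θ > 90° (non-monotone
  there, but such turns are rare — a diagnostic counter reports them);
  zero-length velocity steps give an undefined (NaN) arc.
- Running-median endpoints pass through unchanged (length preservation);
  the 3-step window does not define a truncated-window rule.
- Tracks default to 10 Hz; the sampling rate is always carried by the
  Track, never hard-coded, since both 10 and 12 fps appear in the emulated
  workflow.
- Simulation sizes in the test suite and acceptance script (for example
  10⁴ hazard replicates per shoal size, 100 recovery datasets of 2000
  decisions, 10⁴ silhouette frames over 20 seeds) were chosen as the
  smallest runs whose Monte-Carlo error is comfortably below the tolerances
  being checked.

## Known limitations

- The cue-weight mixture cannot simultaneously anchor the solitary Δv = 1
  follow rate (0.44) and make the group-level slow-cue choice law exactly
  the reported logistic curve (whose value at N_c = 0 is 0.49); the
  defaults anchor the solitary rates, and slope-recovery analyses use the
  neutral-cue law.
- The full-trajectory T_A includes the holding→zone approach and T_D, so
  its power-law exponent is shallower than that of the departure process
  itself; the scaling analyses quote the departure-process medians.
- The silhouette simulator is not an observer model: no retinal geometry,
  contrast, or flicker; the fade/respawn constant is a modelling choice
  constrained only by proportionality to speed.
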