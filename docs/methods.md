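# Methods

This note documents the models, numerical choices and known limitations of
`dyadrel`: what is computed, why the defaults are what they are, and what the
synthetic test bed does and does not establish about real data.

## Observables

A dyad's state at time t is S = (δ, v^g, ω, η): interpersonal distance,
group-velocity magnitude (norm of the *mean* velocity vector — opposed
walkers have v^g = 0), relative-velocity magnitude, and the absolute
body-height difference.  All four are symmetric under swapping the peers and
nonnegative.  Internally everything is seconds and meters; file readers
convert declared units (mm, cm, ms) on ingestion.

Trackers deliver tracks at heterogeneous rates and phases, so the two tracks
of a dyad are linearly interpolated onto a common uniform grid over their
overlapping time span before anything else.  Defaults: grid step 0.5 s,
velocity from finite differences between the farthest neighbours within a
1.0 s window (at a 0.5 s grid this is the plain centered difference;
one-sided at the ends).  Height is a single scalar per pedestrian, so η is
constant along a trajectory.  No validity filtering happens at extraction;
raw observables remain inspectable.

## Empirical distributions

Per relation and observable a 1-D histogram with fixed geometry:

| observable | range        | bins | width    |
|------------|--------------|------|----------|
| δ          | 0–2 m        | 80   | 2.5 cm   |
| v^g        | 0.5–2 m/s    | 90   | 1.67 cm/s|
| ω          | 0–0.5 m/s    | 60   | 0.83 cm/s|
| η          | 0–1.125 m    | 150  | 0.75 cm  |

The lower v^g bound separates walking from standing (the standing-speed
mixture component lies below 0.5 m/s); the δ cap encodes that pairs further
than 2 m apart are not behaving as a group.  Bins are half-open with the last
bin closed; a 1e-9-bin nudge keeps values sitting exactly on an edge in the
upper bin despite floating-point division error, and fitting uses the same
index rule as likelihood lookup so boundary values can never disagree
between training and evaluation.

An event out of range on *any* observable is dropped from *all four*
histograms ("joint exclusion"): the factorized likelihood of Eq.-style
P(S|r) = Π P(s_k|r) must be built from the same event set in every factor.
Events, not dyads, are the pooling unit — long trajectories contribute more
mass, consistent with the per-event classifier they feed.  No smoothing is
applied to the empirical pdfs (an optional ε-mass regularization exists for
the KL divergence only, default 1e-10 on empty target bins).

The hierarchical stage-1 model collapses families/couples/friends into one
"leisure" pdf per observable as the convex mixture weighted by training-set
dyad counts; "work" is the colleagues pdf unchanged.

## Bayesian (event-based) classifier

Posterior per event: P_t(r|S) ∝ P_t(S|r) P_t(r), normalized over the
categories in play (the evidence term cancels).  Prior update:
P_t(r) = (1−α) P_0(r) + α P_{t−1}(r|S).  α=1 (default) chains each posterior
into the next prior; α=0 keeps the initial prior fixed.  P_0 is uniform by
default, or the training-set representation rates.  Priors reset to P_0 at
the start of every dyad.

Degenerate cases follow two distinct rules.  A zero likelihood for *some*
categories simply zeroes those posterior entries — the behavior has never
been seen in those categories; under α=1 such a zero is permanent for the
rest of the trajectory.  A zero for *all* categories, or an out-of-range
event, carries no information and emits the uniform posterior.  By default
that uniform posterior also feeds the prior update (the literal reading of
the update rule); `freeze_prior_on_invalid=True` instead leaves the running
prior untouched across invalid events.  Consequently, with the default
propagation an all-zero or out-of-range event acts as a soft reset and can
revive an α=1-zeroed category; across uninterrupted in-range stretches the
permanence guarantee holds exactly, and the test suite asserts it in that
form.

Per-event decisions are argmax with exact ties broken uniformly at random
from a seeded generator; trajectory-level decisions are the plurality of
per-event winners, ties again seeded-random.

## Functional-metric (trajectory-based) classifier

The dyad's own four histograms (same geometry, built from its in-range
events) are compared against each category's by a per-observable distance
summed over the four dimensions, and the category of minimal distance wins.
The default distance is the 1-D Wasserstein-1 (EMD) computed in closed form
as Σ|CDF_p − CDF_q|·bin_width, which equals the transportation-LP optimum
with |bin-center difference| costs; the four-dimension sum is an upper bound
of the joint EMD for product measures.  Summing EMDs across observables adds
meters to meters-per-second; only the argmin is used, so the mixed units are
harmless, and an optional per-dimension range normalization is available.
KL (directed as D(dyad ‖ category), configurable) and JS are alternatives.
No pseudo-probabilities are derived from distances: the assignment is
purely discrete.  A dyad with zero in-range events is unclassifiable by this
route and is dropped from metric evaluations with a warning.

## Evaluation protocol

Dyad-level (never event-level) random splits: 30% training, 70% test, 50
repetitions by default, reporting per-cell means and standard errors of
row-normalized percentage confusion matrices.  A repetition whose training
or test half misses a category in play is resampled with a logged warning.
Three protocols: flat 4-way; hierarchical stage-1 (work vs leisure, reported
as 2×2 and as 4×2 with detailed ground-truth rows); hierarchical stage-2
(families/couples/friends among leisure dyads only, refit on the leisure
part of the training split).  The families-with-children restriction keeps
only family dyads with a member aged ≤ 15 (other categories untouched).

The median-length filter keeps trajectories whose event count is *strictly*
greater than the median of the evaluated set, measured in events, and is
applied to the test side only — both choices ours, made once and documented
here because the protocol's source leaves them open.

Conditional independence of observables is checked with the normalized
entropy distance 1 − I(X;Y)/H(X,Y) on the 2-D histogram of paired values
(1 = independent, 0 = deterministic; constant inputs return 1 by
convention).

## Synthetic dyad generator

The generator exists so that every module — extraction, fitting, both
classifiers, the protocols — can be exercised end-to-end without external
data.  Its category profiles are *synthetic calibration choices*, not
measured distributions; what they preserve is the qualitative structure of
real dyads:

* δ modes ascend couples (0.55 m) < families (0.65) < friends (0.75) <
  colleagues (0.90);
* v^g displaced upward for colleagues (1.45 m/s vs 1.10–1.20);
* ω lowest for couples (0.07 m/s), highest for colleagues (0.17);
* η half-normal with heavier scale/tails for families (0.17 m, 25% drawn at
  3× scale) and couples (0.12 m, 15%) than colleagues/friends (0.055–0.07 m).

Mechanics: per dyad, target levels are drawn around the category profile
(between-dyad spread 5–6 cm and cm/s); per event, δ, v^g and ω follow
stationary AR(1) series around those targets (within-dyad spread 8–15 cm,
timescales 8 s for δ and 5 s for the speeds).  A centroid advances at v^g
along a slowly turning heading; the members sit ±δ/2 along a relative
orientation whose per-step rotation is chosen so the chord length matches
the drawn relative speed.  Two extraction-aware details: the tangential
budget compensates the known ~1% attenuation of the centered-difference
velocity estimator (curvature, rare direction reversals, magnitude
averaging) and half of the radial (spacing-breathing) variance, which the
estimator suppresses — the generator's contract is that *extracted*
observables match the targets, verified to within 3 autocorrelation-
corrected standard errors in the suite.  Events per dyad are log-normal
(median ≈ 45 events ≈ 22 s, spread 0.8, clipped 6–400): real tracking data
is dominated by short fragments, and trajectory length must be genuinely
informative for the length-filtering protocol to be meaningful.  Heights
are drawn around 1.65 ± 0.07 m with the pair split by the η draw; family
dyads receive one member under 15 with probability 0.5 (default); an
optional standing fraction injects below-threshold group speeds to exercise
the range filter.

Within-dyad wobble deliberately exceeds between-dyad spread.  Two reasons:
real instantaneous spacing fluctuates (gait, obstacles, crowd weaving) far
more than category means differ; and it controls the α=1 failure mode in
which a true category is permanently zeroed once the dyad wanders into a
bin never populated by its (finite) training class — with narrow per-dyad
coverage that elimination probability grows with trajectory length and
inverts the value of long trajectories.  The η channel retains this
pathology by construction (constant per dyad, 150 fine bins, few training
dyads), which is faithful: it reproduces the characteristic
families/couples confusion of the real study.

What passing the synthetic tests does *not* show: environmental effects
(corridor geometry, crowd density), non-walking episodes, sensor noise and
tracking errors, culture- or venue-specific proxemics, and any claim that
the numeric profile values match real categories.  The generator supports
recovery-above-chance and protocol-ordering checks, not quantitative
replication of real-data recognition rates.

## Numerical choices and degenerate inputs

* Posterior vectors are validated to sum to 1 within 1e-12; histogram masses
  within 1e-9.
* Ties in argmax/argmin are broken uniformly at random with the seeded
  generator passed by the caller; every protocol is bit-reproducible given
  its seed.
* Model JSON serialization writes full-precision `repr` floats; round trips
  are bit-exact.
* Empty observation sequences, empty training classes, all-out-of-range
  samples, missing family ages (when the child filter is requested) and
  corrupted model files raise typed errors; unknown pedestrian ids in the
  dyad table are skipped with a logged count.

## Problem sizes in bundled runs

The test suite and the acceptance script run entirely on synthetic data at
sizes chosen for tight feedback loops: 40 dyads/category in shared fixtures,
100 dyads/category × 5 seeds for recovery checks, 60 dyads/category × 5
repetitions in the acceptance script.  Standard errors at these sizes are a
few percentage points, which the assertions respect (chance-level and
ordering checks rather than point targets).

## Known limitations

* The α=1 zero-permanence interacts with finite training histograms: sparse
  classes (notably the constant-η channel) can eliminate the true category
  for entire dyads.  Real deployments would smooth or coarsen η.
* The EMD's mixed units across observables make distances incomparable
  between configurations; only argmin decisions are meaningful.
* Stage-2 assumes stage-1 was correct; no probability propagates between
  stages.
* The generator models no environment and no inter-group interactions; its
  trajectories are statistically, not behaviorally, realistic.
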