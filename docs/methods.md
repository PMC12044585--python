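# Methods

## Model and identification

The analysis operates on a weighted panel of study units.  Each unit i
contributes a weight w_i (its number of observation-years), a binary
outcome Y_i (1 = declining, i.e. mean recruitment strictly below 29
calves per 100 adult females), and one or more binary exposures X_ij
(1 = the continuous covariate lies strictly beyond its cutpoint).  The
factual and counterfactual outcome probabilities are weighted relative
frequencies,

    p1 = Σ w_i Y_i [X_i = 1] / Σ w_i [X_i = 1]
    p0 = Σ w_i Y_i [X_i = 0] / Σ w_i [X_i = 0],

and the probabilities of causation follow the Tian–Pearl point
identification, valid under two assumptions that the package checks or
enforces structurally:

* **Exogeneity** — every queried exposure has in-degree zero in the causal
  DAG (`check_exogeneity`; the pipeline refuses, rather than adjusts,
  non-exogenous queries, because the identification result does not hold
  and silent backdoor correction would misrepresent the model).
* **Monotonicity** — no unit is protected by the exposure.  This is an
  assumption about the world for real data; for synthetic data it is a
  verifiable property of the generator (`check_monotonic` enumerates the
  full exposure lattice).

PN = max(1 − p0/p1, 0), PS = max(1 − (1−p1)/(1−p0), 0),
PNS = max(p1 − p0, 0).  When p1 ≥ p0 these satisfy
PN·p1 = PNS = PS·(1−p0), which the test suite asserts to 1e-12.  PN is
undefined at p1 = 0 and PS at p0 = 1; the package surfaces these as
explicit `None`s with `valid=False`, never as zeros.

Multi-factor queries ("cutblocks > 10 % **and** linear features >
0.2 km/km²") contrast the all-exposed against the all-unexposed world:
units with a mixed configuration belong to neither conditioning set.  The
underlying data for such contrasts do not dictate a unique convention;
exclusion is the interpretation consistent with a cumulative-effect
contrast and is the package's fixed choice.  Strata (e.g. low vs high
landscape productivity) condition both sides.

## Network layer

The causal hypotheses are tiny DAGs (≤ 5 binary nodes), so the Bayesian
network layer is deliberately exact and prior-free: CPT cells are weighted
relative frequencies (a cell with zero support is *empty*, probability
undefined), and evidence queries are answered by full enumeration.  When
the evidence covers all parents of the outcome, the query reduces to a
CPT lookup and is exactly the weighted quadrant proportion — the test
suite checks this equivalence on hundreds of random panels, so the
network route and the direct estimator route cannot drift apart.

**Pruning.**  A hypothesized parent may leave empty CPT cells (joint
configurations never observed).  `prune_parents` repeatedly removes, among
the outcome's parents, the one with the lowest conditional mutual
information (CMI) with the outcome given the other remaining parents,
until the CPT is fully supported or one parent remains.  CMI is computed
in nats from weighted empirical frequencies with 0·log 0 = 0 and a floor
at zero; the base is irrelevant to the argmin.  Ties are broken
lexicographically by variable name and every removal is logged with its
CMI.  The conditional (rather than marginal) form is used because the
criterion is applied in a multi-parent context; marginal MI is available
by passing `given=()`.

## Thresholds

`select_exposure_threshold` formalizes the data-driven rule for
disaggregated factors: the smallest candidate cutpoint c such that at
most `max_exceptions` stable-increasing areas have covariate values
strictly above c, with a non-empty exposed set.  By default candidates are
the sorted distinct observed values, so at zero exceptions the rule
returns the largest observed stable-increasing value and the induced
exposure has p1 = 1.  Exceptions are counted in areas, not
observation-years ("one study area" is an area-level statement); a
weighted variant sits behind a flag.

`sensitivity_sweep` re-binarizes and re-queries over a grid of aggregate
disturbance cutpoints.  The "±30 %" span is read as absolute percentage
points (5 %–65 % around the 35 % policy threshold, 13 grid points at step
5), consistent with reported behavior at 5–15 % and above 60 %.  Grid
rows with an empty conditioning set are kept with `valid=False` so the
sweep always has one row per cutpoint.

## Synthetic generator

`simulate_panel` draws study-area tables from a fully specified SCM so
every pipeline stage can be tested against exact ground truth
(`true_probabilities`, which marginalizes the exposure-indicator lattice
by closed forms plus one-dimensional quadrature over the shared latent).

Defaults describe the emulated evidence base: 58 areas; observation-year
weights on {1..10} with mean ≈ 2.72, so the expected total is ≈ 158
years; covariate families chosen once as field-plausible (they are
modeling choices, not published values): aggregate disturbance =
100·Beta(1.8, 1.2) (most ranges substantially disturbed), burned fraction
= 80·Beta(1, 3) (most ranges lightly burned), mean EVI = 2000 +
2500·Beta(2, 2), and linear-feature density (range 0–0.6 km/km²) and
cutblock cover (0–30 %) as 50/50 mixtures of a shared uniform "industrial
development" latent and independent uniforms, giving the two
anthropogenic footprints a positive correlation without breaking
exposure exogeneity with respect to the outcome noise.  The outcome is
additive on the log-odds scale with non-negative per-exposure increments
(baseline logit(0.55); increments 0.9, 1.2, 0.8, 0.2, 0.7 for
disturbance, linear, cutblock, burned, EVI), monotone by construction;
recruitment is then drawn continuously on the matching side of 29
(29·Beta(2,2) below, 29 + 31·Beta(1.5,3) above) so dichotomization is
genuinely exercised.  One root seed feeds per-stage named substreams, so
adding a covariate leaves the others' draws unchanged.

What the generator does *not* emulate: spatial structure and
jurisdiction-level clustering, temporal trends within areas (only
averages exist upstream), measurement error in recruitment, and
confounding between exposures and outcome noise.  Passing recovery tests
therefore demonstrate correctness of the estimator under the stated
assumptions, not robustness to their violation on real data.

## Numerical and reporting choices

* All internal arithmetic is full precision; rounding (decimal half-up,
  as applied tables print) happens only in the report layer: 3 decimals
  for probabilities, 1 for percentages.
* Recomputing the productivity row's PN/PS from its 3-decimal p1/p0
  (0.980, 0.677) yields 30.9/93.8, while the source table prints
  31.0/93.9 — the printed values evidently round unrounded inputs.  The
  package reports the recomputed values; the discrepancy is a rounding
  artifact, not a formula difference (PNS agrees at 30.3).
* Boundary coding: equality at a cutpoint codes 0 (recruitment of exactly
  29 is stable-increasing; disturbance of exactly 35 % is unexposed),
  matching the strictly-greater / strictly-less phrasing of the
  thresholds.
* Fractional observation-year weights are rejected; weighted and
  weight-expanded estimation are exactly equivalent (asserted, not
  approximated).
* The bootstrap resamples units with replacement keeping their weights,
  reports percentile intervals, and counts resamples on which a quantity
  was unidentified; it needs at least two units.

## Problem sizes

Test and verification runs use panels of up to 16 units against
brute-force enumeration oracles, 200-panel randomized equivalence checks,
and parameter recovery at 100,000 weight-1 areas across 100 seeds (true
PNS 0.3 recovered within ±0.02 in ≥ 95 % of seeds; null-model PNS ≤
0.03).  These sizes make the exact oracles tractable while leaving
sampling error an order of magnitude below the tolerances.

## Known limitations

* Point identification only: no Tian–Pearl interval bounds for
  non-monotonic or non-exogenous settings, and no covariate adjustment —
  the pipeline aborts instead.
* Binary variables only; continuous probabilities of causation are out of
  scope.
* No structure learning: DAGs are user-specified hypotheses; pruning only
  removes arcs, it never adds them.
* Threshold selection maximizes p1 subject to the exception allowance; it
  is not an ROC-style search and does not optimize PNS directly.
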