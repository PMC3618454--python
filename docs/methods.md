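# Methods

## The scientific question

A forager's path can look "Lévy-like" — movement lengths with a heavy,
power-law-distributed tail — for two very different reasons.  A genuine Lévy
process samples every movement length independently from the same
distribution, regardless of what the forager finds; it implies no behavioral
response to resources.  Area-restricted search (ARS) instead switches from
extensive movement (long, straight) to intensive movement (short, tortuous)
after a resource encounter, and can produce similarly heavy-tailed length
distributions as a by-product.  Distinguishing the two therefore cannot be
done from the length distribution alone: it requires knowing where resources
were and how movement changed after encountering them.

This package implements that full analysis chain for destructive foraging in
a circular arena, together with a synthetic-data generator that produces both
kinds of forager, so every stage of the analysis can be validated against
paths whose generating process is known.

## The arena and resource layouts

The arena is a disc of radius R = 110 m surrounded by a fence.  It contains
1440 point items in one of two layouts:

* **dispersed** — item positions i.i.d. uniform over the disc (area-uniform);
* **patched** — 24 non-overlapping circular patches of radius r_p = 8.65 m,
  60 items uniform within each patch.  Patch centers are drawn uniformly over
  the disc of radius R − r_p (patches lie fully inside the fence) and
  accepted only at pairwise distance ≥ 2 r_p, by rejection sampling with a
  configurable attempt budget.

Foraging is destructive: an item is collected the first time the path sweeps
within the detection radius r_d = 0.75 m of it, and never replaced within a
trial.  Detection uses the swept segment (point-to-segment distance), not
vertices only, and the encounter is logged at the earliest arc length at
which the sweep reaches the item.  Trials end at 90 collected items (or a
step cap of 10^5 movements, which guarantees termination in item-free
arenas).

## Movement lengths and turning angles

Paths are polylines produced by move-or-turn locomotion.  A *movement
length* is the distance travelled between two consecutive turns; interior
vertices turning by no more than a collinearity tolerance (default 10^-6
degrees) are merged, and the path's start and end act as turn delimiters.
Lengths are travelled (arc) distances between surviving turns, so their sum
equals the total path length for any tolerance.  *Turning angles* are
absolute heading changes in degrees, in [0, 180].

## The four movement-length models

With l ≥ a (a = smallest observed length by default) the candidates are

| model | density | MLE |
|-------|---------|-----|
| PL   | (μ−1) a^(μ−1) l^(−μ) on [a, ∞) | μ̂ = 1 + n / Σ ln(l_i/a), closed form |
| PLB  | C(μ,a,b) l^(−μ) on [a, b] | bounded scalar search over μ ∈ (−10, 10) |
| Exp  | λ e^(−λ(l−a)) on [a, ∞) | λ̂ = 1/(mean − a), closed form |
| ExpB | λ e^(−λl)/(e^(−λa) − e^(−λb)) on [a, b] | bounded scalar search |

The truncated power law is normalizable for any real μ; the μ = 1 case uses
its logarithmic limit (density ∝ 1/(l ln(b/a))), so empirical fits may land
at μ ≤ 1, as fits to real foraging paths often do.  b defaults to the largest observed
length.  Optimization is Brent search to ~10^-12 in the parameter, i.e. well
below 10^-10 in log-likelihood.

Models are compared by AIC with Akaike weights w_i ∝ exp(−Δ_i/2); the
*evidence ratio* of a model is w_best/w_i, so the best model scores exactly
1.0.  By default k counts only the shape parameter (μ or λ), matching the
likelihood literature this analysis follows; `count_bounds_as_params=True`
additionally counts each data-derived cutoff.

**A structural caveat, discovered and verified here.**  With b set to the
sample maximum, the truncated power law dominates the unbounded power law
*pointwise* in likelihood (its normalizing constant is strictly larger on
[a, max]), and likewise ExpB dominates Exp.  At equal k the bounded variant
therefore always wins the AIC comparison, even on data generated from the
unbounded model — a tautology, not evidence of truncation.  Counting the
bounds as parameters removes the tautology but the likelihood gain from
truncating at the sample maximum is approximately Exp(1)-distributed under
the unbounded model, so the unbounded generator still loses whenever that
gain exceeds 1 (≈ 37% of samples).  Model-selection consistency between a
model and its own data-derived truncation is thus unattainable in principle;
the package's consistency test documents the measured rates.  Between the
power-law and exponential families the comparison is fully consistent.

## Goodness of fit and log-binning

Absolute fit uses the G-test (likelihood-ratio) statistic
G = 2 Σ O_i ln(O_i/E_i) on equal-probability quantile bins of the fitted
model (20 before merging; adjacent bins merged until every expected count is
at least 5), referred to chi-square with df = bins − 1 − k.  Calibration
measured under the true model (truncated power law, n = 500, 1000
replicates): rejection rate 0.047 at nominal 0.05, KS distance of the
p-value distribution from uniform 0.023.

The traditional reference method is logarithmic binning: geometric bins
(default ratio 2) from the smallest length, counts divided by bin width, and
an OLS slope of log10 frequency against log10 geometric bin center over
non-empty bins.  A pure power law l^(−μ) gives slope −μ.

## Synthetic foragers

`AgentConfig` defaults are the reference experimental conditions the
package emulates: 110 m arena, detection
0.75 m, 90-item target, start at the arena center, and cohorts of agents
with trials pooled per agent (the reference design: 16 foragers per
condition, 5 trials each).

* **levy** — movement lengths i.i.d. truncated Pareto (μ = 2 on [1, 110] m
  by default) via inverse-CDF sampling; turns i.i.d. normal with SD 20°.
  No quantity depends on encounter history.
* **brownian** — as above with truncated-exponential lengths.
* **ars** — extensive mode identical to the Lévy walker; on an encounter the
  walker stops at the encounter point and enters intensive mode: movement
  lengths a + Exp(1 m), turns uniform over ±75°, until it has travelled the
  give-up distance D = 20 m without a further encounter.

The fence reflects the heading specularly.  Reflections split the affected
movement at the fence vertex, so a small fraction (~1%) of extracted
movement lengths fall below the sampler's lower cutoff; fits to recover the
generative exponent apply to lengths at or above it.

Intensive-mode defaults were calibrated against the mechanism they must
express, once, during design.  Within a patch the mean free path between
items is ≈ 1/(2 r_d ρ_patch) ≈ 2.6 m, and escaping a locally depleted pocket
takes more than 10 m of tortuous travel, so a 10 m give-up distance abandons
patches after about 8 of their 60 items; D = 20 m (the patch-diameter scale,
2 r_p = 17.3 m) retains the walker until local depletion.  The turn range
trades patch coverage against re-sweeping the 1.5 m-wide detection swath:
±120° produces micro-loops that re-sweep heavily, ±60° under-exploits the
patch; ±75° keeps the full exploitation advantage (≈ 6.6 vs 5.5 items per
100 m for the blind walker in patches) at the smallest measured re-sweep
penalty.  All of these are configuration fields, not constants.

## Encounter response (turning profiles)

For every encounter, each subsequent turn within 20 m of path distance is
assigned to a 1 m bin of distance-after-encounter.  Agents are the unit of
analysis: per-agent bin means are computed first (trials pooled), then the
grand mean and SEM across agents.  The baseline profile repeats the
construction with anchors drawn uniformly by arc length along the same
trajectories, by default as many per trial as that trial had encounters.

The primary contrast averages each agent's turning over the first 5 m after
the anchor and compares encounter anchors with baseline anchors, either by a
two-level repeated-measures F (paired when the profiles cover the same
agents, between-groups otherwise) or by a permutation test (sign-flips
within agents when paired, label shuffles otherwise).  The ARS prediction is
directional — turning *elevated* after encounters — so the permutation test
supports a one-sided alternative, used for that contrast.

A genuine subtlety the synthetic nulls exposed: for a resource-blind walker
in a destructive arena, post-encounter turning sits slightly *below* the
baseline (≈ 2.5° here).  Doubling-back, turn-dense path stretches re-sweep
ground whose items were already removed, so encounters under-sample
tortuous stretches relative to uniformly placed anchors.  A two-sided test
against the baseline therefore rejects a true Lévy process at well above the
nominal rate; the directional test is the faithful formulation of the ARS
hypothesis and is correctly calibrated (0/20 false elevations measured).

## Path transfer

To ask whether paths are adapted to the layout that produced them, each path
is replayed as a fixed geometric object in freshly generated environments of
the other layout, rotated about the arena center by a uniform random angle
(randomizing initial heading while preserving containment — rotation about
the center is the unique pivot with that guarantee).  Performance is items
encountered per 100 m of path (length-normalized so paths of different
lengths are comparable; raw counts are also available).  Replays do not stop
at 90 items: a transferred path has no behavioral feedback.  A fresh
environment is generated for every rotation, since layouts are random per
trial.

Per-path transferred performance is the mean over n_sim rotations (100 in
the full pipeline); per-agent values average the agent's pooled trials.  The
cross-cohort comparisons are: transferred blind-walker paths
versus native ARS paths in patches, and transferred ARS paths versus native
blind paths in the dispersed layout.  The first is a directional prediction
(a deficit) and is tested with a one-sided Welch t-test on per-agent values;
the second asks whether any difference exists and is tested two-sided (a
permutation alternative is provided for both).  Measured over 20 replicate
cohorts of 8 agents × 5 trials with n_sim = 10: the blind-to-patched
deficit is significant in 18/20 cohorts, while the ARS-to-dispersed
comparison shows no significant difference in 17/20 — the transferred ARS
paths do carry a real but small (~4%) re-sweep inefficiency, the
path-geometry cost of intensive search, detectable only at higher power.

## Problem sizes and determinism

Every stochastic stage takes a seed (the pipeline derives all stage seeds
from one master seed), and fixed seeds give byte-identical reports.  Test
and acceptance runs use desk-scale sizes chosen once: cohorts of 8 agents
with 2 trials (turning) or 5 trials (transfer), 20 replicate cohorts for the
directional properties, n = 5000 × 100 replicates for model-selection
consistency, n = 500 × 1000 replicates for G-test calibration, and 10^4–10^5
draws for estimator recovery.  The full-scale pipeline (16 agents × 5
trials per condition, 100 transfer rotations) runs with
`forage run --config config.yaml`.

## Known limitations

* The synthetic agents are homogeneous; real participants vary widely in
  movement scale and turning style, which inflates between-subject variance
  relative to these cohorts.
* The ARS mechanism is a two-state distance-triggered switch; graded or
  time-based intensification is not modeled.
* The arena fence is handled by specular reflection of the heading; real
  foragers presumably steer before contact.
* Movement-length models are fitted to pooled lengths; within-path
  autocorrelation (present by construction for the ARS walker) is ignored by
  the likelihoods, exactly as in the analysis tradition this follows.
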