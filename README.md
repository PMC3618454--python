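# forage

Simulation and likelihood analysis of foraging movement paths: are they
Lévy-like, or area-restricted search?

## The problem

Many foragers — from T cells to humans — produce movement lengths whose
distribution has a heavy, power-law tail, the signature usually attributed
to Lévy flights.  But a Lévy process samples every movement length
independently of resource encounters, whereas *area-restricted search*
(ARS) — switching to short, tortuous movements after finding something —
can generate very similar length distributions while being profoundly
resource-sensitive.  Distinguishing them requires the full record: where
the resources were, what was collected, and how movement changed afterward.

`forage` implements that analysis chain for destructive foraging in a
circular arena (radius 110 m, 1440 hidden items, detection at 0.75 m,
trials ending at 90 collected items), in two resource layouts: *dispersed*
(items uniform over the arena) and *patched* (24 non-overlapping patches of
60 items within 8.65 m of each center).  It provides:

* **environment** — dispersed/patched resource maps and swept-path
  destructive encounter detection;
* **trajectory** — polyline paths, movement lengths l (distance between
  turns) and absolute turning angles θ, CSV I/O;
* **synthetic_agents** — a resource-blind truncated-Lévy walker
  (l ~ l^(−μ) on [a, b], inverse-CDF sampled), a Brownian walker, and a
  two-mode ARS walker with a give-up distance;
* **heavytail_fit** — maximum-likelihood fits of four length models
  (power law, bounded power law, exponential, bounded exponential;
  PL: μ̂ = 1 + n/Σln(l_i/a)), AIC/Akaike weights and evidence ratios,
  G-test goodness of fit on model quantile bins, and log-binned slope
  estimation;
* **encounter_response** — turning as a function of distance after
  encounters vs. a random-location baseline (repeated-measures and
  permutation tests);
* **path_transfer** — replaying rotated paths in the alternative resource
  layout and comparing performance (items per 100 m);
* **pipeline** — the full seeded analysis from one YAML config, via
  `forage run`.

## Worked example

Simulate a small resource-blind Lévy cohort (μ = 2 on [1, 110] m) in the
dispersed layout, pool movement lengths above a 1 m analysis cutoff, and
compare the four models:

```python
import numpy as np
from forage import *

arena = Arena()                                   # 110 m circular meadow
cohort = simulate_cohort(
    n_agents=4, trials_per_agent=2,
    config=AgentConfig(strategy="levy"),          # resource-blind walker
    env_generator=lambda s: generate_dispersed(arena, seed=s),
    seed=7, arena=arena,
)
pooled = MovementSample.pool([movement_lengths(t.trajectory) for t in cohort])
x = pooled.lengths[pooled.lengths >= 1.0]         # drop fence-split fragments
comparison = compare_models(fit_all(x))
for name, ratio in comparison.evidence_ratios.items():
    fit = comparison.fits[name]
    print(f"{name:4s} param={list(fit.params.values())[0]:6.3f} "
          f"AIC={fit.AIC:9.1f} ratio={ratio:.3g}")
gof = g_test(x, comparison.fits[comparison.best_model])
print("best:", comparison.best_model, " G-test p=%.3g" % gof.p_value)
print("log-bin slope: %.2f" % log_bin_slope(x).slope)
```

prints

```
PL   param= 2.055 AIC=  10489.3 ratio=3.78e+09
PLB  param= 2.011 AIC=  10445.2 ratio=1
Exp  param= 0.279 AIC=  12607.7 ratio=inf
ExpB param= 0.279 AIC=  12607.7 ratio=inf
best: PLB  G-test p=0.2
log-bin slope: -2.08
```

The bounded power law wins with evidence ratio 1.0 (best model by
definition), recovers the generative exponent (μ̂ = 2.01), passes the
goodness-of-fit test because the generating process really is a truncated
Lévy walk, and the log-binned slope ≈ −μ.  The exponential models are
rejected with astronomical evidence ratios.  Running an ARS cohort in the patched layout instead and calling
`turning_profile` / `baseline_profile` / `compare_profiles` shows the other
signature: post-encounter turning elevated ~25° over the random-location
baseline (permutation p < 0.05), absent for the Lévy walker.

The full pipeline (both conditions, per-agent and aggregated tables,
turning profiles, both transfer directions) runs from one config:

```sh
forage run --config config.yaml       # see AnalysisConfig for the keys
```

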