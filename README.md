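# chasedot

Simulation and mixed-model analysis of the *chase-detection* paradigm used
to study animacy perception: displays of four identical moving dots in
which one dot (the **wolf**) pursues another (the **sheep**) with a
controllable degree of pursuit fidelity, and observers judge whether a
chase is present.

The package is aimed at researchers in visual psychophysics and
computational cognitive science who want the paradigm's generative side and
its statistical analysis as tested, reproducible code: no participant data
is required anywhere — synthetic observers stand in for human cohorts.

## What it implements

**Displays** (`chasedot.stimulus`). Dots move at 14.5°/s in a rectangular
arena (48 × 30° by default), resampling their heading within a 120° window
roughly every 170 ms. The wolf instead samples, after a 170 ms onset delay,
a heading uniformly within ±*s* of the bearing to its sheep, where the
*chasing subtlety* *s* ∈ {15°, 45°, 75°} (0° = perfect "heat-seeking").
In chase-absent trials the sheep is a fifth, invisible dot. Two constraints
hold on every frame: the wolf–sheep distance stays above 5° and no two dots
overlap. Trials are bit-reproducible from a single seed.

**Cues** (`chasedot.cues`). The social condition adds eyes: the wolf's gaze
tracks the sheep (chase-present only), all other eyes follow their dot's
heading. The non-social condition modulates dot luminance sinusoidally:
wolf and sheep share 3 Hz (phase offset 0.15 rad), distractors run at
0.5 Hz.

**Design** (`chasedot.design`). Three counterbalanced blocks (baseline,
social, non-social), each 6 practice + 75 test trials (per subtlety:
20 chase-present, 5 chase-absent).

**Observers** (`chasedot.observer`). A parametric generator produces
trial-by-trial accuracy from a random-intercept logistic model

```
logit P(correct) = β₀ + β_G·Group + β_A·Age + β_T·Present + β_S·Subtlety
                 + β_soc·Social + β_non·Nonsocial + β_GS·Group×Subtlety + u,
u ~ N(0, σ_u²)
```

with Group coded ASD = 1 / TD = 0 and defaults equal to the published
estimates (β₀ = −1.13, β_G = −0.39, β_A = 0.17, β_T = 0.23, β_S = −0.05,
β_soc = 0.66, β_non = 0.15, β_GS = 0.01; σ_u = 0.8). A heuristic
pair-search observer instead scores all ordered dot pairs on heading
alignment, closing proximity and cue consistency, and answers "chase" when
the best pair clears a noisy criterion.

**Analysis** (`chasedot.analysis`). The same mixed model is fitted by
marginal maximum likelihood with adaptive Gauss–Hermite quadrature
(order configurable; order 1 = Laplace), with Wald Z tests and 95% CIs,
plus per-cell accuracy summaries and d′ with log-linear or half-count
false-alarm corrections. The fitter agrees with `lme4::glmer` to < 0.01 on
every coefficient (tested).

## Worked example

```python
import numpy as np
from chasedot import (GlmmParams, build_design, sample_cohort,
                      simulate_study, fit_random_intercept_logistic, wald_table)

params = GlmmParams()                      # published fixed effects, sigma_u = 0.8
rng = np.random.default_rng(1)
design = build_design(48, rng=rng)         # 48 participants x 243 trials
cohort = sample_cohort(24, params, rng)    # 24 ASD + 24 TD adolescents
responses = simulate_study(design, cohort, params, rng)
fit = fit_random_intercept_logistic(responses)
print(wald_table(fit)[["estimate", "se", "z", "p_formatted"]].round(3))
print(f"sigma_u_hat = {fit.sigma_u_hat:.3f}")
```

prints

```
                  estimate     se       z p_formatted
intercept           -3.516  1.703  -2.065       0.039
group               -0.630  0.278  -2.264       0.024
age                  0.354  0.119   2.981       0.003
trial_type           0.188  0.059   3.164       0.002
subtlety            -0.052  0.002 -32.679      <0.001
social               0.632  0.058  10.893      <0.001
nonsocial            0.162  0.058   2.787       0.005
group_x_subtlety     0.011  0.002   4.972      <0.001
sigma_u_hat = 0.894
```

The refit recovers the generating structure of this single synthetic
cohort: accuracy falls ~0.05 logits per degree of subtlety, the social cue
adds ~0.63 logits while the non-social cue adds little, and the positive
Group×Subtlety coefficient makes the ASD group's performance less dependent
on subtlety (worse than TD near heat-seeking, better at 75°). Intercept and
age are noisy because age only spans 12–16.5 years.

The same pipeline is available from the shell:

```bash
chasedot generate --condition nonsocial --subtlety 15 --present --seed 4 --out trial.csv
chasedot simulate-study --n-per-group 24 --sigma-u 0.8 --seed 1 --out responses.csv
chasedot fit responses.csv --out fit.json
chasedot run --seed 1 --out results/
```

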