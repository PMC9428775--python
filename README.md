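# actimediate

Mediation analysis for school-randomized physical-activity trials, from raw
accelerometer count epochs to bootstrapped indirect effects.

Wearable-based interventions for inactive adolescents are usually
randomized by school and evaluated with hip-worn accelerometers plus
psychosocial questionnaires (self-efficacy, social support, self-regulation,
perceived barriers, enjoyment). Understanding *why* such interventions do or
do not change behavior requires a mediation analysis: did the intervention
move the hypothesized psychosocial mediators (the *a* path), and did those
mediators move behavior (the *b* path)? `actimediate` packages that whole
workflow for biostatisticians and activity-measurement researchers:

- **accelerometry** — 15-s count epochs → daily sedentary / LPA / MVPA
  minutes, with nonwear detection (≥ 60 min of consecutive zero counts),
  count cut-points (sedentary ≤ 25 counts/epoch; age-specific MVPA
  threshold), valid-day rules (≥ 8 h weekdays, ≥ 7 h weekends, ≥ 3 valid
  days) and averaging across valid days;
- **scales** — summed Likert scores for seven registered mediator
  instruments, with reverse keying and strict missing-item handling;
- **mediation** — school random-intercept linear mixed models (REML) for
  the a, b, c and c′ paths, a p < α mediator screen, and a percentile
  bootstrap of the product-of-coefficients indirect effect a×b that
  resamples whole schools stratified by arm;
- **synthetic** — a cluster-trial generator with known ground truth
  (latent mediators → ordinal items; behavior targets → full-day count
  streams) so every stage is testable by parameter recovery;
- **pipeline** — orchestration with a CONSORT-style complete-case filter,
  descriptive and effect tables, deterministic under a fixed seed.

The core estimand, for mediator M and outcome Y with arm A and covariates
X (sex, SES decile, average wear time):

    a :  M_T1 ~ A + M_T0 + X            (+ random school intercept)
    b, c′:  Y_T2 ~ A + M_T1 + M_T0 + Y_T0 + X
    c :  Y_T2 ~ A + M_T0 + Y_T0 + X
    indirect effect = a×b, percentile 95% CI from cluster-bootstrap refits

## Worked example

```python
from actimediate import AnalysisSpec, bootstrap_indirect
from actimediate.synthetic import TrialConfig, simulate_analysis_table

config = TrialConfig(
    a_true={"barriers": 2.5},                    # intervention raises barriers by 2.5 pts
    b_true={("barriers", "sedentary"): 0.8},     # each point adds 0.8 min/day sedentary
    seed=77,
)
table, truth = simulate_analysis_table(config)
result = bootstrap_indirect(table, "barriers", "sedentary", AnalysisSpec(n_boot=200, seed=1))
```

prints (via `python examples/mediation_analysis.py`):

```
a  (arm -> barriers T1)        2.93  p=0.008
b  (barriers T1 -> sed T2)     0.69  p=0.232
c  (total arm effect)         20.00
c' (direct arm effect)        17.98
a*b indirect effect            2.03  95% CI [-1.29, 7.31]
```

The generating indirect effect is 2.5 × 0.8 = 2.0 min/day; the estimate
2.03 recovers it, and the wide CI reflects that only 18 schools carry the
arm contrast. The other scripts in `examples/` walk through epoch
classification, scale scoring and the full pipeline; the `actimediate`
console command (`simulate`, `accel`, `scores`, `mediate`, `run`) exposes
the same stages for shell use with a YAML config.

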