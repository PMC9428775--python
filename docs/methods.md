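# Methods

`actimediate` implements a secondary-analysis pipeline for cluster-randomized
physical-activity trials in adolescents: hip-worn accelerometer count epochs
are reduced to daily sedentary / light (LPA) / moderate-to-vigorous (MVPA)
minutes, psychosocial mediator questionnaires are scored, and intervention →
mediator → behavior pathways are estimated with school random-intercept
linear mixed models and a cluster bootstrap of the product-of-coefficients
indirect effect. Because raw trial data of this kind are rarely public, the
package ships a synthetic-trial generator with known ground truth, so every
stage is testable by parameter recovery.

## Accelerometer processing

Counts are accumulated over fixed epochs (15 s default; any length dividing
60 s is accepted). Processing is per calendar day:

- **Nonwear** — any maximal run of zero-count epochs lasting ≥ 60 min.
  Runs are strict (a single nonzero count breaks them) and never span
  midnight, since wear-time covariates and day-validity are daily
  constructs. Zero runs shorter than the threshold remain wear and classify
  as sedentary.
- **Classification** — wear epochs with ≤ 25 counts/15 s are sedentary;
  epochs at or above the MVPA threshold are MVPA; the band between is LPA.
  The MVPA threshold is either a pinned counts-per-epoch value or an
  age-specific default derived from the Freedson youth energy-cost equation
  (METs = 2.757 + 0.0015·cpm − 0.08957·age − 0.000038·cpm·age) solved at
  4 METs and rescaled to the epoch length (≈ 630 counts/15 s at age 14).
  Every test that depends on classification pins explicit cut-points, so no
  result rests on the default.
- **Validity** — a day is valid with ≥ 8 h wear on weekdays, ≥ 7 h on
  Saturday/Sunday (local calendar; no holiday handling); a
  participant-time point is included with ≥ 3 valid days, and class minutes
  are unweighted means over valid days only. Comparisons are exact in
  epochs, not rounded to whole minutes. Partial recording days are
  processed as-is, and any number of recorded days is accepted.

Two invariants hold by construction and are enforced in tests: classified
sedentary + LPA + MVPA minutes equal wear minutes on every day, and wear +
nonwear equal the recorded duration.

## Scale scoring

Seven instruments are registered (items × levels → range): self-efficacy
5 × 1–6 → 5–30, peer support 5 × 1–5 → 5–25, family support 4 × 1–5 → 4–20,
teacher support 4 × 1–5 → 4–20, self-regulation 6 × 1–5 → 6–30, perceived
barriers 9 × 1–4 → 9–36, enjoyment 16 × 1–5 → 16–80. A score is the plain
sum of item responses. Reverse keying maps a response v to
`level_min + level_max − v` (an involution); the default registry reverse-keys
nothing — instruments in this family contain negatively worded items, but
which ones were reverse-scored is an instrument-level decision, so the
registry exposes `reverse_items` per scale and the config can override it.
A missing item voids the score (no prorating or imputation), consistent
with downstream complete-case analysis.

## Mediation models

All models are linear mixed models with a random school intercept, fitted
by REML. The fit exploits the model's structure: with a single random
intercept the covariance is V = σ²ₑ(I + λZZ′) with one variance ratio
λ = σ²ᵤ/σ²ₑ, so β and σ²ₑ have closed generalized-least-squares forms given
λ and the REML criterion profiles down to a one-dimensional function of λ,
minimized by bounded Brent search on the log scale. This is exact for the
model class, a few milliseconds per fit (it sits inside the bootstrap
loop), and handles the zero-variance boundary cleanly: when the optimum is
at λ = 0 the fit is identical to OLS and the convergence flag is cleared.
The test suite cross-checks it against `statsmodels.MixedLM` and verifies
it attains a REML criterion at least as good on every test dataset. Wald
CIs and p-values use the normal approximation. With ~18 clusters this z-test is expected to be mildly
anticonservative for cluster-level effects (roughly a t with 16 df treated
as normal); the measured type-I error of the mediator screen at the default
trial dimensions runs ≈ 6–9% at nominal 5% across 500-replicate seed
batches (computed by the test suite and the reproduction script). A small-sample df correction is deliberately out of
scope. When the REML school-variance estimate hits the zero boundary — or
the mixed fit fails outright — the model falls back to OLS (mathematically
identical at zero cluster variance) and clears the convergence flag.

For mediator M, outcome Y, arm A (0 = control, 1 = intervention) and
covariates X = {sex, SES decile, average wear}:

- a path: `M_T1 ~ A + M_T0 + X` — the arm coefficient is the mean adjusted
  difference (MAD).
- b and c′: `Y_T2 ~ A + M_T1 + M_T0 + Y_T0 + X` fitted jointly.
- c (total): the same model without `M_T1`.
- indirect effect: a×b, percentile bootstrap CI.

Choices where the design was genuinely open:

- **Wear covariate** — baseline average wear in mediator-stage models,
  follow-up average wear in outcome-stage models (both configurable). The
  baseline adjustment for activity in outcome models uses the baseline of
  the *same* outcome variable.
- **SES decile** — a single continuous 1–10 term by default; categorical
  coding is a config option.
- **Screening** — only mediators with a-path p < α (default .05) proceed
  to formal mediation, with no multiplicity correction, preserving the
  screen-then-mediate design; Benjamini–Hochberg can be enabled for reuse
  beyond that design.
- **Bootstrap unit** — whole schools redrawn with replacement, stratified
  by arm, so every resample preserves the randomized design and the
  school-level dependence; resampled duplicates of a school enter the refit
  as distinct clusters. Participant-level resampling is available via
  `bootstrap_unit="participant"`. Resamples whose refits fail are dropped
  and counted; more than 5% failures aborts with advice (small cluster
  counts make singular resamples likely).

With clustering disabled and a shared covariate set across the three
models, OLS algebra gives c − c′ = a×b exactly; the test suite verifies
this to 8 decimals. With school random effects refitted per model the
identity holds only approximately — variance components differ between
models — which is why the pipeline reports all three quantities rather
than deriving one from the others.

## Synthetic trial generator

Defaults emulate a two-arm school-randomized wearable intervention in
13–15-year-olds: 9 schools/arm × 15 participants/school, additive school
intercepts on both scales (SD 1.5 score units for mediators, 12 min/day for
behaviors), a baseline-anchored ANCOVA-style generation

```
M1 = μ_m + 0.6 (M0 − μ_m) + a_m A + u_s + ε,   ε ~ N(0, 4²)
Y2 = 0.3 μ_y + 0.7 Y0 + c′_y A + Σ_m b_{m,y} M1_m + v_s + covariate terms + ε,  ε ~ N(0, 40²)
```

with default effects a = +1.8 score units on perceived barriers only (the
adverse direction reported for this kind of intervention), b ≡ 0, and direct
effects +22.5 / −16.4 / −6.7 min/day on sedentary/LPA/MVPA. Baseline
mediator means and SDs follow published adolescent samples on these
instruments (e.g. barriers 20.4 ± 4.5, enjoyment 62.7 ± 10.3).

Item responses come from a thresholded latent-continuous model: each item's
value is latent/n_items plus N(0, 0.7²) noise, rounded and clipped to the
admissible levels. The summed score is monotone in expectation in the
latent score, saturates at the scale floor/ceiling, and regresses on the
latent with slope ≈ 0.9 (mild attenuation from rounding and clipping — a
deliberate feature of realistic ordinal measurement).

Count streams realize a target composition exactly: wear epochs carry
counts drawn strictly inside their class band (sedentary uniform on
[1, 25], LPA on [26, MVPA−1], MVPA on [MVPA, 2·MVPA]), shuffled, and framed
by zero-run nonwear blocks of at least 60 min at the day's ends. Wear
averages 750 min/day at a 70/25/5 sedentary/LPA/MVPA split (person-level
Dirichlet jitter, per-day Gaussian jitter of 20 min per class).
Compositions that cannot fit in 24 h, or that leave a nonwear remainder
shorter than one nonwear run, are rejected as infeasible.

Missingness is completely at random per stage, with default rates matching
the per-stage availability of comparable trials (2.9% per survey wave,
9.9% baseline accelerometry, 29.3% follow-up), yielding ≈ 58–63% complete
cases. An accelerometry-missing participant still records days, but all
except two are scaled to ~30% wear so they fall below the valid-day
threshold — exercising the filter rather than bypassing it. The generator
does **not** emulate informative dropout, device-specific count
distributions (counts are uniform within class bands, not ActiGraph-like),
spike tolerance in nonwear, or within-week activity structure; passing
tests therefore validate the pipeline's logic and the estimators'
calibration under the stated model, not device fidelity.

## Problem sizes in the verification suite

Calibration and recovery studies run on the latent-score fast path
(`simulate_analysis_table`), which skips the ordinal and epoch layers —
those add only orthogonal measurement noise to what the estimator studies
measure. Sizes chosen: parameter recovery uses 200 replicates at 18 schools
× 111 participants (n ≈ 2000, tolerance 3 Monte-Carlo SEs); type-I
calibration uses 500 replicates at the default 270-participant dimensions
(acceptance band 3–7% at nominal 5%); the bootstrap degeneracy check uses a
noise-free construction where both stage models fit exactly, so every
resample reproduces the same a×b and the percentile CI has width zero. The
end-to-end pipeline test runs one full-size trial (270 participants,
16 recorded days each, ≈ 25 M epochs) through every stage. The
reproduction script (`scripts/acceptance.py`) uses the full 1000 bootstrap
resamples per mediator-outcome pair, matching the pipeline default.

## Known limitations

- Normal-approximation p-values with few clusters are mildly liberal (see
  above); users with very few schools should prefer the permutation check
  or a participant bootstrap.
- The percentile bootstrap CI is first-order; no BCa correction.
- Single-mediator models only: no joint multiple-mediator, moderated
  mediation, or sex-stratified analysis; no missing-data imputation.
- The complete-case filter implements exactly four conditions (covariates,
  mediators at T0 and T1, valid accelerometry at T0 and at final
  follow-up); post-intervention accelerometry is intentionally not
  required.
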