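# Methods

## The excretion model

A single pulse dose of an indigestible external marker (C32 alkane on
shredded paper, given as gelatin boluses) enters a two-stage mixing system:
an age-dependent first compartment in which newly arrived particles are
unlikely to escape until they have "aged" (comminution/rumination), modelled
as a gamma-2 compartment with rate `λ₁`; an age-independent second
compartment with exponential escape at the passage rate `k₂`; and a pure
transit delay `τ` through the lower tract. Marker concentration in fecal
dry matter is the transit-time density of the sum
`Erlang-2(λ₁) + Exp(k₂) + τ`, scaled by `C₂/k₂`:

    C(t) = C₂ δ² [e^(−k₂u) − (1 + (λ₁−k₂)u) e^(−λ₁u)],  u = t − τ > 0,
    δ = λ₁/(λ₁ − k₂)

Model assumptions: steady-state intake and fecal output over the 4-day
window (the dose-dilution identity `FO = 24·D·k₂/C₂` divides the dose by
the area under the concentration curve, which presumes a constant fecal DM
flow); complete fecal recovery of the marker; instantaneous mixing in each
compartment; no diurnal variation in passage.

Two identities pin the functional form to the quantities the field reports
and are enforced by quadrature oracles in the test suite: the area under
the curve is exactly `C₂/k₂` (independent of `λ₁` and `τ`), and the first
moment of the excretion density is exactly `2/λ₁ + 1/k₂ + τ`, the
total-tract residence time formula.

### Degenerate cases

When `|λ₁ − k₂| < 10⁻⁶·k₂` the general form divides by a vanishing rate
difference; the implementation switches to the analytic limit
`C₂ (k u)²/2 · e^(−ku)` (an Erlang-3 transit density scaled by `C₂/k`).
The `λ₁ → ∞` limit collapses to the single exponential `C₂ e^(−k₂u)`;
both limits are covered by tests. Values of `λ₁ < k₂` are mathematically
valid for the same formula and are not rejected.

## Fitting

Per animal-period, bounded nonlinear least squares on raw (unweighted)
background-corrected concentrations, honouring the original procedure's
constraints: all four parameters strictly positive and `k₂ ≤ 0.061`/h for
rangeland fits (an a-priori cap near the top of reported cattle passage
rates; disabled for total-collection validation data, where faster rates
occur). Bounds used by the solver: `λ₁ ∈ (0, 3]`, `k₂ ∈ (0, cap]`,
`τ ∈ [0, t_last)`, `C₂ ∈ (0, ∞)`.

The search is a fixed, deterministic multi-start: a 180-point grid
(`λ₁ ∈ {0.1, 0.2, 0.35, 0.6, 0.9}`, `k₂ ∈ {0.035, 0.045, 0.055, 0.061}`,
`τ` at {0.5, 0.8, 1.0}× the first nonzero-concentration time, `C₂` at
{0.5, 1.0, 1.5}× the observed maximum) is screened by SSE, and the 10 most
promising starts are refined with scipy's trust-region-reflective damped
least squares (`ftol = xtol = 1e-10`). The screen-then-refine split keeps a
48-curve cohort under a couple of seconds without changing results on the
recovery suite; `n_refine` is configurable. The lowest-SSE converged
solution wins; ties break toward smaller `k₂`, then smaller `λ₁`.
Solutions with `k₂` within 10⁻⁴ (relative) of the cap are flagged
`at_k2_bound`, never silently reported as interior. No randomness enters
fitting, so a series plus a configuration reproduces bit-identical output.

At least 6 included samples are required (4 parameters + 2 residual
degrees of freedom). MSE is reported as SSE/(n−4).

### Data cleaning

Codified versions of rules that are usually applied by hand, so runs are
reproducible; all thresholds are configuration keys and every exclusion
carries a machine-readable reason:

- background subtraction of the pre-dose fecal alkane level, clamped at 0;
- "big dip" flagging: an interior sample below 20% of both neighbours is
  out of sequence on a single-peaked curve and is flagged (not dropped);
- escalation ladder for series that stall: (1) relax solver tolerances by
  ×4 then ×6 (the portable analogue of loosening a convergence offset
  criterion); (2) among sample pairs ≤ 2 h apart with < 10% relative
  concentration difference — near-duplicates that flatten the objective —
  delete the member with the larger residual against the best provisional
  fit and refit; (3) delete flagged dips and refit. Deletions are capped
  at 10% of the series (the field study's overall deletion rate was
  3.74%), and an exhausted ladder raises an error carrying its log.

## Intake and energetics conventions

- Diet quality: fecal-NIRS digestible organic matter (DOM), averaged
  per animal over the sampled days by arithmetic mean. `TDN = DOM × 1.05`;
  `ME = DOM × 4.6 × 0.82` Mcal/kg OM.
- Dry-matter intake: `DMI = FO/(1 − digestibility)` with digestibility =
  TDN for the range convention. The validation convention divides by
  `(1 − TDN)` of the externally assayed forage instead; both are selectable
  in `RunConfig`. The ratio of the reported period means (FO 6.4, DMI 16.6
  kg/d → 61.4% ≈ 58.9% × 1.05) is consistent with the range convention.
- Organic-matter basis: fecal ash is capped at 15% before the OM
  conversion (field samples pick up soil; the observed field average ash of
  ~21% would otherwise understate OM output), so the OM multiplier lies in
  [0.85, 1]. OM intake divides OM-basis fecal output by `(1 − DOM)`, DOM
  being the OM-basis digestibility.
- Percent-of-BW intake is additionally reported multiplied by 0.7639,
  the downward adjustment derived from the total-collection validation in
  which predicted intake averaged ~131% of weighed intake.
- Bite-rate averages require ≥ 3 replicates; fewer yields an explicit
  excluded result (`None`), never a number.
- Pre-weighing shrink: 1%/h for the first 4 h off feed and water, then
  0.25%/h up to 14 h (breakpoints chosen within the conventional "3 to 4 h"
  / "next 8 to 10 h" ranges and exposed in the function signature); longer
  holds warn and hold the shrink at its 14 h value.
- Group summaries are means ± SE by treatment × period. Mixed-model
  inference is deliberately out of scope.

## The synthetic trial generator

Emulates the study conditions: 12 efficient + 12 inefficient cows over a
spring and a summer period; a 6 × 756 mg pulse dose at hour 0
(mid-afternoon); day-1 opportunistic sampling as 6 grabs uniform in
15–27 h post-dose (daybreak onward, respecting the ≥ 12 h mixing lag);
3 samples/d on days 2–3 and 2 on day 4 in jittered morning/midday/afternoon
windows (14 samples per animal-period); multiplicative lognormal noise
compounding the 4.11% intra-assay CV with a 5% biological CV
(cv_total ≈ 6.5%); per-animal background alkane near 6.36 (spring) or
2.94 (summer) mg/kg; kinetic parameters drawn uniformly inside the
observed per-period envelopes, with `C₂` derived from a target fecal
output in 4.5–9.5 kg/d via `C₂ = 24·D·k₂/FO`. Diet quality, grazing
minutes, bite-rate replicates, body weight and ash are drawn around the
period means. One global seed is split hierarchically per animal-period
(`SeedSequence.spawn`), so subsets reproduce independently.

Two controlled departures from ideal behaviour are injectable: a marker
recovery fraction r < 1 (scales every concentration by r and inflates
dose-dilution intake by exactly 1/r — the mechanism by which incomplete
marker recovery inflates predicted intake), and an additive gut-fill
effect for one group × period (implemented by scaling that animal's fecal
output so the kinetics stay self-consistent), used for null/power studies.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about field data: diurnal defecation patterns and
observer-driven sampling gaps; non-steady intake across the 4 days;
assay-error correlation within extraction batches; soil contamination
beyond a static ash value; diet selection or spatial grazing behaviour.
Recovery results on synthetic data are a statement about the estimator
under the stated noise model, not about field accuracy.

A total-collection emulator integrates marker and fecal DM flow over
collection intervals (adaptive quadrature per interval) for
validation-style designs; by `τ + 20/k₂` it recovers ≥ 99.9% of the dose.

## Numerical choices

- Equal-rates switch tolerance `|λ₁ − k₂| < 10⁻⁶ k₂`; concentrations are
  clamped at ≥ 0 to absorb round-off near the switch.
- AUC/quadrature agreement asserted at relative 10⁻⁶, residence-time
  moment agreement at 10⁻⁵ over 1,000 random parameter draws.
- Peak time located by bounded scalar minimisation on
  `[τ, τ + 6/λ₁ + 3/k₂]` (the mode always lies well inside).
- CSV outputs are written at fixed precision so identical runs produce
  byte-identical files.

## Problem sizes used by the verification suites

Parameter recovery uses 200 seeded replicates of the 14-sample schedule
(medians: |rel. err.| ≈ 4% for k₂, 5% for τ, 2–3% for RTG and FO at the
default noise). The null study uses 30 seeded summer cohorts, the
effect-recovery study 100 seeded summer cohorts with a +2 kg fill effect
injected into the inefficient group — the effect is injected in summer
only, so spring cohorts would add runtime without information.

## Known limitations

- No per-fit standard errors for the kinetic parameters (none are
  reported in the procedure this reproduces); uncertainty enters only at
  the group level as SE across animals.
- The k₂ cap makes boundary solutions likely when true passage is fast;
  they are flagged, but downstream quantities inherit the truncation.
- The delay τ is weakly identified when sampling starts well after the
  marker front (first sample ≥ 15 h vs τ up to ~21 h); the multi-start
  grid mitigates, and recovery medians stay within ~5%.
- The dose-dilution fecal output presumes complete marker recovery;
  with recovery r the estimate is biased by 1/r, which is exactly the
  inflation the validation adjustment factor corrects at the intake level.
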