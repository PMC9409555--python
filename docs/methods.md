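# Methods

## Scope and data model

The package operates on irregular laboratory time series: per patient an
ordered list of assessments (integer day relative to the first treatment
day; negative = before therapy), each holding any subset of the four
analytes — leukocytes (LEU, /nl), thrombocytes (THR, /nl), LDH (U/l)
and CRP (mg/l).  Two draws on the same calendar day are treated as one
assessment.  A patient carries a binary pyrexia label and the onset
day(s) of independent episodes; all evaluation logic uses the first
episode only.

Raw concentrations are normalized to `100 · raw / reference`, with
references CRP 2.5 mg/l, LDH 125 U/l, THR 275 /nl and LEU 6.5 /nl
(male) / 6.0 /nl (female).  Only the leukocyte reference is
sex-specific — the other three analytes have a single published
reference — but the whole mapping is overridable via a JSON/YAML
configuration, so fully sex-specific references can be supplied.

## Score algorithm and version semantics

The score at sampling date t0 is built from eight binary change
indicators: S1–S4 compare t0 with the immediately preceding assessment
t−1 (regardless of gap length; an optional maximum lookback is
deliberately not imposed because the sampling process itself is
irregular), S5–S8 repeat the comparison for t−1 vs t−2.  The change
test is a **ratio** test of `previous/current` against a factor F —
falling analytes (LEU, THR) require the ratio ≥ F with F > 1, rising
analytes (LDH, CRP) require it ≤ F with F < 1 — because the published
factors are dimensionless and near 1.  The absolute gate T applies to
the **current** value: a fall only counts once the value is already low
(≤ T), a rise only once it is already high (≥ T); this reading makes
the CRP gate T4 = 800 (20 mg/l) a plausible inflammation floor.  A
missing value, a missing predecessor assessment, or a current value of
exactly 0 (undefined ratio) yields indicator 0; there is no imputation
or interpolation.

Version semantics are cumulative:

1. **v1** — S1–S4 only, unit weights: the plain count of expected
   changes at t0 (maximum 4).
2. **v2** — adds S5–S8, rewarding a trend sustained over two intervals
   (maximum 8).
3. **v3** — weights the indicators with FS1–FS8.
4. **v4** — multiplies by OA1–OA6 for each pair of co-occurring t0
   changes (pairs: LEU↓THR↓, LEU↓LDH↑, LEU↓CRP↑, THR↓LDH↑, THR↓CRP↑,
   LDH↑CRP↑); all applicable factors multiply jointly.
5. **v5** — damps by IS when the infection signature fires and by GC
   when CRP at t0 is below CT (a missing CRP leaves the gate open by
   design, since pyrexia is assumed to raise CRP).

The absolute gates T are active in all versions.  This keeps the
version ladder strictly nested — unit OA factors collapse v4 onto v3,
unit weights collapse v3 onto v2, and dropping the t−1 block collapses
v2 onto v1 — which the test suite enforces pointwise on random
timelines, along with the damping-monotonicity property (v5 ≤ v4
everywhere).

The infection signature requires a joint **rise** of leukocytes and CRP
(each tested like a rising indicator with factors IC and floors IM).
Thrombocyte and LDH rises are also observed in bacterial infection but
with lower sensitivity; these two conditions are evaluated and exposed
but excluded from the default conjunction (`infection_mask`
configurable).  The damping factor IS is not part of the published
variable table, which pins only "much smaller than 1"; the default
IS = 0.1 mirrors the CRP-gate factor GC and is configurable — results
that depend on IS should be read with that in mind.

`max_attainable_score` enumerates all 256 indicator patterns and
maximizes the weighted sum times the simultaneity product of the
pattern.  For the default parameters this is 19.40 × 5.1744 = 100.383
(the all-ones pattern), but enumeration keeps the bound exact even for
parameter sets with OA factors below 1, where the plain product formula
over-counts.

## Time clusters

Four windows, anchored at treatment start T (= day 0) and pyrexia onset
P, each contribute at most one assessment per patient: pre_T
[T−33, T−1], post_T [T+1, T+21], pre_P [P−23, P−1], post_P [P, P+28]
(P0 inclusive).  Non-pyrexia patients run through the same code path
with a pseudo-onset, by default the cohort's mean first-onset day
rounded to the nearest day.  Two rules the cluster definition leaves
open are fixed as follows and kept configurable: within a window the
assessment **closest to the anchoring event** is chosen (T for the
first two windows, P for the last two; ties break toward the later
day), and when windows overlap — inevitable when onset is below ~45
days — the pyrexia-proximal clusters pre_P/post_P claim their
assessment first, the treatment-anchored clusters then pick from the
remainder.  An assessment never serves two clusters.

## Objective and one-round optimization

The tuning objective scores the whole cohort and forms M0P (mean score,
non-pyrexia assessments), MWP (mean, pyrexia assessments) and MWP14
(mean over pyrexia assessments within ±7 days of first onset), combined
as `ratio_all = MWP/(M0P+MWP)` and `ratio_14 = MWP14/(M0P+MWP)`.
`ratio_all` lies in [0, 1]; `ratio_14` has the same denominator but a
window-restricted numerator and routinely exceeds 1 on well-separated
cohorts — it is a ratio of means over different observation sets, not a
proportion.  An all-zero cohort makes both ratios undefined (0/0); this
is reported explicitly rather than coerced.

The search reproduces a deliberately primitive procedure: a **single
pass** over the variables (default order F1–8, T1–8, FS1–8, OA1–6, IS,
GC, IC1–4, IM1–4), each visited once.  Per variable the family
increment (0.01 on ratio/weight scales, 10 on the normalized-percent
scale of the absolute gates, matching the printed precision of the
published values) is walked upward one step at a time until a ratio
strictly decreases or `max_steps_per_variable` (default 50) is reached;
if the upward walk yields nothing, downward is tried.  A candidate is
*kept* only if both ratios are non-decreasing and at least one strictly
increases; flat steps — common for the absolute gates, where a 10-point
move often crosses no observation — are traversed but not kept, so the
retained value is the best of the walk.  Visual-separation judgments
that accompanied the original tuning cannot be automated and are
replaced by this joint-ratio rule.  The step bound is needed because a
weight whose indicator never fires in controls improves the ratio
indefinitely.  The procedure is deterministic given cohort, order and
step table; the audit trail records every objective evaluation.  Inside
the search, scoring runs on a vectorized snapshot of the cohort; the
test suite pins it to the reference scorer at 1e-12 across versions.

## Cohort evaluation

Association analyses treat each scored assessment as one observation
carrying its patient's label; per-patient validation uses the maximum
score of a timeline against a threshold (both levels are exposed for
the ROC).  AUC is the rank-based, tie-aware statistic.  The chi-square
helper is the plain Pearson test (1 df, no continuity correction).

For the quartile odds ratios the pyrexia observations' score quartiles
(inclusive-median quantile convention) define the bins; bins are
lower-closed, so a score equal to a boundary belongs to the upper
quartile, matching "predict pyrexia at score ≥ bound" threshold
semantics.  Two constructions are provided:

* `binning="label"` — the literal construction: dummy 0 for every
  non-pyrexia observation, quartile 1–4 for pyrexia observations.
  Because the dummy then determines the outcome, maximum-likelihood
  logistic regression is completely separated; the affected quartiles
  are reported with an infinite odds ratio and a `separated` flag
  instead of a spuriously converged estimate.
* `binning="score"` (default in the CLI) — the quartile boundaries are
  applied to *all* observations and the lowest occupied quartile is the
  reference, giving finite ML odds ratios whenever the score
  distributions overlap.  With zero-inflated scores tied boundaries can
  empty the lowest quartiles; the reference then shifts up accordingly.

Confidence intervals are 95% Wald intervals on the log-odds scale
(z = 1.959964) from a plain logistic fit — an intentional
simplification of a nested mixed-effects analysis, which is out of
scope.  The proposed classification threshold is the lower bound of the
lowest quartile whose interval excludes 1.

## Synthetic cohorts

The simulator generates what the score assumes about real data, nothing
more:

* **Onset days**: log-normal truncated to [5, 79] days with log-mean
  3.50677 and log-sd 1.06151, solved so the truncated distribution has
  mean 31.0 and median 26.5 days.
* **Sampling**: one pre-treatment draw, then irregular gaps — 2–7 days
  while day < 21 or within ±10 days of onset, 7–21 days otherwise — up
  to a 120-day follow-up; each analyte is independently missing with
  probability 0.10 per assessment.
* **Baselines and noise**: per-patient log-normal multipliers around
  normalized 100 (CV 0.15) and multiplicative log-normal measurement
  noise (CV 0.05), keeping every value positive.
* **Pyrexia signature**: piecewise log-linear bump from 14 days before
  onset to the onset peak — CRP ×4–16, LDH ×1.3–2.0, leukocytes and
  thrombocytes ×0.60–0.85 (log-uniform per patient) — resolving to
  baseline within 10 days after onset, reflecting treatment
  interruption.
* **Infection episodes**: with probability 0.2 per patient, a 7-day
  episode in which CRP (×4–10) and leukocytes (×1.3–2.0) rise together,
  placed clear of the pyrexia window.
* The cohort is ~65% male, matching the development cohort's sex
  balance.

Ground truth (onset, signature and infection windows) is emitted
separately from the cohort files so evaluation code cannot peek.  What
the simulator does **not** model: multiple pyrexia episodes,
treatment-response drift of LDH with tumor burden, correlated
missingness (real CRP is measured *because* fever is suspected),
inter-analyte baseline correlation, laboratory batch effects.  Passing
tests on synthetic cohorts therefore demonstrate internal correctness
and qualitative discrimination behaviour, not clinical performance.

## Problem sizes and numerical choices

The default test and reproduction runs use 50+50-patient cohorts for
discrimination (patient-level AUC on seeded defaults lands around
0.92–0.96), 1000 patients for onset calibration, 1000 random timelines
for oracle equivalence at 1e-9, and a 30+30 exaggerated-signature
cohort (stronger fold changes, low noise, infection CRP peaks kept
below the CRP gate region) for the optimizer-recovery experiment, where
FS6 (planted 4.84, started 3.84) and T4 (planted 800, started 900) are
re-approached within a 12-step probe per coordinate.  Objective
comparisons use an absolute tolerance of 1e-12; score equality between
the scalar and vectorized paths is enforced at 1e-12; quantiles use
numpy's linear (inclusive-median) rule.

## Known limitations

The score is a detection/confirmation aid, not a severity measure: it
falls back to low values as soon as the laboratory trend flattens, even
while symptoms persist, and must not be read as a treatment-decision
tool.  The odds-ratio module's label-mode construction is reported
honestly as separated rather than reproducing finite published
estimates that plain ML logistic regression cannot yield.  IS is a
documented assumption.  Optimization is order-dependent by
construction; the default order follows the published listing and is
configurable.
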