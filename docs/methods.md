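# Methods

## The estimand and the anchor-based estimator

For an instrument scored so that higher = worse, the change score of
patient *i* over recall period (T0, Tk) is Δᵢ = Xᵢ(Tk) − Xᵢ(T0);
negative Δ is improvement.  A Global Rating of Change (GRC) anchor asks
the patient to rate their change over the same period.  The MCID for
improvement is estimated as

    MCID = mean(Δᵢ : patient i rated a minimal improvement),

with 95% CI `mean ± 1.96·sd/√n` and a paired t-test of Δ against zero.
On the 15-point GRC (−7…+7) *minimal improvement* is +2/+3 (0/±1 no
change, ±4/±5 moderate, ±6/±7 large); on the five-point verbal GRC the
subgroup is *somewhat better*.  Only the improvement side is estimated
by default: deterioration subgroups in rehabilitation cohorts are
typically too small, and a deterioration-side run is available but
flagged experimental.

Assumptions: change scores approximately normal within subgroup
(screened, not enforced), anchor validity |r(Δ, GRC)| ≥ 0.30
(preferably ≥ 0.50), independent patients, pair-wise deletion (a change
score exists only when both endpoint scores are complete; nothing is
imputed).  Estimation proceeds with a warning when the anchor is
formally ineligible, because short-recall (discharge) estimates are
conventionally still reported; the eligibility record travels with the
estimate.

The 1.96 normal multiplier is used rather than a t quantile because the
tables this package replicates use it and subgroup sizes are ≥ 80
there; `multiplier="t"` is available.  Displayed values are rounded
half-away-from-zero at one decimal; machine outputs keep full
precision.  No multiple-testing correction is applied anywhere — the
analysis is descriptive, and this is deliberate and prominent.

## Scoring and standardisation

CAT-like: sum of 8 items (0–5), range 0–40.  CCQ-like: mean of 10
items (0–6), range 0–6, domain scores by the same rule on item
subsets.  SGRQ-like: weighted rule, `scale_max·Σwᵢuᵢ/Σwᵢ` with
uᵢ ∈ [0,1] the item's normalised response — the licensed SGRQ weights
are not redistributable, so the engine reads weights from config and a
deterministic synthetic set ships for tests.  Missing-item policy:
strict by default (any missing item makes the questionnaire
unscorable); for the item-mean rule a config switch allows up to a
chosen number of missing items.  Standardisation to the common 0–100
scale is `×100/scale_max`, applied to totals and change scores alike
(linear, sign-preserving).

## Screening

Normality: sample skewness and excess kurtosis (bias-corrected) must
both lie in [−1, +1].  The excess-kurtosis convention is used because a
±1 window only makes sense around zero for normal data.
Floor/ceiling: an effect is flagged when more than 15% of patients
score in the lowest/highest 10% of the scale range.  Degenerate
(zero-variance) samples are flagged non-normal with an explanatory
note.

## Dependency-adjusted comparison

Estimates from different recall periods of one cohort are positively
dependent.  For two estimates with equal standard errors and
correlation ρ, non-overlap of intervals `mean ± z*·SE` is a two-sided
level-α test of equal means when

    z* = z_{1−α/2} · √(2(1−ρ)) / 2 ,

so z* = 1.386 at ρ = 0, 0.98 at ρ = 0.5, and 0 at ρ = 1.  ρ is taken
as the intraclass correlation between baseline and follow-up scores of
the anchor subgroup.  Two multiplier modes exist: `formula` (default,
the expression above) and `lookup`, a step mapping used in a published
application of the rule (ρ rounded to one decimal: ≤ 0.6 → 0.98,
else → 0.62) kept for exact replication of its tables.  The two
disagree at ρ = 0.7 (formula: 0.76); replication of those printed
cells requires `lookup`, and new analyses should use `formula`.

ICC estimator: ICC(1,1), one-way random effects, single measure —
baseline/follow-up pairs have no rater structure, and the systematic
shift between occasions legitimately counts against agreement.  The
two-way consistency form ICC(3,1) is selectable.  Negative estimates
are truncated to 0 with a warning.  The implementation is the
closed-form k = 2 variance-components expression; the test suite checks
it against a brute-force ANOVA oracle (to 1e−12) and against pingouin.

Verdicts: intervals are *disjoint* under strict inequality — touching
intervals count as overlap (conservative).  Native-scale overlap is
only defined within one instrument; cross-instrument comparison uses
the standardised scale, with standardised mean and SD recomputed from
native values before rounding.  Literature thresholds (CAT 2.00,
CCQ 0.40, SGRQ 4.00, stored as positive magnitudes, compared at
negative sign) use a closed-interval convention: a threshold on an
endpoint counts as inside.

`calibrate_overlap_rule` validates the equivalence by simulation:
replicate pairs of ρ-correlated samples under a true null, adjusted
intervals from the *known* ρ (so the check isolates the rule, not ICC
estimation noise), disjointness rate ≈ α.  At n = 100 and 5000
replicates the realised rate is ≈ 0.049–0.054 for ρ ∈ {0, 0.25, 0.5};
fixing z* = 1.96 shows the naive overlap test's severe conservatism
(rate ≈ 0.000).

## Synthetic cohort generator

The generator emulates a 451-patient inpatient pulmonary-rehabilitation
cohort followed for a year:

* **Baselines** — correlated normals (shared severity factor,
  cross-instrument correlation 0.5) at CAT 20.2 ± 7.3, CCQ 2.9 ± 1.2,
  SGRQ 50.7 ± 17.3, clipped to instrument range.  Clipping replaces
  literal truncated-normal sampling; at these moments the boundary
  mass is < 1%, which keeps the correlation structure exact and the
  score distribution independent of n.  Totals are continuous (CAT is
  not rounded to integers) — a simplification documented below.
* **Follow-ups** — F = μ + effect + ρ(B − μ) + σ√(1−ρ²)·η with
  population parameters, so consistency-ICC(B, F) = ρ by construction;
  η shares a within-period factor across instruments (fraction 0.5).
  Per-period effects default to the published full-cohort change means
  (e.g. CAT −3.1 at discharge drifting to −0.9 at twelve months); ICC
  targets default to the published 0.5–0.7 per instrument × period.
  Because of the mean shift, the one-way ICC(1,1) the pipeline reports
  is somewhat below the consistency target — published ICC values are
  matched approximately, not exactly, on synthetic data.
* **Anchors** — grc15 = clip(round(g·(y + s·ε)/√(1+s²)), −7, 7) with
  y the sign-flipped composite standardised change (mean over
  instruments) scaled by its reference SD, gain g = 2.4, ε ~ N(0,1).
  The noise scale s is found by deterministic bisection against the
  per-period validity target (defaults 0.30 → 0.49, rising with recall
  period) on a fixed-seed 50 000-patient calibration sample.  The
  calibration seed does not depend on the cohort seed: replicates of
  one configuration share a single data-generating law, which is what
  makes "generator truth" well defined.  Validity targets refer to the
  composite change (one GRC must serve three instruments); realised
  per-instrument correlations come out at roughly 0.7–0.8 of the
  composite target, reproducing the realistic pattern of an
  ineligible (< 0.30) discharge anchor.  Infeasible targets (beyond
  what the discretised scale can carry) are rejected with a
  diagnostic.  The five-point GRC collapses the 15-point categories
  (no change ↔ same, minimal/moderate ↔ somewhat, large ↔ much) with
  20% ordinal label noise.
* **Missingness** — observed counts 451/355/319/304/309 at
  T1…T5 (scaled proportionally for other cohort sizes), implemented as
  prefixes of one permutation so the twelve-month set strictly
  contains the nine-month set (five returnees: intermittent
  missingness, not monotone dropout); plus 2/1/4 incomplete discharge
  CAT/CCQ/SGRQ questionnaires and one missing discharge GRC.

What the generator does **not** emulate: integer-valued CAT/CCQ items,
informative (outcome-dependent) dropout, response shift or recall
bias, exacerbation dynamics, and item-level response processes
(item tables can be synthesised to match totals but carry no IRT
structure).  Passing recovery tests therefore show the pipeline's
statistical machinery is correct under its stated assumptions — not
that those assumptions hold in any particular real cohort.

## Validation experiments and problem sizes

* ICC vs ANOVA oracle: 25 random instances of 3–10 patients.
* Overlap-rule calibration: n = 100 per sample, 5000 replicates per ρ.
* End-to-end recovery: 200 replicate cohorts of 451 patients;
  per-replicate 95% CIs for all 18 instrument × scheme × period cells
  are checked against the asymptotic subgroup mean computed once at
  120 000 patients.  Pooled coverage ≈ 0.95 (the acceptance bound is
  ≥ 0.90); the small shortfall from nominal comes from using 1.96
  instead of a t quantile at subgroup sizes of 60–110.
* Generator self-targets: one cohort at n = 5000; baseline means
  within ±0.2, consistency ICCs and anchor-composite correlations
  within ±0.05 of target.

These sizes keep the full suite and the reproduction script each
within about half a minute on one CPU while leaving sampling error
well inside the asserted tolerances.

## Known limitations

* The lookup multiplier mode reproduces its source table verbatim,
  including the internally inconsistent 0.62 at ρ = 0.7; the package
  takes no position on that table's provenance and defaults to the
  formula.
* MCID means themselves, anchor-change correlations on real patients,
  and cross-scheme agreement percentages are cohort properties; the
  package reproduces published *arithmetic* exactly but published
  *patient-level* results only qualitatively, via synthetic cohorts.
* Deterioration-side MCIDs are implemented but unvalidated
  (subgroups are small by design in improvement-oriented cohorts).
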