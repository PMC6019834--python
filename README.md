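# mcidkit

Anchor-based estimation of the **Minimal Clinically Important
Difference (MCID)** for COPD health-status questionnaires, with
dependency-adjusted confidence-interval comparison of estimates across
recall periods and anchor designs.

The MCID is the smallest change on a measurement tool that patients
perceive as beneficial.  The anchor-based approach links an
instrument's change score Δ = score(follow-up) − score(baseline)
(negative = improvement) to a retrospective **Global Rating of Change
(GRC)** question.  `mcidkit` implements the full workflow for three
standard COPD instruments — CAT (8 items, sum, 0–40), CCQ (10 items,
item mean, 0–6) and SGRQ-style weighted scoring (0–100) — over a
baseline-to-twelve-months schedule:

1. **Scoring & standardisation** — score item responses per instrument
   rule and rescale to a common 0–100 scale (×100/scale_max).
2. **Anchor categorisation** — 15-point GRC (−7…+7: 0/±1 no change,
   ±2/±3 minimal, ±4/±5 moderate, ±6/±7 large change) and a
   five-point verbal GRC; anchors are eligible when
   |r(Δ, GRC)| ≥ 0.30 (preferred ≥ 0.50).
3. **MCID estimation** — for each instrument × anchor × recall period,
   the MCID is the mean Δ of the *minimally improved* subgroup
   (+2/+3, or *somewhat better*), with 95% CI `mean ± 1.96·sd/√n`,
   paired t-test vs baseline, pair-wise deletion, and
   skewness/kurtosis ±1 normality screening with a >15% floor/ceiling
   rule.
4. **Dependency-adjusted comparison** — estimates from the same cohort
   share patients, so intervals are narrowed with
   `z* = z₀.₉₇₅·√(2(1−ρ))/2`, where ρ is the baseline–follow-up
   intraclass correlation (one-way random ICC(1,1) by default);
   *non-overlap* of two adjusted intervals is then a 5% significance
   test.  Estimates are also compared with literature thresholds
   (CAT 2.00, CCQ 0.40, SGRQ 4.00 points).
5. **Synthetic cohorts** — a generator reproducing the cohort
   structure the method assumes (451 patients, baseline CAT 20.2 ± 7.3,
   CCQ 2.9 ± 1.2, SGRQ 50.7 ± 17.3, discharge improvement, ICC 0.5–0.7,
   calibrated anchor validity, dropout 451→355→319→304→309 with
   twelve-month re-entry), so every stage is testable without any
   external data.

## Worked example

Adjusted comparison of the CAT MCID across recall periods, straight
from published summary rows (mean, SD, N, ICC) — no patient-level data
needed:

```python
from mcidkit.comparison import overlap_matrix
from mcidkit.report import (comparisons_from_summary,
                            comparison_table, load_reference_summaries)

summary = load_reference_summaries()
cat = summary[summary.instrument == "CAT"]
comps = comparisons_from_summary(cat, mode="lookup")
print(comparison_table(comps)[["period", "scheme", "n", "mean",
                               "icc", "z_star", "ci_display"]])
```

```
period scheme   n  mean  icc  z_star   ci_display
    T1  grc15 196  -3.1  0.7    0.62 -3.3 to -2.9
    T2  grc15 107  -2.7  0.6    0.98 -3.3 to -2.1
    T3  grc15  96  -2.7  0.5    0.98 -3.4 to -2.0
    T4  grc15  80  -2.3  0.6    0.98 -3.0 to -1.6
    T5  grc15  88  -2.8  0.5    0.98 -3.5 to -2.1
    T5   grc5  81  -1.4  0.6    0.98 -2.0 to -0.8
```

Each row is one MCID estimate (CAT points; negative = improvement)
with its dependency-adjusted interval `mean ± z*·sd/√n`.  The
15-point-GRC intervals all overlap one another — the recall period has
little impact — while the five-point twelve-month interval
(−2.0 to −0.8) is disjoint from the 15-point twelve-month interval
(−3.5 to −2.1): an anchor with fewer reply options yields a
significantly lower absolute MCID.  `overlap_matrix(comps)` returns
exactly these verdicts.

End-to-end on synthetic patients:

```python
from mcidkit import make_fixture, estimate_mcid
cohort, truth = make_fixture("cohort451")
est = estimate_mcid(cohort, "CAT", "grc15", ("T0", "T5"))
print(est.n, round(est.mean, 1), tuple(round(c, 1) for c in est.ci95))
# 60 -3.7 (-5.2, -2.3)
```

The `examples/` directory has one short script per capability
(scoring, estimation, adjusted comparison, simulation, overlap-rule
calibration).  A thin CLI mirrors the same operations:
`mcid simulate|estimate|compare|report --help`.

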