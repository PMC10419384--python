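# olfact

Tools for studying **post-viral olfactory dysfunction (PVOD)** with the two
olfactory function tests used routinely in Japanese clinics, plus a synthetic
mouse olfactory-bulb imaging pipeline that links the clinical response pattern
to the bulb's DI/DII domain organization.

The package has two arms:

1. **Clinical diagnostics.** Patients take an orthonasal test (T&T
   olfactometry: five odorants, averaged recognition threshold; no response
   when the average is ≥ 5.6) and a retronasal test (intravenous prosultiamine,
   "IVO": a response is any perceived garlic odor within 3 min). Each patient
   falls into one of four combinations — T&T(+)IVO(+), T&T(+)IVO(−),
   T&T(−)IVO(+), T&T(−)IVO(−). For a disease D and combination C, the 2×2
   table (a = C∧D, b = C∧¬D, c = ¬C∧D, d = ¬C∧¬D) gives

   - odds ratio `OR = ad/(bc)` with Wald 95 % CI
     `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`,
   - sensitivity `a/(a+c)`, specificity `d/(b+d)`,

   and a univariable logistic screen (IRLS, Wald p < 0.05) selects predictors
   for a multivariable logistic fit. A deterministic 307-patient fixture
   expands the published per-disease marginals into patient-level records, and
   a parametric simulator draws fresh cohorts.

2. **Imaging analysis.** Synthetic dorsal-bulb GCaMP movies (2 frames/s, 10-s
   odor pulses, ≥ 5 trials/odor, ≥ 60 s between stimuli, 100-µm glomeruli,
   shared exponential photobleach) are analyzed with the standard pipeline:
   circular-ROI traces, ΔF/F₀ = (F−F₀)/F₀ against the 10-s pre-stimulus
   baseline, photobleach correction by subtracting the mean ΔF/F of
   nonresponsive glomeruli, and a one-sided paired t-test (p < 0.05) comparing
   the 10 s after odor onset with the 10 s before. Synthetic NQO1-immunostained
   coronal sections are thresholded (positive when a glomerulus exceeds the
   connective-tissue background mean by 2 SD), reconstructed into a dorsal
   DI/DII domain map, and responsive glomeruli are assigned to domains for
   chi-square and Mann–Whitney comparisons.

## Worked example

```python
from olfact import (build_paper_cohort, make_table, diagnostics,
                    Disease, Combo, chi_square_test)

cohort = build_paper_cohort()            # 307 patient records
table = make_table(cohort, Disease.PVOD, Combo.PN)   # T&T(+) IVO(-) vs PVOD
print(table)                             # ContingencyTable(a=48, b=17, c=70, d=172)
d = diagnostics(table)
print(f"OR {d.odds_ratio:.1f}  sens {d.sensitivity:.0%}  spec {d.specificity:.0%}")
# OR 6.9  sens 41%  spec 91%

print(chi_square_test([[15, 20], [40, 4]]))
# TestResult(statistic=21.281188508461234, df=1,
#            p_value=3.966044971528976e-06, method='chi-square')
```

The first block says that responding to the orthonasal odors while missing the
intravenous odor multiplies the odds of PVOD roughly seven-fold and rules the
disease *in* with high specificity. The chi-square block tests whether the two
odor panels activate the bulb's DI and DII domains in the same proportions
(15/20 vs 40/4 responsive glomeruli): they clearly do not — the intravenous
odor is DI-selective.

The same analyses run from the shell:

```bash
olfact reproduce-paper --outdir results --seed 1
olfact simulate-cohort --out cohort.csv --seed 3
olfact diagnostics 48 17 70 172
```

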