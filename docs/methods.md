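# Methods

## Clinical arm

### Test scoring

**T&T olfactometry.** Five odorants; odors A, C, D, E span recognition-threshold
degrees −2…5, odor B spans −2…4. A "not recognized" (NR) odor is encoded as one
degree above its maximum (6, or 5 for odor B). This encoding is the unique
integer rule consistent with the published scale endpoints: all odors
recognized at the minimum gives an average of −2, nothing recognized gives 5.8.
The averaged score over the five odors classifies the test: **no response when
the average is ≥ 5.6** (boundary inclusive on the no-response side), response
otherwise. Because any fully recognized profile averages at most 4.8, a
non-response requires at least one NR odor.

**IVO test.** Latency is the time from the start of the intravenous
prosultiamine injection to the first report of a garlic odor; duration is the
length of the percept. A response is a percept within the 3-minute window,
encoded as latency ≤ 180 s inclusive; non-responders are stored with absent
latency/duration (right-censored at 180 s). Latency < 10 s is a normal onset;
duration > 60 s a normal duration.

The pair of boolean responses maps to four categories (T&T sign first):
PP, PN, NP, NN.

### Cohort fixture and simulator

Only per-disease marginals are published: the four combination counts, the
male/female totals, and mean ± SD of age, latency, duration and recognition
score for PVOD (N=118), CRS with polyps (117), CRS without polyps (44) and
PTOD (28). `build_paper_cohort` expands them deterministically (fixture seed
20230729): combination and sex counts are exact; ages are drawn from the
published mean ± SD, clipped to 18–90 y. Because the sex×combination and
age×combination joint distributions are not published, **sex and age are
assigned independently of the combination within each disease**. Analyses that
depend on those joints (e.g. the multivariable coefficient of sex) are
therefore fixture artifacts and are not reported as reproduction targets. The
per-odor thresholds of responders are integers jittered around a target drawn
from the disease's recognition-score distribution; non-responders are all-NR,
or occasionally four NR plus one odor at its maximum degree, which lands
exactly on the 5.6 boundary and exercises it. One published internal
inconsistency is resolved in favor of the combination counts: the CRS-without-
polyps IVO-response marginal (39/5) disagrees with the combination counts
(34+4 = 38 responders of 44); the fixture realizes 38/6.

`simulate_cohort` draws fresh cohorts from a `CohortSpec` (per-disease N,
combination probabilities, sex fraction, and the four mean/SD pairs) whose
defaults are the published marginals. Records always re-score to their drawn
combination by construction.

### Diagnostics

Crude 2×2 odds ratios with Wald 95 % CIs (not profile likelihood — Wald matches
the reporting precision of the source tables); the Haldane–Anscombe 0.5
correction is off by default and, when enabled for zero cells, applies to the
OR/CI only, never to sensitivity/specificity. The four headline signatures are
computed as crude ORs because the published text values (6.9, 6.6, 4.0, 8.4)
equal the crude ORs implied by the combination counts, whereas the published
multivariable columns require the unprinted joints.

Logistic regression is Newton–Raphson/IRLS on the Bernoulli log-likelihood:
start at β = 0, convergence when the score max-norm < 1e−8, at most 50
iterations, separation declared when any |β| exceeds 15 during iteration.
Standard errors come from the inverse observed information; Wald z with
two-sided normal p-values. The univariable screen fits each candidate alone
with an intercept and selects Wald p < 0.05; per-predictor failures
(separation, collinearity) are recorded without aborting the screen. On the
fixture, the screen selects PN (β = ln 6.94 ≈ 1.94, p < 0.001) and NP
(negative predictor) but neither PP nor NN; the published univariable table is
internally inconsistent with the combination counts for PP (printed p = 0.04
vs p ≈ 0.19 from the counts), so only count-consistent quantities are targeted.

Chi-square: Pearson statistic Σ(O−E)²/E, expected counts from the margins, df
=(r−1)(c−1), upper-tail p; Yates continuity correction available for 2×2
tables but off by default (the uncorrected statistic already reproduces the
published p < 0.001 bound). Mann–Whitney U uses midranks; for tie-free samples
with n_x·n_y ≤ 400 the p-value is exact via the counting recurrence
N(u; n, m) = N(u−m; n−1, m) + N(u; n, m−1), otherwise a normal approximation
with tie-corrected variance (no continuity correction). With every pooled
value identical the variance is zero and p = 1 is returned.

## Imaging arm

### Forward model

Movies: `pixel(t) = baseline·exp(−λt)·(1 + ΔF/F(t)) + N(0, σ)`, frames at
2 /s, 5 µm/pixel (default field 512×512 ≈ 2.5 mm; the packaged experiment
replica uses 256×256 to keep memory modest), glomeruli as 100-µm circles with
center-in-circle pixel membership shared with the analysis ROIs. The response
waveform rises linearly to the planted amplitude over 1 s, holds through the
10-s stimulus, then decays exponentially (τ = 4 s). The stimulus schedule is a
block design, ≥ 5 trials per odor, exactly 60 s between stimuli. Bleaching is
a single exponential shared by all pixels, matching a correction scheme that
subtracts a reference trace. Noiseless movies are rendered in float64 (their
role is exactness checks); noisy movies in float32, clipped at zero.

Sections: each glomerulus is a sphere at 100 µm depth; a coronal section at
anteroposterior position z shows the circle of radius √(r²−dz²). Section
spacing defaults to 40 µm (not specified by the source protocol;
configurable). The bottom quarter of each section is the connective-tissue
band under the lamina propria, pixels ~ N(bg_mean, bg_sd). DI glomeruli stain
at bg_mean + k·bg_sd (default contrast k = 5), DII glomeruli at the background
mean, with optional per-section and per-pixel noise.

What the generators deliberately omit: optics/PSF blur, motion, hemodynamic
contamination, pharmacokinetics of the intravenous odorant, inter-glomerular
baseline structure, and any registration error between the imaging and
histology frames (both use one shared coordinate frame). Passing tests
therefore validate the *analysis logic* — windowing, correction, calling,
thresholding, projection, assignment — not robustness to those real-data
nuisances.

### Analysis pipeline

ROI traces are pixel means over 100-µm circles; F₀ is the mean of the 20
frames (10 s) immediately before each odor onset — the source protocol says
only "before stimulation", so the window is made symmetric with the 10-s post
window. Response calling compares per-trial post- vs pre-window means with a
**one-sided paired t-test across trials** (increase only; inhibitory responses
are out of scope). The protocol does not name the test; a paired t across ≥ 5
trials is the minimal model consistent with per-recording repetition, and a
Wilcoxon signed-rank alternative sits behind a flag. When the across-trial
variance of the differences is below numerical resolution the t statistic is
undefined and the call is resolved by the sign of the common difference. The
magnitude is the peak of the trial-averaged ΔF/F in the post window (peak
rather than window mean; flag-selectable upstream quantities are exposed in
the call record). No multiple-testing correction is applied across ROIs,
matching the emulated analysis; consequently, at α = 0.05 roughly 5 % of the
truly unresponsive (ROI, odor) pairs are called responsive in any noisy run —
exact planted-count recovery is a noiseless property, and noisy replicas
recover counts to within a few false positives.

Bleach correction is two-pass, since the emulated protocol does not say how
nonresponsive glomeruli were chosen: pass 1 calls responses on uncorrected
ΔF/F; ROIs nonresponsive to every odor form the reference, whose mean ΔF/F
time course is subtracted per trial; pass 2 re-calls on the corrected traces.
If every ROI responds, the correction is skipped with a warning. Subtracting
an additive reference from a multiplicative bleach leaves a second-order
residual ≈ amplitude·λ·Δt (Δt ≈ 6 s between the baseline-window center and
the response peak); at the mild default bleaching (λ = 2·10⁻⁴–2·10⁻³ s⁻¹,
i.e. ~10–70 % signal loss over a 10-minute session) this residual is ≤ 10⁻³–
10⁻² of the amplitude. Very aggressive bleaching additionally inflates the
relative noise of late-trial F₀ estimates; the property checks use the mild
regime.

NQO1 positivity is strict: intensity > background mean + 2·sample SD (n−1).
The dorsal map takes, per coronal column, the label of the dorsal-most
labelled voxel — deeper glomeruli are invisible from the dorsal surface. ROIs
take the domain of their center pixel (majority vote over the footprint behind
a flag); ROIs over unlabeled pixels are UNASSIGNED and excluded from counts.
Odor×domain counts feed the chi-square test; responder magnitudes are compared
between domains per odor with a two-sided Mann–Whitney U.

### Experiment replica

`reproduce_imaging` plants the published responder scale — 35 orthonasal-mix
responders (15 DI / 20 DII) and 44 intravenous-odor responders (40 DI / 4 DII)
plus 10 nonresponders — on a shuffled grid, amplitudes N(0.30, 0.05) for the
mixture and N(0.55, 0.08) for the intravenous odor (the latter stronger, as in
the recorded data), 5 trials per odor, noise σ = 2 on a baseline of 100, λ =
0.002 s⁻¹. The field is 256×256 px at 5 µm/px so the full movie (~1360 frames)
stays near 350 MB. A published glomerulus-level discussion figure of 93.2 %
DI among intravenous-odor responders conflicts with the underlying counts
(40/44 = 90.9 %); the counts are taken as authoritative.

## Numerical and design notes

- Coordinates are 0-based `(t, row, col)`; rows anterior→posterior, columns
  medial→lateral; ROI/glomerulus pixel membership is center-in-circle with
  distance ≤ radius.
- Exact Mann–Whitney enumeration is limited to n_x·n_y ≤ 400 and tie-free
  pooled samples; with ties the tie-corrected normal approximation is used at
  any size.
- The fixture seed and all simulation seeds are explicit arguments; every
  pipeline run emits a manifest (config hash, seed, versions).
- CLI exit codes: 0 success, 2 validation error, 3 numerical failure.

## Known limitations

- The cohort fixture cannot reproduce any statistic that depends on the
  unpublished sex×combination or age×combination joints.
- The bleach model is a single shared exponential; spatially heterogeneous
  bleaching would not cancel exactly under reference subtraction.
- Domain mapping assumes the histology and imaging share one coordinate frame;
  cross-modal registration is out of scope.
- The detection test treats trials as exchangeable within a recording;
  adaptation across trials is not modelled.
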