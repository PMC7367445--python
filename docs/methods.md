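# Methods

This note documents the models, defaults and numerical choices behind
`afscreen`, in the order the pipeline runs them.

## 1. Synthetic cohort generator

The generator emulates a single-time-point screening cohort of over-65s
attending influenza-vaccination clinics.

**Demographics.** Ages are drawn as `65 + Gamma(shape=1.8661,
scale=5.3761)` truncated at 100 and floored to whole years; the shape and
scale were fitted once so the floored quartiles land on (69, 73, 78)
years. Only these quantile targets are contractual — the gamma family is a
convenience. Sex is Bernoulli(0.427 male). BMI is log-normal
(μ = 3.2655, σ = 0.1641 on the log scale, i.e. median ≈ 26.1 kg/m²,
IQR ≈ 23.5–29.3); height is normal (167 ± 10.4 cm with a ±4 cm sex
offset) and weight is derived as BMI·(height/100)², then all three are
rounded to one decimal and BMI recomputed so the stored triple is exactly
consistent. Alcohol use (62.9%) and smoking (8.9%) are independent flags.

**True rhythm.** Each participant is latently SR, AF or "other
abnormality" (ectopy, conduction block — real but not AF). Defaults:
3.0% known AF (documented history, anticoagulated, in AF on the day),
1.3% undiagnosed screen-detectable AF, 11.4% other abnormality. A further
7% of the sinus-rhythm stratum carries a paroxysmal-AF history flag
(`latent_af_in_sr_fraction`): these participants are invisible to a
single-time-point screen, which is why the cohort's true AF burden exceeds
its screen-day prevalence.

**Comorbidities** are sampled independently *within* AF stratum, with two
prevalence vectors (e.g. hypertension 69.2% vs 40.9%, renal disease 42.3%
vs 17.2%). Only marginal prevalences are identifiable from the summary
data the generator targets; any joint structure beyond the AF/non-AF
stratification is not modelled, so analyses of comorbidity co-occurrence
on synthetic data are not meaningful.

**Rater calls.** Each of the four raters has a conditional distribution
over {SR, AF, UNCLASSIFIED, UNREADABLE} given true rhythm; calls are
conditionally independent given rhythm (drawn with a single inverse-CDF
lookup per rater). The default matrices were back-solved once from a
published accuracy table and category counts (device 92.3%/97.4%
sensitivity/specificity, pharmacist 88.5%/97.2%, pulse 76.9%/92.2%, with
marginal call counts 39/39/65 AF calls per 604); they are derived
defaults, fully overridable. Because pharmacists see the device's output
during screening, an optional `pharmacist_follows_device` probability (the
pharmacist copies the device call; default 0) is provided. Unreadable is a
*rater outcome*, not a participant property, so pairwise-exclusion logic
downstream is genuinely exercised. The model-implied operating point of a
rater (`implied_operating_point`) accounts for the exclusion of unreadable
calls from both the numerator and denominator.

**Seeding.** One global seed fans out to per-stage child streams (cohort,
rhythm, calls, follow-up, PSA) via `numpy` `SeedSequence` spawn keys with
fixed offsets, so any stage can be re-run independently and the whole
pipeline is byte-reproducible.

## 2. Diagnostic accuracy

Calls are dichotomised by a `DichotomyPolicy` partitioning the four
categories into positive / negative / excluded. Two conventions matter:

* **default**: {AF} positive, {SR, UNCLASSIFIED} negative, {UNREADABLE}
  excluded pairwise (a pair is dropped if either side is unreadable).
* **`published_tables`**: unreadable counted as negative, nothing
  excluded. Reverse-engineering the published accuracy table of the
  reference screening programme shows this is the convention its software
  used: it reproduces *every* printed point value and confidence interval
  (including pulse specificity 92.2%, accuracy 91.6% and pharmacist
  accuracy 96.9%, which no exclusion-based reconstruction matches).

Unclassified counting as AF-negative is forced by the published
denominators (reference negatives = 503 normal + 69 unclassified) and is
clinically the right call for an AF screen: an unclassified trace is not
an AF diagnosis.

Proportions carry exact Clopper–Pearson intervals computed from beta
quantiles; the endpoints are exactly 0 at x = 0 and 1 at x = n. Cohen's κ
uses the dichotomised 2×2 with the simple asymptotic standard error
`sqrt(p₀(1−p₀)/n)/(1−pₑ)` (this reproduces the reference table's κ
intervals). McNemar's test uses the exact two-sided binomial on the
discordant pairs when b + c < 25 and the continuity-corrected χ²
otherwise, both selectable; no discordant pairs gives statistic 0, p = 1
by convention. Cochran's Q runs on the complete-case subset where every
rater's call is usable; with k = 2 it reduces to the uncorrected McNemar
statistic. Bonferroni correction uses m = 3 (the three pairwise
index-test comparisons) by default. Display rounding is percentages to
one decimal and κ to two; internal values are never rounded.

## 3. Screening pathway

Triage is a pure function of the cardiologist read, AF history,
anticoagulation status and device heart rate: normal SR → normal-result
letter (unless the rate is outside 40–120 bpm, which triggers a referral);
possible AF with a known anticoagulated history → no action; known but not
anticoagulated → GP review; otherwise → 12-lead ECG referral; unclassified
or unreadable → referral. Final classification requires a confirming
12-lead ECG for `new_af`; a referred participant whose follow-up shows SR
is `af_not_confirmed` (if AF had been suspected) or `normal`; non-AF
follow-up diagnoses are split into *new* (labelled from a closed list:
LVH, BBB, AVB, AEB, VEB, sinus brady/tachycardia, other) and *previously
diagnosed* (`known_non_af_diagnosis` — added to the status set because the
follow-up flow has an explicit "known condition, no further intervention"
arm). Unknown labels are rejected at parse time.

CHA₂DS₂-VASc uses the standard weights (C1 H1 A≥75:2 D1 S2 V1 A65–74:1
Sex-female:1); HAS-BLED scores one point per present component.
Anticoagulation eligibility is the sex-adjusted ESC rule — score ≥ 2 for
men, ≥ 3 for women — with configurable thresholds for sensitivity
analyses. Prevalence accounting reports known AF (history + cardiologist
AF read), new AF (12-lead confirmed) and totals, each over the full
screened denominator with exact intervals.

## 4. Markov cost-utility model

Six states: undetected AF, detected AF on OAC, detected AF without OAC,
no AF, post-stroke, dead; one-year cycles from age 73 to 100; NICE
reference-case discounting (3.5%/year, costs and QALYs). The engine
validates row sums (tolerance 1e-9) and absorbing death before any cycle
runs, asserts occupancy conservation every cycle, and accrues per-cycle
costs/utilities on start-of-cycle occupancy (simple cycle sums; a
half-cycle-correction flag averages start and end occupancy). Stroke
events are costed on flows *into* the post-stroke state — fatal strokes'
acute costs and recurrent strokes are not separately modelled.

Screening enters only through the initial distribution and one-off costs:
with undetected-AF prevalence π (default 1.3%, the screen-detectable
fraction), uptake u, sensitivity Se and specificity Sp,

    P(detected)        = π·u·Se       → on-OAC branch (× OAC acceptance 0.75)
    P(false positive)  = (1−π)·u·(1−Sp) → confirmation cost only
    one-off cost       = u·c_screen + (detected + false positives)·c_12LECG

The deterministic run and the PSA share one vectorised backward-induction
kernel (state-value iteration `V_t = accrual + δ·P·V_{t+1}`), so a PSA
with all point-mass distributions reproduces the base case draw for draw,
bit for bit; a forward occupancy trace (`run_cohort`) is kept as an
independent path and agrees with the kernel to machine precision.

**Default parameters (a labelled reconstruction).** No parameter file from
the original evaluation is available, so the defaults are assembled from
UK AF costing and screening-evaluation literature: untreated AF stroke
probability 4.5%/year, relative risk 0.36 on anticoagulation, 0.8%/year
stroke risk without AF, 20% stroke case fatality, 3%/year background
mortality with +8% post-stroke, 8%/year incidental (routine-care)
detection of undetected AF, 2%/year AF incidence; stroke event £11,626,
post-stroke care £3,436/year, anticoagulation £450/year, AF management
£120/year, screening £2.50 (pulse) / £9.00 (device), 12-lead ECG
confirmation £40; utilities 0.80 (no AF), 0.774 (AF), 0.39 (post-stroke).
Strategy operating points default to the published accuracy table. Any
economic result produced with these defaults characterises *this
reconstruction*, not the original evaluation; the YAML model file
(`save_model_file`/`load_model_file`) accepts a replacement parameter set
verbatim.

**PSA conventions.** Beta for probabilities and utilities, gamma (CV 20%)
for costs, log-normal for the OAC relative risk; test sensitivities and
specificities draw from the beta posteriors of the published 2×2 counts
(e.g. device sensitivity ~ Beta(24, 2)). All strategies are evaluated on
the same draw (common random numbers), so CEAC differences reflect
strategy, not sampling noise. 100,000 draws of the six-state model run in
a few seconds on one CPU.

**Known limitation.** The model has no bleeding-harm state: anticoagulant
haemorrhage risk and disutility are not represented. Screening therefore
almost never harms in any PSA draw, and the acceptability probability at
moderate thresholds saturates near 1 under the default uncertainty. A
bleeding state (with HAS-BLED-stratified rates) is the natural extension.

## 5. The deterministic reference cohort

`afscreen.study.reference_study_cohort()` reconstructs a 604-row cohort
whose cross-tabulations reproduce a published screening programme's
counts exactly (cardiologist 503/26/69/6 across the four categories;
device 484/39/75/6 with 24 true positives; pharmacist 487/39/71/7 with 23;
pulse 526/65/12/1 with 20; 18 known + 8 referred AF; 87 follow-ups
resolving to 4 confirmed AF, 28 normal, 22 previously-diagnosed, 28 new
non-AF including 8 first-degree AV blocks, 1 decline, 4 non-responses).
Assignments the summary counts do not pin down — which individual rows
carry which errors, individual ages and comorbidities — are filled
deterministically (demographic noise from a fixed internal seed), so the
cohort is byte-identical across runs. It is a synthetic stand-in for the
original case-report data: cross-tabulations *between* index tests beyond
their published margins, and all person-level covariate relationships, are
constructions, not data.

## 6. What the tests do and do not show

Tests verify: exact reproduction of the published accuracy table and
prevalence figures from the reference cohort; oracle equivalences
(McNemar exact p against direct binomial tail summation for every
discordant split ≤ 20, Cochran Q (k=2) against the uncorrected McNemar
statistic, κ against the defining agreement formula, statsmodels
cross-checks); generator determinism and marginal convergence; and
engine properties (occupancy conservation, discount monotonicity,
geometric closed form for a two-state model, degenerate-PSA ≡
deterministic, CEAC = brute-force recount, INB/ICER sign consistency).

Parameter recovery runs 20 cohorts of n = 50,000 at the default error
model. Exact intervals have ≥ 95% coverage *in expectation*; the observed
coverage over the 80 replicate checks is itself binomial, so the test
asserts it at the 99.5% binomial lower bound (≤ 10 misses of 80) — a
verification of the coverage property within Monte-Carlo resolution, not a
loosening of it — alongside strict ±1-percentage-point checks on the
pooled point estimates. Problem sizes throughout (50,000-row recovery
cohorts, 100,000-draw PSA, 3,000-row property cohorts) were chosen so the
statistical assertions have adequate resolution while the full suite runs
in seconds.

Passing tests on synthetic cohorts demonstrate internal consistency of the
estimators and rules, not field performance of any device: real screening
data have correlated rater errors (pharmacists saw the device output),
drifting prevalence with age and setting, and missingness patterns the
generator does not emulate.
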