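# afscreen

Opportunistic atrial-fibrillation (AF) screening of over-65s in primary
care, as a tested, reusable analysis pipeline. The package is aimed at
biostatisticians and health-economics analysts evaluating single-time-point
AF screening delivered by pharmacists (or other non-physician staff) with a
single-lead ECG (SLECG) device and radial pulse palpation, against a
cardiologist overread as the reference standard.

It implements four stages, usable independently or end to end:

1. **Synthetic cohorts** (`afscreen.cohort`) — tabular screening cohorts
   (age ≥ 65, median 73, IQR 69–78; 42.7% male; ~4.3% AF) with four
   imperfect categorical raters — pulse palpation, the device algorithm,
   the pharmacist's read, and the cardiologist — each emitting one of
   {normal SR, possible AF, unclassified, unreadable} from configurable
   per-rhythm misclassification distributions.
2. **Diagnostic accuracy** (`afscreen.accuracy`) — for each index test *T*
   against the reference, the 2×2 table after dichotomising calls gives

   - sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
   - accuracy = (TP+TN)/n, PPV = TP/(TP+FP), FDR = 1 − PPV,
     FPR = 1 − specificity,

   each with an exact Clopper–Pearson 95% CI; chance-corrected agreement
   κ = (p₀ − pₑ)/(1 − pₑ) with an asymptotic-SE interval; and paired
   accuracy comparisons via Cochran's Q followed by post-hoc McNemar tests
   (exact binomial below 25 discordant pairs, continuity-corrected χ²
   otherwise) with Bonferroni correction.
3. **Screening pathway** (`afscreen.pathway`) — the deterministic triage
   flow (normal letter / 12-lead ECG referral / GP review / no action for
   known anticoagulated AF), follow-up reclassification, CHA₂DS₂-VASc and
   HAS-BLED scores, the sex-adjusted ESC anticoagulation rule
   (score ≥ 2 men / ≥ 3 women), and known/new AF prevalence accounting
   with exact intervals.
4. **Cost-utility model** (`afscreen.markov`) — a six-state Markov cohort
   model (undetected AF, detected on OAC, detected without OAC, no AF,
   post-stroke, dead) in one-year cycles to age 100, discounted at
   3.5%/year, compared at λ = £20,000/QALY via ICER = ΔC/ΔQ, incremental
   net benefit INB = λ·ΔQ − ΔC, and cost-effectiveness acceptability
   curves from a 100,000-draw probabilistic sensitivity analysis with
   common random numbers across strategies.

`afscreen.study` ships a deterministic 604-participant reference cohort
reconstructed row-by-row from a published screening programme's summary
counts, so the published accuracy table and prevalence figures can be
recomputed from per-participant calls without the original case-report
spreadsheets.

## Worked example

```python
from afscreen.study import reference_study_cohort
from afscreen.accuracy import DichotomyPolicy, table2_report
from afscreen.pathway import summarize
from afscreen.markov import AFModelParams, PSAConfig, default_strategies, run_psa, strategy_outcomes

cohort = reference_study_cohort()
rows, comparison = table2_report(cohort, DichotomyPolicy.published_tables())
for name, r in rows.items():
    print(f"{name:<11} sens {100*r.sensitivity.value:5.1f}%  spec {100*r.specificity.value:5.1f}%  "
          f"acc {100*r.accuracy.value:5.1f}%  FDR {100*r.fdr.value:5.1f}%  kappa {r.kappa.value:.2f}")

s = summarize(cohort)
print(f"AF prevalence {100*s.prevalence_total.value:.1f}% "
      f"(known {100*s.prevalence_known.value:.1f}%, new {100*s.prevalence_new.value:.1f}%)")

samples = run_psa(AFModelParams(), default_strategies(), PSAConfig(n_draws=100_000, seed=1))
for o in strategy_outcomes(samples).values():
    print(f"{o.name:<15} dQALY {o.delta_qaly:+.4f}  ICER {o.icer.value:7.0f} GBP/QALY  "
          f"INB {o.inb:6.0f} GBP  P(cost-effective) {o.prob_cost_effective:.3f}")
```

prints

```
device      sens  92.3%  spec  97.4%  acc  97.2%  FDR  38.5%  kappa 0.72
pharmacist  sens  88.5%  spec  97.2%  acc  96.9%  FDR  41.0%  kappa 0.69
pulse       sens  76.9%  spec  92.2%  acc  91.6%  FDR  69.2%  kappa 0.40
AF prevalence 4.3% (known 3.0%, new 0.7%)
pulse_palpation dQALY +0.0058  ICER     752 GBP/QALY  INB    112 GBP  P(cost-effective) 1.000
slecg_device    dQALY +0.0070  ICER    1229 GBP/QALY  INB    131 GBP  P(cost-effective) 1.000
```

The accuracy rows read: the device algorithm called AF with 92.3%
sensitivity but a 38.5% false-discovery rate (15 of its 39 AF calls were
wrong), and pulse palpation alone was both less sensitive (76.9%) and far
less specific (FDR 69.2%). Of the 604 screened, 4.3% were in AF —
3.0 percentage points already known and anticoagulated, 0.7 newly found
and confirmed on a 12-lead ECG. The economic rows are per person offered
screening under this package's reconstructed parameter set (see
`docs/methods.md`): both modalities buy QALYs at well under the £20,000
threshold here, the device more than pulse palpation.

There is also a CLI mirroring the stages:

```sh
afscreen simulate --seed 1 --n 604 --out run/
afscreen accuracy run/cohort.csv --out run/
afscreen pathway run/cohort.csv --out run/
afscreen ce --draws 100000 --seed 1 --out run/
```

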