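# arfdx — acute rheumatic fever diagnosis calculator

Acute rheumatic fever (ARF) is a post-streptococcal autoimmune illness
with no diagnostic test: diagnosis applies the Australian revision of
the Jones criteria, a set of *major* and *minor* clinical, laboratory,
electrocardiographic and echocardiographic manifestations whose
weighting depends on the patient's population risk stratum. Repeated
or severe episodes cause rheumatic heart disease (RHD), so missed
diagnoses forfeit secondary antibiotic prophylaxis. The criteria are
complex enough that clinicians unfamiliar with ARF — common in the
high-turnover workforces of high-burden regions such as northern
Australia — benefit from an electronic decision-support calculator.

`arfdx` is such a calculator, plus the statistical harness needed to
validate one against an expert-panel gold standard, for clinicians,
epidemiologists and guideline developers who need a scriptable,
auditable implementation:

- **criteria engine** — assigns the ordered category
  `Not ARF < Possible < Probable < Definite` from a structured patient
  record. A *definite* diagnosis requires evidence of preceding group A
  streptococcal infection plus a complete pathway: 2 major
  manifestations, or 1 major + 2 minor, or (for a documented
  recurrence) 3 minor. A presentation one element short triggers the
  clinician question "Is ARF considered the most likely diagnosis?"
  (yes → probable, uncertain → possible, no → not ARF). High-risk
  settings (ARF incidence > 30/100,000/year in 5–14-year-olds, all-age
  RHD prevalence > 2/1,000, or Aboriginal and/or Torres Strait Islander
  patients in rural/remote settings) use fever ≥ 38 °C and
  ESR ≥ 30 mm/h and count more joint findings as major; low-risk
  settings use 38.5 °C and 60 mm/h. All thresholds and the age-banded
  upper limits of normal (PR interval, ASO / anti-DNase B titres) are
  overridable configuration.
- **agreement statistics** — the 4×4 gold-vs-calculator
  cross-tabulation (rows = gold standard, columns = calculator),
  Cohen's kappa κ = (Pₒ − Pₑ)/(1 − Pₑ) with the asymptotic standard
  error SE = √(Pₒ(1 − Pₒ)/(n(1 − Pₑ)²)), and one-vs-rest sensitivity /
  specificity per category plus micro-averaged overall values.
- **synthetic cohorts** — seeded, reproducible suspected-ARF cohorts
  with known gold labels for end-to-end testing, plus named clinical
  fixture cases.

## Worked example

Diagnose a high-risk 10-year-old with culture-negative monoarthritis,
fever 38.6 °C, CRP 40 mg/L and an anti-DNase B titre of 800 IU/mL
(cases.json holds a list of patient records):

```json
[
  {
    "age": 10.0,
    "indigenous_rural_remote": true,
    "prior_arf_rhd": "confirmed-none",
    "joint_finding": "aseptic-monoarthritis",
    "carditis": "absent",
    "max_temperature": 38.6,
    "crp": 40.0,
    "adb_titre": 800.0
  }
]
```

```console
$ arfdx diagnose cases.json --format text
record 0: definite (initial)
```

The monoarthritis is a major manifestation in a high-risk setting, the
fever and raised CRP are two minors, and the elevated titre supplies
streptococcal evidence — the 1 major + 2 minor pathway is complete, so
the calculator returns *definite* (every JSON result also carries the
differential-diagnosis and specialist-advice advisories). Entering the
same joint finding as `monoarthralgia` (pain, not arthritis) drops the
case below *definite*: that single entry choice is exactly the kind of
ambiguity the agreement harness is built to measure.

Validate a calculator against an expert panel from a confusion table
(or a two-column `gold,predicted` CSV):

```console
$ arfdx evaluate table.json --format text
Agreement report (rows = gold standard, columns = calculator)

             not-arf  possible  probable  definite     total
not-arf            3         0         0         1         4
possible           1         4         0         1         6
probable           0         1         1         0         2
definite           0         0         0        23        23
total              4         5         1        25        35

observed agreement  Po = 0.8857 (89%)
expected agreement  Pe = 0.5086
Cohen's kappa          = 0.767 (SE 0.109, 95% CI 0.553-0.982)

per-category (one-vs-rest)   sensitivity  specificity
  not-arf                            75%          97%
  possible                           67%          97%
  probable                           50%         100%
  definite                          100%          83%
  overall (micro-average)            89%          96%
discordant: 4/35 (11%)
```

κ = 0.767 is conventionally read as excellent agreement; the
calculator is most accurate for *definite* and *not ARF*, while the
possible/probable boundary — which turns on clinician confidence —
accounts for most disagreement.

Simulate a reproducible 35-patient cohort with gold labels:

```console
$ arfdx simulate --seed 7 --n 35 -o cohort.json
wrote 35 simulated patients to cohort.json
```

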