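# Methods

## The diagnostic model

ARF diagnosis is criterion-based. A presentation is resolved in four
steps, mirroring the package's pipeline:

1. **Risk group.** A patient is high-risk if an explicit override says
   so, if they are Aboriginal and/or Torres Strait Islander living
   rurally/remotely, or if their community's ARF incidence exceeds
   30/100,000/year in 5–14-year-olds or all-age RHD prevalence exceeds
   2/1,000 (both strict `>`, as the criteria print them). Precedence is
   override → Indigenous rural/remote → epidemiology, and the basis is
   recorded on the result. With no risk input at all the engine raises
   a risk-indeterminate error rather than guessing: the deployed
   calculator forces this choice up front, and a library must not
   default it silently.
2. **Manifestations.** Carditis (clinical or subclinical on
   echocardiogram), Sydenham chorea, erythema marginatum and
   subcutaneous nodules are major in both risk groups. The single
   joint finding is placed per group — high-risk: polyarthritis,
   aseptic monoarthritis and polyarthralgia major, monoarthralgia
   minor; low-risk: polyarthritis major, polyarthralgia and aseptic
   monoarthritis minor, monoarthralgia nothing. Fever and the
   ESR/CRP minor use the group's thresholds, compared inclusively
   (`>=`) exactly as printed. A PR interval strictly above the age
   ULN is a minor unless carditis is already counted as a major
   (standard Jones-criteria practice; the suppression is recorded in
   the profile's notes so it is auditable). Absent or pending
   measurements contribute nothing.
3. **Streptococcal evidence.** An ASO or anti-DNase B titre strictly
   above the age ULN, documented rising titres, or a positive throat
   culture / rapid antigen test. "Strictly above" is a convention
   choice: the criteria say "within normal limits" for no-evidence
   without fixing the boundary, so a titre exactly at the ULN is
   treated as normal and the boundary is exercised from both sides in
   tests. A positive culture alone is accepted as evidence even in
   high-risk settings (where carriage is common) and is flagged in the
   evidence basis so downstream users can discount it.
4. **Category.** Pathways are (2 major), (1 major + 2 minor), and for
   a documented recurrence (3 minor), each plus streptococcal
   evidence, giving **Definite**. A *shortfall* — exactly one deficit,
   i.e. one manifestation short of a pathway with evidence (and at
   least one manifestation present), or a complete pathway without
   evidence — triggers the clinician question; yes/uncertain/no map to
   Probable/Possible/Not ARF, with "uncertain" the default when no
   answer is supplied. Two or more deficits are Not ARF without the
   question; whether a deployed calculator would still ask is
   unknowable from its published behaviour, and not asking is the
   conservative reading of "falls short by either one manifestation
   or evidence".

Further engine decisions where the design was genuinely open:

- **Single joint finding.** The record schema carries exactly one
  (pre-ranked) joint finding, which contributes to at most one column.
  The criteria list joint items under both major and minor without
  stating a double-counting rule; making the schema carry one finding
  prevents one clinical phenomenon counting twice.
- **Unknown prior history** is assessed as an initial episode (the
  conservative choice: the three-minor recurrence pathway stays
  closed) and attaches a history-verification advisory.
- **Echo-pending carditis** contributes nothing and attaches the
  advisory "If echocardiogram is pending, base decision on clinical
  assessment until echocardiogram result is available." Every result
  carries the differential-diagnosis advisory and "In complicated or
  early cases, or those with incomplete investigations, seek
  specialist advice." — the wording the revised calculator displays.
- **ULN defaults.** The criteria attest that age-specific ULN tables
  for PR interval and streptococcal serology exist but do not print
  them. The shipped defaults are the Australian guideline's bands
  (PR 140/160/180/200 ms at <3/3–11/12–16/≥17 y; ASO
  170/276/238/177/127 and anti-DNase B 366/499/473/390/265 IU/mL at
  <5/5–14/15–24/25–34/≥35 y). They are configuration with a schema
  version; unknown config fields are rejected so a typo cannot
  silently alter a threshold, and engine tests inject their own flat
  tables so the suite never depends on these defaults. Age bands are
  half-open `[low, high)` years for unambiguous boundaries.

The resulting category map is monotone: adding a manifestation,
raising a lab value, upgrading the joint finding
(monoarthralgia < polyarthralgia < aseptic monoarthritis <
polyarthritis) or adding streptococcal evidence never lowers the
category at fixed clinician judgement. This is asserted empirically
over 10,000 generated presentations, and the category assignment is
checked exhaustively against an independently written transcription of
the criteria text over the full (majors, minors, evidence, episode,
judgement) cross-product.

## Agreement statistics

The validation harness cross-tabulates paired gold (expert-panel) and
calculator labels with rows = gold, columns = calculator — the
orientation is stated in every output because transposition is the
classic silent bug here. From the table it computes:

- **Cohen's kappa** κ = (Pₒ − Pₑ)/(1 − Pₑ) with the asymptotic
  standard error SE = √(Pₒ(1 − Pₒ)/(n(1 − Pₑ)²)) and a normal 95%
  interval clipped to [−1, 1]. The published interval for the
  35-patient validation study (0.568–0.967) implies a slightly smaller
  SE than this formula; the method actually used is not identifiable,
  so this package reports the standard asymptotic interval and treats
  only κ itself as a reproducible quantity. A degenerate table with
  all mass in one diagonal cell yields κ = 1; Pₑ = 1 with Pₒ < 1 is an
  explicit undefined-kappa error (unreachable from count data, kept as
  a guard).
- **Per-category sensitivity/specificity** by one-vs-rest collapse:
  sens_k = TP_k/rowsum_k, spec_k = TN_k/(n − rowsum_k) with
  TN_k = n − rowsum_k − colsum_k + TP_k. A zero denominator is
  reported as an explicit not-applicable marker, never 0 or 100.
- **Overall metrics** micro-averaged over the four collapses; raw
  proportions are always available, and percentages are additionally
  rendered to the nearest integer (half away from zero) to match the
  granularity validation studies print.

The shipped 35-patient validation table is reconstructed from its
published marginals — gold (4, 6, 2, 23), calculator (4, 5, 1, 25) —
and diagonal (3, 4, 1, 23). These determine every statistic above;
the four off-diagonal discordant cells are a consistent completion.
The narrative description of the four discordant cases implies a
gold-NotARF → calculator-Possible disagreement that those marginals do
not admit; the marginals and diagonal are internally consistent and
reproduce κ = 0.767, so they are taken as authoritative and the
narrative discrepancy is noted here rather than resolved.

## Synthetic cohort generator

The generator emulates a consecutively enrolled suspected-ARF cohort
at a tertiary hospital in a high-burden region, solely to exercise
code paths end-to-end; it does not model true ARF epidemiology,
seasonality or regional burden. Defaults (chosen once, as the
generator's definition of the study conditions):

- `n = 35`, `risk_mix = 0.9` high-risk, `recurrence_fraction = 0.1`,
  ages uniform on 3–30 years;
- manifestation prevalences set so the simulated category mix is
  dominated by Definite (roughly two-thirds), matching the gold-label
  mix of a suspected-ARF referral cohort: joint findings
  polyarthritis 0.35 / aseptic monoarthritis 0.25 / polyarthralgia
  0.12 / monoarthralgia 0.10, carditis 0.35 (+0.05 echo-pending),
  chorea 0.08, skin majors 0.02 each, rising titres 0.20, positive
  culture 0.15;
- lab values are lognormal with the **threshold-exceedance
  probability as the directly specified knob** (temperature 0.70 vs
  38 °C; ESR and CRP 0.60 vs 30; serology 0.60 and PR 0.15 vs the age
  ULN): the median is derived as ln m = ln T − σ·Φ⁻¹(1 − p), so
  prevalences, not distribution shapes, are the contract;
- per-field missingness (5–20%) emulating incomplete investigations;
- a **discordance model** that, at rate 4/35 by default, relabels a
  case's gold label to an adjacent category in the ordered scale —
  the near-miss pattern of real panel disagreements (a joint finding
  read down, an excluded differential). At rate 0 the gold labels are
  exactly the calculator's own output, so the closed loop gives κ = 1
  by construction.

Randomness uses one seed with counter-based per-patient substreams
(`default_rng([seed, i])`), so patient *i* is identical whatever the
cohort size and insertion order cannot cascade; the perturbation
stream is separate.

What passing simulator-based tests shows — and does not. The generator
produces schema-valid records whose gold labels are engine output plus
a controlled perturbation; tests on it verify the engine's invariants,
the statistics' behaviour at known rates, and the I/O round trip. It
cannot show calibration against real patients: real presentations have
correlated manifestations (carditis with fever, serology with culture
timing), non-lognormal labs, and panel disagreements driven by
information outside the record (aspirate appearance, antibiotic
pre-treatment), none of which are modelled.

## Numerical and testing choices

- Problem sizes: the monotonicity property uses 10,000 generated
  presentations; the binomial-agreement property uses 200 replicate
  35-patient cohorts with a 5σ band on the mean agreement; the
  cross-product oracle check is exhaustive (640 combinations). The
  whole suite runs in well under a minute.
- Kappa and the per-category metrics are cross-checked in tests
  against statsmodels and against hand-written brute-force oracles
  (double-loop counting, explicit 2×2 collapse); the implementations
  themselves are independent of both.
- Percentages use floor(100x + 0.5) so rendering is deterministic
  across platforms.
- The CSV projection of patient records is RFC 4180 with a mandatory
  header; empty cell = not measured; booleans are `true`/`false`.
  JSON is canonical. Record validation is pydantic, and the JSON
  Schemas for records and cohort specs are exported by
  `patient_record_schema()` / `cohort_spec_schema()`.

## Known limitations

- The possible/probable boundary is inherently subjective (clinician
  confidence); the engine reproduces the mapping, not the judgement.
- No management or prophylaxis-duration guidance; diagnosis only.
- No encoding of non-Australian criteria revisions or low-burden
  serology reference ranges; the configuration mechanism exists for
  users who need them.
- The kappa confidence interval is the asymptotic normal one; with
  n = 35 and a skewed marginal it is approximate, and no bootstrap or
  exact interval is provided.
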