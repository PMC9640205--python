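# Methods

`adrlong` models an anonymized, app-based active-surveillance campaign for
post-vaccination adverse drug reactions (ADRs) over a three-dose COVID-19
vaccination schedule. It implements the full server-side chain — identity
issuance, staged ingestion, consistency curation, analytics — together with
a synthetic-cohort generator calibrated to a published academic campaign of
3,712 invited vaccinees, of whom 2,733 participated.

## Pseudonymous identity

Longitudinal linkage without identification is obtained by pairing each
device's push-notification token with a freshly drawn random version-4
UUID. The UUID is *sampled*, never derived from the token: any digest-based
scheme (salted or not) is reversible to an adversary who can enumerate
candidate tokens, so one-wayness demands true randomness plus a private
server-side pairing table. The pairing table is the only way back from an
id to a token; it is used exclusively to address push reminders and is
excluded from every export. A device that rotates its push token therefore
becomes a new respondent — a known limitation inherited from the design,
accepted because token rotation cannot be observed by an anonymous server.

## Staged ingestion and reminders

The submission protocol is strictly ordered per respondent: register, one
medical-history questionnaire, then per administration a vaccination record
followed (ideally) by an ADR report. The server stores submissions
append-only and answers with bare acknowledgments only (one-way
architecture — no stored content ever flows back to a client).

Each accepted vaccination schedules a reminder due `administered_at + 7`
calendar days. The source system sends reminders but does not state a
cadence; the policy here is one push at the due date, repeated every 2 days
while unresolved, capped at 3 sends and truncated at the study-window end —
a bounded, testable choice. ADR submissions resolve the earliest open
reminder; authoritative ADR-to-dose attribution is deferred to curation
because the server cannot know dose semantics at ingest time.

## Curation rules

The published analysis reports discarding "nonconsistent" submissions after
manual inspection without enumerating criteria. Reproducibility requires
explicit rules, so curation codifies the minimal consistency the staged
protocol implies, applied in order with a per-record discard log:

* **R1** — vaccinations from respondents with no medical history;
* **R2** — among vaccinations sharing a calendar date, all but the
  earliest-submitted;
* **R3** — scanning in submission order, vaccinations whose date does not
  strictly exceed every previously retained date;
* **R4** — ADR reports submitted before the first retained vaccination
  date;
* **R5** — ADR reports in excess of the retained vaccination count
  (earliest kept).

Retained vaccinations, ordered by date, receive ordinal dose labels 1, 2,
3, … (doses beyond 3 flagged out-of-study), and the k-th retained ADR
report is attributed to dose k — ordinal rather than time-window matching,
because the protocol solicits exactly one ADR questionnaire per
vaccination. Curation is conservative (retained + discarded = input),
deterministic, idempotent, and never fails.

## Synthetic cohort

The simulator generates event streams with the statistical structure of the
observed cohort, so the pipeline can be exercised end-to-end without the
(undeposited) real data.

* **Funnel.** Participation is a chain of conditional Bernoulli draws:
  register/history with probability 0.736, then vaccination submission per
  dose conditional on the previous dose's submission (0.863, 0.754, 0.101)
  and an ADR report conditional on the same dose's vaccination submission
  (0.943, 0.905, 0.944). Dose 3 is spontaneous (no hub, no reminders),
  hence its small rate.
* **Stratified retention.** Flat per-dose rates cannot reproduce the
  published per-stratum stage compositions (the age mix shifts from 47.6%
  under-30 at the history stage to 53.7% at dose-2 submission). Each stage
  therefore carries a logistic participation model,
  `p = logistic(intercept + institution + gender + age-band offsets)`, with
  the five free parameters solved at calibration time against the five
  independent published retention margins over the parent stage's
  demographic composition. A purely multiplicative rate model was rejected:
  the observed margins imply per-cell rates above 1 (up to 1.23 at dose 2),
  which a logistic link avoids by construction. Calibrated margins
  reproduce the published stage compositions to ~1e-4 (the residual comes
  from the three-decimal rounding of the demographic mixes).
* **Demographics.** Institution, gender, and age band are independent
  categorical draws matching the published margins (0.613/0.387,
  0.552 female, 0.476/0.406/0.118); ages are uniform within bands
  ([19, 29], [30, 55], [56, 80], matching the observed 19–80 range). The
  true joint distribution is not published; only margins are calibrated.
* **Chronic conditions.** Per-condition, per-gender Bernoulli draws. The
  published prevalences appear only graphically; defaults are fixed once at
  plausible values bounded by the reported maximum (0.078), male-dominant
  except asthma, liver, and autoimmune disease, with hypertension (male)
  and autoimmune disease (female) showing the widest gaps, as reported.
* **Symptoms.** Conditionally independent per-symptom Bernoulli draws with
  probability `logistic(base + gender + age-band + dose offsets)`. Base
  log-odds favor injection-site pain, tiredness, headache, muscular pain,
  fever, sleepiness, and joint pain; the female offset (+0.5) and young-age
  gradient (+0.5 / +0.25 / 0) encode the reported pattern that women and
  younger respondents report more symptoms; dose offsets (0, −0.4, −0.2)
  encode the dose-2 dip with a partial dose-3 rebound. Exact per-symptom
  prevalences are not published; these defaults are fixed once. An optional
  shared per-report frailty term can induce symptom co-occurrence but is
  off by default (no co-occurrence structure is published).
* **Vaccine mix.** Per-dose categorical draws: Vaxzevria-dominant at doses
  1–2, mRNA-only at dose 3, consistent with the pooled published counts
  (62.8 / 29.0 / 8.1 / 0.1%) and with no Vaxzevria boosters.
* **Corruption.** Optional per-rule injection of inconsistencies (ghost
  vaccinations without history, duplicate dates, backdated records,
  premature and surplus ADR reports), each constructed to trigger exactly
  one curation rule once, with exact ground-truth bookkeeping; off by
  default.
* **Randomness.** One root seed; respondent *i* uses a substream keyed
  `(seed, i)`, so enlarging the cohort never perturbs earlier respondents
  and identical config + seed is byte-for-byte reproducible.

### What the simulator does not emulate

Calendar clustering of appointments, the true joint demographic
distribution, ADR severity, symptom co-occurrence (by default), and
non-monotone reporting behavior. One visible consequence: because ADR
submission is conditional only on the same dose's vaccination submission,
a simulated respondent can skip the dose-1 questionnaire yet answer the
dose-2 one; ordinal attribution then labels that report dose 1. At
calibrated rates this inflates the dose-1 ADR stage count by ~3–4% and
deflates dose 2 correspondingly, while leaving within-stage stratum
compositions essentially unchanged (shifts < 0.5 percentage points, well
inside sampling noise). Passing tests therefore certify the pipeline's
bookkeeping and the calibrated composition, not real-world reporting
behavior.

## Analytics conventions

* **Percentages** are rounded half-up to one decimal. The source tables
  are internally inconsistent about rounding; half-up maximizes agreement.
  Four printed values cannot be reproduced from their own printed counts
  under any rounding convention and are treated as typesetting/truncation
  artifacts: 977/2360 printed 41.1 (computes 41.4), 2360/2733 printed 86.3
  (computes 86.4), 2226/3712 printed 59.9 in one passage and 60.0 (correct)
  in another, and 35/179 printed 19.5 (computes 19.6).
* **Age bands** partition adult ages as [18, 29], [30, 55], [56, ∞).
* **Dichotomy.** Symptom counts split at ≥3 vs <3 (an exactly-3 report is
  in the high group); the alternative "more than 3 / fewer than 3" reading
  is not exhaustive and is rejected.
* **Chi-square.** Pearson statistic Σ(O−E)²/E without continuity
  correction, df = (r−1)(c−1), computed via `scipy.stats.chi2_contingency`;
  zero row/column margins are an error. No multiplicity adjustment across
  tests (matching the source's per-figure reporting).
* **Empty strata** are absent from outputs, never zero rows —
  distinguishing "no respondents" from "no events".
* **Flows.** The longitudinal flow matrix is restricted to complete
  responders (ADR reports attributed to all three doses) over the
  symptom-count classes {0, 1, 2, 3, >3}; total flow is conserved across
  both dose transitions by construction.

## Problem sizes used in the test suite

Oracle-equivalence suites run 1,000 randomized respondent fixtures against
independent brute-force reimplementations of the curation rules and all
tallies. Calibration recovery simulates 5,000 invitees across 20 seeds and
requires every published stage percentage to fall within 3 binomial
standard errors on at least 19 of 20 seeds; the packaged acceptance script
runs one full campaign at the calibrated size (3,712 invitees). These sizes
were chosen to give the statistical checks adequate power while keeping a
full run inexpensive.

## Known limitations

The discarded-record count of the real campaign is not published, so no
check exists on it. Chi-square statistics and p-values of the source's
dichotomy figures are shown only graphically and carry no numeric targets.
The service contract is realized in-process (transport-agnostic); the real
push gateway and mobile clients are out of scope behind the notifier and
payload contracts.
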