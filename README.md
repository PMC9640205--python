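# adrlong

Anonymized longitudinal adverse-drug-reaction (ADR) surveillance for a
multi-dose vaccination campaign: a testable, end-to-end reimplementation of
an app-based active-reporting system, from pseudonymous identity issuance
to longitudinal analytics, plus a calibrated synthetic-cohort simulator.

It is aimed at pharmacovigilance and biostatistics practitioners who want
to study (or stress-test) the mechanics of anonymous longitudinal ADR
collection: how device tokens map one-way onto stable respondent ids, how a
staged register → history → vaccination → day-7 ADR protocol behaves, how
inconsistent submissions are curated into per-dose timelines, and what the
resulting participation funnel and symptom analytics look like.

## What it computes

For a cohort of respondents followed over doses d = 1, 2, 3:

* **Participation tables** — counts n and relative frequencies n/N (one
  decimal, half-up) per stratum (institution, gender, age band
  {<30, 30–55, >55}) at each funnel stage: medical history, per-dose
  vaccination submission, per-dose ADR report.
* **Vaccine mix** — per-dose and pooled shares of the four administered
  products.
* **Prevalence** — chronic-disease prevalence by gender and per-symptom
  ADR prevalence by gender × age band × dose.
* **Symptom-count dichotomy** — reporters split into ≥3 vs <3 symptoms,
  cross-tabulated against a stratifier and tested with Pearson's
  chi-square, X² = Σ (O−E)²/E with E = (row total × column total)/N and
  df = (r−1)(c−1), no continuity correction.
* **Longitudinal flows** — for complete responders, transition counts
  between symptom-count classes {0, 1, 2, 3, >3} across doses 1→2 and 2→3
  (Sankey-ready; flow is conserved across levels).

The synthetic generator draws a three-dose campaign whose participation
funnel, stratified stage compositions, vaccine mix, and gender/age/dose
symptom gradients are calibrated to a published academic campaign (3,712
invited; 2,733 histories; 2,360/1,779/179 vaccination submissions;
2,226/1,610/169 ADR reports). See `docs/methods.md` for the model and every
calibration decision.

## Worked example

```python
import adrlong as al

config = al.default_config()            # calibrated campaign, 3712 invited
stream = al.simulate(config, seed=1)    # reproducible event stream
dataset = al.build_dataset(stream.to_export())   # curate + label doses

table = al.participation_table(dataset, "gender", "adr", dose=1)
print(table.N, table.strata)

stat, df, p = al.chi_square(al.dichotomize(dataset, dose=1, stratifier="gender"))
print(round(stat, 2), df, p < 0.001)

fm = al.flow_matrix(dataset)
print(fm.complete_responders, fm.level_total(1) == fm.level_total(2))
```

prints

```
2305 (('male', 1053, 45.7), ('female', 1252, 54.3))
197.16 1 True
147 True
```

meaning: 2,305 simulated respondents filed a dose-1 ADR report, 54.3% of
them women; the ≥3-symptom share differs between genders (X² = 197.16 on
1 df, p < 0.001, women reporting more symptoms, as in the real campaign);
147 respondents reported after all three doses, and their class-transition
flows conserve mass across the two dose transitions.

The same pipeline runs from a shell:

```bash
adrlong simulate --config config.yaml --seed 1
adrlong curate   --config config.yaml
adrlong report   --config config.yaml
```

writing the three-table export (`histories.csv`, `vaccinations.csv`,
`adr_reports.csv`, plus `ground_truth.csv`), the curated
`analysis_dataset.csv` / `discard_log.csv`, and the plot-ready reports
(`participation_tables.csv`, `vaccine_mix.csv`, `prevalence.csv`,
`contingency.csv`, `flows.csv`, `summary.txt`).

## Layout

| Module | Responsibility |
| --- | --- |
| `adrlong.core_model` | Closed vocabularies, record types, payload validation |
| `adrlong.identity` | One-way token → respondent-id pseudonymization |
| `adrlong.ingest` | Staged ingestion, reminder scheduling, store export |
| `adrlong.curation` | Consistency rules R1–R5, dose labeling, discard log |
| `adrlong.simulator` | Calibrated synthetic campaign generator |
| `adrlong.analytics` | Tables, prevalence, chi-square, flow matrix |
| `adrlong.pipeline` / `adrlong.cli` | Batch orchestration and CLI |
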