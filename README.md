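# adpatterns

Longitudinal antidepressant treatment-pattern mining and stepwise-guideline
(CANMAT 2016) concordance scoring over EMR-style prescription tables, with a
synthetic EMR generator so the whole pipeline is testable without clinical
data.

The pipeline:

1. **synthetic_emr** — simulates patient-level record tables (patients,
   prescriptions, diagnoses, visits, procedures) with per-patient ground
   truth; `clean` mode realizes intended treatment trajectories exactly,
   `noisy` mode adds refill jitter and short attempts.
2. **cohort_builder** — new-user cohort selection: index date (first
   antidepressant dispense in the accrual window after a 365-day washout),
   fixed-precedence exclusions (prior ECT, bipolar/schizophrenia, CNS
   disease, age 18–64, MDD diagnosis, multi-drug index), treatment episode
   (ends after >120 antidepressant-free days) and follow-up window.
3. **pattern_engine** — merges each drug's supply runs with a 14-day grace
   period, classifies every medication change (switch / add-on / attempt
   via the 30-day supply and 30-day overlap rules), assigns treatment
   levels and per-level durations.
4. **canmat_rules** — drug catalog and drug → line-of-treatment tier table,
   shipped as editable TSV files (`src/adpatterns/data/`).
5. **concordance_classifier** — labels each patient's first three levels
   concordant/discordant with reason codes.
6. **reporting_stats** — proportion tables, Cochran-Armitage trend test,
   duration/pattern tables, discordance flow and utilization rates.

## CLI

```bash
adpatterns simulate --out data/raw --n-patients 5000 --seed 1
adpatterns cohort --in data/raw --out data/work
adpatterns patterns --in data/raw --cohort data/work/cohort.tsv --out data/work
adpatterns concordance --cohort data/work/cohort.tsv \
    --transitions data/work/transitions.tsv --out data/work
adpatterns report --in data/raw --work data/work --out data/report
```

Every stage exchanges plain TSV tables, so externally exported EMR tables
with the same columns can be substituted for the simulator output.
`report` writes table analogs (proportions, durations, patterns,
discordance flow) plus `run_summary.json` with counts, proportions and
trend statistics.

## Data files

`src/adpatterns/data/drug_catalog.tsv` (drug, class, antidepressant flag)
and `src/adpatterns/data/canmat_tiers.tsv` (drug, role monotherapy/adjunct,
line 1–3, superior-efficacy flag) are transcribed from the CANMAT 2016
recommendations and deliberately editable: all concordance logic reads the
loaded table and never hard-codes drug names.
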