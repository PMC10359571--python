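# lynchledger

Tools for building a national, patient-level ledger of germline mismatch
repair (MMR) gene testing — the laboratory analyses that diagnose Lynch
syndrome — from heterogeneous regional laboratory extracts, and for
answering the epidemiological questions such a ledger enables: how many
people have been tested, what was found, what cancers they had, and what
fraction of the predicted carrier population has been identified.

Regional genetics laboratories have historically stored MMR testing
records (genes *MLH1*, *MSH2*, *MSH6*, *PMS2*) in incompatible local
systems: some can export structured tables, others only clinical report
wording in which the variant (`c.942+3A>T`, `p.(Thr117Met)`) is embedded
in free text and copy-number variants appear as natural language
("deletion of exons 1-6"). Amalgamating them nationally requires

1. **keyed pseudonymisation** at ingest — pseudo-ID1 = HMAC of the
   NHS number (mod-11 validated), pseudo-ID2 = HMAC of date of birth +
   postcode — with raw identifiers stripped and scrubbed;
2. **dialect harmonisation** into a common data model (one record per
   gene per test), including HGVS extraction from free text, syntactic
   HGVS validation, copy-number-variant language detection and
   pathogenicity-label normalisation (P / LP / VUS / LB / B);
3. **test-episode construction**: a patient's records are collapsed into
   episodes of at most 365 days anchored at the earliest authorisation
   date, deduplicated, and summarised by the most significant result
   under the total order P > LP > VUS > abnormal unclassified > normal;
4. **registry linkage**: deterministic matching to an ICD-10-coded
   cancer registry on pseudo-ID1 (falling back to pseudo-ID2), with
   cancers classed as before/after the first test report date and
   grouped by site (colorectal C18–C20, uterine C54–C55, other);
5. **coverage imputation**: laboratory-level annual audit counts
   (financial years 1998–2016, inflated by out-of-scope activity) are
   down-adjusted by a per-laboratory pooled ratio
   `f = Σ observed / Σ audit` over overlap years, back-filled flat for
   1996–1997, and combined with observed counts into a consensus
   national series; carrier yields follow as
   `carriers = round(N_fullgene × r_fullgene) + round(N_targeted × r_targeted)`
   with detection rates r_fullgene = 0.15 and r_targeted = 0.45.

Because real records sit under healthcare data governance, the package
ships a first-class synthetic-data generator (`lynchledger.synthgen`)
that emulates the laboratory dialects, identifier missingness, planted
result mixes, registry and audit data with known ground truth — every
pipeline stage is tested against what was planted.

## Worked example

```sh
lynchledger run-all --seed 1 --n-patients 2000 --out demo_out
```

runs generator → pseudonymisation → harmonisation → episodes → linkage →
coverage → summary on a 2000-patient synthetic cohort and prints the
manifest:

```json
{
 "counts": {
  "cdm_records": 4567,
  "episodes": 2043,
  "linked_cancers": 1153,
  "patients": 2000,
  "planted_tests": 2043,
  "quarantined_rows": 0,
  "registry_rows": 1153
 },
 "coverage_pct": 71.11033762617473,
 "key_fingerprint": "c48a01f49fd0",
 "seed": 1,
 "version": "0.1.0"
}
```

2043 planted tests (2000 patients, 43 with a repeat episode) expand to
4567 per-gene records, collapse back into 2043 episodes, and all 1153
registry cancers of linkable patients link. `demo_out/coverage.json`
shows the imputation: 2043 observed tests against a consensus total of
2873 once pre-submission laboratory activity is imputed from audit
counts, i.e. the patient-level dataset covers 71.1% of estimated
national activity under these synthetic conditions. Summary tables
(per-year totals, gene combinations, result breakdowns, cancer timing)
are written under `demo_out/summary/`.

The carrier arithmetic on the published national scale:

```python
>>> from lynchledger import estimate_carriers, carrier_fraction
>>> estimate_carriers(14191, 12428, 0.15, 0.45)
(2129, 5593)
>>> round(carrier_fraction(2129 + 5593, 279, 56_000_000), 2)
3.85
```

14,191 full-gene and 12,428 targeted analyses yield an expected 2,129 +
5,593 = 7,722 detected carriers — under 5% of the ~200,000 carriers
predicted for a population of 56 million at prevalence 1/279.

## Layout

| module | role |
| --- | --- |
| `lynchledger.synthgen` | synthetic extracts, registry, audit counts, truth ledger |
| `lynchledger.pseudonym` | NHS-number validation, keyed pseudonyms, identifier stripping |
| `lynchledger.harmonise` | dialect mapping, HGVS extraction/validation, CNV language, concordance audit |
| `lynchledger.episodes` | deduplication, 365-day episode collapsing, severity hierarchy |
| `lynchledger.linkage` | registry pseudonymisation and linkage, cancer timing, ICD-10 grouping |
| `lynchledger.coverage` | audit down-adjustment, interpolation, consensus totals, carrier yields |
| `lynchledger.report` | summary tables, end-to-end pipeline, manifest |
| `lynchledger.cli` | `lynchledger` command with one subcommand per stage |

### File formats

Structured extracts are CSV (`nhs_number, dob, postcode,
authorised_date, report_date, test_type, genes, variant_gene,
variant_cdna, variant_protein, cnv_description, overall_result,
classification`); the semi-structured dialect is CSV with DD/MM/YYYY
dates and a `ReportText` column; the free-text dialect is JSONL with one
report object per line. The registry is CSV (`nhs_number, dob, postcode,
icd10, diagnosis_date`), audit counts CSV (`lab_code, financial_year,
audit_count`), the harmonised common data model CSV + JSONL with
identical content, quarantined rows JSONL with reason codes, and the
truth ledger JSONL (read only by tests). Dialect mappings are
declarative `DialectSpec` objects serialisable to YAML.
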