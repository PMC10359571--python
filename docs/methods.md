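# Methods

This note records how the pipeline models national amalgamation of
germline MMR (mismatch repair) laboratory testing data, the parameters
that matter, what the synthetic data does and does not emulate, and the
design choices made where the design was genuinely open.

## Pseudonymisation

Pseudonyms are HMAC-SHA256 digests truncated to 32 hex characters,
keyed by a run-scoped secret. Pseudo-ID1 digests the canonical NHS
number (spaces/hyphens removed) and is created only for numbers passing
the standard mod-11 check (weights 10..2 on the first nine digits,
check digit `11 − (sum mod 11)`, 11 → 0, 10 → invalid). Pseudo-ID2
digests `YYYY-MM-DD|POSTCODE` with the postcode upper-cased and
whitespace-stripped; both date of birth and postcode must be present.
A keyed one-way digest gives the two properties linkage needs —
reproducibility under a persisted key and irreversibility without it —
without any key-escrow machinery; domain prefixes (`ID1|`, `ID2|`)
keep the two token families disjoint. Tokens are 128-bit prefixes, so
collisions among ≤10⁶ inputs are vanishingly unlikely (tested to 10⁵).

After tokens are derived, raw identifier fields are removed and every
remaining string field is scanned for identifier-shaped residue
(10-digit runs, UK-postcode shapes, ISO or DD/MM/YYYY dates). Free-text
report fields are redacted in place; a hit in any structured field is a
hard failure, because no record may move downstream carrying raw
identifiers. The scrubber patterns were chosen not to collide with
clinical content: HGVS tokens, gene symbols and exon ranges do not
match any of them (tested explicitly).

## Harmonisation and the HGVS grammar subset

Each laboratory dialect is described declaratively (`DialectSpec`):
column mappings, date format, result/scope vocabularies, free-text
fields. Mapping expands one extract row into one common-data-model
record per gene tested. Rows that cannot be mapped — unparseable date,
unknown gene symbol, unrecognised result label — are quarantined with a
reason code; mapped + quarantined always equals input rows, so nothing
is silently dropped.

The HGVS extractor covers the subset that structured laboratory
reporting actually uses for small variants: `c.` substitutions with
optional intronic offsets (`c.942+3A>T`), del/dup/ins/delins with
ranges, and `p.` three-letter protein changes including frameshift,
termination and synonymous (`=`). Genomic (`g.`), mitochondrial,
non-coding prefixes, complex alleles and mosaicism are deliberately out
of scope: copy-number variants, the dominant cause of non-HGVS variant
descriptions, are routed to a curated natural-language lexicon
(exon/whole-gene deletion-duplication-rearrangement phrasings) instead
of being forced through the grammar. Validation is syntax plus internal
consistency only — positions ≥ 1, range start ≤ end, substitution
ref ≠ alt, insertions carry a sequence — with no transcript or
reference-sequence lookup, keeping the package fully offline.

Pathogenicity labels are normalised case-insensitively onto the
five-tier scale, accepting IARC class numerals ("class 5" → P,
"class 3" → VUS); anything unrecognised becomes `unclassified`. Result
polarity follows the standard definitions: a record is abnormal if
labelled positive or carrying a P/LP/VUS (or unclassified) variant;
records whose only variants are benign/likely benign are normal.

A concordance audit compares computational against manual per-gene
counts and passes at min/max ≥ 0.95 for every gene, skipping
zero-denominator genes with a warning.

## Episodes

Records of one patient are date-sorted and collapsed greedily into
episodes **anchored** at the earliest authorisation date: a record
joins the open episode while it lies within 365 days of the anchor,
otherwise it opens a new episode. The anchored rule (rather than an
unbounded rolling chain) is forced by the episode-date semantics: the
earliest date names the episode, so no member may sit more than 365
days from it. The test suite checks equivalence with an independent
characterisation — the unique contiguous partition of the sorted dates
whose blocks each span ≤ 365 days and cannot absorb the next date.

Deduplication removes exact repeats of (pseudonym pair, gene, date,
variant, classification). Episode severity is the maximum of member
severities under P > LP > VUS > abnormal-unclassified > normal (B/LB
members rank as normal). Scope comes from the extract's test-type field
when mapped; otherwise a multi-gene episode is a full-gene screen and a
single-gene presence test for a named familial variant is targeted,
with the derivation flagged. Patients with multiple episodes contribute
each episode to per-year tables but count once in unique-patient
totals; identifier-less records can only be grouped within one
(laboratory, date) pair, so distinct unlinkable patients tested the
same day at the same laboratory cannot be separated — the same
limitation the real pseudonymised data has.

## Linkage and cancer timing

Linkage is exact and deterministic: pseudo-ID1 where both sides carry
it, else pseudo-ID2, else unlinkable; an ID1 match with a disagreeing
ID2 is logged and ID1 wins, the NHS number being the stronger
identifier. Timing is relative to the report date of the patient's
*first* test episode; a diagnosis on exactly the reference date counts
as before-test (documented tie rule). All primaries are kept — a
patient can contribute cancers on both sides and is then flagged
`both`. ICD-10 grouping: C18–C20 colorectal, C54–C55 uterine, all other
codes "other".

## Coverage imputation and carrier arithmetic

Audit counts exist per laboratory for financial years 1998–2016
(1 April–31 March, labelled by starting year) and are inflated for some
laboratories by out-of-scope work. The adjustment factor is the pooled
ratio Σ observed / Σ audit over the years where both series exist,
clamped to (0, 1]; pooling damps single-year noise that a mean of
per-year ratios would amplify. Adjustment applies only to years before
the laboratory's earliest observed submission, so observed counts
always win. The two pre-audit years (1996, 1997) are back-filled flat
with the laboratory's earliest adjusted count, for laboratories already
present in the first audit year; "interpolation" admits many formulas
and the flat back-fill is the simplest that adds a small positive
increment of the right order. All counts are rounded half-up once, at
the final step. The audit series carries no full-gene/targeted split,
so imputed years are apportioned by each laboratory's observed
full-gene share (the overall share for laboratories with no observed
years) — an explicit modelling choice, flagged here because the real
split for early years is unknowable from audit data.

Carrier yields use the observed detection rates — 15% P/LP on
full-gene analyses, 45% abnormal on targeted (cascade) analyses — and
the detected fraction compares the summed yield with a predicted
carrier population of population / prevalence-denominator (defaults
56,000,000 and 279).

## The synthetic generator

The generator's defaults are the study conditions: 15% P/LP and 6% VUS
planted on full-gene tests (P:LP ≈ 14:1), 5% benign/likely benign, 20%
of abnormal results as natural-language CNVs, classifications reported
for 29% of abnormal results, 42% of tests targeted with a 45% abnormal
rate, ~70% of full-gene patients with a pre-test cancer registration, a
0.59/0.14/0.27 colorectal/uterine/other site mix, identifier
missingness giving ≈ 89.6/1.2/9.2/0.1% both/ID1-only/ID2-only/none
strata, 2.6% of patients with a repeat episode beyond 365 days, and
three laboratories covering the three dialects with audit inflation
factors 1.25/1.0/1.5. Half of the no-NHS-number stratum carries a
malformed (check-digit-failing) number rather than a blank so the
validator is exercised on realistic bad input. Pre-submission activity
is generated as Poisson(40) analyses per laboratory-year — counts only,
never patient-level, because those laboratories could not extract such
records; submissions begin at a financial-year boundary so observed and
historic activity never share a year. Free-text reports are templated
with randomised filler so extraction cannot succeed positionally, and
one dialect uses DD/MM/YYYY dates to force parser dialect handling.

Everything derives from one integer seed through three independent
numpy substreams (patients, historic counts, report filler); a fixed
seed yields byte-identical output files.

What the synthetic data does **not** emulate: real LIMS idiosyncrasies
beyond three dialects, transcript-accurate variant descriptions,
OCR-grade free-text noise, family structure, misrecorded identifiers
(identifiers are either present, absent or check-digit-invalid — never
subtly wrong), and registry under-ascertainment. Passing tests
therefore demonstrate correctness of the pipeline's logic under known
ground truth, not extraction performance on arbitrary real-world report
wording.

## Problem sizes and numerical choices

The default test suite runs cohorts of 150–10,000 patients; the
parameter-recovery checks use n = 10,000 with exact 99% binomial
intervals (`scipy.stats.binom.ppf`) as the oracle, and the acceptance
script uses 5,000-patient cohorts — sizes at which planted rates are
recovered tightly while a full run completes in seconds. The episode
oracle is exhaustive for up to three dates on a boundary grid
(including 364/365/366) and randomly sampled (2,500 multisets of up to
five dates over a 1,000-day span) beyond that. The adjustment-factor
round trip tolerates exactly the audit-rounding bound
0.5 × (overlap years) / Σ audit; adjusted counts must land within ±1
of truth per laboratory-year. P/LP recovery is measured on a run with
classifications fully reported, mirroring how a detection rate can only
be observed in laboratories that classify every abnormal result.

## Known limitations

Syntax-only HGVS validation accepts well-formed but biologically
impossible variants; the CNV lexicon is curated, not learned, and will
miss phrasings outside it; deterministic linkage cannot tolerate
identifier typos (no fuzzy matching by design); the full-gene/targeted
split of imputed years is an apportionment, not data; and uncertainty
intervals are not produced for imputed totals.
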