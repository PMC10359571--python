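"""Laboratory-dialect harmonisation into the common data model (CDM).

Regional laboratories submit mismatch-repair (MMR) gene testing extracts
in whatever shape their LIMS can produce: fully structured tables,
semi-structured tables with the result buried in clinical report wording,
or free-text reports serialised one per line.  This module maps each
dialect into a single per-gene record shape (:class:`CdmRecord`), pulling
HGVS-compliant variant descriptions out of free text, validating their
syntax, recognising copy-number variants described in natural language,
and normalising pathogenicity labels onto the standard five-tier scale
(P / LP / VUS / LB / B).

Rows that cannot be mapped (unparseable date, unknown gene symbol, missing
mandatory fields) are quarantined with a reason code, never silently
dropped: mapped + quarantined always equals the input row count.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Any, Iterable, Iterator, Literal

import yaml
from pydantic import BaseModel, field_validator, model_validator

from .pseudonym import PseudonymPair, make_pair, strip_identifiers

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

Classification = Literal["P", "LP", "VUS", "LB", "B", "unclassified"]

#: severity order used when one result must represent a test episode
SIGNIFICANCE_ORDER = ("normal", "abnormal_unclassified", "VUS", "LP", "P")


class CdmRecord(BaseModel):
    """One gene's result within one laboratory test, pseudonymised.

    The four-part common data model: linkage pseudonyms, test-episode
    data (dates, laboratory, scope), the per-gene result polarity, and
    the detected variant (cDNA/protein HGVS or a natural-language CNV
    phrase).
    """

    pseudo_id1: str | None = None
    pseudo_id2: str | None = None
    lab_code: str
    authorised_date: date
    report_date: date | None = None
    scope: Literal["full_gene", "targeted"]
    scope_derived: bool = False
    gene: Literal["MLH1", "MSH2", "MSH6", "PMS2"]
    result_label: Literal["positive", "negative"]
    classification: Classification | None = None
    variant_cdna: str | None = None
    variant_protein: str | None = None
    cnv_text: str | None = None
    source_text: str | None = None

    @model_validator(mode="after")
    def _dates_ordered(self) -> "CdmRecord":
        if self.report_date is not None and self.authorised_date > self.report_date:
            raise ValueError("authorised_date must be <= report_date")
        return self

    @property
    def pseudo_ids(self) -> PseudonymPair:
        return PseudonymPair(self.pseudo_id1, self.pseudo_id2)

    def significance(self) -> str:
        """Rank this record on the P > LP > VUS > abnormal-unclassified >
        normal severity scale.

        A record counts as abnormal if labelled positive or carrying a
        VUS/LP/P (or unclassified) variant; negative results and records
        whose only variants are benign/likely benign are normal.
        """
        if self.classification in ("P", "LP", "VUS"):
            return self.classification
        if self.classification in ("B", "LB"):
            return "normal"
        if self.result_label == "positive" or self.variant_cdna or self.cnv_text:
            return "abnormal_unclassified"
        return "normal"


# --------------------------------------------------------------------------
# HGVS grammar subset (syntax only — no transcript or sequence lookup)

_POS = r"[1-9]?\d+(?:[+-]\d+)?"  # allows 0 so the validator can reject it
_BASES = r"[ACGTacgt]+"
CDNA_PATTERN = re.compile(
    rf"c\.(?P<start>{_POS})(?:_(?P<end>{_POS}))?"
    rf"(?:"
    rf"(?P<ref>{_BASES})>(?P<alt>{_BASES})"
    rf"|(?P<op>delins|del|dup|ins)(?P<opseq>{_BASES})?"
    rf")"
    rf"(?![A-Za-z0-9>_])"
)

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|"
    "Trp|Tyr|Val|Ter"
)
PROTEIN_PATTERN = re.compile(
    rf"p\.\(?(?P<ref>{_AA3})(?P<pos>\d+)"
    rf"(?P<change>(?:{_AA3})|\*|fs(?:Ter\d+|\*\d+)?|del|dup|=)"
    rf"\)?(?![A-Za-z0-9])"
)


def extract_hgvs(text: str) -> list[tuple[str, str]]:
    """Find all HGVS-shaped cDNA and protein tokens in free text.

    Returns ``(kind, token)`` pairs, ``kind`` in {"cdna", "protein"}, in
    order of appearance; matches never overlap.  The supported grammar
    covers c. substitutions (including intronic offsets such as
    ``c.942+3A>T``), del/dup/ins/delins, and p. three-letter changes
    including frameshift and termination.  Copy-number variants written
    in natural language ("deletion of exons 1-6") deliberately do not
    match — they are routed to :func:`detect_cnv_language`.
    """
    hits: list[tuple[int, int, str, str]] = []
    for m in CDNA_PATTERN.finditer(text):
        hits.append((m.start(), m.end(), "cdna", m.group(0)))
    for m in PROTEIN_PATTERN.finditer(text):
        hits.append((m.start(), m.end(), "protein", m.group(0)))
    hits.sort()
    out: list[tuple[str, str]] = []
    last_end = -1
    for start, end, kind, token in hits:
        if start >= last_end:
            out.append((kind, token))
            last_end = end
    return out


@dataclass(frozen=True)
class HgvsValidation:
    valid: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.valid


def validate_hgvs(token: str) -> HgvsValidation:
    """Syntactic validation of a single HGVS token.

    Checks grammar membership plus internal consistency: positions must
    be >= 1, range start <= end, substitution ref != alt, insertions
    carry an inserted sequence.  No reference-sequence lookup is done.
    """
    token = token.strip()
    m = CDNA_PATTERN.fullmatch(token)
    if m:
        return _validate_cdna(m)
    m = PROTEIN_PATTERN.fullmatch(token)
    if m:
        return _validate_protein(m)
    return HgvsValidation(False, "not in supported HGVS grammar")


def _anchor_position(pos: str) -> int:
    return int(re.match(r"\d+", pos).group(0))


def _validate_cdna(m: re.Match) -> HgvsValidation:
    start = _anchor_position(m.group("start"))
    if start < 1:
        return HgvsValidation(False, "position must be >= 1")
    end = m.group("end")
    if end is not None:
        end_pos = _anchor_position(end)
        if end_pos < 1:
            return HgvsValidation(False, "position must be >= 1")
        if end_pos < start:
            return HgvsValidation(False, "range end before start")
    if m.group("ref") is not None:
        if end is not None and m.group("ref"):
            return HgvsValidation(False, "substitution takes a single position")
        if m.group("ref").upper() == m.group("alt").upper():
            return HgvsValidation(False, "reference and alternate are identical")
        if len(m.group("ref")) != 1 or len(m.group("alt")) != 1:
            return HgvsValidation(False, "substitution is single-nucleotide")
    else:
        op, seq = m.group("op"), m.group("opseq")
        if op in ("ins", "delins") and not seq:
            return HgvsValidation(False, f"{op} requires an inserted sequence")
        if op == "ins" and end is None:
            return HgvsValidation(False, "ins requires a flanking range")
    return HgvsValidation(True)


def _validate_protein(m: re.Match) -> HgvsValidation:
    if int(m.group("pos")) < 1:
        return HgvsValidation(False, "position must be >= 1")
    ref, change = m.group("ref"), m.group("change")
    if change == ref:
        return HgvsValidation(False, "reference and alternate residues identical")
    if ref == "Ter" and change not in ("del", "dup", "="):
        # extensions are outside the supported subset
        return HgvsValidation(False, "change from Ter not supported")
    return HgvsValidation(True)


# --------------------------------------------------------------------------
# Natural-language CNV phrases

_CNV_PATTERNS = [
    re.compile(p, re.IGNORECASE)
    for p in (
        r"\b(?:deletion|duplication|rearrangement)\s+(?:of\s+)?(?:the\s+)?exons?\b",
        r"\bexons?\s+\d+(?:\s*(?:-|–|to)\s*\d+)?\s+(?:is|are|was|were\s+)?"
        r"(?:deleted|duplicated|rearranged)\b",
        r"\bexons?\s+\d+(?:\s*(?:-|–|to)\s*\d+)?\s+(?:deletion|duplication)\b",
        r"\bwhole[- ]gene\s+(?:deletion|duplication)\b",
        r"\bwhole\s+gene\s+(?:deletion|duplication)\b",
        r"\b(?:deletion|duplication)\s+of\s+(?:the\s+)?(?:whole|entire)\s+gene\b",
        r"\blarge\s+(?:genomic\s+)?(?:deletion|duplication|rearrangement)\b",
        r"\bcopy\s+number\s+(?:loss|gain|variant|change)\b",
    )
]


def detect_cnv_language(text: str) -> bool:
    """True iff *text* matches the curated copy-number-variant lexicon."""
    return any(p.search(text) for p in _CNV_PATTERNS)


# --------------------------------------------------------------------------
# Pathogenicity label normalisation

_CLASSIFICATION_SYNONYMS: dict[str, Classification] = {}
for _target, _names in {
    "P": ("p", "pathogenic", "class 5", "class v", "5"),
    "LP": ("lp", "likely pathogenic", "probably pathogenic", "class 4", "class iv", "4"),
    "VUS": ("vus", "uncertain", "uncertain significance", "unknown significance",
            "variant of uncertain significance", "class 3", "class iii", "3"),
    "LB": ("lb", "likely benign", "probably benign", "class 2", "class ii", "2"),
    "B": ("b", "benign", "class 1", "class i", "1"),
}.items():
    for _n in _names:
        _CLASSIFICATION_SYNONYMS[_n] = _target


def normalise_classification(label: str | None) -> Classification:
    """Map a laboratory's pathogenicity wording onto {P, LP, VUS, LB, B};
    anything unrecognised (including blank) becomes ``unclassified``."""
    if label is None:
        return "unclassified"
    key = re.sub(r"\s+", " ", str(label).strip().lower())
    return _CLASSIFICATION_SYNONYMS.get(key, "unclassified")


# --------------------------------------------------------------------------
# Dialect specifications

class DialectSpec(BaseModel):
    """Declarative description of one laboratory's extract format."""

    dialect_name: str
    file_format: Literal["csv", "jsonl"]
    date_format: str = "%Y-%m-%d"
    columns: dict[str, str] = {}
    result_vocabulary: dict[str, str] = {}
    scope_vocabulary: dict[str, str] = {}
    free_text_fields: list[str] = []
    gene_list_separator: str = "|"

    @field_validator("result_vocabulary", "scope_vocabulary", mode="before")
    @classmethod
    def _lower_keys(cls, v: dict) -> dict:
        return {str(k).strip().lower(): val for k, val in (v or {}).items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectSpec":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


#: the three built-in dialects the synthetic generator emits
BUILTIN_DIALECTS: dict[str, DialectSpec] = {
    "structured": DialectSpec(
        dialect_name="structured",
        file_format="csv",
        date_format="%Y-%m-%d",
        columns={
            "nhs_number": "nhs_number", "dob": "dob", "postcode": "postcode",
            "authorised_date": "authorised_date", "report_date": "report_date",
            "test_type": "test_type", "genes": "genes",
            "variant_gene": "variant_gene", "variant_cdna": "variant_cdna",
            "variant_protein": "variant_protein", "cnv_text": "cnv_description",
            "result": "overall_result", "classification": "classification",
        },
        result_vocabulary={"normal": "negative", "abnormal": "positive"},
        scope_vocabulary={"diagnostic": "full_gene", "full gene": "full_gene",
                          "predictive": "targeted", "targeted": "targeted"},
    ),
    "semistructured": DialectSpec(
        dialect_name="semistructured",
        file_format="csv",
        date_format="%d/%m/%Y",
        columns={
            "nhs_number": "NHSNo", "dob": "DateOfBirth", "postcode": "PostCode",
            "authorised_date": "AuthDate", "report_date": "ReportDate",
            "test_type": "TestType", "genes": "GenesTested",
            "report_text": "ReportText",
        },
        scope_vocabulary={"diag": "full_gene", "diagnostic screen": "full_gene",
                          "pred": "targeted", "predictive": "targeted"},
        free_text_fields=["report_text"],
        gene_list_separator=";",
    ),
    "freetext": DialectSpec(
        dialect_name="freetext",
        file_format="jsonl",
        date_format="%Y-%m-%d",
        columns={
            "nhs_number": "nhs_number", "dob": "dob", "postcode": "postcode",
            "authorised_date": "authorised_date", "report_date": "report_date",
            "genes": "genes", "report_text": "report_text",
        },
        free_text_fields=["report_text"],
        gene_list_separator="|",
    ),
}


# --------------------------------------------------------------------------
# Extract mapping

@dataclass
class QuarantinedRow:
    row_number: int
    reason: str
    raw: dict = field(repr=False, default_factory=dict)


@dataclass
class MappingResult:
    records: list[CdmRecord]
    quarantined: list[QuarantinedRow]
    n_input_rows: int


def _read_rows(path: str | Path, spec: DialectSpec) -> Iterator[dict[str, Any]]:
    path = Path(path)
    if spec.file_format == "csv":
        with open(path, newline="") as fh:
            yield from csv.DictReader(fh)
    else:
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    yield json.loads(line)


def _parse_date(value: str | None, fmt: str) -> date | None:
    if value is None or str(value).strip() == "":
        return None
    return datetime.strptime(str(value).strip(), fmt).date()


_NEG_CONTEXT = re.compile(
    r"\bno\s+(?:pathogenic\s+)?(?:sequence\s+)?(?:variant|mutation|abnormalit)",
    re.IGNORECASE)
_POS_CONTEXT = re.compile(
    r"\b(?:heterozygous|pathogenic|likely pathogenic|uncertain|variant"
    r"\s+(?:was\s+)?(?:detected|identified)|mutation\s+(?:was\s+)?detected)",
    re.IGNORECASE)
_GENE_IN_TEXT = re.compile(r"\b(MLH1|MSH2|MSH6|PMS2)\b")
_CLASS_IN_TEXT = re.compile(
    r"\bclassified\s+as\s+(?:a\s+)?([A-Za-z 0-9]+?)\s*(?:variant)?\s*[.,;]",
    re.IGNORECASE)
_NOT_FOUND = re.compile(
    r"\b(?:was|were)\s+not\s+(?:detected|identified|present)\b|\babsent\b",
    re.IGNORECASE)
_PRESENCE_TEST = re.compile(r"\bfamilial\s+variant\b|\bpredictive\b", re.IGNORECASE)


def _interpret_free_text(text: str) -> dict[str, Any]:
    """Pull gene, variant, CNV phrase and classification out of report wording."""
    tokens = extract_hgvs(text)
    cdna = next((t for k, t in tokens if k == "cdna"), None)
    protein = next((t for k, t in tokens if k == "protein"), None)
    has_cnv = detect_cnv_language(text)
    m = _CLASS_IN_TEXT.search(text)
    classification = normalise_classification(m.group(1)) if m else None
    presence_test = bool(_PRESENCE_TEST.search(text))
    # a mentioned-but-negated variant is the one sought, not a finding
    negated = bool(_NOT_FOUND.search(text))
    variant_gene = None
    if cdna or has_cnv:
        # the gene named nearest before the variant mention
        anchor = text.find(cdna) if cdna else len(text)
        genes_before = [(g.start(), g.group(1)) for g in _GENE_IN_TEXT.finditer(text)
                        if g.start() < anchor]
        if genes_before:
            variant_gene = genes_before[-1][1]
        else:
            g = _GENE_IN_TEXT.search(text)
            variant_gene = g.group(1) if g else None
    if negated:
        abnormal = False
    else:
        abnormal = bool(cdna or has_cnv) or (
            bool(_POS_CONTEXT.search(text)) and not _NEG_CONTEXT.search(text))
    return {
        "variant_cdna": cdna if abnormal else None,
        "variant_protein": protein if abnormal else None,
        "cnv_text": text if (has_cnv and abnormal) else None,
        "classification": classification if abnormal else None,
        "variant_gene": variant_gene if abnormal else None,
        "abnormal": abnormal,
        "presence_test": presence_test,
    }


def map_extract(extract_file: str | Path, spec: DialectSpec, key: bytes | str,
                lab_code: str | None = None) -> MappingResult:
    """Map one laboratory extract into per-gene CDM records.

    Each input row describes one test of one or more genes; it expands to
    one :class:`CdmRecord` per gene.  Pseudonyms are created and raw
    identifiers stripped here, at ingest.  Unmappable rows are quarantined
    with a reason and counted: mapped-row + quarantined-row totals always
    reconcile with the input.
    """
    lab = lab_code or Path(extract_file).stem
    records: list[CdmRecord] = []
    quarantined: list[QuarantinedRow] = []
    n_rows = 0
    col = spec.columns.get
    for i, row in enumerate(_read_rows(extract_file, spec)):
        n_rows += 1
        try:
            records.extend(_map_row(row, spec, key, lab, col))
        except Exception as exc:  # noqa: BLE001 - quarantine, never drop
            safe = {k: v for k, v in row.items()
                    if col("nhs_number") != k and col("dob") != k and col("postcode") != k}
            quarantined.append(QuarantinedRow(i, str(exc), safe))
    return MappingResult(records, quarantined, n_rows)


def _map_row(row: dict, spec: DialectSpec, key: bytes | str, lab: str,
             col) -> list[CdmRecord]:
    get = lambda name: row.get(col(name) or "", None)  # noqa: E731
    authorised = _parse_date(get("authorised_date"), spec.date_format)
    if authorised is None:
        raise ValueError("missing or unparseable authorised date")
    report = _parse_date(get("report_date"), spec.date_format)

    genes_raw = get("genes") or ""
    genes = [g.strip().upper() for g in genes_raw.split(spec.gene_list_separator)
             if g.strip()]
    if not genes:
        raise ValueError("no genes listed")
    unknown = [g for g in genes if g not in MMR_GENES]
    if unknown:
        raise ValueError(f"unknown gene symbol(s): {','.join(unknown)}")

    pair = make_pair(get("nhs_number"), get("dob"), get("postcode"), key)

    scope_raw = (get("test_type") or "").strip().lower()
    scope = spec.scope_vocabulary.get(scope_raw)
    scope_derived = False
    if scope is None:
        scope_derived = True

    interp: dict[str, Any] = {}
    source_text = None
    for ft_field in spec.free_text_fields:
        text = get(ft_field)
        if text:
            source_text = text
            interp = _interpret_free_text(text)
            break
    if not spec.free_text_fields:
        result_raw = (get("result") or "").strip().lower()
        label = spec.result_vocabulary.get(result_raw)
        if label is None:
            raise ValueError(f"unknown result label: {result_raw!r}")
        interp = {
            "variant_cdna": get("variant_cdna") or None,
            "variant_protein": get("variant_protein") or None,
            "cnv_text": get("cnv_text") or None,
            "classification": (normalise_classification(get("classification"))
                               if (get("classification") or "").strip() else None),
            "variant_gene": (get("variant_gene") or "").strip().upper() or None,
            "abnormal": label == "positive",
        }

    if scope is None:
        # derive: single-gene presence test for a specific variant -> targeted
        scope = ("targeted" if (len(genes) == 1 and interp.get("presence_test"))
                 else "full_gene")

    variant_gene = interp.get("variant_gene")
    if variant_gene and variant_gene not in genes and variant_gene in MMR_GENES:
        genes.append(variant_gene)

    out: list[CdmRecord] = []
    for gene in genes:
        is_variant_gene = interp.get("abnormal") and (
            variant_gene == gene or (variant_gene is None and len(genes) == 1))
        base = {
            "lab_code": lab,
            "authorised_date": authorised,
            "report_date": report,
            "scope": scope,
            "scope_derived": scope_derived,
            "gene": gene,
            "result_label": "positive" if is_variant_gene else "negative",
            "classification": interp.get("classification") if is_variant_gene else None,
            "variant_cdna": interp.get("variant_cdna") if is_variant_gene else None,
            "variant_protein": interp.get("variant_protein") if is_variant_gene else None,
            "cnv_text": interp.get("cnv_text") if is_variant_gene else None,
            "source_text": source_text,
        }
        clean = strip_identifiers(base, pair)
        clean.pop("unlinkable")
        out.append(CdmRecord(**clean))
    return out


# --------------------------------------------------------------------------
# Concordance audit

@dataclass
class ConcordanceReport:
    passed: bool
    ratios: dict[str, float]
    skipped: list[str]


def concordance_audit(computational: dict[str, int], manual: dict[str, int],
                      threshold: float = 0.95) -> ConcordanceReport:
    """Compare computational vs manual per-gene extraction counts.

    Passes iff min/max >= *threshold* for every gene present in both
    tallies; genes with a zero denominator are skipped with a warning
    entry rather than failing the audit.
    """
    if set(computational) != set(manual):
        raise ValueError("gene universes differ between extractions")
    ratios: dict[str, float] = {}
    skipped: list[str] = []
    for gene in computational:
        comp, man = computational[gene], manual[gene]
        if max(comp, man) == 0:
            skipped.append(gene)
            continue
        ratios[gene] = min(comp, man) / max(comp, man)
    passed = all(r >= threshold for r in ratios.values())
    return ConcordanceReport(passed, ratios, skipped)


# --------------------------------------------------------------------------
# CDM I/O

_CDM_FIELDS = list(CdmRecord.model_fields)


def write_cdm(records: Iterable[CdmRecord], csv_path: str | Path,
              jsonl_path: str | Path | None = None) -> None:
    """Write CDM rows as CSV (and optionally JSONL with identical content)."""
    rows = [r.model_dump(mode="json") for r in records]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CDM_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    if jsonl_path is not None:
        with open(jsonl_path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_cdm(csv_path: str | Path) -> list[CdmRecord]:
    out = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            clean = {k: (None if v == "" else v) for k, v in row.items()}
            clean["scope_derived"] = str(row.get("scope_derived")).lower() in ("true", "1")
            out.append(CdmRecord(**clean))
    return out
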