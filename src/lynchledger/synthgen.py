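"""Synthetic laboratory extracts, cancer registry and audit counts.

Real germline MMR testing records are held under healthcare data
governance and cannot be redistributed, so every downstream stage of this
package is exercised on synthetic data with known ground truth.  The
generator emulates the obstacles the pipeline exists to solve:

* several laboratory extract *dialects* — a fully structured CSV, a
  semi-structured CSV whose results live in clinical report wording
  (with DD/MM/YYYY dates), and a free-text JSONL of one report per line
  (ISO dates) in which HGVS variants are embedded verbatim and
  copy-number variants are described in natural language only;
* patient identifiers (mod-11-valid NHS numbers, DOB, postcode) with
  configurable missingness, including deliberately invalid NHS numbers;
* planted result mixes mirroring observed national rates (~15% P/LP on
  full-gene analyses, ~45% abnormal on targeted analyses, ~29% of
  abnormal results carrying a pathogenicity classification);
* a cancer registry of ICD-10-coded diagnoses timed before/after tests;
* laboratory-level annual audit counts (financial years 1998–2016)
  inflated by out-of-scope activity.

Everything is driven by one integer seed: the same configuration always
produces byte-identical files.  Ground truth goes to a separate *truth
ledger* that the pipeline never reads — it exists for tests only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .coverage import AUDIT_FIRST_YEAR, AUDIT_LAST_YEAR, financial_year
from .harmonise import MMR_GENES

__all__ = [
    "LabConfig",
    "GeneratorConfig",
    "SourcePatient",
    "PlantedTest",
    "PlantedCancer",
    "generate_patients",
    "generate_historic_counts",
    "write_lab_extracts",
    "write_registry",
    "write_audit_counts",
    "write_truth_ledger",
]


class LabConfig(BaseModel):
    lab_code: str
    dialect: Literal["structured", "semistructured", "freetext"]
    first_submission_year: int = Field(ge=1996, le=2020)
    activity_start_year: int = Field(default=1996, ge=1990)
    audit_inflation: float = Field(default=1.0, ge=1.0)


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic cohort.

    Rate defaults mirror the observed national figures: P/LP detection
    0.15 and VUS 0.06 on full-gene analyses, abnormal rate 0.45 on
    targeted analyses, pathogenicity classification available for 29% of
    abnormal results, ~70% of full-gene patients with a pre-test cancer
    registration, a colorectal-dominated site mix, and identifier
    missingness reproducing the both/ID1-only/ID2-only/none linkage
    strata (≈90.2/0.5/8.6/0.7%).
    """

    n_patients: int = Field(default=2000, ge=0)
    seed: int = 0
    labs: list[LabConfig] = Field(default_factory=lambda: [
        LabConfig(lab_code="LAB01", dialect="structured",
                  first_submission_year=2000, activity_start_year=1996,
                  audit_inflation=1.25),
        LabConfig(lab_code="LAB02", dialect="semistructured",
                  first_submission_year=2004, activity_start_year=1996,
                  audit_inflation=1.0),
        LabConfig(lab_code="LAB03", dialect="freetext",
                  first_submission_year=2010, activity_start_year=2000,
                  audit_inflation=1.5),
    ])
    rate_plp: float = Field(default=0.15, ge=0, le=1)
    rate_vus: float = Field(default=0.06, ge=0, le=1)
    rate_lbb: float = Field(default=0.05, ge=0, le=1)
    rate_cnv_among_abnormal: float = Field(default=0.20, ge=0, le=1)
    rate_classification_reported: float = Field(default=0.29, ge=0, le=1)
    rate_targeted: float = Field(default=0.42, ge=0, le=1)
    rate_targeted_abnormal: float = Field(default=0.45, ge=0, le=1)
    p_no_nhs: float = Field(default=0.093, ge=0, le=1)
    p_no_dob_postcode: float = Field(default=0.012, ge=0, le=1)
    pretest_cancer_rate_fullgene: float = Field(default=0.70, ge=0, le=1)
    posttest_cancer_rate: float = Field(default=0.05, ge=0, le=1)
    cancer_rate_targeted: float = Field(default=0.15, ge=0, le=1)
    registry_cancer_site_mix: dict[str, float] = Field(
        default_factory=lambda: {"colorectal": 0.59, "uterine": 0.14,
                                 "other": 0.27})
    repeat_episode_rate: float = Field(default=0.026, ge=0, le=1)
    historic_annual_tests: float = Field(default=40.0, ge=0)
    last_test_date: date = date(2020, 3, 31)

    @field_validator("registry_cancer_site_mix")
    @classmethod
    def _mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"colorectal", "uterine", "other"}:
            raise ValueError("site mix needs colorectal/uterine/other weights")
        if any(w < 0 for w in v.values()) or sum(v.values()) <= 0:
            raise ValueError("site mix weights must be non-negative, not all zero")
        return v

    def lab(self, code: str) -> LabConfig:
        for lab in self.labs:
            if lab.lab_code == code:
                return lab
        raise KeyError(code)


@dataclass
class PlantedTest:
    authorised_date: date
    report_date: date
    lab_code: str
    scope: str  # full_gene | targeted
    genes: tuple[str, ...]
    true_result: str  # P | LP | VUS | LB | B | normal
    variant_gene: Optional[str] = None
    variant_cdna: Optional[str] = None
    variant_protein: Optional[str] = None
    cnv_phrase: Optional[str] = None
    sought_variant: Optional[str] = None  # targeted tests with a normal result
    classification_reported: bool = False


@dataclass
class PlantedCancer:
    icd10: str
    diagnosis_date: date
    site_group: str


@dataclass
class SourcePatient:
    person_uid: str
    nhs_number: Optional[str]
    nhs_number_valid: bool
    dob: Optional[date]
    postcode: Optional[str]
    planted_tests: list[PlantedTest] = field(default_factory=list)
    planted_cancers: list[PlantedCancer] = field(default_factory=list)

    @property
    def expected_stratum(self) -> str:
        id1 = self.nhs_number is not None and self.nhs_number_valid
        id2 = self.dob is not None and self.postcode is not None
        return {(True, True): "both", (True, False): "id1_only",
                (False, True): "id2_only", (False, False): "none"}[(id1, id2)]


# --------------------------------------------------------------------------
# Identifier synthesis

def _nhs_check_digit(nine: str) -> int:
    weighted = sum(int(d) * w for d, w in zip(nine, range(10, 1, -1)))
    check = 11 - (weighted % 11)
    return 0 if check == 11 else check


def _make_nhs_number(rng: np.random.Generator, valid: bool) -> str:
    while True:
        nine = "".join(str(d) for d in rng.integers(0, 10, size=9))
        check = _nhs_check_digit(nine)
        if check == 10:
            continue
        if valid:
            return nine + str(check)
        return nine + str((check + 3) % 10)


_PC_LETTERS = "ABDEFGHJLNPQRSTUWXYZ"


def _make_postcode(rng: np.random.Generator) -> str:
    pick = lambda s: s[rng.integers(0, len(s))]  # noqa: E731
    return (pick(_PC_LETTERS) + pick(_PC_LETTERS) + str(rng.integers(1, 10))
            + " " + str(rng.integers(0, 10)) + pick(_PC_LETTERS) + pick(_PC_LETTERS))


def _rand_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


# --------------------------------------------------------------------------
# Variant synthesis

_CNV_TEMPLATES = (
    "deletion of exons {a}-{b}",
    "duplication of exons {a}-{b}",
    "deletion of exon {a}",
    "whole gene deletion",
    "whole gene duplication",
)


def _make_cdna(rng: np.random.Generator) -> str:
    pos = int(rng.integers(1, 2500))
    kind = rng.random()
    bases = "ACGT"
    if kind < 0.60:  # substitution, occasionally intronic
        offset = f"{'+' if rng.random() < 0.5 else '-'}{int(rng.integers(1, 20))}" \
            if rng.random() < 0.2 else ""
        ref = bases[rng.integers(0, 4)]
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        return f"c.{pos}{offset}{ref}>{alt}"
    if kind < 0.75:
        return f"c.{pos}_{pos + int(rng.integers(1, 10))}del"
    if kind < 0.85:
        return f"c.{pos}dup"
    if kind < 0.95:
        ins = "".join(bases[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        return f"c.{pos}_{pos + 1}ins{ins}"
    return f"c.{pos}_{pos + int(rng.integers(1, 6))}delinsAT"


_AA = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
       "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")


def _make_protein(rng: np.random.Generator) -> str:
    ref = _AA[rng.integers(0, len(_AA))]
    alt_pool = [a for a in _AA if a != ref] + ["Ter"]
    alt = alt_pool[rng.integers(0, len(alt_pool))]
    return f"p.({ref}{int(rng.integers(1, 900))}{alt})"


def _make_cnv(rng: np.random.Generator) -> str:
    template = _CNV_TEMPLATES[rng.integers(0, len(_CNV_TEMPLATES))]
    a = int(rng.integers(1, 12))
    return template.format(a=a, b=a + int(rng.integers(1, 8)))


def _gene_panel(rng: np.random.Generator, year: int) -> tuple[str, ...]:
    """Gene combinations drift with the calendar, echoing assay history:
    MLH1/MSH2 era, MSH6 uptake from 2006, four-gene panels dominant later."""
    if year < 2006:
        options = [("MLH1",), ("MSH2",), ("MLH1", "MSH2")]
        weights = [0.25, 0.25, 0.50]
    elif year < 2011:
        options = [("MLH1", "MSH2"), ("MLH1", "MSH2", "MSH6"),
                   ("MSH6",), ("MLH1", "MSH2", "MSH6", "PMS2")]
        weights = [0.40, 0.30, 0.10, 0.20]
    else:
        options = [("MLH1", "MSH2", "MSH6", "PMS2"),
                   ("MLH1", "MSH2", "MSH6"), ("MLH1", "MSH2")]
        weights = [0.70, 0.20, 0.10]
    return options[rng.choice(len(options), p=weights)]


# --------------------------------------------------------------------------
# Cohort generation

_SITE_CODES = {
    "colorectal": ("C18.0", "C18.2", "C18.7", "C18.9", "C19", "C20"),
    "uterine": ("C54.1", "C54.9", "C55"),
    "other": ("C15.9", "C16.9", "C25.9", "C50.9", "C56", "C61", "C64.9",
              "C67.9", "C71.9"),
}


def _plant_result(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    u = rng.random()
    if u < cfg.rate_plp:
        return "P" if rng.random() < 14 / 15 else "LP"
    if u < cfg.rate_plp + cfg.rate_vus:
        return "VUS"
    if u < cfg.rate_plp + cfg.rate_vus + cfg.rate_lbb:
        return "LB" if rng.random() < 0.5 else "B"
    return "normal"


def _plant_test(rng: np.random.Generator, cfg: GeneratorConfig,
                lab: LabConfig, authorised: date) -> PlantedTest:
    report = authorised + timedelta(days=int(rng.integers(7, 61)))
    targeted = rng.random() < cfg.rate_targeted
    if targeted:
        gene = MMR_GENES[rng.integers(0, 4)]
        sought = _make_cdna(rng)
        abnormal = rng.random() < cfg.rate_targeted_abnormal
        return PlantedTest(
            authorised_date=authorised, report_date=report,
            lab_code=lab.lab_code, scope="targeted", genes=(gene,),
            true_result="P" if abnormal else "normal",
            variant_gene=gene if abnormal else None,
            variant_cdna=sought if abnormal else None,
            sought_variant=None if abnormal else sought,
            classification_reported=(
                abnormal and rng.random() < cfg.rate_classification_reported),
        )
    genes = _gene_panel(rng, authorised.year)
    result = _plant_result(rng, cfg)
    test = PlantedTest(
        authorised_date=authorised, report_date=report,
        lab_code=lab.lab_code, scope="full_gene", genes=genes,
        true_result=result,
    )
    if result != "normal":
        test.variant_gene = genes[rng.integers(0, len(genes))]
        if result in ("P", "LP", "VUS") and rng.random() < cfg.rate_cnv_among_abnormal:
            test.cnv_phrase = _make_cnv(rng)
        else:
            test.variant_cdna = _make_cdna(rng)
            if rng.random() < 0.6:
                test.variant_protein = _make_protein(rng)
        if result in ("LB", "B"):
            # benign variants only read as normal when so classified
            test.classification_reported = True
        else:
            test.classification_reported = (
                rng.random() < cfg.rate_classification_reported)
    return test


def generate_patients(config: GeneratorConfig) -> list[SourcePatient]:
    """Generate the synthetic cohort with planted tests and cancers.

    Deterministic in ``config.seed``; planted result frequencies,
    identifier missingness and cancer site mix match the configured
    rates in expectation.
    """
    if not config.labs:
        raise ValueError("at least one laboratory must be configured")
    rng = np.random.default_rng([abs(config.seed), 0])
    sites = sorted(config.registry_cancer_site_mix)
    weights = np.array([config.registry_cancer_site_mix[s] for s in sites])
    weights = weights / weights.sum()

    patients: list[SourcePatient] = []
    for i in range(config.n_patients):
        no_nhs = rng.random() < config.p_no_nhs
        # half of the NHS-less stratum carries a malformed number so the
        # validator sees realistic bad input, half is simply missing
        if no_nhs:
            nhs = _make_nhs_number(rng, valid=False) if rng.random() < 0.5 else None
        else:
            nhs = _make_nhs_number(rng, valid=True)
        no_dp = rng.random() < config.p_no_dob_postcode
        dob = None if no_dp else _rand_date(rng, date(1930, 1, 1), date(1999, 12, 31))
        postcode = None if no_dp else _make_postcode(rng)

        lab = config.labs[rng.integers(0, len(config.labs))]
        # submissions begin at a financial-year boundary, so observed
        # counts and pre-submission (historic) activity never share a year
        start = date(max(lab.first_submission_year, 2001), 4, 1)
        first_test = _rand_date(rng, start, config.last_test_date)
        tests = [_plant_test(rng, config, lab, first_test)]
        if rng.random() < config.repeat_episode_rate:
            gap = int(rng.integers(366, 1500))
            second = first_test + timedelta(days=gap)
            if second <= config.last_test_date:
                tests.append(_plant_test(rng, config, lab, second))

        patient = SourcePatient(
            person_uid=f"SYN{i:07d}", nhs_number=nhs,
            nhs_number_valid=nhs is not None and not no_nhs,
            dob=dob, postcode=postcode, planted_tests=tests,
        )
        _plant_cancers(rng, config, patient, sites, weights)
        patients.append(patient)
    return patients


def _plant_cancers(rng: np.random.Generator, cfg: GeneratorConfig,
                   patient: SourcePatient, sites: list[str],
                   weights: np.ndarray) -> None:
    first = min(t.report_date for t in patient.planted_tests)
    scope = patient.planted_tests[0].scope

    def add(diagnosis: date) -> None:
        site = sites[rng.choice(len(sites), p=weights)]
        codes = _SITE_CODES[site]
        patient.planted_cancers.append(PlantedCancer(
            icd10=codes[rng.integers(0, len(codes))],
            diagnosis_date=diagnosis, site_group=site))

    def pre_date() -> date:
        d = first - timedelta(days=int(rng.integers(30, 5475)))
        return max(d, date(1995, 1, 1))

    if scope == "full_gene":
        if rng.random() < cfg.pretest_cancer_rate_fullgene:
            add(pre_date())
            if rng.random() < 0.20:  # second primary before testing
                add(pre_date())
        if rng.random() < cfg.posttest_cancer_rate:
            d = first + timedelta(days=int(rng.integers(30, 2000)))
            if d <= date(2019, 12, 31):
                add(d)
    else:
        if rng.random() < cfg.cancer_rate_targeted:
            if rng.random() < 0.65:
                add(pre_date())
            if rng.random() < 0.40:
                d = first + timedelta(days=int(rng.integers(30, 2000)))
                if d <= date(2019, 12, 31):
                    add(d)


# --------------------------------------------------------------------------
# Report wording (free-text dialects)

_FILLERS = (
    "DNA was extracted from a peripheral blood sample.",
    "Analysis was performed by bidirectional Sanger sequencing.",
    "Analysis included MLPA dosage assessment.",
    "Testing was carried out in accordance with local protocols.",
    "Results were reviewed and authorised by a clinical scientist.",
    "This result should be interpreted in the context of the clinical findings.",
)

_CLASS_WORDS = {"P": "pathogenic", "LP": "likely pathogenic",
                "VUS": "uncertain", "LB": "likely benign", "B": "benign"}


def _filler(rng: np.random.Generator) -> str:
    return _FILLERS[rng.integers(0, len(_FILLERS))]


def _report_text(rng: np.random.Generator, t: PlantedTest) -> str:
    genes = ", ".join(t.genes)
    parts = [_filler(rng)]
    if t.scope == "targeted":
        sought = t.variant_cdna or t.sought_variant
        parts.append(f"Predictive testing for the familial variant {sought} "
                     f"in {t.genes[0]} was performed.")
        if t.true_result == "normal":
            parts.append("The familial variant was not detected.")
        else:
            parts.append("The familial variant was detected.")
            if t.classification_reported:
                parts.append("This variant is classified as "
                             f"{_CLASS_WORDS[t.true_result]}.")
    elif t.true_result == "normal":
        parts.append(f"Screening of the {genes} coding regions was performed.")
        parts.append("No pathogenic variant was detected.")
    elif t.cnv_phrase:
        parts.append(f"Screening of the {genes} coding regions was performed.")
        parts.append(f"Dosage analysis of {t.variant_gene} identified a "
                     f"{t.cnv_phrase}.")
        if t.classification_reported:
            parts.append(f"This is classified as {_CLASS_WORDS[t.true_result]}.")
    else:
        prot = f" {t.variant_protein}" if t.variant_protein else ""
        parts.append(f"Screening of the {genes} coding regions was performed.")
        if t.classification_reported:
            parts.append(f"In {t.variant_gene} a heterozygous variant "
                         f"{t.variant_cdna}{prot} was identified, classified as "
                         f"{_CLASS_WORDS[t.true_result]}.")
        else:
            parts.append(f"In {t.variant_gene} a heterozygous variant "
                         f"{t.variant_cdna}{prot} was identified.")
    parts.append(_filler(rng))
    return " ".join(parts)


# --------------------------------------------------------------------------
# Extract / registry / audit writers

def write_lab_extracts(patients: list[SourcePatient], config: GeneratorConfig,
                       outdir: str | Path) -> dict[str, Path]:
    """Write one extract file per laboratory in its configured dialect.

    Every planted test becomes exactly one extract row (conservation);
    identifiers are emitted raw, as submitted by real laboratories —
    pseudonymisation happens downstream at ingest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([abs(config.seed), 2])
    rows: dict[str, list[dict]] = {lab.lab_code: [] for lab in config.labs}
    for patient in patients:
        for t in patient.planted_tests:
            lab = config.lab(t.lab_code)
            rows[lab.lab_code].append(_extract_row(rng, patient, t, lab))

    paths: dict[str, Path] = {}
    for lab in config.labs:
        if lab.dialect == "freetext":
            path = outdir / f"{lab.lab_code}.jsonl"
            with open(path, "w") as fh:
                for row in rows[lab.lab_code]:
                    fh.write(json.dumps(row, sort_keys=True) + "\n")
        else:
            path = outdir / f"{lab.lab_code}.csv"
            fieldnames = _DIALECT_COLUMNS[lab.dialect]
            with open(path, "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=fieldnames)
                writer.writeheader()
                writer.writerows(rows[lab.lab_code])
        paths[lab.lab_code] = path
    return paths


_DIALECT_COLUMNS = {
    "structured": ["nhs_number", "dob", "postcode", "authorised_date",
                   "report_date", "test_type", "genes", "variant_gene",
                   "variant_cdna", "variant_protein", "cnv_description",
                   "overall_result", "classification"],
    "semistructured": ["NHSNo", "DateOfBirth", "PostCode", "AuthDate",
                       "ReportDate", "TestType", "GenesTested", "ReportText"],
}


def _extract_row(rng: np.random.Generator, p: SourcePatient, t: PlantedTest,
                 lab: LabConfig) -> dict:
    if lab.dialect == "structured":
        abnormal = t.true_result in ("P", "LP", "VUS")
        return {
            "nhs_number": p.nhs_number or "",
            "dob": p.dob.isoformat() if p.dob else "",
            "postcode": p.postcode or "",
            "authorised_date": t.authorised_date.isoformat(),
            "report_date": t.report_date.isoformat(),
            "test_type": "predictive" if t.scope == "targeted" else "diagnostic",
            "genes": "|".join(t.genes),
            "variant_gene": t.variant_gene or "",
            "variant_cdna": t.variant_cdna if abnormal else "",
            "variant_protein": t.variant_protein if abnormal else "",
            "cnv_description": t.cnv_phrase or "",
            "overall_result": "abnormal" if abnormal else "normal",
            "classification": (_CLASS_WORDS[t.true_result]
                               if t.true_result != "normal"
                               and t.classification_reported else ""),
        }
    if lab.dialect == "semistructured":
        return {
            "NHSNo": p.nhs_number or "",
            "DateOfBirth": p.dob.strftime("%d/%m/%Y") if p.dob else "",
            "PostCode": p.postcode or "",
            "AuthDate": t.authorised_date.strftime("%d/%m/%Y"),
            "ReportDate": t.report_date.strftime("%d/%m/%Y"),
            "TestType": "Pred" if t.scope == "targeted" else "Diag",
            "GenesTested": ";".join(t.genes),
            "ReportText": _report_text(rng, t),
        }
    return {
        "nhs_number": p.nhs_number or "",
        "dob": p.dob.isoformat() if p.dob else "",
        "postcode": p.postcode or "",
        "authorised_date": t.authorised_date.isoformat(),
        "report_date": t.report_date.isoformat(),
        "genes": "|".join(t.genes),
        "report_text": _report_text(rng, t),
    }


def write_registry(patients: list[SourcePatient], path: str | Path) -> int:
    """Write the raw synthetic cancer registry (one row per planted
    cancer, identifiers still raw — pseudonymised by the same scheme as
    the extracts before linkage).  Returns the row count."""
    path = Path(path)
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "nhs_number", "dob", "postcode", "icd10", "diagnosis_date"])
        writer.writeheader()
        for p in patients:
            for c in p.planted_cancers:
                writer.writerow({
                    "nhs_number": p.nhs_number or "",
                    "dob": p.dob.isoformat() if p.dob else "",
                    "postcode": p.postcode or "",
                    "icd10": c.icd10,
                    "diagnosis_date": c.diagnosis_date.isoformat(),
                })
                n += 1
    return n


def generate_historic_counts(config: GeneratorConfig) -> dict[tuple[str, int], int]:
    """True annual analysis counts for each laboratory's pre-submission
    years (activity the lab performed but could never extract patient-level).

    Poisson around ``historic_annual_tests``, deterministic in the seed
    and independent of the patient stream.
    """
    rng = np.random.default_rng([abs(config.seed), 1])
    out: dict[tuple[str, int], int] = {}
    for lab in config.labs:
        for fy in range(lab.activity_start_year, lab.first_submission_year):
            out[(lab.lab_code, fy)] = int(rng.poisson(config.historic_annual_tests))
    return out


def true_observed_counts(patients: list[SourcePatient]
                         ) -> dict[tuple[str, int], int]:
    """Planted tests per laboratory per financial year (ground truth)."""
    out: dict[tuple[str, int], int] = {}
    for p in patients:
        for t in p.planted_tests:
            key = (t.lab_code, financial_year(t.authorised_date))
            out[key] = out.get(key, 0) + 1
    return out


def write_audit_counts(patients: list[SourcePatient], config: GeneratorConfig,
                       path: str | Path) -> dict[tuple[str, int], int]:
    """Write the laboratory-level annual audit table (fy 1998–2016 only).

    Each count is the laboratory's true analysis total for that financial
    year (historic plus planted) multiplied by the configured inflation
    factor and rounded — emulating audit counts padded by out-of-scope
    activity.
    """
    historic = generate_historic_counts(config)
    planted = true_observed_counts(patients)
    audit: dict[tuple[str, int], int] = {}
    for lab in config.labs:
        for fy in range(max(AUDIT_FIRST_YEAR, lab.activity_start_year),
                        AUDIT_LAST_YEAR + 1):
            true = historic.get((lab.lab_code, fy), 0) + \
                planted.get((lab.lab_code, fy), 0)
            if fy < lab.first_submission_year or true > 0:
                audit[(lab.lab_code, fy)] = int(np.floor(
                    true * lab.audit_inflation + 0.5))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["lab_code", "financial_year",
                                                "audit_count"])
        writer.writeheader()
        for (lab_code, fy), count in sorted(audit.items()):
            writer.writerow({"lab_code": lab_code, "financial_year": fy,
                             "audit_count": count})
    return audit


def write_truth_ledger(patients: list[SourcePatient], config: GeneratorConfig,
                       path: str | Path) -> None:
    """Ground truth for tests only — the pipeline never reads this file."""
    historic = generate_historic_counts(config)
    with open(path, "w") as fh:
        meta = {
            "type": "meta",
            "historic_counts": {f"{lab}|{fy}": n
                                for (lab, fy), n in sorted(historic.items())},
            "config": json.loads(config.model_dump_json()),
        }
        fh.write(json.dumps(meta, sort_keys=True) + "\n")
        for p in patients:
            rec = asdict(p)
            rec["type"] = "patient"
            rec["expected_stratum"] = p.expected_stratum
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
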