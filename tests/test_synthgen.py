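"""Synthetic cohort generator: determinism, conservation, planted rates."""

import filecmp
import json
from pathlib import Path

import pytest
from pydantic import ValidationError
from scipy.stats import binom

from lynchledger.coverage import financial_year
from lynchledger.pseudonym import validate_nhs_number
from lynchledger.synthgen import (
    GeneratorConfig,
    LabConfig,
    generate_historic_counts,
    generate_patients,
    true_observed_counts,
    write_audit_counts,
    write_lab_extracts,
    write_registry,
)


def binomial_ci(n: int, p: float, level: float = 0.99) -> tuple[int, int]:
    """Central binomial interval used as the recovery oracle."""
    alpha = (1 - level) / 2
    return int(binom.ppf(alpha, n, p)), int(binom.ppf(1 - alpha, n, p))


def test_zero_patients_gives_empty_cohort():
    assert generate_patients(GeneratorConfig(seed=0, n_patients=0)) == []


def test_invalid_fraction_is_configuration_error():
    with pytest.raises(ValidationError):
        GeneratorConfig(rate_plp=1.5)
    with pytest.raises(ValidationError):
        GeneratorConfig(labs=[LabConfig(lab_code="L", dialect="structured",
                                        first_submission_year=2000,
                                        audit_inflation=0.5)])


def test_same_seed_byte_identical_outputs(tmp_path, small_config):
    dirs = []
    for name in ("a", "b"):
        d = tmp_path / name
        d.mkdir()
        patients = generate_patients(small_config)
        write_lab_extracts(patients, small_config, d)
        write_registry(patients, d / "registry.csv")
        write_audit_counts(patients, small_config, d / "audit.csv")
        dirs.append(d)
    files = sorted(p.name for p in dirs[0].iterdir())
    assert files
    for name in files:
        assert filecmp.cmp(dirs[0] / name, dirs[1] / name, shallow=False), name


def test_extract_row_conservation(tmp_path, small_cohort, small_config):
    paths = write_lab_extracts(small_cohort, small_config, tmp_path)
    total_rows = 0
    for lab in small_config.labs:
        path = paths[lab.lab_code]
        lines = path.read_text().splitlines()
        total_rows += len(lines) - (1 if path.suffix == ".csv" else 0)
    planted = sum(len(p.planted_tests) for p in small_cohort)
    assert total_rows == planted


def test_planted_test_invariants(small_cohort):
    for p in small_cohort:
        if p.nhs_number is not None:
            assert validate_nhs_number(p.nhs_number) is p.nhs_number_valid
        for t in p.planted_tests:
            if t.scope == "targeted":
                assert len(t.genes) == 1
            if t.true_result in ("P", "LP", "VUS"):
                assert t.variant_cdna or t.cnv_phrase
            assert t.authorised_date <= t.report_date


def test_plp_rate_within_binomial_ci():
    cfg = GeneratorConfig(seed=1, n_patients=1000, rate_targeted=0.0)
    patients = generate_patients(cfg)
    tests = [t for p in patients for t in p.planted_tests]
    plp = sum(t.true_result in ("P", "LP") for t in tests)
    lo, hi = binomial_ci(len(tests), cfg.rate_plp)
    assert lo <= plp <= hi


def test_registry_rows_match_planted_cancers(tmp_path, small_cohort):
    n = write_registry(small_cohort, tmp_path / "reg.csv")
    assert n == sum(len(p.planted_cancers) for p in small_cohort)
    rows = (tmp_path / "reg.csv").read_text().splitlines()
    assert len(rows) - 1 == n


def test_empty_registry(tmp_path):
    assert write_registry([], tmp_path / "reg.csv") == 0


def test_colorectal_share_within_binomial_ci():
    cfg = GeneratorConfig(seed=3, n_patients=2000,
                          registry_cancer_site_mix={"colorectal": 0.6,
                                                    "uterine": 0.15,
                                                    "other": 0.25})
    patients = generate_patients(cfg)
    cancers = [c for p in patients for c in p.planted_cancers]
    colorectal = sum(c.site_group == "colorectal" for c in cancers)
    assert all(c.icd10.startswith(("C18", "C19", "C20"))
               for c in cancers if c.site_group == "colorectal")
    lo, hi = binomial_ci(len(cancers), 0.6)
    assert lo <= colorectal <= hi


def test_audit_counts_are_inflated_true_counts(tmp_path, small_cohort,
                                               small_config):
    audit = write_audit_counts(small_cohort, small_config,
                               tmp_path / "audit.csv")
    historic = generate_historic_counts(small_config)
    planted = true_observed_counts(small_cohort)
    assert audit, "audit table should not be empty"
    for (lab_code, fy), count in audit.items():
        assert 1998 <= fy <= 2016
        lab = small_config.lab(lab_code)
        true = historic.get((lab_code, fy), 0) + planted.get((lab_code, fy), 0)
        assert count == int(true * lab.audit_inflation + 0.5)


def test_identity_inflation_preserves_counts(tmp_path):
    cfg = GeneratorConfig(seed=5, n_patients=300, labs=[
        LabConfig(lab_code="L1", dialect="structured",
                  first_submission_year=2000, audit_inflation=1.0)])
    patients = generate_patients(cfg)
    audit = write_audit_counts(patients, cfg, tmp_path / "audit.csv")
    historic = generate_historic_counts(cfg)
    planted = true_observed_counts(patients)
    for (lab, fy), count in audit.items():
        assert count == historic.get((lab, fy), 0) + planted.get((lab, fy), 0)


def test_freetext_reports_embed_variants_verbatim(tmp_path):
    cfg = GeneratorConfig(seed=9, n_patients=300, labs=[
        LabConfig(lab_code="FT", dialect="freetext",
                  first_submission_year=2000)])
    patients = generate_patients(cfg)
    paths = write_lab_extracts(patients, cfg, tmp_path)
    rows = [json.loads(line)
            for line in Path(paths["FT"]).read_text().splitlines()]
    tests = [t for p in patients for t in p.planted_tests]
    assert len(rows) == len(tests)
    checked_hgvs = checked_cnv = 0
    for row, t in zip(rows, tests):
        if t.variant_cdna:
            assert t.variant_cdna in row["report_text"]
            checked_hgvs += 1
        if t.cnv_phrase:
            assert t.cnv_phrase in row["report_text"]
            assert "c." not in row["report_text"]
            checked_cnv += 1
    assert checked_hgvs > 10 and checked_cnv >= 3


def test_truth_ledger_never_needed_by_pipeline(pipeline_run):
    """The pipeline outputs exist without reading the truth ledger; the
    ledger is present for tests and carries every planted test."""
    _, outdir, manifest = pipeline_run
    from conftest import read_truth
    meta, patients = read_truth(outdir)
    assert meta["historic_counts"]
    assert sum(len(p["planted_tests"]) for p in patients) == \
        manifest["counts"]["planted_tests"]


def test_financial_year_boundaries():
    from datetime import date
    assert financial_year(date(2000, 3, 31)) == 1999
    assert financial_year(date(2000, 4, 1)) == 2000
    assert financial_year(date(2000, 12, 31)) == 2000
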