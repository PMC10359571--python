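"""HGVS extraction/validation, CNV language, dialect mapping, concordance."""

import pytest

from lynchledger.harmonise import (
    BUILTIN_DIALECTS,
    concordance_audit,
    detect_cnv_language,
    extract_hgvs,
    map_extract,
    normalise_classification,
    read_cdm,
    validate_hgvs,
    write_cdm,
)
from lynchledger.synthgen import (GeneratorConfig, LabConfig,
                                  generate_patients, write_lab_extracts)

KEY = "unit-test-key"


@pytest.mark.parametrize("text,expected", [
    ("heterozygous variant c.942+3A>T detected", [("cdna", "c.942+3A>T")]),
    ("deletion of exons 1-6 of MSH2", []),
    ("c.100A>G p.(Thr34Ala)", [("cdna", "c.100A>G"), ("protein", "p.(Thr34Ala)")]),
    ("c.1852_1854del found", [("cdna", "c.1852_1854del")]),
    ("c.942-2dup and c.100_101insACG", [("cdna", "c.942-2dup"),
                                        ("cdna", "c.100_101insACG")]),
    ("c.100_105delinsAT seen", [("cdna", "c.100_105delinsAT")]),
    ("p.Arg117fs and p.(Gln234Ter)", [("protein", "p.Arg117fs"),
                                      ("protein", "p.(Gln234Ter)")]),
    ("no variant here", []),
    ("", []),
])
def test_extract_hgvs(text, expected):
    assert extract_hgvs(text) == expected


def test_extracted_tokens_never_overlap():
    tokens = extract_hgvs("c.100A>G c.200_204del p.(Thr34Ala)")
    assert [t for _, t in tokens] == ["c.100A>G", "c.200_204del", "p.(Thr34Ala)"]


@pytest.mark.parametrize("token,valid", [
    ("c.100A>G", True),
    ("c.942+3A>T", True),
    ("c.100A>", False),        # missing alternate
    ("c.0A>G", False),         # position must be >= 1
    ("c.100A>A", False),       # ref == alt
    ("c.100_99del", False),    # range end before start
    ("c.100_102del", True),
    ("c.100dup", True),
    ("c.100_101insACG", True),
    ("c.100insACG", False),    # ins needs a flanking range
    ("c.100_102ins", False),   # ins needs a sequence
    ("c.100_102delins", False),
    ("c.100_102delinsTT", True),
    ("p.(Thr34Ala)", True),
    ("p.Thr34Ala", True),
    ("p.(Thr34Thr)", False),   # silent change written as a substitution
    ("p.(Thr34=)", True),
    ("p.(Arg117fs)", True),
    ("p.(Arg117fs*12)", True),
    ("p.(Gln234Ter)", True),
    ("g.123A>G", False),       # genomic prefix outside supported subset
    ("deletion of exons 1-6", False),
    ("", False),
])
def test_validate_hgvs(token, valid):
    assert bool(validate_hgvs(token)) is valid


def test_validation_failures_carry_reasons():
    assert "position" in validate_hgvs("c.0A>G").reason


@pytest.mark.parametrize("text,expected", [
    ("deletion of exons 1-6", True),
    ("whole gene duplication", True),
    ("duplication of exons 3-5 detected", True),
    ("exon 7 deletion", True),
    ("copy number loss affecting MSH2", True),
    ("c.100A>G", False),
    ("no abnormality detected", False),
])
def test_detect_cnv_language(text, expected):
    assert detect_cnv_language(text) is expected


@pytest.mark.parametrize("label,expected", [
    ("Pathogenic", "P"),
    ("class 5", "P"),
    ("likely pathogenic", "LP"),
    ("Class 4", "LP"),
    ("class 3", "VUS"),
    ("VUS", "VUS"),
    ("uncertain", "VUS"),
    ("Likely Benign", "LB"),
    ("benign", "B"),
    ("", "unclassified"),
    (None, "unclassified"),
    ("something odd", "unclassified"),
])
def test_normalise_classification(label, expected):
    assert normalise_classification(label) == expected


@pytest.fixture(scope="module", params=["structured", "semistructured", "freetext"])
def mapped_dialect(request, tmp_path_factory):
    dialect = request.param
    cfg = GeneratorConfig(seed=21, n_patients=250, labs=[
        LabConfig(lab_code="LX", dialect=dialect, first_submission_year=2000)])
    patients = generate_patients(cfg)
    outdir = tmp_path_factory.mktemp(f"extract_{dialect}")
    paths = write_lab_extracts(patients, cfg, outdir)
    result = map_extract(paths["LX"], BUILTIN_DIALECTS[dialect], KEY,
                         lab_code="LX")
    return patients, result


def test_mapping_conservation(mapped_dialect):
    patients, result = mapped_dialect
    n_tests = sum(len(p.planted_tests) for p in patients)
    assert result.n_input_rows == n_tests
    assert result.quarantined == []


def test_one_record_per_gene_per_test(mapped_dialect):
    patients, result = mapped_dialect
    expected = sum(len(t.genes) for p in patients for t in p.planted_tests)
    assert len(result.records) == expected


def test_planted_variants_recovered(mapped_dialect):
    """Every planted HGVS variant resurfaces verbatim on the right gene;
    planted CNVs surface as CNV text and never as a cDNA token."""
    from lynchledger.pseudonym import make_pair

    patients, result = mapped_dialect
    by_test = {}
    for r in result.records:
        by_test[(r.pseudo_id1, r.pseudo_id2, r.authorised_date, r.gene)] = r
    n_var = n_cnv = 0
    for p in patients:
        pair = make_pair(p.nhs_number, p.dob, p.postcode, KEY)
        if not pair.linkable:
            continue
        for t in p.planted_tests:
            if t.true_result not in ("P", "LP", "VUS"):
                continue
            rec = by_test[(pair.pseudo_id1, pair.pseudo_id2,
                           t.authorised_date, t.variant_gene)]
            if t.variant_cdna:
                assert rec.variant_cdna == t.variant_cdna
                n_var += 1
            else:
                assert rec.cnv_text and t.cnv_phrase in rec.cnv_text
                assert rec.variant_cdna is None
                n_cnv += 1
    assert n_var > 5 and n_cnv > 1


def test_no_raw_identifiers_in_cdm(mapped_dialect):
    patients, result = mapped_dialect
    nhs_numbers = {p.nhs_number for p in patients if p.nhs_number}
    postcodes = {p.postcode for p in patients if p.postcode}
    for r in result.records:
        dump = r.model_dump_json()
        for ident in nhs_numbers | postcodes:
            assert ident not in dump


def test_structured_multigene_negative_row(tmp_path):
    path = tmp_path / "lab.csv"
    path.write_text(
        "nhs_number,dob,postcode,authorised_date,report_date,test_type,genes,"
        "variant_gene,variant_cdna,variant_protein,cnv_description,"
        "overall_result,classification\n"
        "9434765919,1960-01-02,SW1A 1AA,2012-05-01,2012-06-01,diagnostic,"
        "MLH1|MSH2|MSH6|PMS2,,,,,normal,\n")
    result = map_extract(path, BUILTIN_DIALECTS["structured"], KEY, "LX")
    assert len(result.records) == 4
    assert all(r.result_label == "negative" for r in result.records)
    assert {r.gene for r in result.records} == {"MLH1", "MSH2", "MSH6", "PMS2"}


@pytest.mark.parametrize("row,reason_part", [
    ("9434765919,1960-01-02,SW1A 1AA,not-a-date,,diagnostic,MLH1,,,,,normal,",
     "date"),
    ("9434765919,1960-01-02,SW1A 1AA,2012-05-01,,diagnostic,BRCA1,,,,,normal,",
     "unknown gene"),
    ("9434765919,1960-01-02,SW1A 1AA,2012-05-01,,diagnostic,MLH1,,,,,oddity,",
     "result label"),
])
def test_bad_rows_quarantined_not_dropped(tmp_path, row, reason_part):
    path = tmp_path / "lab.csv"
    header = ("nhs_number,dob,postcode,authorised_date,report_date,test_type,"
              "genes,variant_gene,variant_cdna,variant_protein,"
              "cnv_description,overall_result,classification\n")
    good = ("9434765919,1960-01-02,SW1A 1AA,2012-05-01,,diagnostic,MLH1,"
            ",,,,normal,\n")
    path.write_text(header + good + row + "\n")
    result = map_extract(path, BUILTIN_DIALECTS["structured"], KEY, "LX")
    assert result.n_input_rows == 2
    assert len(result.records) == 1
    assert len(result.quarantined) == 1
    assert reason_part in result.quarantined[0].reason.lower()
    # quarantined raw rows must not retain identifiers
    assert "9434765919" not in str(result.quarantined[0].raw)


def test_cdm_round_trip(tmp_path, mapped_dialect):
    _, result = mapped_dialect
    write_cdm(result.records, tmp_path / "cdm.csv", tmp_path / "cdm.jsonl")
    back = read_cdm(tmp_path / "cdm.csv")
    assert back == result.records


def test_dialect_spec_yaml_round_trip(tmp_path):
    spec = BUILTIN_DIALECTS["semistructured"]
    spec.to_yaml(tmp_path / "spec.yaml")
    from lynchledger.harmonise import DialectSpec
    assert DialectSpec.from_yaml(tmp_path / "spec.yaml") == spec


class TestConcordanceAudit:
    def test_exact_match_passes(self):
        rep = concordance_audit({"MLH1": 100}, {"MLH1": 100})
        assert rep.passed and rep.ratios["MLH1"] == 1.0

    def test_below_threshold_fails(self):
        assert not concordance_audit({"MLH1": 94}, {"MLH1": 100}).passed

    def test_boundary_passes(self):
        assert concordance_audit({"MLH1": 96}, {"MLH1": 100}).passed
        assert concordance_audit({"MLH1": 95}, {"MLH1": 100}).passed

    def test_zero_denominator_skipped(self):
        rep = concordance_audit({"MLH1": 0, "MSH2": 50}, {"MLH1": 0, "MSH2": 50})
        assert rep.passed and rep.skipped == ["MLH1"]

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            concordance_audit({"MLH1": 1}, {"MSH2": 1})
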