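"""Schema validation, consistency checks, units survey."""

import json

import pytest

from mwtabkit import (
    CorruptionClass,
    FixtureSpec,
    SchemaLoadError,
    check_consistency,
    default_schemas,
    generate_document,
    generate_mwtab_text,
    inject_corruption,
    load_schemas,
    parse_mwtab,
    survey_units,
    validate_document,
    validate_section,
    write_mwtab,
)

PROJECT_REQUIRED = {
    "PROJECT_TITLE", "PROJECT_SUMMARY", "INSTITUTE", "LAST_NAME",
    "FIRST_NAME", "ADDRESS", "EMAIL", "PHONE",
}
PROJECT_OPTIONAL = {
    "PROJECT_TYPE", "DEPARTMENT", "LABORATORY", "FUNDING_SOURCE",
    "PROJECT_COMMENTS", "PUBLICATIONS", "CONTRIBUTIONS", "DOI",
}


def test_project_schema_required_and_optional_sets():
    schema = default_schemas()["PROJECT"]
    assert set(schema.required_keys) == PROJECT_REQUIRED
    assert len(schema.required_keys) == 8
    assert set(schema.optional_keys) == PROJECT_OPTIONAL
    assert "DOI" in schema.optional_keys
    assert "EMAIL" in schema.value_rules and "PHONE" in schema.value_rules


def test_missing_project_title_yields_one_descriptive_error(ms_doc):
    doc, _ = ms_doc
    del doc.sections["PROJECT"].items["PROJECT_TITLE"]
    issues = validate_section(doc.sections["PROJECT"], default_schemas()["PROJECT"])
    assert len(issues) == 1
    (issue,) = issues
    assert issue.severity == "error"
    assert issue.code == "MISSING_REQUIRED_FIELD"
    assert issue.key == "PROJECT_TITLE"
    assert "PROJECT_TITLE" in issue.message and "required" in issue.message


def test_complete_project_section_validates_clean(ms_doc):
    doc, _ = ms_doc
    issues = validate_section(doc.sections["PROJECT"], default_schemas()["PROJECT"])
    assert issues == []


def test_email_without_at_sign_is_constraint_violation(ms_doc):
    doc, _ = ms_doc
    doc.sections["PROJECT"].items["EMAIL"] = "not-an-email"
    issues = validate_section(doc.sections["PROJECT"], default_schemas()["PROJECT"])
    assert [i.code for i in issues] == ["CONSTRAINT_VIOLATION"]
    assert issues[0].key == "EMAIL"


def test_unknown_key_is_warning_not_error(ms_doc):
    doc, _ = ms_doc
    doc.sections["PROJECT"].items["MYSTERY_FIELD"] = "x"
    issues = validate_section(doc.sections["PROJECT"], default_schemas()["PROJECT"])
    assert [(i.code, i.severity) for i in issues] == [("UNKNOWN_KEY", "warning")]


def test_user_schema_override_moves_doi_to_required(tmp_path, ms_doc):
    schemas = json.loads((
        __import__("importlib").resources.files("mwtabkit")
        / "schemas" / "mwtab_schema.json").read_text())
    schemas["PROJECT"]["optional"].remove("DOI")
    schemas["PROJECT"]["required"].append("DOI")
    path = tmp_path / "custom.json"
    path.write_text(json.dumps(schemas))
    doc, _ = ms_doc
    issues = validate_document(doc, load_schemas(str(path)))
    assert [i.key for i in issues if i.code == "MISSING_REQUIRED_FIELD"] == ["DOI"]


def test_malformed_user_schema_raises_with_location(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text("{not json")
    with pytest.raises(SchemaLoadError, match="line 1"):
        load_schemas(str(path))
    path2 = tmp_path / "overlap.json"
    path2.write_text(json.dumps(
        {"PROJECT": {"required": ["DOI"], "optional": ["DOI"]}}))
    with pytest.raises(SchemaLoadError, match="DOI"):
        load_schemas(str(path2))


def test_pristine_document_validates_with_zero_findings(ms_text):
    text, _ = ms_text
    assert validate_document(parse_mwtab(text)) == []


def test_missing_end_reported_exactly_once(ms_text):
    text, _ = ms_text
    bad, _ = inject_corruption(text, CorruptionClass.MISSING_END)
    issues = validate_document(parse_mwtab(bad))
    assert [i.code for i in issues] == ["MISSING_END"]
    assert "#END" in issues[0].message


def test_empty_units_reported_for_blanked_ms_table(ms_text):
    text, _ = ms_text
    bad, _ = inject_corruption(text, CorruptionClass.EMPTY_UNITS)
    issues = validate_document(parse_mwtab(bad))
    assert [i.code for i in issues] == ["EMPTY_UNITS"]


def test_validation_is_deterministic(ms_text):
    text, _ = ms_text
    bad, _ = inject_corruption(text, CorruptionClass.DROP_REQUIRED_KEY, seed=4)
    doc = parse_mwtab(bad)
    assert validate_document(doc) == validate_document(doc)


def test_adding_valid_required_key_never_adds_errors(ms_doc):
    doc, _ = ms_doc
    del doc.sections["STUDY"].items["STUDY_TITLE"]
    n_before = sum(1 for i in validate_document(doc) if i.severity == "error")
    doc.sections["STUDY"].items["STUDY_TITLE"] = "restored title"
    n_after = sum(1 for i in validate_document(doc) if i.severity == "error")
    assert n_after <= n_before


# -- consistency ---------------------------------------------------------


def test_matching_ssf_and_columns_no_mismatch(ms_doc):
    doc, _ = ms_doc
    assert [i for i in check_consistency(doc) if i.code == "COLUMN_MISMATCH"] == []


def test_deleted_ssf_record_triggers_column_mismatch(ms_doc):
    doc, _ = ms_doc
    doc.sections["SUBJECT_SAMPLE_FACTORS"].ssf_records.pop()
    issues = [i for i in check_consistency(doc) if i.code == "COLUMN_MISMATCH"]
    assert len(issues) == 1
    assert "6" in issues[0].message and "5" in issues[0].message
    assert issues[0].severity == "warning"


def test_document_without_table_has_no_consistency_findings():
    from mwtabkit import MwTabDocument, Section
    doc = MwTabDocument()
    doc.add_section(Section(name="PROJECT", prefix="PR"))
    assert check_consistency(doc) == []


def test_id_mismatch_between_header_and_source_name(ms_doc):
    doc, _ = ms_doc
    doc.source_id = "AN999999.txt"
    codes = [i.code for i in check_consistency(doc)]
    assert codes == ["ID_MISMATCH"]


def test_row_arity_rereported_by_consistency(ms_text):
    text, _ = ms_text
    bad, _ = inject_corruption(text, CorruptionClass.ROW_ARITY, seed=2)
    doc = parse_mwtab(bad)
    codes = [i.code for i in check_consistency(doc)]
    assert codes == ["ROW_ARITY"]


# -- units survey --------------------------------------------------------


def _docs_with_units(units_list):
    docs = []
    for i, units in enumerate(units_list):
        doc, _ = generate_document(
            FixtureSpec(seed=i, n_samples=2, n_metabolites=2,
                        units=units if units is not None else ""))
        if units is None:
            doc.data_table.units = ""
        docs.append(doc)
    return docs


def test_units_survey_counts_missing():
    docs = _docs_with_units(["peak area"] * 7 + [None] * 3)
    survey = survey_units(docs)
    assert survey.missing_count == 3
    assert survey.tally == {"peak area": 7}
    assert survey.total == 10


def test_units_survey_case_folding_merges_variants():
    docs = _docs_with_units(["Peak height", "Peak height", "peak height"])
    verbatim = survey_units(docs, "verbatim")
    assert verbatim.tally == {"Peak height": 2, "peak height": 1}
    folded = survey_units(docs, "case-folded")
    assert folded.tally == {"peak height": 3}


def test_units_survey_empty_input():
    survey = survey_units([])
    assert survey.tally == {} and survey.missing_count == 0


def test_units_survey_rejects_unknown_normalization():
    with pytest.raises(ValueError):
        survey_units([], "upper")


def test_issue_str_and_dict_forms(ms_text):
    text, _ = ms_text
    bad, _ = inject_corruption(text, CorruptionClass.EMPTY_UNITS)
    (issue,) = validate_document(parse_mwtab(bad))
    rendered = str(issue)
    assert "EMPTY_UNITS" in rendered and "ERROR" in rendered
    assert issue.as_dict()["code"] == "EMPTY_UNITS"


def test_issue_constructor_guards():
    from mwtabkit import ValidationIssue
    with pytest.raises(ValueError):
        ValidationIssue(severity="fatal", code="MISSING_END", section="",
                        message="x")
    with pytest.raises(ValueError):
        ValidationIssue(severity="error", code="NOT_A_CODE", section="",
                        message="x")
    with pytest.raises(ValueError):
        ValidationIssue(severity="error", code="MISSING_END", section="",
                        message="")


def test_unknown_section_warned(ms_doc):
    from mwtabkit import Section
    doc, _ = ms_doc
    doc.add_section(Section(name="CUSTOM_BLOCK"))
    codes = [i.code for i in validate_document(doc)]
    assert codes == ["UNKNOWN_SECTION"]


def test_schema_rule_shape_guards(tmp_path):
    path = tmp_path / "odd.json"
    path.write_text(json.dumps(
        {"PROJECT": {"required": [], "optional": ["X"],
                     "value_rules": {"X": {"frobnicate": 1}}}}))
    with pytest.raises(SchemaLoadError, match="pattern.*enum|enum.*pattern"):
        load_schemas(str(path))
    path.write_text(json.dumps({"PROJECT": {"value_rules": {"X": {"pattern": "["}}}}))
    with pytest.raises(SchemaLoadError, match="pattern"):
        load_schemas(str(path))
    path.write_text(json.dumps([1]))
    with pytest.raises(SchemaLoadError, match="top level"):
        load_schemas(str(path))
    path.write_text(json.dumps({"PROJECT": 5}))
    with pytest.raises(SchemaLoadError, match="PROJECT"):
        load_schemas(str(path))
    with pytest.raises(SchemaLoadError, match="cannot read"):
        load_schemas(str(tmp_path / "ghost.json"))


def test_enum_rule_violation():
    from mwtabkit import FixtureSpec, generate_document
    doc, _ = generate_document(FixtureSpec(seed=8))
    doc.sections["ANALYSIS"].items["ANALYSIS_TYPE"] = "SPECTROSCOPY"
    issues = [i for i in validate_document(doc) if i.code == "CONSTRAINT_VIOLATION"]
    assert len(issues) == 1 and issues[0].key == "ANALYSIS_TYPE"
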