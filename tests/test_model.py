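"""Document-model access, mutation and invariants."""

import pytest

from mwtabkit import (
    DataTable,
    MwTabDocument,
    Section,
    UnknownKeyError,
    UnknownSectionError,
    get_value,
    list_sample_columns,
    parse_mwtab,
    set_value,
    write_mwtab,
)

HEADER = "#METABOLOMICS WORKBENCH STUDY_ID:ST000001 ANALYSIS_ID:AN000001"


def test_header_fields_exposed_as_pseudo_section():
    text = f"{HEADER}\nVERSION\t1\nCREATED_ON\t2017-08-30\n#PROJECT\nPR:PROJECT_TITLE\tT\n#END\n"
    doc = parse_mwtab(text)
    assert get_value(doc, "METABOLOMICS WORKBENCH", "VERSION") == "1"
    assert doc["METABOLOMICS WORKBENCH"]["STUDY_ID"] == "ST000001"
    assert doc.header.analysis_id == "AN000001"


def test_unknown_section_and_key_errors_name_the_target(ms_doc):
    doc, _ = ms_doc
    with pytest.raises(UnknownSectionError, match="NO_SUCH_SECTION"):
        get_value(doc, "NO_SUCH_SECTION", "X")
    with pytest.raises(UnknownKeyError, match="NO_SUCH_KEY"):
        get_value(doc, "PROJECT", "NO_SUCH_KEY")


def test_continuation_lines_merge_into_single_value():
    frags = ["alpha beta gamma", "delta epsilon", "zeta"]
    lines = [HEADER, "VERSION\t1", "CREATED_ON\t2017-01-01", "#PROJECT"]
    lines += [f"PR:PROJECT_SUMMARY\t{f}" for f in frags]
    lines.append("#END")
    doc = parse_mwtab("\n".join(lines) + "\n")
    merged = get_value(doc, "PROJECT", "PROJECT_SUMMARY")
    # independent oracle: total fragment length plus one separator per join
    assert len(merged) == sum(len(f) for f in frags) + (len(frags) - 1)
    assert merged == " ".join(frags)


def test_set_value_round_trips_and_preserves_order(ms_doc):
    doc, _ = ms_doc
    set_value(doc, "PROJECT", "PROJECT_SUMMARY", "new project summary")
    assert get_value(doc, "PROJECT", "PROJECT_SUMMARY") == "new project summary"
    # setting the identical value is serialization-idempotent
    before = write_mwtab(doc)
    set_value(doc, "PROJECT", "PROJECT_SUMMARY", "new project summary")
    assert write_mwtab(doc) == before


def test_set_value_unknown_section_raises(ms_doc):
    doc, _ = ms_doc
    with pytest.raises(UnknownSectionError):
        set_value(doc, "NOPE", "KEY", "v")


def test_new_key_appends_at_section_tail_after_reparse(ms_doc):
    doc, _ = ms_doc
    set_value(doc, "PROJECT", "DOI", "10.1/xyz")
    reparsed = parse_mwtab(write_mwtab(doc))
    keys = list(reparsed["PROJECT"].keys())
    assert keys.count("DOI") == 1 and keys[-1] == "DOI"


def test_list_sample_columns_matches_generator(ms_doc):
    doc, truth = ms_doc
    assert list_sample_columns(doc) == truth.sample_names


def test_list_sample_columns_empty_without_table():
    doc = MwTabDocument()
    doc.add_section(Section(name="PROJECT", prefix="PR"))
    assert list_sample_columns(doc) == []


def test_data_table_row_arity_enforced_at_construction():
    with pytest.raises(ValueError, match="expected 2"):
        DataTable(kind="MS_METABOLITE_DATA", units="peak area",
                  column_names=["S1", "S2"], rows=[("alanine", ["1"])])


def test_section_cannot_mix_ssf_records_and_table():
    from mwtabkit import SubjectSampleFactorRecord
    with pytest.raises(ValueError):
        Section(name="PROJECT",
                ssf_records=[SubjectSampleFactorRecord(local_sample_id="S1")])


def test_order_preservation_of_parsed_triples(ms_text):
    text, truth = ms_text
    doc = parse_mwtab(text)
    parsed = [
        (name, key)
        for name, sec in doc.sections.items()
        for key in sec.items
    ]
    expected = [(s, k) for s, k, _ in truth.items]
    assert parsed == expected


def test_verbatim_value_storage(ms_text):
    text, truth = ms_text
    doc = parse_mwtab(text)
    for section, key, value in truth.items:
        assert get_value(doc, section, key) == value


def test_header_pseudo_section_mutation_and_membership(ms_doc):
    doc, _ = ms_doc
    view = doc["METABOLOMICS WORKBENCH"]
    view["VERSION"] = "2"
    assert doc.header.version == "2"
    assert "VERSION" in view and "NOPE" not in view
    assert view.keys() == ["VERSION", "CREATED_ON", "STUDY_ID", "ANALYSIS_ID"]
    with pytest.raises(UnknownKeyError):
        view["NOT_A_HEADER_FIELD"]
    with pytest.raises(UnknownKeyError, match="cannot hold"):
        set_value(doc, "METABOLOMICS WORKBENCH", "NOT_A_HEADER_FIELD", "x")


def test_document_iteration_and_membership(ms_doc):
    doc, truth = ms_doc
    assert "PROJECT" in doc and "METABOLOMICS WORKBENCH" in doc
    assert "NOPE" not in doc
    assert len(list(doc)) == truth.n_sections


def test_units_readable_through_data_section(ms_doc):
    doc, truth = ms_doc
    assert get_value(doc, "MS_METABOLITE_DATA", "UNITS") == truth.units
    with pytest.raises(UnknownKeyError):
        get_value(doc, "MS_METABOLITE_DATA", "NOPE")


def test_model_equality_ignores_provenance_but_not_content(ms_spec):
    from mwtabkit import generate_document
    d1, _ = generate_document(ms_spec)
    d2, _ = generate_document(ms_spec)
    d2.source_id = "elsewhere.txt"
    assert d1 == d2
    d2.sections["PROJECT"].items["PROJECT_TITLE"] = "changed"
    assert d1 != d2
    assert d1 != "not a document"


def test_data_table_factor_row_arity_enforced():
    with pytest.raises(ValueError, match="factor row"):
        DataTable(kind="MS_METABOLITE_DATA", column_names=["S1", "S2"],
                  factor_row=["only one"])
    with pytest.raises(ValueError, match="kind"):
        DataTable(kind="BOGUS")


def test_invalid_section_names_rejected():
    with pytest.raises(ValueError):
        Section(name="")
    with pytest.raises(ValueError):
        Section(name="lowercase")
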