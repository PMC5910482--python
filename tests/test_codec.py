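"""Syntactic building and both serializations."""

import json

import pytest

from mwtabkit import (
    LayoutPolicy,
    MappingError,
    ParseError,
    build_document,
    get_value,
    parse_json,
    parse_mwtab,
    tokenize,
    write_json,
    write_mwtab,
)

HEADER = "#METABOLOMICS WORKBENCH STUDY_ID:ST000001 ANALYSIS_ID:AN000001"


def test_repeated_keys_merge_in_order():
    text = (f"{HEADER}\n#PROJECT\nPR:PROJECT_SUMMARY\tpart A\n"
            "PR:PROJECT_SUMMARY\tpart B\n#END\n")
    doc = parse_mwtab(text)
    assert get_value(doc, "PROJECT", "PROJECT_SUMMARY") == "part A part B"


def test_header_and_end_only_gives_zero_sections():
    doc = build_document(tokenize("#METABOLOMICS WORKBENCH\n#END\n"))
    assert doc.sections == {}
    assert doc.end_marker_seen


def test_fixture_section_count_matches_ground_truth(ms_text):
    text, truth = ms_text
    doc = parse_mwtab(text)
    assert len(doc.sections) == truth.n_sections


def test_empty_text_is_fatal():
    with pytest.raises(ParseError, match="METABOLOMICS WORKBENCH") as err:
        parse_mwtab("")
    assert err.value.code == "NO_FILE_HEADER"


def test_leading_blank_lines_same_document_plus_finding(ms_text):
    text, _ = ms_text
    clean = parse_mwtab(text)
    dirty = parse_mwtab("\n\n" + text)
    assert dirty == clean
    assert [f.code for f in dirty.parse_findings] == ["LEADING_CONTENT"]


def test_orphan_item_recovered_into_unattributed_section():
    doc = parse_mwtab("#METABOLOMICS WORKBENCH\nSTRAY_KEY\tv\n#END\n")
    # item after the header block but with no section: header keys go to the
    # header; anything else is unattributed
    assert "STRAY_KEY" not in doc.header.as_items()


def test_item_before_any_header_is_orphan():
    doc = parse_mwtab("ORPHAN\tx\n#METABOLOMICS WORKBENCH\n#END\n")
    codes = {f.code for f in doc.parse_findings}
    assert "ORPHAN_ITEM" in codes and "LEADING_CONTENT" in codes
    assert doc.sections["UNATTRIBUTED"].items["ORPHAN"] == "x"


def test_table_without_end_closed_at_section_boundary():
    text = (f"{HEADER}\n#MS_METABOLITE_DATA\nMS_METABOLITE_DATA:UNITS\tpeak area\n"
            "MS_METABOLITE_DATA_START\nSamples\tS1\nalanine\t1.0\n"
            "#END\n")
    doc = parse_mwtab(text)
    assert "TABLE_WITHOUT_END" in {f.code for f in doc.parse_findings}
    table = doc.data_table
    assert table is not None and table.rows == [("alanine", ["1.0"])]


def test_units_attached_from_adjacent_item():
    text = (f"{HEADER}\n#NMR_BINNED_DATA\nNMR_BINNED_DATA:UNITS\tIntensity\n"
            "NMR_BINNED_DATA_START\nBin range(ppm)\tS1\n0.50-0.54\t7.1\n"
            "NMR_BINNED_DATA_END\n#END\n")
    doc = parse_mwtab(text)
    assert doc.data_table.units == "Intensity"
    assert doc.data_table.kind == "NMR_BINNED_DATA"


def test_parse_write_parse_is_fixed_point(ms_text):
    text, _ = ms_text
    doc = parse_mwtab(text)
    out = write_mwtab(doc)
    assert parse_mwtab(out) == doc
    assert write_mwtab(parse_mwtab(out)) == out


def test_empty_units_survives_write(ms_text):
    text, _ = ms_text
    doc = parse_mwtab(text)
    doc.data_table.units = ""
    out = write_mwtab(doc)
    assert "MS_METABOLITE_DATA:UNITS" in out
    assert parse_mwtab(out).data_table.units == ""


def test_section_header_line_count(ms_doc):
    doc, truth = ms_doc
    out = write_mwtab(doc)
    hash_lines = [l for l in out.splitlines() if l.startswith("#")]
    # one per section plus the file header and #END
    assert len(hash_lines) == truth.n_sections + 2


def test_long_values_rewrap_into_continuation_lines():
    layout = LayoutPolicy(wrap_width=40)
    value = "word " * 30
    text = (f"{HEADER}\n#PROJECT\nPR:PROJECT_SUMMARY\t{value.strip()}\n#END\n")
    doc = parse_mwtab(text)
    out = write_mwtab(doc, layout)
    assert out.count("PR:PROJECT_SUMMARY") > 1
    assert parse_mwtab(out) == doc


def test_unwrappable_value_stays_on_one_line():
    layout = LayoutPolicy(wrap_width=10)
    text = (f"{HEADER}\n#PROJECT\nPR:ADDRESS\tvalue  with  double  spaces\n#END\n")
    doc = parse_mwtab(text)
    out = write_mwtab(doc, layout)
    assert out.count("PR:ADDRESS") == 1
    assert parse_mwtab(out) == doc


def test_json_round_trip_identity(ms_doc):
    doc, _ = ms_doc
    assert parse_json(write_json(doc)) == doc


def test_json_is_strict_json_with_expected_shapes(ms_doc):
    doc, truth = ms_doc
    payload = json.loads(write_json(doc))  # strict-mode parse
    assert list(payload)[0] == "METABOLOMICS WORKBENCH"
    ssf = payload["SUBJECT_SAMPLE_FACTORS"]
    assert isinstance(ssf, list) and len(ssf) == len(truth.ssf_records)
    data = payload["MS_METABOLITE_DATA"]
    assert data["Units"] == truth.units
    assert data["Samples"] == truth.sample_names
    assert len(data["Data"]) == len(truth.table_rows)
    # all scalars are strings — never JSON numbers
    row = data["Data"][0]
    assert all(isinstance(v, str) for v in row.values())


def test_json_information_parity(ms_doc):
    doc, truth = ms_doc
    back = parse_json(write_json(doc))
    triples = {
        (name, key, sec.items[key])
        for name, sec in back.sections.items() for key in sec.items
    }
    assert triples == {(s, k, v) for s, k, v in truth.items}
    assert back.data_table.rows == truth.table_rows


def test_json_with_ssf_object_not_array_is_mapping_error():
    bad = json.dumps({"METABOLOMICS WORKBENCH": {"VERSION": "1"},
                      "SUBJECT_SAMPLE_FACTORS": {"Sample ID": "S1"}})
    with pytest.raises(MappingError, match="SUBJECT_SAMPLE_FACTORS"):
        parse_json(bad)


def test_json_non_object_top_level_is_mapping_error():
    with pytest.raises(MappingError):
        parse_json("[1, 2]")


def test_json_numeric_scalar_is_mapping_error():
    bad = json.dumps({"PROJECT": {"PROJECT_TITLE": 42}})
    with pytest.raises(MappingError, match="PROJECT_TITLE"):
        parse_json(bad)


def test_json_syntax_error_carries_position():
    with pytest.raises(json.JSONDecodeError):
        parse_json("{not json")


def test_mwtab_json_mwtab_composition(ms_text):
    text, _ = ms_text
    doc = parse_mwtab(text)
    again = parse_json(write_json(doc))
    assert write_mwtab(again) == write_mwtab(doc) == text
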