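"""Schema-checked metadata readers/writers and their determinism."""
import json

import numpy as np
import pytest

from megbids import read_json_sidecar, read_tsv_table, write_json_sidecar, write_tsv_table
from megbids.errors import ContractError

MINIMAL_MEG = {
    "TaskName": "rest",
    "SamplingFrequency": 2400.0,
    "PowerLineFrequency": 60,
    "DewarPosition": "upright",
    "SoftwareFilters": "n/a",
    "DigitizedLandmarks": True,
    "DigitizedHeadPoints": True,
}


class TestJsonSidecar:
    def test_minimal_conformant_meg_sidecar(self, tmp_path):
        p = tmp_path / "x_meg.json"
        p.write_text(json.dumps(MINIMAL_MEG))
        doc, violations = read_json_sidecar(p, "meg")
        assert doc == MINIMAL_MEG
        assert violations == []

    def test_wrong_type_is_one_violation(self, tmp_path):
        bad = {**MINIMAL_MEG, "SamplingFrequency": "fast"}
        p = tmp_path / "x_meg.json"
        p.write_text(json.dumps(bad))
        _doc, violations = read_json_sidecar(p, "meg")
        assert len(violations) == 1
        assert violations[0].code == "TYPE" and violations[0].location == "SamplingFrequency"

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_k_deleted_keys_give_k_missing_violations(self, tmp_path, k):
        rng = np.random.default_rng(k)
        doc = dict(MINIMAL_MEG)
        dropped = rng.choice(sorted(MINIMAL_MEG), size=k, replace=False)
        for key in dropped:
            del doc[key]
        p = tmp_path / "x_meg.json"
        p.write_text(json.dumps(doc))
        _doc, violations = read_json_sidecar(p, "meg")
        missing = [v for v in violations if v.code == "MISSING-KEY"]
        assert sorted(v.location for v in missing) == sorted(dropped)

    def test_malformed_json_is_single_fatal_violation(self, tmp_path):
        p = tmp_path / "x_meg.json"
        p.write_text('{"TaskName": ')
        doc, violations = read_json_sidecar(p, "meg")
        assert doc is None
        assert [v.code for v in violations] == ["JSON-PARSE"]

    def test_stringified_boolean_rejected(self, tmp_path):
        p = tmp_path / "x_meg.json"
        p.write_text(json.dumps({**MINIMAL_MEG, "DigitizedLandmarks": "true"}))
        _doc, violations = read_json_sidecar(p, "meg")
        assert [v.location for v in violations] == ["DigitizedLandmarks"]

    def test_unknown_keys_preserved_and_reported_as_info(self, tmp_path):
        p = tmp_path / "x_meg.json"
        p.write_text(json.dumps({**MINIMAL_MEG, "Mystery": 1}))
        doc, violations = read_json_sidecar(p, "meg")
        assert doc["Mystery"] == 1
        assert [(v.code, v.severity) for v in violations] == [("UNKNOWN-KEY", "info")]


class TestTsvTable:
    def test_minimal_channels_table(self, tmp_path):
        p = tmp_path / "x_channels.tsv"
        p.write_text("name\ttype\tunits\nMLC11\tMEGGRADAXIAL\tT\n")
        df, violations = read_tsv_table(p, "channels")
        assert len(df) == 1 and violations == []

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "x_events.tsv"
        p.write_text("onset\n1.0\n")
        _df, violations = read_tsv_table(p, "events")
        assert any(v.code == "MISSING-COLUMN" and v.location == "duration" for v in violations)

    def test_na_sentinel_decodes_to_missing(self, tmp_path):
        p = tmp_path / "x_events.tsv"
        p.write_text("onset\tduration\n1.5\tn/a\n")
        df, violations = read_tsv_table(p, "events")
        assert violations == []
        assert df["duration"][0] is None

    def test_ragged_row_reported(self, tmp_path):
        p = tmp_path / "x_channels.tsv"
        p.write_text("name\ttype\tunits\nMLC11\tMEGGRADAXIAL\tT\textra\n")
        _df, violations = read_tsv_table(p, "channels")
        assert any(v.code == "RAGGED-ROW" for v in violations)

    def test_duplicate_identifier_reported(self, tmp_path):
        p = tmp_path / "x_channels.tsv"
        p.write_text("name\ttype\tunits\nA\tEOG\tV\nA\tECG\tV\n")
        _df, violations = read_tsv_table(p, "channels")
        assert any(v.code == "DUPLICATE-VALUE" for v in violations)


class TestWriteDeterminism:
    def test_json_write_twice_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        write_json_sidecar(MINIMAL_MEG, a, "meg")
        write_json_sidecar(MINIMAL_MEG, b, "meg")
        assert a.read_bytes() == b.read_bytes()

    def test_json_write_read_round_trip(self, tmp_path):
        p = tmp_path / "a.json"
        write_json_sidecar(MINIMAL_MEG, p, "meg")
        doc, violations = read_json_sidecar(p, "meg")
        assert doc == MINIMAL_MEG and violations == []

    def test_refuses_missing_required_key(self, tmp_path):
        doc = {k: v for k, v in MINIMAL_MEG.items() if k != "DewarPosition"}
        with pytest.raises(ContractError, match="DewarPosition"):
            write_json_sidecar(doc, tmp_path / "a.json", "meg")

    def test_tsv_read_write_fixed_point(self, tmp_path):
        p = tmp_path / "x_events.tsv"
        canonical = "onset\tduration\ttrial_type\n1.000\t0.050\tstandard\n2.000\tn/a\tn/a\n"
        p.write_text(canonical)
        df, _ = read_tsv_table(p, "events")
        out = tmp_path / "y_events.tsv"
        write_tsv_table(df, out, "events")
        assert out.read_text() == canonical

    def test_every_fixture_metadata_file_is_a_fixed_point(self, valid_tree):
        schema = {
            "meg": "meg", "coordsystem": "coordsystem", "T1w": "T1w",
            "dataset_description": "dataset_description", "channels": "channels",
            "events": "events", "scans": "scans", "participants": "participants",
        }
        checked = 0
        for a in valid_tree.artifacts:
            ext = a.entity_set.extension
            p = valid_tree.path(a)
            if ext == "json":
                before = p.read_bytes()
                doc, _ = read_json_sidecar(p, schema[a.entity_set.suffix], check_required=False)
                write_json_sidecar(doc, p, schema[a.entity_set.suffix], check_required=False)
                assert p.read_bytes() == before, a.relative_path
                checked += 1
            elif ext == "tsv":
                before = p.read_bytes()
                df, _ = read_tsv_table(p, schema[a.entity_set.suffix])
                write_tsv_table(df, p, schema[a.entity_set.suffix])
                assert p.read_bytes() == before, a.relative_path
                checked += 1
        assert checked > 10
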