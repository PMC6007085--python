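"""Curation: manifest handling, tree assembly, plugin extraction, atomicity."""
import numpy as np
import pytest
import yaml

from megbids import (
    CurationManifest,
    Recording,
    curate,
    extract_metadata,
    load_manifest,
    scan_tree,
)
from megbids.errors import CurationError
from megbids.synthraw import write_synthetic_raw

MEG_META = {
    "SamplingFrequency": 1200.0,
    "PowerLineFrequency": 50,
    "DewarPosition": "upright",
    "SoftwareFilters": "n/a",
    "DigitizedLandmarks": False,
    "DigitizedHeadPoints": False,
}


def _one_recording_manifest(tmp_path, **over):
    raw = tmp_path / "acq" / "raw1.fif"
    raw.parent.mkdir(exist_ok=True)
    raw.write_bytes(b"\0" * 32)
    rec = Recording(
        subject="01", task="rest", run=1, raw_path=str(raw),
        meg=dict(MEG_META), channels=[{"name": "MLC11", "type": "MEGGRADAXIAL", "units": "T"}],
        acq_time="2018-06-19T09:00:00",
    )
    for k, v in over.items():
        setattr(rec, k, v)
    return CurationManifest(name="tiny", recordings=[rec])


def test_single_recording_curates_and_self_validates(tmp_path):
    tree, report = curate(_one_recording_manifest(tmp_path), tmp_path / "out")
    paths = sorted(a.relative_path for a in tree.artifacts)
    assert paths == [
        "dataset_description.json",
        "participants.tsv",
        "sub-01/meg/sub-01_task-rest_run-01_channels.tsv",
        "sub-01/meg/sub-01_task-rest_run-01_meg.fif",
        "sub-01/meg/sub-01_task-rest_run-01_meg.json",
        "sub-01/sub-01_scans.tsv",
    ]
    assert report.count("ERROR") == 0


def test_duplicate_recording_key_refused(tmp_path):
    m = _one_recording_manifest(tmp_path)
    m.recordings.append(
        Recording(subject="01", task="rest", run=1,
                  raw_path=m.recordings[0].raw_path, meg=dict(MEG_META))
    )
    with pytest.raises(CurationError, match="duplicate"):
        curate(m, tmp_path / "out")


def test_missing_required_metadata_names_recording_and_key(tmp_path):
    meta = {k: v for k, v in MEG_META.items() if k != "DewarPosition"}
    m = _one_recording_manifest(tmp_path, meg=meta)
    with pytest.raises(CurationError, match="DewarPosition"):
        curate(m, tmp_path / "out")


def test_nonempty_output_refused(tmp_path):
    out = tmp_path / "out"
    out.mkdir()
    (out / "x").write_text("")
    with pytest.raises(CurationError, match="not empty"):
        curate(_one_recording_manifest(tmp_path), out)


def test_failed_recording_leaves_no_partial_files(tmp_path):
    m = _one_recording_manifest(tmp_path)
    bad_raw = tmp_path / "acq" / "raw2.fif"
    bad_raw.write_bytes(b"\0")
    m.recordings.append(
        Recording(subject="02", task="rest", run=1, raw_path=str(bad_raw),
                  meg={k: v for k, v in MEG_META.items() if k != "SoftwareFilters"})
    )
    out = tmp_path / "out"
    with pytest.raises(CurationError):
        curate(m, out)
    assert not list(out.rglob("sub-02*"))


def test_link_mode_hardlinks_payload(tmp_path):
    m = _one_recording_manifest(tmp_path)
    tree, report = curate(m, tmp_path / "out", mode="link")
    placed = tree.path("sub-01/meg/sub-01_task-rest_run-01_meg.fif")
    assert placed.stat().st_nlink >= 2
    assert report.count("ERROR") == 0


def test_directory_payload_moved_intact(tmp_path):
    raw = tmp_path / "acq" / "raw.ds"
    raw.mkdir(parents=True)
    (raw / "inner.res4").write_bytes(b"\1\2\3")
    m = CurationManifest(
        name="ctf",
        recordings=[Recording(subject="01", task="rest", run=1,
                              raw_path=str(raw), meg=dict(MEG_META))],
    )
    tree, report = curate(m, tmp_path / "out")
    payload = tree.find("sub-01/meg/sub-01_task-rest_run-01_meg.ds")
    assert payload is not None and payload.is_directory_payload
    assert (tree.path(payload) / "inner.res4").read_bytes() == b"\1\2\3"
    assert report.count("ERROR") == 0


def test_manifest_yaml_round_trip(tmp_path):
    raw = tmp_path / "r.fif"
    raw.write_bytes(b"")
    doc = {
        "dataset": {"name": "demo", "bids_version": "1.4.0"},
        "recordings": [
            {"subject": "01", "task": "rest", "run": 1, "raw_path": str(raw),
             "meg": {"DewarPosition": "upright"}}
        ],
        "participants": [{"participant_id": "sub-01", "age": 30}],
    }
    p = tmp_path / "manifest.yaml"
    p.write_text(yaml.safe_dump(doc))
    m = load_manifest(p)
    assert m.name == "demo"
    assert m.recordings[0].subject == "01"
    assert m.recordings[0].meg == {"DewarPosition": "upright"}
    assert m.participants[0]["age"] == 30


class TestExtraction:
    def test_synthetic_header_echo(self, tmp_path):
        raw = tmp_path / "x.raw"
        write_synthetic_raw(raw, 274, 2400.0, 300.0, np.random.default_rng(0))
        fields, notes = extract_metadata(raw, "synthetic")
        assert fields == {
            "MEGChannelCount": 274,
            "SamplingFrequency": 2400.0,
            "RecordingDuration": 300.0,
        }
        assert notes == []

    def test_unknown_plugin_yields_empty_partial_with_note(self, tmp_path):
        fields, notes = extract_metadata(tmp_path / "x.raw", "vendor-x")
        assert fields == {} and len(notes) == 1

    def test_plugin_parse_failure_raises(self, tmp_path):
        raw = tmp_path / "x.raw"
        raw.write_bytes(b"not a header")
        with pytest.raises(CurationError):
            extract_metadata(raw, "synthetic")

    def test_manifest_values_override_plugin_values(self, tmp_path):
        raw = tmp_path / "acq" / "r.raw"
        raw.parent.mkdir()
        write_synthetic_raw(raw, 100, 600.0, 10.0, np.random.default_rng(1))
        m = CurationManifest(
            name="x",
            plugin="synthetic",
            recordings=[Recording(subject="01", task="rest", run=1, raw_path=str(raw),
                                  meg={**MEG_META, "SamplingFrequency": 1200.0})],
        )
        tree, _ = curate(m, tmp_path / "out")
        import json
        doc = json.loads(tree.path("sub-01/meg/sub-01_task-rest_run-01_meg.json").read_text())
        assert doc["SamplingFrequency"] == 1200.0  # manifest wins
        assert doc["MEGChannelCount"] == 100  # plugin contribution kept
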