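"""Filename grammar: parse/build round-trips, rejection reasons, placement."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megbids import EntitySet, build_name, expected_location, parse_name, try_parse_name
from megbids.errors import ContractError, FilenameError
from megbids.fixtures import corrupt_name, random_entity_set
from megbids.grammar import allowed_locations, missing_required


class TestParse:
    @pytest.mark.parametrize(
        "name, entities, suffix, ext",
        [
            (
                "sub-01_ses-01_task-rest_run-01_meg.json",
                {"sub": "01", "ses": "01", "task": "rest", "run": "01"},
                "meg",
                "json",
            ),
            ("sub-01_task-noise_run-01_meg.ds", {"sub": "01", "task": "noise", "run": "01"}, "meg", "ds"),
            ("participants.tsv", {}, "participants", "tsv"),
            ("dataset_description.json", {}, "dataset_description", "json"),
            ("task-rest_meg.json", {"task": "rest"}, "meg", "json"),  # inheritance sidecar
            ("sub-01_ses-02_coordsystem.json", {"sub": "01", "ses": "02"}, "coordsystem", "json"),
            ("sub-01_headshape.pos", {"sub": "01"}, "headshape", "pos"),
        ],
    )
    def test_accepts_canonical_names(self, name, entities, suffix, ext):
        es = parse_name(name)
        assert es.as_dict() == entities
        assert es.suffix == suffix
        assert es.extension == ext

    @pytest.mark.parametrize(
        "name, reason",
        [
            ("sub-01_run-01_task-rest_meg.fif", "bad-order"),
            ("sub-01_sub-02_task-rest_meg.fif", "bad-order"),
            ("sub-01_space-x_task-rest_meg.fif", "bad-key"),
            ("sub-01_task-re!st_meg.fif", "bad-label"),
            ("sub-01_task-rest_run-xx_meg.fif", "bad-label"),
            ("sub-01_task-rest_megx.fif", "bad-suffix"),
            ("sub-01_meg_task-rest.json", "bad-suffix"),
            ("README", "bad-suffix"),
            ("sub-01_task-rest_meg.txt", "no-match"),  # extension outside rule
        ],
    )
    def test_rejects_with_single_reason(self, name, reason):
        es, got = try_parse_name(name)
        assert es is None
        assert got == reason
        with pytest.raises(FilenameError) as exc:
            parse_name(name)
        assert exc.value.reason == reason


class TestBuild:
    def test_run_zero_padded(self):
        es = EntitySet.create({"sub": "01", "task": "noise", "run": "1"}, "meg", "ds")
        assert build_name(es) == "sub-01_task-noise_run-01_meg.ds"

    def test_bare_study_files(self):
        assert build_name(EntitySet.create({}, "participants", "tsv")) == "participants.tsv"

    def test_session_coordsystem(self):
        es = EntitySet.create({"sub": "01", "ses": "01"}, "coordsystem", "json")
        assert build_name(es) == "sub-01_ses-01_coordsystem.json"

    def test_missing_required_entity_refused(self):
        es = EntitySet.create({"sub": "01"}, "meg", "fif")
        assert missing_required(es) == ["task"]
        with pytest.raises(ContractError, match="task"):
            build_name(es)

    def test_reduced_entity_sidecar_allowed_when_opted_in(self):
        es = EntitySet.create({"task": "rest"}, "meg", "json")
        assert build_name(es, require_complete=False) == "task-rest_meg.json"


class TestRoundTrip:
    def test_seeded_random_entity_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            e = random_entity_set(rng)
            assert parse_name(build_name(e)) == e

    def test_corrupted_names_all_rejected(self):
        rng = np.random.default_rng(99)
        reasons = {"bad-order", "bad-key", "bad-label", "bad-suffix", "no-match"}
        for _ in range(500):
            name, _family = corrupt_name(rng)
            es, reason = try_parse_name(name)
            assert es is None
            assert reason in reasons

    @settings(max_examples=200, derandomize=True)
    @given(
        sub=st.from_regex(r"[A-Za-z0-9]{1,6}", fullmatch=True),
        task=st.from_regex(r"[A-Za-z0-9]{1,6}", fullmatch=True),
        run=st.integers(min_value=1, max_value=99),
    )
    def test_property_parse_inverts_build(self, sub, task, run):
        es = EntitySet.create(
            {"sub": sub, "task": task, "run": f"{run:02d}"}, "meg", "fif"
        )
        assert parse_name(build_name(es)) == es


class TestPlacement:
    @pytest.mark.parametrize(
        "entities, suffix, ext, expected",
        [
            ({"sub": "01", "ses": "02"}, "coordsystem", "json", "sub-01/ses-02/"),
            ({"sub": "01", "task": "faces", "run": "02"}, "events", "tsv", "sub-01/meg/"),
            ({"sub": "01", "ses": "01", "task": "rest", "run": "01"}, "meg", "fif", "sub-01/ses-01/meg/"),
            ({}, "participants", "tsv", ""),
            ({"sub": "02"}, "T1w", "json", "sub-02/anat/"),
            ({"sub": "02", "ses": "01"}, "scans", "tsv", "sub-02/ses-01/"),
        ],
    )
    def test_expected_location(self, entities, suffix, ext, expected):
        assert expected_location(EntitySet.create(entities, suffix, ext)) == expected

    def test_every_fixture_artifact_at_an_allowed_location(self, valid_tree):
        for a in valid_tree.artifacts:
            assert a.parent in allowed_locations(a.entity_set), a.relative_path
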