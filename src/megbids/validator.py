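"""MEG-BIDS conformance checking.

A rule engine over a scanned :class:`~megbids.model.DatasetTree` producing a
coded, severity-graded :class:`ValidationReport`.  Raw vendor payloads are
never opened — only their presence, naming, and directory-ness matter.  Rule
families:

* **F** — filename grammar and placement for every path;
* **D** — required study metadata (``dataset_description.json``);
* **M** — every MEG recording resolves a ``*_meg.json`` with the required
  keys and a channels table;
* **C** — coordinate-system documents: present when landmarks were
  digitised, registry-valid system and units, non-degenerate fiducials;
* **X** — cross-checks (channel counts vs channels.tsv, scans.tsv
  referential integrity, participants two-way match, event onsets within the
  recording, AssociatedEmptyRoom link);
* **T** — per-file JSON/TSV schema findings surfaced with their own codes.

Severity policy: structural, grammar, and required-metadata failures are
ERRORs; cross-count mismatches and best-practice deviations are WARNINGs
(vendors differ legitimately).  The code↔severity mapping is fixed in
:data:`ISSUE_REGISTRY`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import AmbiguityError, ContractError, ResolutionError
from .grammar import EntitySet, allowed_locations, missing_required
from .inherit import resolve, resolve_table
from .model import ArtifactRecord, DatasetTree, query
from .sidecars import (
    SCHEMAS,
    Violation,
    read_json_sidecar,
    read_tsv_table,
)
from . import coords as _coords

__all__ = [
    "ISSUE_REGISTRY",
    "ValidationIssue",
    "ValidationReport",
    "validate",
    "render_report",
    "report_from_json",
]

DATASET_SENTINEL = "<dataset>"

#: code -> (severity, description).  Stable registry; every issue emitted by
#: :func:`validate` uses one of these codes with exactly this severity.
ISSUE_REGISTRY: dict[str, tuple[str, str]] = {
    "MEG-E001": ("ERROR", "path does not match the filename grammar"),
    "MEG-E002": ("ERROR", "dataset_description.json missing"),
    "MEG-E003": ("ERROR", "dataset_description.json lacks Name or BIDSVersion"),
    "MEG-E004": ("ERROR", "file is not at its expected location"),
    "MEG-E005": ("ERROR", "malformed JSON document"),
    "MEG-E010": ("ERROR", "MEG recording resolves no _meg.json sidecar"),
    "MEG-E011": ("ERROR", "effective _meg.json metadata lacks a required key"),
    "MEG-E012": ("ERROR", "metadata value has wrong type or is out of vocabulary"),
    "MEG-E013": ("ERROR", "TSV table is structurally invalid"),
    "MEG-E014": ("ERROR", "duplicate identifier within a table"),
    "MEG-E020": ("ERROR", "landmarks digitised but no coordsystem document for session"),
    "MEG-E021": ("ERROR", "MEGCoordinateSystem missing or not a registry token"),
    "MEG-E022": ("ERROR", "MEGCoordinateUnits missing or invalid"),
    "MEG-E023": ("ERROR", "anatomical landmarks are collinear or malformed"),
    "MEG-E031": ("ERROR", "scans.tsv references a missing file"),
    "MEG-E040": ("ERROR", "ambiguous or unresolvable sidecar inheritance"),
    "MEG-W011": ("WARNING", "MEG recording has no channels table"),
    "MEG-W030": ("WARNING", "channel-count field disagrees with channels.tsv"),
    "MEG-W032": ("WARNING", "participants.tsv and subject folders disagree"),
    "MEG-W033": ("WARNING", "event onset beyond RecordingDuration"),
    "MEG-W034": ("WARNING", "AssociatedEmptyRoom path does not exist"),
    "MEG-I001": ("INFO", "unknown metadata key preserved verbatim"),
}


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    path: str
    message: str
    rule_ref: str = ""

    @property
    def severity(self) -> str:
        return ISSUE_REGISTRY[self.code][0]

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity,
            "path": self.path,
            "message": self.message,
            "rule_ref": self.rule_ref,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def count(self, severity: str) -> int:
        return sum(1 for i in self.issues if i.severity == severity)

    @property
    def verdict(self) -> str:
        return "invalid" if self.count("ERROR") else "valid"

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def sorted_issues(self) -> list[ValidationIssue]:
        return sorted(self.issues, key=lambda i: (i.path, i.code, i.message))

    def to_dict(self) -> dict:
        return {
            "schema_version": "1",
            "verdict": self.verdict,
            "counts": {
                "ERROR": self.count("ERROR"),
                "WARNING": self.count("WARNING"),
                "INFO": self.count("INFO"),
            },
            "issues": [i.to_dict() for i in self.sorted_issues()],
        }


class _Emitter:
    def __init__(self, report: ValidationReport):
        self.report = report

    def __call__(self, code: str, path: str, message: str, rule_ref: str = "") -> None:
        if code not in ISSUE_REGISTRY:
            raise ContractError(f"unknown issue code {code!r}")
        self.report.issues.append(ValidationIssue(code, path, message, rule_ref))


# ---------------------------------------------------------------------------


def _violation_code(v: Violation, schema_name: str) -> Optional[str]:
    """Map a sidecar schema violation onto a registry code (None = skip)."""
    if v.code == "JSON-PARSE":
        return "MEG-E005"
    if v.code == "UNKNOWN-KEY":
        return "MEG-I001"
    if v.code in ("MISSING-COLUMN", "RAGGED-ROW", "DUPLICATE-COLUMN"):
        return "MEG-E013"
    if v.code == "DUPLICATE-VALUE":
        return "MEG-E014"
    if v.code in ("TYPE", "VALUE"):
        return "MEG-E012"
    if v.code == "MISSING-KEY":
        # per-file missing keys in _meg.json are judged after inheritance (E011);
        # dataset_description and coordsystem have their own codes
        return None
    return "MEG-E012"


_COUNT_FIELD_TYPES = {
    "MEGChannelCount": {"MEGMAG", "MEGGRADAXIAL", "MEGGRADPLANAR"},
    "MEGREFChannelCount": {"MEGREFMAG", "MEGREFGRADAXIAL"},
    "EEGChannelCount": {"EEG"},
    "EOGChannelCount": {"EOG"},
    "ECGChannelCount": {"ECG"},
    "EMGChannelCount": {"EMG"},
    "MiscChannelCount": {"MISC"},
    "TriggerChannelCount": {"TRIG"},
}

EMPTYROOM_SUBJECT = "emptyroom"


def validate(tree: DatasetTree, config: Optional[dict] = None) -> ValidationReport:
    """Apply the full rule set to a scanned tree; always returns a report."""
    report = ValidationReport()
    emit = _Emitter(report)

    # --- family F: grammar and placement -----------------------------------
    for path in tree.unclassified:
        emit("MEG-E001", path, "filename matches no MEG-BIDS pattern", "grammar")
    for a in tree.artifacts:
        allowed = allowed_locations(a.entity_set)
        if a.parent not in allowed:
            emit(
                "MEG-E004",
                a.relative_path,
                f"expected under {allowed[0] or '<root>'!r}, found under {a.parent or '<root>'!r}",
                "placement",
            )
        if a.is_raw_recording() and missing_required(a.entity_set):
            emit(
                "MEG-E001",
                a.relative_path,
                f"recording name lacks required entities {missing_required(a.entity_set)}",
                "grammar",
            )

    # --- family D: dataset description --------------------------------------
    dd = tree.find("dataset_description.json")
    if dd is None:
        emit("MEG-E002", DATASET_SENTINEL, "dataset_description.json is missing", "D")
    else:
        doc, violations = read_json_sidecar(tree.path(dd), "dataset_description")
        if doc is None:
            emit("MEG-E005", dd.relative_path, violations[0].message, "D")
        else:
            for key in ("Name", "BIDSVersion"):
                if key not in doc or not isinstance(doc[key], str) or not doc[key]:
                    emit("MEG-E003", dd.relative_path, f"missing or empty {key}", "D")

    # --- family T: per-file schema findings ---------------------------------
    json_suffix_schemas = {"meg": "meg", "T1w": "T1w"}
    tsv_suffix_schemas = {
        "channels": "channels",
        "events": "events",
        "scans": "scans",
        "participants": "participants",
    }
    tables: dict[str, object] = {}
    for a in tree.artifacts:
        suffix, ext = a.entity_set.suffix, a.entity_set.extension
        if ext == "json" and suffix in json_suffix_schemas:
            doc, violations = read_json_sidecar(
                tree.path(a), json_suffix_schemas[suffix], check_required=False
            )
            for v in violations:
                code = _violation_code(v, suffix)
                if code:
                    emit(code, a.relative_path, v.message, f"schema:{suffix}")
            if suffix == "T1w" and doc is not None:
                _check_landmarks(doc.get("AnatomicalLandmarkCoordinates"), a, emit)
        elif ext == "tsv" and suffix in tsv_suffix_schemas:
            df, violations = read_tsv_table(tree.path(a), tsv_suffix_schemas[suffix])
            tables[a.relative_path] = df
            for v in violations:
                code = _violation_code(v, suffix)
                if code:
                    emit(code, a.relative_path, v.message, f"schema:{suffix}")

    # --- family C: coordinate systems ---------------------------------------
    coordsystems: dict[str, dict] = {}
    for a in query(tree, suffix="coordsystem"):
        doc, violations = read_json_sidecar(tree.path(a), "coordsystem", check_required=False)
        if doc is None:
            emit("MEG-E005", a.relative_path, violations[0].message, "C")
            continue
        coordsystems[a.relative_path] = doc
        schema = SCHEMAS["coordsystem"]
        sys_tok = doc.get("MEGCoordinateSystem")
        if sys_tok not in schema["required"]["MEGCoordinateSystem"]["enum"]:
            emit(
                "MEG-E021",
                a.relative_path,
                f"MEGCoordinateSystem {sys_tok!r} is not a registry token",
                "C",
            )
        elif sys_tok == "Other" and not doc.get("MEGCoordinateSystemDescription"):
            emit(
                "MEG-E021",
                a.relative_path,
                "MEGCoordinateSystem 'Other' requires MEGCoordinateSystemDescription",
                "C",
            )
        if doc.get("MEGCoordinateUnits") not in ("m", "cm", "mm"):
            emit(
                "MEG-E022",
                a.relative_path,
                f"MEGCoordinateUnits {doc.get('MEGCoordinateUnits')!r} invalid",
                "C",
            )
        for v in violations:
            if v.code in ("TYPE",) and v.location.startswith(
                ("AnatomicalLandmarkCoordinates", "HeadCoilCoordinates")
            ):
                emit("MEG-E012", a.relative_path, v.message, "C")
        units = doc.get("MEGCoordinateUnits")
        _check_landmarks(
            doc.get("AnatomicalLandmarkCoordinates"),
            a,
            emit,
            units=units if units in _coords.UNIT_FACTORS else "m",
        )

    # --- family M + X: recordings -------------------------------------------
    recordings = [a for a in tree.artifacts if a.is_raw_recording()]
    sessions_needing_coords: dict[tuple, str] = {}
    for rec in recordings:
        try:
            trace = resolve(tree, rec, "meg")
        except (AmbiguityError, ResolutionError) as exc:
            emit("MEG-E040", rec.relative_path, str(exc), "M")
            continue
        effective = trace.effective
        if not trace.applied:
            emit("MEG-E010", rec.relative_path, "no applicable _meg.json sidecar", "M")
        else:
            for key in SCHEMAS["meg"]["required"]:
                if key not in effective:
                    emit(
                        "MEG-E011",
                        rec.relative_path,
                        f"effective metadata lacks required key {key}",
                        "M",
                    )
        channels_art = resolve_table(tree, rec, "channels")
        if channels_art is None:
            emit("MEG-W011", rec.relative_path, "no channels.tsv describes this recording", "M")

        sub, ses = rec.entity_set.get("sub"), rec.entity_set.get("ses")
        if effective.get("DigitizedLandmarks") is True:
            sessions_needing_coords.setdefault((sub, ses), rec.relative_path)

        # X: channel-count cross-check
        if channels_art is not None:
            df = tables.get(channels_art.relative_path)
            if df is not None and "type" in getattr(df, "columns", ()):
                type_counts = df["type"].value_counts().to_dict()
                for fld, types in _COUNT_FIELD_TYPES.items():
                    if fld in effective and isinstance(effective[fld], int):
                        actual = sum(type_counts.get(t, 0) for t in types)
                        if actual != effective[fld]:
                            emit(
                                "MEG-W030",
                                rec.relative_path,
                                f"{fld} = {effective[fld]} but channels.tsv has {actual}",
                                "X",
                            )
        # X: event onsets within the recording
        duration = effective.get("RecordingDuration")
        events_art = resolve_table(tree, rec, "events")
        if events_art is not None and isinstance(duration, (int, float)):
            df = tables.get(events_art.relative_path)
            if df is not None and "onset" in getattr(df, "columns", ()):
                for raw in df["onset"]:
                    try:
                        onset = float(raw)
                    except (TypeError, ValueError):
                        continue
                    if onset > duration:
                        emit(
                            "MEG-W033",
                            events_art.relative_path,
                            f"event onset {onset} s exceeds RecordingDuration {duration} s",
                            "X",
                        )
                        break
        # X: empty-room association
        er = effective.get("AssociatedEmptyRoom")
        if isinstance(er, str) and er:
            if not (Path(tree.root) / er).exists():
                emit(
                    "MEG-W034",
                    rec.relative_path,
                    f"AssociatedEmptyRoom {er!r} does not exist",
                    "X",
                )

    # C: coordsystem presence per session needing it
    for (sub, ses), rec_path in sorted(
        sessions_needing_coords.items(), key=lambda kv: str(kv[0])
    ):
        entities = {"sub": sub} if ses is None else {"sub": sub, "ses": ses}
        if not query(tree, entities, suffix="coordsystem"):
            where = f"sub-{sub}" + (f"/ses-{ses}" if ses else "")
            emit(
                "MEG-E020",
                where,
                "DigitizedLandmarks is true but no coordsystem.json found for this session",
                "C",
            )

    # X: scans.tsv referential integrity
    for a in query(tree, suffix="scans"):
        df = tables.get(a.relative_path)
        if df is None or "filename" not in getattr(df, "columns", ()):
            continue
        base = Path(tree.root) / a.parent
        for raw in df["filename"]:
            if raw is None:
                continue
            if not (base / raw).exists():
                emit("MEG-E031", a.relative_path, f"listed file {raw!r} does not exist", "X")

    # X: participants two-way match
    part = tree.find("participants.tsv")
    folder_subs = {
        s for s in tree.subjects if s is not None and s != EMPTYROOM_SUBJECT
    }
    if part is not None:
        df = tables.get(part.relative_path)
        if df is not None and "participant_id" in getattr(df, "columns", ()):
            listed = {
                str(v)[len("sub-"):]
                for v in df["participant_id"]
                if v is not None and str(v).startswith("sub-")
            }
            for missing in sorted(folder_subs - listed):
                emit(
                    "MEG-W032",
                    part.relative_path,
                    f"subject folder sub-{missing} has no participants.tsv row",
                    "X",
                )
            for orphan in sorted(listed - folder_subs - {EMPTYROOM_SUBJECT}):
                emit(
                    "MEG-W032",
                    part.relative_path,
                    f"participants.tsv row sub-{orphan} has no subject folder",
                    "X",
                )

    return report


def _check_landmarks(landmarks, artifact: ArtifactRecord, emit, units: str = "mm") -> None:
    """Collinearity check on an AnatomicalLandmarkCoordinates mapping."""
    if not isinstance(landmarks, dict):
        return
    if not all(k in landmarks for k in ("NAS", "LPA", "RPA")):
        return
    try:
        fid = _coords.Fiducials(
            landmarks["NAS"], landmarks["LPA"], landmarks["RPA"],
            units if units in _coords.UNIT_FACTORS else "mm",
        )
        fid.check_noncollinear()
    except _coords.GeometryError as exc:
        emit("MEG-E023", artifact.relative_path, str(exc), "C")
    except Exception:
        emit("MEG-E023", artifact.relative_path, "landmark coordinates malformed", "C")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(report: ValidationReport, format: str = "text", strict: bool = False) -> str:
    """Render a report as text, json, or tsv (deterministic ordering).

    ``strict`` promotes WARNINGs to ERRORs in the rendered verdict/counts
    (the underlying report is unchanged).
    """
    issues = report.sorted_issues()
    n_err = report.count("ERROR") + (report.count("WARNING") if strict else 0)
    n_warn = 0 if strict else report.count("WARNING")
    verdict = "invalid" if n_err else "valid"
    if format == "text":
        lines = [f"{verdict}: {n_err} errors, {n_warn} warnings"]
        for i in issues:
            sev = "ERROR" if (strict and i.severity == "WARNING") else i.severity
            lines.append(f"  [{sev}] {i.code} {i.path}: {i.message}")
        return "\n".join(lines) + "\n"
    if format == "json":
        d = report.to_dict()
        if strict:
            d["verdict"] = verdict
            d["counts"] = {"ERROR": n_err, "WARNING": n_warn, "INFO": report.count("INFO")}
        return json.dumps(d, indent=4) + "\n"
    if format == "tsv":
        lines = ["code\tseverity\tpath\tmessage"]
        for i in issues:
            msg = i.message.replace("\t", " ")
            lines.append(f"{i.code}\t{i.severity}\t{i.path}\t{msg}")
        return "\n".join(lines) + "\n"
    raise ContractError(f"unknown report format {format!r}")


def report_from_json(text: str) -> ValidationReport:
    """Inverse of ``render_report(..., format='json')`` (modulo ordering)."""
    d = json.loads(text)
    return ValidationReport(
        issues=[
            ValidationIssue(i["code"], i["path"], i["message"], i.get("rule_ref", ""))
            for i in d["issues"]
        ]
    )
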