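"""Build a conformant MEG-BIDS tree from a curation manifest.

The manifest is a declarative YAML-compatible mapping describing the raw
recordings to organise (native payloads are opaque — files or CTF-style
directories) together with their metadata.  Curation places every payload at
its canonical name and location, writes all sidecars through
:mod:`megbids.sidecars`, assembles ``scans.tsv`` / ``participants.tsv`` /
``dataset_description.json``, and finishes by self-validating the result.

Metadata can optionally be pre-filled by an extraction plugin keyed on a
plugin id; manifest-provided values always override plugin values.  The
package ships exactly one plugin, for the synthetic fixture raw format.
"""
from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any, Callable, Mapping, Optional

import pandas as pd
import yaml

from .errors import CurationError
from .grammar import EntitySet, build_name, expected_location
from .model import DatasetTree, scan_tree
from .sidecars import SCHEMAS, write_json_sidecar, write_tsv_table
from .synthraw import read_synthetic_raw_header
from .validator import ValidationReport, validate

__all__ = [
    "Recording",
    "CurationManifest",
    "load_manifest",
    "curate",
    "extract_metadata",
    "register_plugin",
    "PLUGINS",
]

PLUGINS: dict[str, Callable[[str], dict]] = {
    "synthetic": lambda path: read_synthetic_raw_header(path),
}


def register_plugin(plugin_id: str, reader: Callable[[str], dict]) -> None:
    """Register a metadata-extraction plugin (``raw_path -> partial sidecar``)."""
    PLUGINS[plugin_id] = reader


def extract_metadata(raw_path: str | Path, plugin_id: Optional[str]) -> tuple[dict, list[str]]:
    """Extract a partial MEG sidecar from a raw payload via a plugin.

    Returns ``(fields, notes)``; an unknown/absent plugin yields an empty
    partial plus an informational note, a plugin parse failure raises.
    """
    if plugin_id is None or plugin_id not in PLUGINS:
        return {}, [f"no extraction plugin registered for {plugin_id!r}; no fields extracted"]
    return PLUGINS[plugin_id](str(raw_path)), []


@dataclass
class Recording:
    """One raw recording to curate."""

    subject: str
    task: str
    run: Optional[int] = None
    session: Optional[str] = None
    acq: Optional[str] = None
    proc: Optional[str] = None
    raw_path: str = ""
    meg: dict = field(default_factory=dict)
    channels: Optional[list[dict]] = None
    events: Optional[list[dict]] = None
    coordsystem: Optional[dict] = None
    acq_time: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.subject, self.session, self.task, self.acq,
                None if self.run is None else int(self.run), self.proc)

    def entity_set(self, extension: Optional[str]) -> EntitySet:
        ents: dict[str, str] = {"sub": self.subject}
        if self.session is not None:
            ents["ses"] = self.session
        ents["task"] = self.task
        if self.acq is not None:
            ents["acq"] = self.acq
        if self.run is not None:
            ents["run"] = str(int(self.run)).zfill(2)
        if self.proc is not None:
            ents["proc"] = self.proc
        return EntitySet.create(ents, "meg", extension)


@dataclass
class CurationManifest:
    name: str
    bids_version: str = "1.4.0"
    authors: list[str] = field(default_factory=list)
    plugin: Optional[str] = None
    recordings: list[Recording] = field(default_factory=list)
    participants: Optional[list[dict]] = None

    def check(self) -> None:
        seen: set[tuple] = set()
        for rec in self.recordings:
            if rec.key in seen:
                raise CurationError(
                    f"duplicate recording key {rec.key} (subject/session/task/acq/run/proc must be unique)"
                )
            seen.add(rec.key)
            if not Path(rec.raw_path).exists():
                raise CurationError(f"raw_path {rec.raw_path!r} does not exist")


def load_manifest(path: str | Path) -> CurationManifest:
    """Load a manifest from its YAML file."""
    data = yaml.safe_load(Path(path).read_text("utf-8"))
    if not isinstance(data, dict):
        raise CurationError(f"manifest {path} is not a mapping")
    ds = data.get("dataset", {})
    recs = []
    for raw in data.get("recordings", []):
        recs.append(
            Recording(
                subject=str(raw["subject"]),
                task=str(raw["task"]),
                run=raw.get("run"),
                session=None if raw.get("session") is None else str(raw["session"]),
                acq=raw.get("acq"),
                proc=raw.get("proc"),
                raw_path=str(raw["raw_path"]),
                meg=dict(raw.get("meg", {})),
                channels=raw.get("channels"),
                events=raw.get("events"),
                coordsystem=raw.get("coordsystem"),
                acq_time=raw.get("acq_time"),
            )
        )
    return CurationManifest(
        name=str(ds.get("name", "Untitled")),
        bids_version=str(ds.get("bids_version", "1.4.0")),
        authors=list(ds.get("authors", [])),
        plugin=data.get("plugin"),
        recordings=recs,
        participants=data.get("participants"),
    )


def _payload_extension(raw_path: Path) -> str:
    suffix = raw_path.suffix.lstrip(".")
    if not suffix:
        raise CurationError(f"raw payload {raw_path} has no extension")
    return suffix


def _place_payload(src: Path, dest: Path, mode: str) -> None:
    dest.parent.mkdir(parents=True, exist_ok=True)
    if mode == "link":
        if src.is_dir():
            raise CurationError("link mode is not supported for directory payloads")
        dest.hardlink_to(src.resolve())
    elif src.is_dir():
        shutil.copytree(src, dest)
    else:
        shutil.copy(src, dest)


def curate(
    manifest: CurationManifest,
    out_root: str | Path,
    mode: str = "copy",
) -> tuple[DatasetTree, ValidationReport]:
    """Materialise a manifest as a MEG-BIDS tree and self-validate it.

    ``out_root`` must be absent or empty.  Each recording is written
    atomically: if anything fails, the files written for that recording are
    removed before the error propagates.
    """
    manifest.check()
    if mode not in ("copy", "link"):
        raise CurationError(f"unknown mode {mode!r}")
    root = Path(out_root)
    if root.exists() and any(root.iterdir()):
        raise CurationError(f"output directory {root} is not empty")
    root.mkdir(parents=True, exist_ok=True)

    write_json_sidecar(
        {"Name": manifest.name, "BIDSVersion": manifest.bids_version,
         **({"Authors": manifest.authors} if manifest.authors else {})},
        root / "dataset_description.json",
        "dataset_description",
    )

    scans: dict[tuple[str, Optional[str]], list[dict]] = {}
    coordsystems: dict[tuple[str, Optional[str]], dict] = {}

    for rec in sorted(manifest.recordings, key=lambda r: tuple(str(k) for k in r.key)):
        written: list[Path] = []
        try:
            _curate_one(manifest, rec, root, mode, written, scans, coordsystems)
        except Exception:
            for p in reversed(written):
                if p.is_dir():
                    shutil.rmtree(p, ignore_errors=True)
                elif p.exists():
                    p.unlink()
            # prune directories the failed recording left empty
            for p in written:
                parent = p.parent
                while parent != root and parent.exists() and not any(parent.iterdir()):
                    parent.rmdir()
                    parent = parent.parent
            raise

    for (sub, ses), doc in sorted(coordsystems.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ents = {"sub": sub, **({"ses": ses} if ses else {})}
        es = EntitySet.create(ents, "coordsystem", "json")
        path = root / expected_location(es) / build_name(es)
        path.parent.mkdir(parents=True, exist_ok=True)
        write_json_sidecar(doc, path, "coordsystem", check_required=False)

    for (sub, ses), rows in sorted(scans.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ents = {"sub": sub, **({"ses": ses} if ses else {})}
        es = EntitySet.create(ents, "scans", "tsv")
        path = root / expected_location(es) / build_name(es)
        df = pd.DataFrame(sorted(rows, key=lambda r: r["filename"]), dtype=object)
        write_tsv_table(df, path, "scans")

    _write_participants(manifest, root)

    tree = scan_tree(root)
    return tree, validate(tree)


def _curate_one(manifest, rec, root, mode, written, scans, coordsystems) -> None:
    raw = Path(rec.raw_path)
    ext = _payload_extension(raw)
    es = rec.entity_set(ext)
    loc = expected_location(es)
    payload_name = build_name(es)
    dest = root / loc / payload_name
    _place_payload(raw, dest, mode)
    written.append(dest)

    extracted, _notes = extract_metadata(raw, manifest.plugin)
    sidecar = {"TaskName": rec.task, **extracted, **rec.meg}
    missing = [k for k in SCHEMAS["meg"]["required"] if k not in sidecar]
    if missing:
        raise CurationError(
            f"recording {rec.key}: missing required metadata key {missing[0]!r}"
        )
    sidecar_es = rec.entity_set("json")
    sidecar_path = root / loc / build_name(sidecar_es)
    write_json_sidecar(sidecar, sidecar_path, "meg")
    written.append(sidecar_path)

    if rec.channels is not None:
        ch_es = rec.entity_set(None)
        ch_es = EntitySet(ch_es.entities, "channels", "tsv")
        ch_path = root / loc / build_name(ch_es)
        write_tsv_table(pd.DataFrame(rec.channels, dtype=object), ch_path, "channels")
        written.append(ch_path)

    if rec.events is not None:
        ev_es = EntitySet(rec.entity_set(None).entities, "events", "tsv")
        ev_path = root / loc / build_name(ev_es)
        write_tsv_table(pd.DataFrame(rec.events, dtype=object), ev_path, "events")
        written.append(ev_path)

    if rec.coordsystem is not None:
        coordsystems.setdefault((rec.subject, rec.session), dict(rec.coordsystem))

    rel_from_session = f"{es.rule.modality}/{payload_name}"
    scans.setdefault((rec.subject, rec.session), []).append(
        {"filename": rel_from_session, "acq_time": rec.acq_time}
    )


def _write_participants(manifest: CurationManifest, root: Path) -> None:
    if manifest.participants is not None:
        rows = [dict(r) for r in manifest.participants]
    else:
        subs = sorted(
            {r.subject for r in manifest.recordings if r.subject != "emptyroom"}
        )
        rows = [{"participant_id": f"sub-{s}"} for s in subs]
    rows.sort(key=lambda r: str(r.get("participant_id", "")))
    df = pd.DataFrame(rows, dtype=object)
    write_tsv_table(df, root / "participants.tsv", "participants")
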