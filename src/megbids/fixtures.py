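"""Seeded synthetic MEG-BIDS fixtures: valid trees, manifests, and mutations.

The generator emulates the structure of public MEG-BIDS releases: several
subjects, optional multiple sessions, task and resting-state runs with a
CTF-like channel layout (axial gradiometers, reference sensors, a few
physiological and trigger channels) sampled at 2400 Hz for five minutes, an
empty-room noise recording under the dedicated subject label ``emptyroom``
with task label ``noise``, and an anatomical T1w JSON carrying the fiducial
field.  Payload bodies are pseudorandom bytes in the self-describing
synthetic raw format — no physiological signal content.

All randomness flows from one integer seed through per-subject
``SeedSequence`` substreams, so regeneration is deterministic byte for byte.

Named mutation operators produce *invalid* trees, each introducing exactly
one defect with a known expected validator code — the test bed for the
mutation-kill matrix.
"""
from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np

from .curation import CurationManifest, Recording, curate
from .errors import FixtureError
from .grammar import ENTITY_ORDER, EntitySet, RULES, build_name, expected_location
from .model import DatasetTree, scan_tree
from .sidecars import write_json_sidecar
from .synthraw import write_synthetic_raw

__all__ = [
    "FixtureSpec",
    "DEFAULT_CHANNEL_PROFILE",
    "build_manifest",
    "generate_dataset",
    "generate_layered_tree",
    "random_entity_set",
    "corrupt_name",
    "MUTATION_OPERATORS",
    "MutationRecord",
    "mutate",
]

#: CTF-like layout: 270 axial gradiometers + reference and auxiliary channels.
DEFAULT_CHANNEL_PROFILE: dict[str, int] = {
    "MEGGRADAXIAL": 270,
    "MEGREFMAG": 4,
    "EOG": 2,
    "ECG": 1,
    "TRIG": 1,
    "MISC": 2,
}

_TASK_NAMES = ["rest", "auditory", "visual", "faces", "motor"]
_CHANNEL_UNITS = {
    "MEGMAG": "T", "MEGGRADAXIAL": "T", "MEGGRADPLANAR": "T/m",
    "MEGREFMAG": "T", "MEGREFGRADAXIAL": "T",
    "EEG": "V", "EOG": "V", "ECG": "V", "EMG": "V", "TRIG": "V", "MISC": "V",
}
_CHANNEL_PREFIX = {
    "MEGMAG": "MAG", "MEGGRADAXIAL": "MLC", "MEGGRADPLANAR": "MLP",
    "MEGREFMAG": "BR", "MEGREFGRADAXIAL": "GR",
    "EEG": "EEG", "EOG": "EOG", "ECG": "ECG", "EMG": "EMG",
    "TRIG": "STIM", "MISC": "MISC",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of one synthetic dataset."""

    seed: int = 0
    n_sub: int = 3
    n_ses: int = 1
    n_task: int = 1
    n_run: int = 2
    include_emptyroom: bool = True
    include_anat: bool = True
    channel_profile: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_PROFILE)
    )
    sampling_frequency: float = 2400.0
    power_line_frequency: float = 60.0
    recording_duration: float = 300.0
    event_rate: float = 0.5  # events per second for task runs
    units: str = "cm"
    coordinate_system: str = "CTF"

    def __post_init__(self):
        for name in ("n_sub", "n_ses", "n_task", "n_run"):
            if getattr(self, name) < 1:
                raise FixtureError(f"{name} must be >= 1")

    @property
    def use_sessions(self) -> bool:
        # session folders only when the study really has several sessions
        return self.n_ses > 1

    def task_names(self) -> list[str]:
        names = list(_TASK_NAMES)
        while len(names) < self.n_task:
            names.append(f"task{len(names) + 1:02d}")
        return names[: self.n_task]


def _channel_rows(profile: Mapping[str, int]) -> list[dict]:
    rows = []
    for ctype in sorted(profile):
        for i in range(profile[ctype]):
            rows.append(
                {
                    "name": f"{_CHANNEL_PREFIX[ctype]}{i + 1:03d}",
                    "type": ctype,
                    "units": _CHANNEL_UNITS[ctype],
                    "low_cutoff": "0.0",
                    "high_cutoff": "600.0",
                    "status": "good",
                }
            )
    return rows


def _count_fields(profile: Mapping[str, int]) -> dict[str, int]:
    groups = {
        "MEGChannelCount": ("MEGMAG", "MEGGRADAXIAL", "MEGGRADPLANAR"),
        "MEGREFChannelCount": ("MEGREFMAG", "MEGREFGRADAXIAL"),
        "EEGChannelCount": ("EEG",),
        "EOGChannelCount": ("EOG",),
        "ECGChannelCount": ("ECG",),
        "EMGChannelCount": ("EMG",),
        "MiscChannelCount": ("MISC",),
        "TriggerChannelCount": ("TRIG",),
    }
    return {
        fld: sum(profile.get(t, 0) for t in types)
        for fld, types in groups.items()
        if sum(profile.get(t, 0) for t in types) > 0
    }


def _fiducials_cm(rng: np.random.Generator) -> dict[str, list[float]]:
    """Plausible landmark triangle in a CTF-style device frame (cm)."""
    jit = lambda s: float(rng.normal(0, s))
    nas = [9.8 + jit(0.4), jit(0.3), jit(0.3)]
    lpa = [jit(0.3), 7.4 + jit(0.4), jit(0.3)]
    rpa = [jit(0.3), -7.4 - jit(0.4), jit(0.3)]
    return {
        "NAS": [round(c, 3) for c in nas],
        "LPA": [round(c, 3) for c in lpa],
        "RPA": [round(c, 3) for c in rpa],
    }


def _event_rows(rng: np.random.Generator, rate: float, duration: float, sfreq: float) -> list[dict]:
    rows = []
    t = 0.0
    kinds = ["standard", "deviant"]
    while True:
        t += float(rng.exponential(1.0 / rate))
        if t >= duration:
            break
        onset = round(t, 3)
        rows.append(
            {
                "onset": f"{onset:.3f}",
                "duration": "0.050",
                "trial_type": kinds[int(rng.integers(0, len(kinds)))],
                "value": str(int(rng.integers(1, 9))),
                "sample": str(int(round(onset * sfreq))),
            }
        )
    return rows


def _emptyroom_relpath(spec: FixtureSpec) -> str:
    ents = {"sub": "emptyroom"}
    if spec.use_sessions:
        ents["ses"] = "01"
    ents.update({"task": "noise", "run": "01"})
    es = EntitySet.create(ents, "meg", "raw")
    return expected_location(es) + build_name(es)


def build_manifest(spec: FixtureSpec, raw_dir: str | Path) -> tuple[CurationManifest, list[str]]:
    """Expand a spec into a curation manifest plus the expected file list.

    Raw payloads are written under ``raw_dir`` (a staging area); the expected
    list enumerates every relative path the curated tree will contain.
    """
    raw_dir = Path(raw_dir)
    raw_dir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_sub + 1)
    tasks = spec.task_names()
    channels = _channel_rows(spec.channel_profile)
    counts = _count_fields(spec.channel_profile)
    meg_count = counts.get("MEGChannelCount", 0)

    recordings: list[Recording] = []
    participants: list[dict] = []
    expected: set[str] = {"dataset_description.json", "participants.tsv"}
    er_rel = _emptyroom_relpath(spec) if spec.include_emptyroom else None

    def add_recording(sub: str, ses: Optional[str], task: str, run: int,
                      rng: np.random.Generator, idx: int, emptyroom: bool) -> None:
        ents = {"sub": sub, **({"ses": ses} if ses else {}),
                "task": task, "run": str(run).zfill(2)}
        es = EntitySet.create(ents, "meg", "raw")
        staging = raw_dir / build_name(es)
        write_synthetic_raw(
            staging, meg_count, spec.sampling_frequency, spec.recording_duration, rng
        )
        meg = {
            "TaskName": task,
            "Manufacturer": "CTF",
            "SamplingFrequency": spec.sampling_frequency,
            "PowerLineFrequency": spec.power_line_frequency,
            "DewarPosition": "upright",
            "SoftwareFilters": "n/a",
            "DigitizedLandmarks": not emptyroom,
            "DigitizedHeadPoints": not emptyroom,
            "RecordingDuration": spec.recording_duration,
            "RecordingType": "continuous",
            **counts,
        }
        if er_rel is not None and not emptyroom:
            meg["AssociatedEmptyRoom"] = er_rel
        rec = Recording(
            subject=sub,
            session=ses,
            task=task,
            run=run,
            raw_path=str(staging),
            meg=meg,
            channels=channels,
            events=None if emptyroom else _event_rows(
                rng, spec.event_rate, spec.recording_duration, spec.sampling_frequency
            ),
            coordsystem=None,
            acq_time=f"2018-06-19T{9 + idx % 10:02d}:{(idx * 7) % 60:02d}:00",
        )
        recordings.append(rec)
        loc = expected_location(es)
        expected.add(loc + build_name(es))
        expected.add(loc + build_name(rec.entity_set("json")))
        expected.add(loc + build_name(EntitySet(rec.entity_set(None).entities, "channels", "tsv")))
        if rec.events is not None:
            expected.add(loc + build_name(EntitySet(rec.entity_set(None).entities, "events", "tsv")))

    idx = 0
    for s in range(spec.n_sub):
        sub = f"{s + 1:02d}"
        rng = np.random.default_rng(streams[s])
        fid = _fiducials_cm(rng)
        participants.append(
            {
                "participant_id": f"sub-{sub}",
                "age": str(int(rng.integers(20, 61))),
                "sex": ["F", "M"][int(rng.integers(0, 2))],
            }
        )
        for j in range(spec.n_ses):
            ses = f"{j + 1:02d}" if spec.use_sessions else None
            for task in tasks:
                for r in range(1, spec.n_run + 1):
                    add_recording(sub, ses, task, r, rng, idx, emptyroom=False)
                    idx += 1
            # one coordsystem per subject/session, attached to the first recording
            for rec in recordings:
                if rec.subject == sub and rec.session == ses and rec.coordsystem is None:
                    rec.coordsystem = {
                        "MEGCoordinateSystem": spec.coordinate_system,
                        "MEGCoordinateUnits": spec.units,
                        "AnatomicalLandmarkCoordinates": fid,
                        "AnatomicalLandmarkCoordinateSystem": spec.coordinate_system,
                        "AnatomicalLandmarkCoordinateUnits": spec.units,
                    }
                    break
            ents = {"sub": sub, **({"ses": ses} if ses else {})}
            expected.add(
                expected_location(EntitySet.create(ents, "coordsystem", "json"))
                + build_name(EntitySet.create(ents, "coordsystem", "json"))
            )
            expected.add(
                expected_location(EntitySet.create(ents, "scans", "tsv"))
                + build_name(EntitySet.create(ents, "scans", "tsv"))
            )

    if spec.include_emptyroom:
        rng = np.random.default_rng(streams[-1])
        for j in range(spec.n_ses):
            ses = f"{j + 1:02d}" if spec.use_sessions else None
            add_recording("emptyroom", ses, "noise", 1, rng, idx, emptyroom=True)
            idx += 1
            ents = {"sub": "emptyroom", **({"ses": ses} if ses else {})}
            expected.add(
                expected_location(EntitySet.create(ents, "scans", "tsv"))
                + build_name(EntitySet.create(ents, "scans", "tsv"))
            )

    manifest = CurationManifest(
        name=f"Synthetic MEG study (seed {spec.seed})",
        bids_version="1.4.0",
        authors=["megbids fixture generator"],
        plugin="synthetic",
        recordings=recordings,
        participants=participants,
    )
    return manifest, sorted(expected)


def generate_dataset(spec: FixtureSpec, out: str | Path) -> tuple[DatasetTree, list[str]]:
    """Materialise a fully valid tree; returns (tree, expected file list).

    Refuses a non-empty output directory.  The result validates with zero
    ERRORs by construction, and two runs with the same spec are
    byte-identical.
    """
    out = Path(out)
    if out.exists() and any(out.iterdir()):
        raise FixtureError(f"output directory {out} is not empty")
    with tempfile.TemporaryDirectory() as staging:
        manifest, expected = build_manifest(spec, staging)
        tree, _report = curate(manifest, out)
    if spec.include_anat:
        anat_seq = np.random.SeedSequence(spec.seed).spawn(spec.n_sub + 2)
        for s in range(spec.n_sub):
            sub = f"{s + 1:02d}"
            rng = np.random.default_rng(anat_seq[s])
            ents = {"sub": sub}
            if spec.use_sessions:
                ents["ses"] = "01"
            es = EntitySet.create(ents, "T1w", "json")
            loc = expected_location(es)
            path = out / loc / build_name(es)
            path.parent.mkdir(parents=True, exist_ok=True)
            fid_mm = {
                k: [round(float(c), 2) for c in (np.asarray(v) * 10.0 + rng.normal(0, 0.05, 3))]
                for k, v in _fiducials_cm(rng).items()
            }
            write_json_sidecar(
                {"AnatomicalLandmarkCoordinates": fid_mm, "CoordinateUnits": "mm"},
                path,
                "T1w",
            )
            expected.append(loc + build_name(es))
        tree = scan_tree(out)
    return tree, sorted(expected)


# ---------------------------------------------------------------------------
# layered sidecar trees (inheritance test bed)
# ---------------------------------------------------------------------------

_KEY_POOL = {
    "PowerLineFrequency": [50, 60],
    "DewarPosition": ["upright", "supine"],
    "SoftwareFilters": ["n/a"],
    "Manufacturer": ["CTF", "Elekta", "KIT"],
    "RecordingDuration": [120.0, 300.0, 600.0],
    "TaskName": ["rest", "listen"],
}


def generate_layered_tree(seed: int, out: str | Path) -> dict:
    """Small tree with sidecars layered across hierarchy levels.

    Produces one target recording plus a random subset of applicable
    ``*_meg.json`` files at the root, subject, session, and run-folder
    levels (each with a random key subset), and one *non-applicable* decoy
    (different task) at the root.  Returns a description with the target's
    relative path and the per-level sidecar contents, for oracle comparison.
    """
    rng = np.random.default_rng(seed)
    out = Path(out)
    task = "rest"
    use_ses = bool(rng.integers(0, 2))
    ents = {"sub": "01", **({"ses": "01"} if use_ses else {}), "task": task, "run": "01"}
    target_es = EntitySet.create(ents, "meg", "raw")
    loc = expected_location(target_es)
    target_rel = loc + build_name(target_es)
    (out / loc).mkdir(parents=True, exist_ok=True)
    write_synthetic_raw(out / target_rel, 10, 1000.0, 60.0, rng)

    def rand_doc() -> dict:
        keys = sorted(
            rng.choice(sorted(_KEY_POOL), size=int(rng.integers(1, 5)), replace=False)
        )
        return {k: _KEY_POOL[k][int(rng.integers(0, len(_KEY_POOL[k])))] for k in keys}

    levels = []
    level_specs = [("", {"task": task})]
    level_specs.append((f"sub-01/", {"sub": "01", "task": task}))
    if use_ses:
        level_specs.append((f"sub-01/ses-01/", {"sub": "01", "ses": "01", "task": task}))
    level_specs.append((loc, dict(ents)))
    for folder, sc_ents in level_specs:
        if rng.random() < 0.75:
            es = EntitySet.create(sc_ents, "meg", "json")
            name = build_name(es, require_complete=False)
            doc = rand_doc()
            (out / folder).mkdir(parents=True, exist_ok=True)
            write_json_sidecar(doc, out / folder / name)
            levels.append({"path": f"{folder}{name}", "doc": doc})
    # decoy: applicable to nothing here (different task)
    decoy = {"PowerLineFrequency": 50}
    write_json_sidecar(decoy, out / "task-listen_meg.json")
    return {"target": target_rel, "layers": levels, "decoy": "task-listen_meg.json"}


# ---------------------------------------------------------------------------
# random entity sets and corrupted names (grammar fuzzing)
# ---------------------------------------------------------------------------

_SUFFIX_CHOICES = ["meg", "channels", "events", "coordsystem", "scans", "photo", "T1w"]


def random_entity_set(rng: np.random.Generator) -> EntitySet:
    """A random grammar-valid, canonical (zero-padded run) entity set."""
    suffix = _SUFFIX_CHOICES[int(rng.integers(0, len(_SUFFIX_CHOICES)))]
    rule = RULES[suffix]

    def label() -> str:
        alphabet = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
        n = int(rng.integers(1, 8))
        return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), n))

    ents = {}
    for key in ENTITY_ORDER:
        if key in rule.required or (key in rule.optional and rng.random() < 0.5):
            if key == "run":
                ents[key] = f"{int(rng.integers(1, 100)):02d}"
            else:
                ents[key] = label()
    extensions = rule.extensions or ("pos",)
    ext = extensions[int(rng.integers(0, len(extensions)))]
    return EntitySet.create(ents, suffix, ext)


def corrupt_name(rng: np.random.Generator) -> tuple[str, str]:
    """A name guaranteed invalid, with the reason family that breaks it."""
    es = random_entity_set(rng)
    while len(es.entities) < 2:
        es = random_entity_set(rng)
    name = build_name(es)
    stem, ext = name.split(".", 1)
    tokens = stem.split("_")
    mode = int(rng.integers(0, 5))
    if mode == 0:  # swap two entity tokens out of canonical order
        i = int(rng.integers(0, len(tokens) - 2))
        tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
        return "_".join(tokens) + "." + ext, "bad-order"
    if mode == 1:  # unknown entity key
        key, value = tokens[0].split("-", 1)
        tokens[0] = f"zz{key}-{value}"
        return "_".join(tokens) + "." + ext, "bad-key"
    if mode == 2:  # illegal character inside a label
        key, value = tokens[0].split("-", 1)
        tokens[0] = f"{key}-{value}+x"
        return "_".join(tokens) + "." + ext, "bad-label"
    if mode == 3:  # unknown suffix
        tokens[-1] = "megg"
        return "_".join(tokens) + "." + ext, "bad-suffix"
    # duplicate the first entity (violates strict canonical order)
    tokens.insert(1, tokens[0])
    return "_".join(tokens) + "." + ext, "bad-order"


# ---------------------------------------------------------------------------
# mutation operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    operator: str
    path: str  # touched path (relative to tree root)
    expected_code: str
    description: str


def _first(tree: DatasetTree, **kw) -> Optional[Path]:
    from .model import query

    hits = query(tree, kw.get("entities"), kw.get("suffix"))
    ext = kw.get("extension")
    if ext is not None:
        hits = [a for a in hits if a.entity_set.extension == ext]
    if kw.get("raw_only"):
        hits = [a for a in hits if a.is_raw_recording()]
    if kw.get("exclude_emptyroom"):
        hits = [a for a in hits if a.entity_set.get("sub") != "emptyroom"]
    return hits[0].relative_path if hits else None


def _edit_json(root: Path, rel: str, fn: Callable[[dict], None]) -> None:
    p = root / rel
    doc = json.loads(p.read_text("utf-8"))
    fn(doc)
    p.write_text(json.dumps(doc, indent=4) + "\n", "utf-8")


def _edit_lines(root: Path, rel: str, fn: Callable[[list[str]], list[str]]) -> None:
    p = root / rel
    lines = p.read_text("utf-8").split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    p.write_text("\n".join(fn(lines)) + "\n", "utf-8")


def _op_break_entity_order(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="events", extension="tsv")
    if rel is None:
        return None
    name = rel.rsplit("/", 1)[-1]
    stem, ext = name.split(".", 1)
    tokens = stem.split("_")
    # move the run token before the task token
    keys = [t.split("-", 1)[0] for t in tokens[:-1]]
    if "run" not in keys or "task" not in keys:
        return None
    run_tok = tokens[keys.index("run")]
    tokens.remove(run_tok)
    tokens.insert(keys.index("task"), run_tok)
    new = "/".join(rel.split("/")[:-1] + ["_".join(tokens) + "." + ext])
    (root / rel).rename(root / new)
    return new


def _op_bad_label_chars(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="events", extension="tsv")
    if rel is None:
        return None
    new = rel.replace("_task-", "_task-bad.lbl-", 1)
    if new == rel:
        return None
    (root / rel).rename(root / new)
    return new


def _op_delete_dataset_description(tree: DatasetTree, root: Path) -> Optional[str]:
    p = root / "dataset_description.json"
    if not p.exists():
        return None
    p.unlink()
    return "dataset_description.json"


def _op_blank_dataset_name(tree: DatasetTree, root: Path) -> Optional[str]:
    p = root / "dataset_description.json"
    if not p.exists():
        return None
    _edit_json(root, "dataset_description.json", lambda d: d.pop("Name", None))
    return "dataset_description.json"


def _op_corrupt_json(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="coordsystem", extension="json")
    if rel is None:
        return None
    (root / rel).write_text('{"MEGCoordinateSystem": "CTF",', "utf-8")
    return rel


def _op_remove_meg_sidecar(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="meg", extension="json")
    if rel is None:
        return None
    (root / rel).unlink()
    return rel


def _op_drop_required_meg_key(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="meg", extension="json")
    if rel is None:
        return None
    _edit_json(root, rel, lambda d: d.pop("DewarPosition", None))
    return rel


def _op_stringify_boolean(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="meg", extension="json")
    if rel is None:
        return None
    _edit_json(root, rel, lambda d: d.__setitem__("DigitizedLandmarks", "true"))
    return rel


def _op_remove_channels_file(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="channels", extension="tsv")
    if rel is None:
        return None
    (root / rel).unlink()
    return rel


def _op_mismatch_channel_count(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="meg", extension="json")
    if rel is None:
        return None
    def bump(d):
        d["MEGChannelCount"] = int(d.get("MEGChannelCount", 0)) + 1
    _edit_json(root, rel, bump)
    return rel


def _op_invalid_coordinate_system(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="coordsystem", extension="json")
    if rel is None:
        return None
    _edit_json(root, rel, lambda d: d.__setitem__("MEGCoordinateSystem", "MagicSpace"))
    return rel


def _op_invalid_units(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="coordsystem", extension="json")
    if rel is None:
        return None
    _edit_json(root, rel, lambda d: d.__setitem__("MEGCoordinateUnits", "furlong"))
    return rel


def _op_collinear_fiducials(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="coordsystem", extension="json")
    if rel is None:
        return None
    def flatten(d):
        fid = d.get("AnatomicalLandmarkCoordinates")
        if not fid:
            raise FixtureError("coordsystem has no landmarks")
        nas, rpa = np.asarray(fid["NAS"], float), np.asarray(fid["RPA"], float)
        # exact midpoint: rounding would leave a sliver of triangle area
        fid["LPA"] = [float(c) for c in (nas + rpa) / 2.0]
    _edit_json(root, rel, flatten)
    return rel


def _op_ragged_tsv_row(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="channels", extension="tsv")
    if rel is None:
        return None
    def fn(lines):
        if len(lines) > 1:
            lines[1] = lines[1] + "\textra"
        return lines
    _edit_lines(root, rel, fn)
    return rel


def _op_duplicate_channel_name(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="channels", extension="tsv")
    if rel is None:
        return None
    def fn(lines):
        if len(lines) < 3:
            raise FixtureError("channels table too small")
        first = lines[1].split("\t")
        second = lines[2].split("\t")
        second[0] = first[0]
        lines[2] = "\t".join(second)
        return lines
    _edit_lines(root, rel, fn)
    return rel


def _op_scans_missing_file(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="scans", extension="tsv")
    if rel is None:
        return None
    _edit_lines(root, rel, lambda lines: lines + ["meg/ghost_meg.raw\tn/a"])
    return rel


def _op_orphan_participant_row(tree: DatasetTree, root: Path) -> Optional[str]:
    p = root / "participants.tsv"
    if not p.exists():
        return None
    def fn(lines):
        n_cols = len(lines[0].split("\t"))
        lines.append("\t".join(["sub-99"] + ["n/a"] * (n_cols - 1)))
        return lines
    _edit_lines(root, "participants.tsv", fn)
    return "participants.tsv"


def _op_event_onset_past_duration(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="events", extension="tsv")
    if rel is None:
        return None
    def fn(lines):
        header = lines[0].split("\t")
        onset_i = header.index("onset")
        if len(lines) < 2:
            raise FixtureError("events table empty")
        cells = lines[1].split("\t")
        cells[onset_i] = "100000.000"
        lines[1] = "\t".join(cells)
        return lines
    _edit_lines(root, rel, fn)
    return rel


def _op_misplace_file(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="coordsystem", extension="json")
    if rel is None:
        return None
    parent, name = rel.rsplit("/", 1)
    new = f"{parent}/meg/{name}" if (root / parent / "meg").is_dir() else None
    if new is None:
        return None
    (root / rel).rename(root / new)
    return new


def _op_break_emptyroom_link(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="meg", extension="json", exclude_emptyroom=True)
    if rel is None:
        return None
    doc = json.loads((root / rel).read_text("utf-8"))
    if "AssociatedEmptyRoom" not in doc:
        return None
    _edit_json(root, rel, lambda d: d.__setitem__("AssociatedEmptyRoom", "sub-emptyroom/meg/missing_meg.raw"))
    return rel


def _op_ambiguous_sidecars(tree: DatasetTree, root: Path) -> Optional[str]:
    # an inheritance tie is a property of a *pair*: this is the one operator
    # that touches two files (both newly added, same depth, same specificity)
    rec = next((a for a in tree.artifacts if a.is_raw_recording()
                and a.entity_set.get("run") is not None), None)
    if rec is None:
        return None
    ents = rec.entity_set.as_dict()
    keep = {k: v for k, v in ents.items() if k in ("sub", "ses")}
    a_ents = {**keep, "task": ents["task"]}
    b_ents = {**keep, "run": ents["run"]}
    for e in (a_ents, b_ents):
        es = EntitySet.create(e, "meg", "json")
        write_json_sidecar({}, root / rec.parent / build_name(es, require_complete=False))
    return rec.parent + build_name(EntitySet.create(a_ents, "meg", "json"), require_complete=False)


def _op_drop_coordsystem(tree: DatasetTree, root: Path) -> Optional[str]:
    rel = _first(tree, suffix="coordsystem", extension="json")
    if rel is None:
        return None
    (root / rel).unlink()
    return rel


#: operator id -> (expected issue code, description, apply function)
MUTATION_OPERATORS: dict[str, tuple[str, str, Callable]] = {
    "break-entity-order": ("MEG-E001", "rename a file with entities out of canonical order", _op_break_entity_order),
    "bad-label-chars": ("MEG-E001", "rename a file with an illegal character in a label", _op_bad_label_chars),
    "delete-dataset-description": ("MEG-E002", "remove dataset_description.json", _op_delete_dataset_description),
    "blank-dataset-description-name": ("MEG-E003", "drop the Name key from dataset_description.json", _op_blank_dataset_name),
    "corrupt-json": ("MEG-E005", "truncate a coordsystem.json mid-document", _op_corrupt_json),
    "remove-meg-sidecar": ("MEG-E010", "delete a run's _meg.json", _op_remove_meg_sidecar),
    "drop-required-meg-key": ("MEG-E011", "remove DewarPosition from a _meg.json", _op_drop_required_meg_key),
    "stringify-boolean": ("MEG-E012", "turn DigitizedLandmarks into the string 'true'", _op_stringify_boolean),
    "ragged-tsv-row": ("MEG-E013", "append an extra cell to a channels.tsv row", _op_ragged_tsv_row),
    "duplicate-channel-name": ("MEG-E014", "give two channels the same name", _op_duplicate_channel_name),
    "drop-coordsystem": ("MEG-E020", "delete a session's coordsystem.json", _op_drop_coordsystem),
    "invalid-coordinate-system-token": ("MEG-E021", "set MEGCoordinateSystem to a non-registry token", _op_invalid_coordinate_system),
    "invalid-units": ("MEG-E022", "set MEGCoordinateUnits to an unknown unit", _op_invalid_units),
    "collinear-fiducials": ("MEG-E023", "move LPA onto the NAS-RPA line", _op_collinear_fiducials),
    "scans-references-missing-file": ("MEG-E031", "add a scans.tsv row for a nonexistent file", _op_scans_missing_file),
    "misplace-file": ("MEG-E004", "move a coordsystem.json into the meg folder", _op_misplace_file),
    "remove-channels-file": ("MEG-W011", "delete a run's channels.tsv", _op_remove_channels_file),
    "mismatch-channel-count": ("MEG-W030", "offset MEGChannelCount by +1", _op_mismatch_channel_count),
    "orphan-participant-row": ("MEG-W032", "add a participants.tsv row without a folder", _op_orphan_participant_row),
    "event-onset-past-duration": ("MEG-W033", "set an event onset beyond the recording end", _op_event_onset_past_duration),
    "break-emptyroom-link": ("MEG-W034", "point AssociatedEmptyRoom at a missing path", _op_break_emptyroom_link),
    "ambiguous-sidecars": ("MEG-E040", "add two equally specific applicable sidecars", _op_ambiguous_sidecars),
}


def mutate(tree_path: str | Path, operator_id: str, seed: int = 0) -> MutationRecord:
    """Apply exactly one named defect to a valid tree, in place.

    Deterministic: the target file is the lexicographically first applicable
    artifact.  Refuses (raises :class:`FixtureError`) when the operator is
    inapplicable to this tree.
    """
    if operator_id not in MUTATION_OPERATORS:
        raise FixtureError(f"unknown mutation operator {operator_id!r}")
    expected_code, description, fn = MUTATION_OPERATORS[operator_id]
    root = Path(tree_path)
    tree = scan_tree(root)
    touched = fn(tree, root)
    if touched is None:
        raise FixtureError(f"operator {operator_id!r} is not applicable to {tree_path}")
    return MutationRecord(operator_id, touched, expected_code, description)
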