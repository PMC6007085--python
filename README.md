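# megbids

A self-contained toolkit for the **MEG-BIDS** standard: model, read, write,
curate, and validate Brain Imaging Data Structure trees for
magnetoencephalography.

MEG has no common raw file format — CTF/VSM, Elekta/Neuromag/MEGIN,
Yokogawa/KIT, and Neuroscan/KRISS systems each write their own binary
containers. MEG-BIDS side-steps this by organising *unprocessed* recordings in
their native vendor format inside a standard folder hierarchy
(study → subject → session → modality → run) and carrying all metadata in
sidecar text files: a `*_meg.json` document per run, channel and event tables
(`*_channels.tsv`, `*_events.tsv`), a per-session coordinate-system document
(`*_coordsystem.json`) with the anatomical fiducials, acquisition times
(`scans.tsv`), and study-level files (`participants.tsv`,
`dataset_description.json`).

This package is for people who curate, share, or consume such datasets —
lab data managers converting acquisitions, repository maintainers checking
submissions, and tool authors who need a typed in-memory model of a dataset
tree. Raw vendor payloads are always treated as opaque: only their names,
placement, and (optionally) plugin-extracted header fields matter.

## What it implements

* **Filename grammar** — bidirectional mapping between filenames and entity
  sets `sub-<L>[_ses-<L>][_task-<L>][_acq-<L>][_run-<D>][_proc-<L>]_<suffix>.<ext>`,
  with a placement rule per suffix. Parsing is total: every invalid name gets
  exactly one reason code (`bad-order`, `bad-key`, `bad-label`, `bad-suffix`,
  `no-match`). The grammar table ships as machine-readable JSON.
* **Tree model** — a deterministic scanner that indexes a directory into
  artifacts (CTF-style `.ds` directory payloads are leaves, never descended
  into) and a submap-based query.
* **Sidecar I/O** — schema-checked JSON/TSV readers that accumulate coded
  violations instead of aborting, and byte-deterministic writers (`n/a` is the
  single missing-value sentinel in TSV).
* **Inheritance** — the effective metadata of a data file is the key-level
  merge of all applicable sidecars, ordered shallowest→deepest: *the
  description file closer to the data prevails*. Full provenance is returned;
  exact specificity ties are errors, not silent choices.
* **Coordinate frames** — head frames built from the nasion and pre-auricular
  landmarks: ALS (CTF/KIT: +x anterior, origin mid-ears) and RAS
  (Elekta/Neuromag: +x right, +y anterior), proper rigid transforms between
  them, exact power-of-ten unit conversion.
* **Validator** — a rule engine with a fixed code↔severity registry
  (`MEG-E…` errors, `MEG-W…` warnings) covering grammar, placement, required
  metadata, coordinate documents, and cross-file consistency
  (channel counts vs `channels.tsv`, `scans.tsv` referential integrity,
  participants two-way match, event onsets vs recording duration,
  empty-room links).
* **Curator** — builds a conformant tree from a declarative YAML manifest of
  raw recordings, with a metadata-extraction plugin interface, then
  self-validates.
* **Fixtures** — a seeded generator of fully valid synthetic studies
  (CTF-like 270-gradiometer layout, 2400 Hz, five-minute runs, empty-room
  noise recording, anatomical fiducial JSONs) plus 22 named mutation
  operators, each introducing one defect with a known expected issue code.

## Worked example

```python
from megbids import FixtureSpec, generate_dataset, render_report, validate

tree, expected = generate_dataset(FixtureSpec(seed=7, n_sub=3), "study")
print(f"generated {len(expected)} files")
print(render_report(validate(tree), "text").strip())
```

prints

```
generated 39 files
valid: 0 errors, 0 warnings
```

— 39 files because each of the 3 subjects has two task runs (raw payload +
`_meg.json` + `_channels.tsv` + `_events.tsv`), one `coordsystem.json`, one
`scans.tsv`, and one anatomical `T1w.json`, the empty-room subject adds a
noise run, and two study-level files sit at the root. The validator's
`0 errors` means every filename parses and is well placed, every recording
resolves complete effective metadata, and all cross-checks pass.

Inheritance in one picture (`examples/03_inheritance.py`): a root-level
`task-rest_meg.json` sets `PowerLineFrequency: 60`, the run-level sidecar
overrides it with `50` and adds `DewarPosition`; the resolved trace is

```
effective metadata: {'PowerLineFrequency': 50, 'DewarPosition': 'upright'}
  depth 0: task-rest_meg.json contributes []
  depth 2: sub-01/meg/sub-01_task-rest_run-01_meg.json contributes ['DewarPosition', 'PowerLineFrequency']
```

The `examples/` directory holds one short script per capability; each builds
its own input and prints what it computes. There is also a thin CLI:

```sh
megbids fixture --seed 7 --subjects 3 --out study
megbids validate study --format json
megbids convert --manifest manifest.yaml --out bids_out
megbids inspect study --resolve sub-01/meg/sub-01_task-rest_run-01_meg.raw
```

Exit codes: 0 valid/success, 1 invalid dataset, 2 usage error, 3 internal
error.

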