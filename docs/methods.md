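# Methods

This note records the model behind each component, the defaults and why they
were chosen, the numerical conventions, and what the synthetic test bed does
and does not establish about real data.

## The filename grammar

A name is a sequence of `key-value` entity pairs in the fixed order
`sub < ses < task < acq < run < proc`, a suffix, and an extension. Labels are
ASCII alphanumerics (`[A-Za-z0-9]+`); `run` labels are all digits. Hyphens
and underscores are structural delimiters and therefore illegal inside
labels. Two study files are "bare" (`participants.tsv`,
`dataset_description.json`). The per-suffix rule table — required/optional
entities, allowed extensions, placement — lives in
`src/megbids/data/grammar.json` and is the single source of truth for the
parser, the validator, and the curator.

Design choices that were genuinely open:

* **Parsing is syntactic; completeness is contextual.** The inheritance
  principle requires reduced-entity sidecar names (a root-level
  `task-rest_meg.json` has no `sub`), so `parse_name` accepts any entity
  subset in canonical order, and the *required*-entity check is applied
  separately: by `build_name` (on by default) and by the validator for raw
  recordings at their run location.
* **Tolerant reader, canonical writer for `run`.** Any digit count is
  accepted on parse; building zero-pads to width 2. Consequently
  `build ∘ parse` is the identity only on canonical names (run width ≥ 2);
  `parse ∘ build` is the identity on all valid entity sets. The fixture
  generator emits canonical names only.
* **Rejection reasons are exhaustive and mutually exclusive** because the
  checks run in a fixed order (suffix → pair syntax → key vocabulary →
  order/duplicates → label charset → extension) and the first failure wins.
  Extension problems report `no-match`, the catch-all of the five-code
  vocabulary.
* **Empty-room recordings** are ordinary runs with task label `noise`,
  conventionally under the dedicated subject `emptyroom`; the validator
  accepts them under any subject and exempts `emptyroom` from the
  participants-table match.
* **Sessions are optional.** Single-session studies may omit `ses` entities
  and folders entirely; session-level rules (coordsystem, scans placement)
  then apply at the subject level. The generator emits session folders only
  when `n_ses > 1`, so both layouts are exercised.

## Sidecar schemas and serialisation

Schemas are shipped as JSON (`src/megbids/data/sidecar_schemas.json`) and
interpreted by a small engine that *accumulates* violations — missing
required key, wrong JSON type (booleans must be JSON booleans, numbers
finite), out-of-vocabulary value, ragged TSV row, duplicate identifier —
rather than stopping at the first. Only a file that fails to parse at all
produces a single fatal-for-that-file finding.

The `_meg.json` required-key set is `TaskName`, `SamplingFrequency`,
`PowerLineFrequency` (50 or 60 Hz), `DewarPosition`, `SoftwareFilters`,
`DigitizedLandmarks`, `DigitizedHeadPoints`; everything else (manufacturer,
channel counts, `RecordingDuration`, `AssociatedEmptyRoom`, …) is optional,
and unknown keys are preserved verbatim and reported as informational. The
channel `type` vocabulary is closed (unknown types are errors); `units` is
free text with vendor variation tolerated.

Writers are deterministic by construction: JSON uses schema key order then
alphabetical, 4-space indent, trailing newline; TSV uses schema column
order, LF endings, and lowercase `n/a` as the sole missing-value sentinel.
This makes write∘read a byte-level fixed point on canonical files, which the
tests assert for every generated artifact.

## Inheritance

A sidecar applies to a data file when its entities are a submap of the
target's and it sits at the root or in a directory on the target's path.
Applicable files are ordered by (directory depth ascending, entity count
ascending) and merged **key by key**, so the file closer to the data
prevails per field — chosen over whole-file replacement because conflicts
are defined at field granularity. Two applicable files with equal depth and
equal entity count cannot be ordered; that is an explicit ambiguity error
(surfaced by the validator as `MEG-E040`) rather than a silent tie-break.
For TSV sidecars (channels, events) row-level merging is undefined, so the
deepest applicable table wins outright; this whole-file precedence is a
documented choice.

## Coordinate frames

Internal unit is metres; `cm`/`mm` are converted at ingest. Conversion is
applied as repeated multiplication/division by 10 so same-direction
compositions are bit-exact. From the fiducials (NAS, LPA, RPA):

* **ALS** (CTF, KIT): origin = midpoint(LPA, RPA); x̂ = unit(NAS − origin);
  ẑ = unit(x̂ × (LPA − RPA)); ŷ = ẑ × x̂.
* **RAS** (Elekta/Neuromag): x̂ = unit(RPA − LPA); origin = projection of NAS
  onto the LPA–RPA line; ŷ = unit(NAS − origin); ẑ = x̂ × ŷ.

These formulas follow the de-facto vendor conventions; the registry is
closed (`CTF`, `KIT`, `ElektaNeuromag`) with `Other` available through an
explicit `FrameConvention` object carrying a description. All rotations are
proper (det = +1) and orthonormal within 1e-9; fiducial triangles with area
≤ 1e-12 m² are rejected as degenerate. Frame-to-frame mapping is
`frame(to) ∘ frame(from)⁻¹`, and the tests establish rigid-motion
equivariance and cross-convention round-trips at 1e-9 (measured ≈ 1e-16).

## Validator

Issue codes live in a fixed registry (`ISSUE_REGISTRY`); the code↔severity
mapping never varies. Severity policy: structural, grammar, and
required-metadata failures are errors; cross-count mismatches and
best-practice deviations are warnings, because vendors legitimately differ.
Raw payloads are never opened — presence, naming, and directory-ness only.
I/O failures become issues; the validator always returns a report. Reports
render to text/JSON/TSV with deterministic (path, code) ordering, and the
JSON rendering round-trips to an equal report.

## Curator

The manifest is a declarative YAML mapping — deliberately so, to keep
vendor-format parsing out of the write path while still exercising it end to
end. Payloads are copied by default (`link` mode hard-links file payloads
for large studies). Metadata precedence is plugin < manifest; `TaskName`
defaults to the task entity. Each recording is written atomically: on
failure its files (and any directories left empty) are removed before the
error propagates. `acq_time` is written at second precision; the first
recording of a subject/session that supplies fiducials provides that
session's `coordsystem.json`. Curation ends with a self-validation, and the
generator/curator agreement (inventory == expected file list, zero errors,
byte-identical reruns) is asserted in the acceptance suite.

## Synthetic fixtures

The generator emulates the shape of public MEG-BIDS releases: multiple
subjects and optional sessions, two runs per task by default, a CTF-like
channel complement (270 axial gradiometers, 4 reference magnetometers, EOG,
ECG, trigger and misc channels), 2400 Hz sampling, five-minute continuous
runs, 60 Hz power line, fiducials as a plausible non-collinear triangle
(nasion ~10 cm anterior, pre-auricular points ~±7.5 cm lateral, in cm, CTF
convention), task events as a Poisson stream at 0.5 events/s, an empty-room
noise recording, and per-subject anatomical fiducials in mm. Where the
standard does not fix a number these defaults are a one-time choice of
typical acquisition values, not tuning knobs.

Raw payloads use a synthetic self-describing format (64-byte header: magic,
MEG channel count, sampling frequency, duration; pseudorandom body) so the
opaque-payload machinery and the extraction plugin are testable without any
vendor format. The header's channel count is defined as the MEG-type count
so the plugin's `MEGChannelCount` is directly comparable with the
channels-table cross-check. All randomness flows from one seed through
per-subject `SeedSequence` substreams; regeneration is byte-identical.

**What passing tests do not show:** payload bodies carry no physiological
signal, channels/events are statistically uniform across runs, and no real
vendor header is ever parsed — so the tests establish the correctness of the
organisational machinery (grammar, placement, inheritance, validation,
curation), not robustness to the quirks of real acquisition software, clock
skew in `acq_time`, or vendor-specific channel naming.

Each mutation operator introduces exactly one defect into a valid tree and
names the issue code it must provoke; the kill matrix additionally checks
that no *new* error of any other code appears, and that every ERROR code in
the registry is provoked by at least one operator. The one documented
exception to single-file diffs is `ambiguous-sidecars`: an inheritance tie
is a property of a pair, so it adds two equally specific sidecars.

## Problem sizes

The default suites use small studies (1–3 subjects, ≤2 sessions, ≤2 runs,
~1 KB payload bodies) and the stated sampling scales: 500 + 500 names, 20
random specs, the full 22-operator matrix, 200 layered inheritance trees,
and 100 fiducial triangles. These sizes make every property check cheap to
re-run while still covering both session and session-less layouts, empty
room on/off, and anatomy on/off.

## Known limitations

* Only the six entities above are modelled (no `echo`, `space`, …) and only
  `T1w` is recognised among MRI files, solely for the fiducial field.
* Derivatives, stimulus files, and HED event annotations are out of scope;
  `derivatives/`, `sourcedata/`, and `code/` are ignored by the scanner.
* No real vendor plugin ships; the plugin interface is exercised by the
  synthetic format only.
* `headshape` files are checked for naming/placement only, and photographs
  only for existence and naming.
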