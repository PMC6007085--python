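"""Bidirectional grammar between filenames and entity sets.

A MEG-BIDS filename is a sequence of ``key-value`` entity pairs in a fixed
canonical order (``sub < ses < task < acq < run < proc``), a suffix naming the
artifact kind (``meg``, ``channels``, ``events``, ``coordsystem``, ...), and an
extension::

    sub-01_ses-01_task-rest_run-01_meg.fif

Two study-level files are "bare" (no entities): ``participants.tsv`` and
``dataset_description.json``.

The grammar table — one rule per suffix, with required/optional entities,
allowed extensions, and the placement of the file within the tree — is shipped
as a JSON document (``megbids/data/grammar.json``) so that the validator and
curator consume a single source of truth.

Parsing is purely syntactic: it accepts any entity subset in canonical order,
because the inheritance principle allows metadata files higher in the tree to
carry fewer entities than the data they describe (a root-level
``task-rest_meg.json`` applies to every matching run).  Whether the *required*
entities of a rule are present is a separate check (:func:`missing_required`),
enforced by :func:`build_name` and by the validator at run-item placement.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

from .errors import ContractError, FilenameError

__all__ = [
    "ENTITY_ORDER",
    "GrammarRule",
    "RULES",
    "EntitySet",
    "parse_name",
    "try_parse_name",
    "build_name",
    "expected_location",
    "missing_required",
    "grammar_table",
]


def _load_table() -> dict:
    text = resources.files("megbids.data").joinpath("grammar.json").read_text("utf-8")
    return json.loads(text)


_TABLE = _load_table()

ENTITY_ORDER: tuple[str, ...] = tuple(_TABLE["entity_order"])
_ENTITY_RANK = {k: i for i, k in enumerate(ENTITY_ORDER)}
RUN_PAD_WIDTH: int = int(_TABLE["run_pad_width"])
_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass(frozen=True)
class GrammarRule:
    """Filename rule for one suffix."""

    suffix: str
    required: frozenset[str]
    optional: frozenset[str]
    extensions: tuple[str, ...] | None  # None means any extension (vendor-specific)
    placement: str  # root | session | modality-folder
    modality: Optional[str] = None
    bare: bool = False
    directory_extensions: frozenset[str] = field(default_factory=frozenset)
    raw_extensions: frozenset[str] = field(default_factory=frozenset)
    inheritable_extensions: frozenset[str] = field(default_factory=frozenset)

    def allows_extension(self, ext: Optional[str]) -> bool:
        if ext is None:
            # extension may be absent only for directory-style raw payloads
            return bool(self.directory_extensions) or self.extensions is None
        return self.extensions is None or ext in self.extensions


def _load_rules() -> dict[str, GrammarRule]:
    rules = {}
    for suffix, raw in _TABLE["suffixes"].items():
        ext = raw["extensions"]
        rules[suffix] = GrammarRule(
            suffix=suffix,
            required=frozenset(raw["required"]),
            optional=frozenset(raw["optional"]),
            extensions=None if ext == "*" else tuple(ext),
            placement=raw["placement"],
            modality=raw.get("modality"),
            bare=raw.get("bare", False),
            directory_extensions=frozenset(raw.get("directory_extensions", [])),
            raw_extensions=frozenset(raw.get("raw_extensions", [])),
            inheritable_extensions=frozenset(raw.get("inheritable_extensions", [])),
        )
    return rules


RULES: dict[str, GrammarRule] = _load_rules()


def grammar_table() -> dict:
    """Return a deep copy of the machine-readable grammar table."""
    return json.loads(json.dumps(_TABLE))


@dataclass(frozen=True)
class EntitySet:
    """Ordered entity pairs + suffix + extension identifying one file's role.

    ``entities`` is stored as a tuple of (key, value) pairs in canonical order;
    construction validates order, key vocabulary, and label charset.
    """

    entities: tuple[tuple[str, str], ...]
    suffix: str
    extension: Optional[str] = None

    def __post_init__(self):
        seen = []
        for key, value in self.entities:
            if key not in _ENTITY_RANK:
                raise ContractError(f"unknown entity key {key!r}")
            if seen and _ENTITY_RANK[key] <= _ENTITY_RANK[seen[-1]]:
                raise ContractError(
                    f"entity {key!r} out of canonical order {ENTITY_ORDER}"
                )
            if not _LABEL_RE.match(value):
                raise ContractError(f"invalid label {value!r} for entity {key!r}")
            if key == "run" and not value.isdigit():
                raise ContractError(f"run label must be all digits, got {value!r}")
            seen.append(key)
        if self.suffix not in RULES:
            raise ContractError(f"unknown suffix {self.suffix!r}")

    # -- mapping-style access -------------------------------------------------
    @classmethod
    def create(
        cls,
        entities: Mapping[str, str] | None = None,
        suffix: str = "meg",
        extension: Optional[str] = None,
    ) -> "EntitySet":
        """Build an EntitySet from an arbitrary-order mapping of entities."""
        entities = dict(entities or {})
        unknown = set(entities) - set(ENTITY_ORDER)
        if unknown:
            raise ContractError(f"unknown entity keys {sorted(unknown)}")
        ordered = tuple((k, str(entities[k])) for k in ENTITY_ORDER if k in entities)
        return cls(ordered, suffix, extension)

    def as_dict(self) -> dict[str, str]:
        return dict(self.entities)

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self.as_dict().get(key, default)

    def contains(self, other: "EntitySet") -> bool:
        """True if ``other``'s entities are a submap of this set's entities."""
        mine = self.as_dict()
        return all(mine.get(k) == v for k, v in other.entities)

    def has_submap(self, entities: Mapping[str, str]) -> bool:
        mine = self.as_dict()
        return all(mine.get(k) == v for k, v in entities.items())

    @property
    def rule(self) -> GrammarRule:
        return RULES[self.suffix]

    def __len__(self) -> int:
        return len(self.entities)


_BARE_NAMES = {
    f"{suffix}.{rule.extensions[0]}": suffix
    for suffix, rule in RULES.items()
    if rule.bare and rule.extensions
}


def try_parse_name(filename: str):
    """Parse a filename; return ``(EntitySet, None)`` or ``(None, reason)``.

    Rejection reasons are exhaustive and mutually exclusive: the checks run in
    a fixed order and the first failing check supplies the single reason code.
    """
    if "/" in filename or "\\" in filename:
        return None, "no-match"
    if filename in _BARE_NAMES:
        suffix = _BARE_NAMES[filename]
        ext = filename.split(".", 1)[1]
        return EntitySet((), suffix, ext), None

    if "." in filename:
        stem, ext = filename.split(".", 1)
        if not ext:
            return None, "no-match"
    else:
        stem, ext = filename, None
    if not stem:
        return None, "no-match"

    tokens = stem.split("_")
    suffix = tokens[-1]
    rule = RULES.get(suffix)
    if rule is None or rule.bare:
        return None, "bad-suffix"

    pairs = []
    for token in tokens[:-1]:
        if "-" not in token:
            return None, "no-match"
        key, value = token.split("-", 1)
        pairs.append((key, value))

    for key, _ in pairs:
        if key not in _ENTITY_RANK:
            return None, "bad-key"
    ranks = [_ENTITY_RANK[k] for k, _ in pairs]
    if any(b <= a for a, b in zip(ranks, ranks[1:])):
        return None, "bad-order"
    for key, value in pairs:
        if not _LABEL_RE.match(value) or (key == "run" and not value.isdigit()):
            return None, "bad-label"
    allowed = rule.required | rule.optional
    if any(key not in allowed for key, _ in pairs):
        return None, "bad-key"
    if not rule.allows_extension(ext):
        return None, "no-match"
    return EntitySet(tuple(pairs), suffix, ext), None


def parse_name(filename: str) -> EntitySet:
    """Parse a filename into an :class:`EntitySet`, else raise :class:`FilenameError`."""
    entity_set, reason = try_parse_name(filename)
    if entity_set is None:
        raise FilenameError(reason, f"{filename!r} rejected: {reason}")
    return entity_set


def missing_required(entity_set: EntitySet) -> list[str]:
    """Entity keys required by the suffix rule but absent from the set."""
    present = set(entity_set.as_dict())
    return sorted(entity_set.rule.required - present)


def build_name(
    entity_set: EntitySet,
    run_pad: int = RUN_PAD_WIDTH,
    require_complete: bool = True,
) -> str:
    """Serialise an :class:`EntitySet` to its canonical filename.

    ``run`` values are zero-padded to ``run_pad`` digits (canonical writer);
    with ``require_complete`` the suffix rule's required entities must all be
    present (set it False when writing reduced-entity inheritance sidecars).
    """
    rule = entity_set.rule
    if require_complete:
        missing = missing_required(entity_set)
        if missing:
            raise ContractError(
                f"missing required entity {missing[0]!r} for suffix {rule.suffix!r}"
            )
    if rule.bare:
        if entity_set.entities:
            raise ContractError(f"suffix {rule.suffix!r} takes no entities")
        return f"{rule.suffix}.{rule.extensions[0]}"
    parts = []
    for key, value in entity_set.entities:
        if key == "run":
            value = value.zfill(run_pad)
        parts.append(f"{key}-{value}")
    parts.append(rule.suffix)
    name = "_".join(parts)
    if entity_set.extension is not None:
        if not rule.allows_extension(entity_set.extension):
            raise ContractError(
                f"extension {entity_set.extension!r} not allowed for suffix {rule.suffix!r}"
            )
        name = f"{name}.{entity_set.extension}"
    elif not rule.allows_extension(None):
        raise ContractError(f"suffix {rule.suffix!r} requires an extension")
    return name


def expected_location(entity_set: EntitySet) -> str:
    """Expected directory (relative to the dataset root, trailing ``/``) .

    Study-level files live at the root; session-specific files (coordsystem,
    headshape, photo, scans) directly in the subject or session folder; data
    files and their run-level sidecars in the modality folder.
    """
    rule = entity_set.rule
    if rule.placement == "root":
        return ""
    sub = entity_set.get("sub")
    if sub is None:
        return ""  # reduced-entity inheritance sidecar at the root
    parts = [f"sub-{sub}"]
    ses = entity_set.get("ses")
    if ses is not None:
        parts.append(f"ses-{ses}")
    if rule.placement == "modality-folder":
        parts.append(rule.modality)
    return "/".join(parts) + "/"


def allowed_locations(entity_set: EntitySet) -> list[str]:
    """All directories where this artifact may legally sit.

    Raw payloads and session-specific files have exactly one home
    (:func:`expected_location`); inheritable metadata files (``_meg.json``,
    ``_channels.tsv``, ``_events.tsv``) may also sit at any ancestor level
    consistent with their entities (root if no ``sub``, subject folder if no
    ``ses``, ...).
    """
    rule = entity_set.rule
    inheritable = (
        entity_set.extension is not None
        and entity_set.extension in rule.inheritable_extensions
    )
    if not inheritable:
        return [expected_location(entity_set)]
    sub = entity_set.get("sub")
    if sub is None:
        return [""]
    locs = []
    ses = entity_set.get("ses")
    base = [f"sub-{sub}"] + ([f"ses-{ses}"] if ses is not None else [])
    # the file may live at the deepest folder its entities reach, or inside
    # the modality folder below it
    locs.append("/".join(base) + "/")
    if rule.placement == "modality-folder":
        locs.append("/".join(base + [rule.modality]) + "/")
    return locs
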