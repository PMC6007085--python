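"""Metadata inheritance: resolve effective metadata for a data file.

A metadata file applies to a data file when (a) its entities are a submap of
the data file's entities, and (b) it sits at the dataset root or in a
directory on the data file's path (subject folder, session folder, or the
data file's own directory).  Applicable files are ordered shallowest-first,
then least-specific-first (fewer entities first); the effective metadata is a
key-level merge in that order, so the description file closer to the data
prevails key by key.

For TSV sidecars (channels, events) row-level merging is undefined, so the
deepest applicable table wins outright (whole-file precedence).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import AmbiguityError, ResolutionError
from .grammar import RULES
from .model import ArtifactRecord, DatasetTree

__all__ = ["ResolutionTrace", "applicable_sidecars", "resolve", "resolve_table"]


@dataclass
class ResolutionTrace:
    """Provenance of one resolution: which files contributed which keys."""

    target: ArtifactRecord
    applied: list[tuple[str, int, list[str]]] = field(default_factory=list)
    #         (sidecar relative path, directory depth, keys this file finally contributes)
    effective: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target": self.target.relative_path,
            "applied": [
                {"path": p, "depth": d, "keys_contributed": k} for p, d, k in self.applied
            ],
            "effective": self.effective,
        }


def _depth(artifact: ArtifactRecord) -> int:
    return artifact.relative_path.count("/")


def applicable_sidecars(
    tree: DatasetTree,
    target: ArtifactRecord,
    suffix: str,
    extension: Optional[str] = None,
) -> list[ArtifactRecord]:
    """Sidecars of ``suffix`` applicable to ``target``, shallowest first.

    Two distinct applicable sidecars with the same depth *and* the same entity
    count cannot be ordered; that is an :class:`AmbiguityError`.
    """
    if extension is None:
        rule = RULES[suffix]
        exts = sorted(rule.inheritable_extensions) or (
            list(rule.extensions) if rule.extensions else []
        )
    else:
        exts = [extension]
    target_dir = target.parent
    candidates = []
    for a in tree.artifacts:
        if a.relative_path == target.relative_path:
            continue
        if a.entity_set.suffix != suffix or a.entity_set.extension not in exts:
            continue
        if a.is_raw_recording():
            continue
        if not target.entity_set.contains(a.entity_set):
            continue
        # must sit at the root or in a directory on the target's path
        if a.parent != "" and not target_dir.startswith(a.parent):
            continue
        candidates.append(a)
    candidates.sort(key=lambda a: (_depth(a), len(a.entity_set), a.relative_path))
    for x, y in zip(candidates, candidates[1:]):
        if _depth(x) == _depth(y) and len(x.entity_set) == len(y.entity_set):
            raise AmbiguityError(
                f"cannot order applicable sidecars {x.relative_path!r} and "
                f"{y.relative_path!r} (same depth, same specificity) for "
                f"target {target.relative_path!r}"
            )
    return candidates


def resolve(tree: DatasetTree, target: ArtifactRecord, suffix: str = "meg") -> ResolutionTrace:
    """Merge all applicable JSON sidecars into the effective metadata map."""
    order = applicable_sidecars(tree, target, suffix, extension="json")
    trace = ResolutionTrace(target=target)
    effective: dict = {}
    winners: dict[str, str] = {}
    docs = []
    for a in order:
        try:
            doc = json.loads(tree.path(a).read_text("utf-8"))
            if not isinstance(doc, dict):
                raise ValueError("top level is not an object")
        except (OSError, ValueError) as exc:
            raise ResolutionError(
                f"unreadable applicable sidecar {a.relative_path!r}: {exc}"
            ) from exc
        docs.append((a, doc))
        for key, value in doc.items():
            effective[key] = value
            winners[key] = a.relative_path
    for a, doc in docs:
        contributed = sorted(k for k in doc if winners[k] == a.relative_path)
        trace.applied.append((a.relative_path, _depth(a), contributed))
    trace.effective = effective
    return trace


def resolve_table(
    tree: DatasetTree, target: ArtifactRecord, suffix: str
) -> Optional[ArtifactRecord]:
    """Whole-file precedence for TSV sidecars: the deepest applicable wins."""
    order = applicable_sidecars(tree, target, suffix, extension="tsv")
    return order[-1] if order else None
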