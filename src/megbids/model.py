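"""In-memory model of a MEG-BIDS directory tree and the scanner that builds it.

The scanner walks a study folder, classifies every file through the filename
grammar, and records raw vendor payloads stored as directories (CTF ``.ds``)
as single leaf artifacts without descending into them.  ``derivatives/``,
``sourcedata/``, ``code/`` and hidden files are ignored by default.
"""
from __future__ import annotations

import fnmatch
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ContractError, MegBidsError
from .grammar import ENTITY_ORDER, EntitySet, RULES, try_parse_name

__all__ = ["ArtifactRecord", "DatasetTree", "scan_tree", "query", "DEFAULT_IGNORES"]

DEFAULT_IGNORES = ("derivatives", "sourcedata", "code")


def _level_for(relative_path: str) -> str:
    """Hierarchy level from the artifact's directory position."""
    parts = relative_path.split("/")[:-1]
    if not parts:
        return "study"
    if len(parts) == 1:
        return "subject"
    if len(parts) == 2 and parts[1].startswith("ses-"):
        return "session"
    return "run-item"


@dataclass(frozen=True)
class ArtifactRecord:
    """One classified file (or directory payload) in the dataset."""

    relative_path: str
    entity_set: EntitySet
    level: str
    is_directory_payload: bool = False

    @property
    def parent(self) -> str:
        """Containing directory with trailing slash ('' for the root)."""
        idx = self.relative_path.rfind("/")
        return "" if idx < 0 else self.relative_path[: idx + 1]

    @property
    def name(self) -> str:
        return self.relative_path.rsplit("/", 1)[-1]

    def is_raw_recording(self) -> bool:
        """True for a native-format MEG recording payload (not a sidecar)."""
        es = self.entity_set
        if es.suffix != "meg":
            return False
        if self.is_directory_payload:
            return True
        return es.extension in RULES["meg"].raw_extensions


@dataclass
class DatasetTree:
    """Indexed model of a scanned MEG-BIDS directory."""

    root: str
    artifacts: list[ArtifactRecord] = field(default_factory=list)
    unclassified: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> set[str]:
        return {
            a.entity_set.get("sub")
            for a in self.artifacts
            if a.entity_set.get("sub") is not None
        }

    @property
    def sessions(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a in self.artifacts:
            sub, ses = a.entity_set.get("sub"), a.entity_set.get("ses")
            if sub is not None and ses is not None:
                out.setdefault(sub, set()).add(ses)
        return out

    def path(self, artifact: ArtifactRecord | str) -> Path:
        rel = artifact if isinstance(artifact, str) else artifact.relative_path
        return Path(self.root) / rel

    def find(self, relative_path: str) -> Optional[ArtifactRecord]:
        for a in self.artifacts:
            if a.relative_path == relative_path:
                return a
        return None

    def inventory(self) -> pd.DataFrame:
        """Tabular inventory (one row per artifact) for TSV export."""
        rows = []
        for a in self.artifacts:
            d = a.entity_set.as_dict()
            rows.append(
                {
                    "relative_path": a.relative_path,
                    **{k: d.get(k, "n/a") for k in ENTITY_ORDER},
                    "suffix": a.entity_set.suffix,
                    "extension": a.entity_set.extension or "n/a",
                }
            )
        cols = ["relative_path", *ENTITY_ORDER, "suffix", "extension"]
        return pd.DataFrame(rows, columns=cols)


def _ignored(rel: str, name: str, ignore_rules: Sequence[str]) -> bool:
    if name.startswith("."):
        return True
    top = rel.split("/", 1)[0]
    if top in DEFAULT_IGNORES:
        return True
    return any(fnmatch.fnmatch(rel, pat) or fnmatch.fnmatch(name, pat) for pat in ignore_rules)


def _is_directory_payload(name: str) -> bool:
    es, _ = try_parse_name(name)
    if es is None or es.suffix != "meg":
        return False
    if es.extension is not None:
        return es.extension in RULES["meg"].directory_extensions
    # extension-less payload directories must carry entities, so a plain
    # modality folder named "meg" is still descended into
    return len(es.entities) > 0


def scan_tree(root: str | os.PathLike, ignore_rules: Sequence[str] = ()) -> DatasetTree:
    """Scan a directory into a :class:`DatasetTree`.

    Deterministic: entries are visited in lexicographic order.  Directory-style
    raw payloads (names parsing with suffix ``meg`` and a vendor directory
    extension such as ``.ds``) are recorded as single artifacts and not
    descended into.  Unreadable subpaths are recorded as unclassified with a
    read-failure note rather than raising.
    """
    rootp = Path(root)
    if not rootp.is_dir():
        raise MegBidsError(f"dataset root {root!s} does not exist or is not a directory")
    tree = DatasetTree(root=str(rootp))

    def visit(dirpath: Path, rel_dir: str) -> None:
        try:
            entries = sorted(os.listdir(dirpath))
        except OSError as exc:  # pragma: no cover - exercised only on broken perms
            tree.unclassified.append(f"{rel_dir} [read failure: {exc.__class__.__name__}]")
            return
        for name in entries:
            rel = f"{rel_dir}{name}"
            if _ignored(rel, name, ignore_rules):
                continue
            full = dirpath / name
            if full.is_dir():
                if _is_directory_payload(name):
                    es, _ = try_parse_name(name)
                    tree.artifacts.append(
                        ArtifactRecord(rel, es, _level_for(rel), is_directory_payload=True)
                    )
                else:
                    visit(full, rel + "/")
            else:
                es, reason = try_parse_name(name)
                if es is None:
                    tree.unclassified.append(rel)
                else:
                    tree.artifacts.append(ArtifactRecord(rel, es, _level_for(rel)))

    visit(rootp, "")
    tree.artifacts.sort(key=lambda a: a.relative_path)
    tree.unclassified.sort()
    return tree


def query(
    tree: DatasetTree,
    entities: Mapping[str, str] | None = None,
    suffix: Optional[str] = None,
) -> list[ArtifactRecord]:
    """Artifacts whose entity sets contain ``entities`` as a submap.

    Stable order (lexicographic by relative path).  Unknown filter keys are a
    usage error.
    """
    entities = dict(entities or {})
    unknown = set(entities) - set(ENTITY_ORDER)
    if unknown:
        raise ContractError(f"unknown filter keys {sorted(unknown)}")
    out = [
        a
        for a in tree.artifacts
        if a.entity_set.has_submap(entities)
        and (suffix is None or a.entity_set.suffix == suffix)
    ]
    return sorted(out, key=lambda a: a.relative_path)
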