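"""Typed readers/writers for MEG-BIDS metadata artifacts.

Covers the MEG sidecar JSON (``*_meg.json``), coordinate-system JSON
(``*_coordsystem.json``), the anatomical-MRI fiducial JSON (``*_T1w.json``),
``dataset_description.json``, and the TSV tables (channels, events, scans,
participants).

Design contract:

* Readers never abort on a schema problem — they return the parsed document
  plus an accumulated list of :class:`Violation` records (missing required
  key, wrong type, out-of-vocabulary value, ragged row, ...).  Only a
  malformed file (bad JSON, unreadable bytes) yields a single fatal-for-this-
  file violation.
* Writers are deterministic: JSON with schema-ordered keys and 4-space
  indent; TSV with schema column order, LF endings, and the exact lowercase
  sentinel ``n/a`` for missing values.  Repeated writes are byte-identical,
  and write∘read is a fixed point on canonical files.

Schemas are shipped as a JSON document (``megbids/data/sidecar_schemas.json``)
and interpreted by a small engine here; the validator maps the violation codes
to its own issue registry.
"""
from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import pandas as pd

from .errors import ContractError

__all__ = [
    "Violation",
    "SCHEMAS",
    "read_json_sidecar",
    "write_json_sidecar",
    "validate_json_document",
    "read_tsv_table",
    "write_tsv_table",
    "validate_tsv_table",
    "schema_for_suffix",
]

NA = "n/a"

SCHEMAS: dict[str, dict] = json.loads(
    resources.files("megbids.data").joinpath("sidecar_schemas.json").read_text("utf-8")
)


@dataclass(frozen=True)
class Violation:
    """One schema finding for a metadata file."""

    code: str  # JSON-PARSE, MISSING-KEY, TYPE, VALUE, UNKNOWN-KEY,
    #            MISSING-COLUMN, DUPLICATE-COLUMN, RAGGED-ROW, DUPLICATE-VALUE
    location: str  # key, column, or column[row]
    message: str
    severity: str = "error"  # error | info


def schema_for_suffix(suffix: str) -> Optional[dict]:
    return SCHEMAS.get(suffix)


# ---------------------------------------------------------------------------
# JSON documents
# ---------------------------------------------------------------------------

def _is_number(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool) and math.isfinite(v)


def _check_vector_map(key: str, value: Any, spec: Mapping, out: list[Violation]) -> None:
    if not isinstance(value, dict):
        out.append(Violation("TYPE", key, f"{key} must be a mapping of 3-vectors"))
        return
    allowed = spec.get("keys")
    if allowed is not None:
        bad = sorted(set(value) - set(allowed))
        if bad:
            out.append(Violation("VALUE", key, f"unknown landmark keys {bad}"))
        if spec.get("exact_keys") and set(value) != set(allowed):
            out.append(
                Violation("VALUE", key, f"{key} must contain exactly {sorted(allowed)}")
            )
    for label, vec in value.items():
        ok = (
            isinstance(vec, (list, tuple))
            and len(vec) == 3
            and all(_is_number(c) for c in vec)
        )
        if not ok:
            out.append(
                Violation("TYPE", f"{key}.{label}", "coordinate must be a 3-vector of finite numbers")
            )


def _check_value(key: str, value: Any, spec: Mapping, out: list[Violation]) -> None:
    typ = spec.get("type")
    if typ == "string":
        if not isinstance(value, str):
            out.append(Violation("TYPE", key, f"{key} must be a string"))
            return
    elif typ == "boolean":
        if not isinstance(value, bool):
            out.append(Violation("TYPE", key, f"{key} must be a JSON boolean"))
            return
    elif typ == "number":
        if not _is_number(value):
            out.append(Violation("TYPE", key, f"{key} must be a finite number"))
            return
    elif typ == "integer":
        if not (isinstance(value, int) and not isinstance(value, bool)):
            out.append(Violation("TYPE", key, f"{key} must be an integer"))
            return
    elif typ == "array":
        if not isinstance(value, list):
            out.append(Violation("TYPE", key, f"{key} must be an array"))
            return
    elif typ == "object_or_na":
        if not (isinstance(value, dict) or value == NA):
            out.append(Violation("TYPE", key, f'{key} must be an object or "{NA}"'))
            return
    elif typ == "vector_map":
        _check_vector_map(key, value, spec, out)
        return
    if "enum" in spec and value not in spec["enum"]:
        out.append(
            Violation("VALUE", key, f"{key} value {value!r} not in {spec['enum']}")
        )
        return
    if "min" in spec and _is_number(value) and value < spec["min"]:
        out.append(Violation("VALUE", key, f"{key} must be >= {spec['min']}"))
    if "exclusive_min" in spec and _is_number(value) and value <= spec["exclusive_min"]:
        out.append(Violation("VALUE", key, f"{key} must be > {spec['exclusive_min']}"))


def validate_json_document(
    doc: Mapping[str, Any],
    schema_name: str,
    check_required: bool = True,
) -> list[Violation]:
    """Schema-check a parsed JSON document; unknown keys are informational."""
    schema = SCHEMAS[schema_name]
    out: list[Violation] = []
    if check_required:
        for key in schema["required"]:
            if key not in doc:
                out.append(Violation("MISSING-KEY", key, f"required key {key} absent"))
    known = {**schema["required"], **schema["optional"]}
    for key, value in doc.items():
        spec = known.get(key)
        if spec is None:
            out.append(
                Violation("UNKNOWN-KEY", key, f"key {key} not in schema {schema_name}", "info")
            )
        else:
            _check_value(key, value, spec, out)
    return out


def read_json_sidecar(
    path: str | Path,
    schema_name: Optional[str] = None,
    check_required: bool = True,
) -> tuple[Optional[dict], list[Violation]]:
    """Read a JSON sidecar; returns (document, violations).

    The document is returned even when violations are present; only malformed
    JSON yields ``(None, [JSON-PARSE violation])``.
    """
    try:
        text = Path(path).read_text("utf-8")
        doc = json.loads(text)
        if not isinstance(doc, dict):
            raise ValueError("top level is not an object")
    except (OSError, ValueError) as exc:
        return None, [Violation("JSON-PARSE", "<file>", f"cannot parse JSON: {exc}")]
    violations = (
        validate_json_document(doc, schema_name, check_required) if schema_name else []
    )
    return doc, violations


def write_json_sidecar(
    doc: Mapping[str, Any],
    path: str | Path,
    schema_name: Optional[str] = None,
    check_required: bool = True,
) -> None:
    """Serialise ``doc`` deterministically; refuse on (non-info) violations."""
    order: list[str] = []
    if schema_name is not None:
        violations = [
            v
            for v in validate_json_document(doc, schema_name, check_required)
            if v.severity == "error"
        ]
        if violations:
            v = violations[0]
            raise ContractError(f"refusing to write {path}: {v.location}: {v.message}")
        order = SCHEMAS[schema_name].get("key_order", [])
    rank = {k: i for i, k in enumerate(order)}
    keys = sorted(doc, key=lambda k: (rank.get(k, len(rank)), k))
    ordered = {k: doc[k] for k in keys}
    Path(path).write_text(json.dumps(ordered, indent=4) + "\n", "utf-8")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_DATETIME_RE = re.compile(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}")


def _check_cell(col: str, row_idx: int, raw, spec: Mapping, out: list[Violation]) -> None:
    # cells may be native numbers when validating an in-memory table pre-write
    raw = str(raw)
    loc = f"{col}[{row_idx}]"
    typ = spec.get("type")
    if typ in ("number", "number_or_na"):
        try:
            val = float(raw)
        except ValueError:
            out.append(Violation("TYPE", loc, f"{loc}: {raw!r} is not a number"))
            return
        if not math.isfinite(val):
            out.append(Violation("TYPE", loc, f"{loc}: value must be finite"))
            return
        if "min" in spec and val < spec["min"]:
            out.append(Violation("VALUE", loc, f"{loc}: must be >= {spec['min']}"))
            return
    elif typ == "integer":
        if not raw.lstrip("-").isdigit():
            out.append(Violation("TYPE", loc, f"{loc}: {raw!r} is not an integer"))
            return
        if "min" in spec and int(raw) < spec["min"]:
            out.append(Violation("VALUE", loc, f"{loc}: must be >= {spec['min']}"))
            return
    elif typ == "datetime_or_na":
        if not _DATETIME_RE.match(raw):
            out.append(Violation("TYPE", loc, f"{loc}: {raw!r} is not ISO 8601"))
            return
    if "enum" in spec and raw not in spec["enum"]:
        out.append(Violation("VALUE", loc, f"{loc}: {raw!r} not in {spec['enum']}"))
    if "pattern" in spec and not re.fullmatch(spec["pattern"], raw):
        out.append(Violation("VALUE", loc, f"{loc}: {raw!r} does not match {spec['pattern']}"))


def validate_tsv_table(df: pd.DataFrame, schema_name: str) -> list[Violation]:
    """Schema-check an in-memory table (missing cells already ``None``)."""
    schema = SCHEMAS[schema_name]
    cols = schema["columns"]
    out: list[Violation] = []
    for col, spec in cols.items():
        if spec.get("required") and col not in df.columns:
            out.append(Violation("MISSING-COLUMN", col, f"mandatory column {col} absent"))
    if not schema.get("extra_columns", False):
        for col in df.columns:
            if col not in cols:
                out.append(
                    Violation("UNKNOWN-KEY", col, f"column {col} not in schema {schema_name}", "info")
                )
    for col in df.columns:
        spec = cols.get(col)
        if spec is None:
            continue
        series = df[col]
        for row_idx, raw in enumerate(series):
            if raw is None:
                if spec.get("type") in ("number", "integer") or (
                    spec.get("required") and "or_na" not in str(spec.get("type"))
                    and spec.get("type") is not None
                ):
                    out.append(
                        Violation("TYPE", f"{col}[{row_idx}]", f"{col}[{row_idx}] may not be n/a")
                    )
                continue
            _check_cell(col, row_idx, raw, spec, out)
        if spec.get("unique"):
            values = [v for v in series if v is not None]
            dupes = sorted({v for v in values if values.count(v) > 1})
            for d in dupes:
                out.append(
                    Violation("DUPLICATE-VALUE", col, f"duplicate {col} value {d!r}")
                )
    return out


def read_tsv_table(
    path: str | Path, schema_name: Optional[str] = None
) -> tuple[Optional[pd.DataFrame], list[Violation]]:
    """Read a TSV table; returns (DataFrame of str/None cells, violations).

    Tab-delimited, first row is the header, ``n/a`` decodes to ``None``.
    Ragged rows and duplicate headers are reported as violations; ragged rows
    are truncated/padded so the table is still usable downstream.
    """
    out: list[Violation] = []
    try:
        text = Path(path).read_text("utf-8")
    except OSError as exc:
        return None, [Violation("JSON-PARSE", "<file>", f"cannot read file: {exc}")]
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        return None, [Violation("RAGGED-ROW", "<file>", "empty table (no header)")]
    header = lines[0].split("\t")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            out.append(Violation("DUPLICATE-COLUMN", col, f"duplicate header column {col!r}"))
        seen.add(col)
    rows: list[list[Optional[str]]] = []
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != len(header):
            out.append(
                Violation(
                    "RAGGED-ROW",
                    f"row {i}",
                    f"row {i} has {len(cells)} cells, header has {len(header)}",
                )
            )
            cells = (cells + [NA] * len(header))[: len(header)]
        rows.append([None if c == NA else c for c in cells])
    df = pd.DataFrame(rows, columns=header, dtype=object)
    if schema_name is not None:
        out.extend(validate_tsv_table(df, schema_name))
    return df, out


def write_tsv_table(
    df: pd.DataFrame, path: str | Path, schema_name: Optional[str] = None
) -> None:
    """Serialise a table deterministically (schema column order, LF, ``n/a``)."""
    if schema_name is not None:
        violations = [v for v in validate_tsv_table(df, schema_name) if v.severity == "error"]
        if violations:
            v = violations[0]
            raise ContractError(f"refusing to write {path}: {v.location}: {v.message}")
        order = SCHEMAS[schema_name].get("column_order", [])
    else:
        order = []
    rank = {c: i for i, c in enumerate(order)}
    cols = sorted(df.columns, key=lambda c: (rank.get(c, len(rank)), list(df.columns).index(c)))
    lines = ["\t".join(cols)]
    for _, row in df[cols].iterrows():
        lines.append(
            "\t".join(NA if (v is None or (isinstance(v, float) and math.isnan(v))) else str(v) for v in row)
        )
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")
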