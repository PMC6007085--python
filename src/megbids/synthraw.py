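"""Synthetic raw MEG payload format (test-bed stand-in for vendor formats).

Real MEG vendors each ship their own binary container (CTF ``.ds``
directories, Neuromag ``.fif``, KIT ``.con``/``.sqd``); this package treats
all of them as opaque payloads.  For testing the opaque-payload machinery and
the metadata-extraction plugin interface end to end, fixtures use a minimal
self-describing format (extension ``.raw``):

* 64-byte header: 8-byte magic ``SYNMEG01``, little-endian ``uint32`` MEG
  channel count, ``float64`` sampling frequency (Hz), ``float64`` recording
  duration (s), zero padding to 64 bytes;
* a pseudorandom byte body (no physiological content).
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import CurationError

__all__ = ["MAGIC", "HEADER_SIZE", "write_synthetic_raw", "read_synthetic_raw_header"]

MAGIC = b"SYNMEG01"
HEADER_SIZE = 64
_HEADER_FMT = "<8sIdd"
BODY_SIZE = 1024


def write_synthetic_raw(
    path: str | Path,
    n_channels: int,
    sampling_frequency: float,
    duration: float,
    rng: np.random.Generator,
    body_size: int = BODY_SIZE,
) -> None:
    header = struct.pack(_HEADER_FMT, MAGIC, n_channels, sampling_frequency, duration)
    header = header.ljust(HEADER_SIZE, b"\0")
    body = rng.integers(0, 256, size=body_size, dtype=np.uint8).tobytes()
    Path(path).write_bytes(header + body)


def read_synthetic_raw_header(path: str | Path) -> dict:
    """Parse the 64-byte header; raises :class:`CurationError` on a bad file."""
    p = Path(path)
    try:
        blob = p.read_bytes()[:HEADER_SIZE]
        magic, n_channels, sfreq, duration = struct.unpack_from(_HEADER_FMT, blob)
    except (OSError, struct.error) as exc:
        raise CurationError(f"cannot parse synthetic raw header of {path}: {exc}") from exc
    if magic != MAGIC:
        raise CurationError(f"{path}: bad magic {magic!r} (not a synthetic raw file)")
    return {
        "MEGChannelCount": int(n_channels),
        "SamplingFrequency": float(sfreq),
        "RecordingDuration": float(duration),
    }
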