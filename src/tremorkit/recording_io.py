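"""Reading multi-channel text recordings and writing tabular results.

Tremor recordings arrive as plain-text numeric matrices (.txt/.csv): one row
per sample, one column per channel, exported from whatever acquisition system
was used. The sampling rate is never stored in these files, so it must be
supplied by the caller. A :class:`Recording` pairs the sample matrix with the
rate and an ordered list of :class:`ChannelSpec` describing each channel's
role (accelerometer or surface EMG), source column and limb.
"""

from __future__ import annotations

import csv
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ChannelSpecError, InsufficientDataError, ParseError

__all__ = [
    "ChannelRole",
    "Limb",
    "ChannelSpec",
    "Recording",
    "read_recording",
    "write_table",
    "write_recording",
]


class ChannelRole(enum.Enum):
    ACC = "ACC"
    EMG = "EMG"


class Limb(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class ChannelSpec:
    """One channel of a recording: label, role, source column, limb."""

    name: str
    role: ChannelRole
    column: int
    limb: Limb = Limb.NONE

    def __post_init__(self) -> None:
        if self.column < 0:
            raise ChannelSpecError(f"column index must be >= 0, got {self.column}")


@dataclass
class Recording:
    """Multi-channel time series with a common sampling rate.

    ``samples`` has shape (n_samples, n_channels); channel order matches
    ``channels``. Amplitude units are whatever the acquisition system
    produced (ACC in acceleration units, EMG in voltage units).
    """

    samples: np.ndarray
    fs: float
    channels: list[ChannelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.shape[0] < 2:
            raise InsufficientDataError(
                f"a recording needs at least 2 samples, got {self.samples.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ParseError("recording contains non-finite values")
        if self.channels and len(self.channels) != self.samples.shape[1]:
            raise ChannelSpecError(
                f"{len(self.channels)} channel specs for {self.samples.shape[1]} data columns"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by spec name."""
        for i, spec in enumerate(self.channels):
            if spec.name == name:
                return self.samples[:, i]
        raise ChannelSpecError(f"no channel named {name!r}")

    def spec(self, name: str) -> ChannelSpec:
        for spec in self.channels:
            if spec.name == name:
                return spec
        raise ChannelSpecError(f"no channel named {name!r}")


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")

# Sniffing precedence: tab > comma > semicolon > whitespace runs.
_DELIMITERS = ("\t", ",", ";", None)


def _sniff_delimiter(line: str) -> str | None:
    for d in _DELIMITERS[:-1]:
        if d in line:
            return d
    return None  # whitespace runs


def _tokenize(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [t.strip() for t in line.split(delim)]


def read_recording(
    path: str | Path,
    channel_specs: Sequence[ChannelSpec],
    fs: float,
) -> Recording:
    """Load a plain-text numeric matrix into a :class:`Recording`.

    The delimiter is auto-detected from the first data line (precedence:
    tab, comma, semicolon, whitespace runs). One optional leading header
    line of non-numeric tokens is skipped; any later non-numeric token is a
    :class:`ParseError` naming the line and column. ``fs`` is always
    user-supplied — it is never inferred from the file.
    """
    path = Path(path)
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not channel_specs:
        raise ChannelSpecError("at least one ChannelSpec is required")
    cols = [s.column for s in channel_specs]
    if len(set(cols)) != len(cols):
        raise ChannelSpecError(f"duplicate column indices in channel specs: {cols}")

    lines = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not lines:
        raise InsufficientDataError(f"{path}: file contains no data")

    delim = _sniff_delimiter(lines[0][1])
    first_tokens = _tokenize(lines[0][1], delim)
    start = 0
    if not all(_NUMBER_RE.match(t) for t in first_tokens):
        start = 1  # single header line tolerated
        if len(lines) > 1:
            delim = _sniff_delimiter(lines[1][1])

    rows: list[list[float]] = []
    ncols: int | None = None
    for lineno, ln in lines[start:]:
        tokens = _tokenize(ln, delim)
        if ncols is None:
            ncols = len(tokens)
        elif len(tokens) != ncols:
            raise ParseError(
                f"{path}: line {lineno} has {len(tokens)} columns, expected {ncols}",
                line=lineno,
            )
        row = []
        for colno, tok in enumerate(tokens):
            if not _NUMBER_RE.match(tok):
                raise ParseError(
                    f"{path}: non-numeric token {tok!r} at line {lineno}, column {colno + 1}",
                    line=lineno,
                    column=colno + 1,
                )
            row.append(float(tok))
        rows.append(row)

    if len(rows) < 2:
        raise InsufficientDataError(
            f"{path}: found {len(rows)} data rows, need at least 2"
        )
    data = np.asarray(rows, dtype=float)
    bad = [c for c in cols if c >= data.shape[1]]
    if bad:
        raise ChannelSpecError(
            f"{path}: column indices {bad} out of range (file has {data.shape[1]} columns)"
        )
    samples = data[:, cols]
    return Recording(samples=samples, fs=fs, channels=list(channel_specs))


def write_recording(recording: Recording, path: str | Path, delimiter: str = "\t") -> None:
    """Write a recording as the plain-text matrix format the reader consumes."""
    np.savetxt(path, recording.samples, fmt="%.17g", delimiter=delimiter)


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write a sequence of homogeneous records as CSV (with header) or JSON.

    Finite floats round-trip at full double precision (17 significant
    digits). An empty sequence produces a header-only CSV / empty JSON array.
    """
    rows = list(rows)
    path = Path(path)
    if rows:
        fieldset = set(rows[0].keys())
        for r in rows[1:]:
            if set(r.keys()) != fieldset:
                raise ValueError("records do not share a common field set")
    if format == "csv":
        fieldnames = list(rows[0].keys()) if rows else []
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(fieldnames)
            for r in rows:
                writer.writerow(
                    [f"{v:.17g}" if isinstance(v, float) else v for v in (r[k] for k in fieldnames)]
                )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2, default=float)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r} (use 'csv' or 'json')")


def read_table(path: str | Path) -> list[dict[str, object]]:
    """Read back a table written by :func:`write_table` (CSV or JSON by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return json.load(fh)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        out = []
        for rec in reader:
            parsed: dict[str, object] = {}
            for k, v in rec.items():
                try:
                    parsed[k] = float(v)
                except (TypeError, ValueError):
                    parsed[k] = v
            out.append(parsed)
        return out
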