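"""Quantitative Sanger-trace model and its plain-text serialization.

A trace is the quantitative content of a chromatogram: one row per template
position with four non-negative channel intensities (A, C, G, T) and the
called base.  The called base is always the argmax channel; ties and
all-zero rows call ``N`` so low-quality positions are flagged rather than
guessed.

The canonical on-disk form is a TSV dialect with header
``pos\\tA\\tC\\tG\\tT\\tcalled_base`` (UTF-8, LF).  An adapter can ingest
ABIF ``.ab1`` files, but bit-exact round-tripping is guaranteed only for the
TSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
TRACE_HEADER = "pos\tA\tC\tG\tT\tcalled_base"


class TraceParseError(ValueError):
    """A trace table violates the dialect; the message names the line."""


def call_bases(channels: np.ndarray) -> np.ndarray:
    """Call the argmax base per position; ties and all-zero rows give N."""
    channels = np.asarray(channels, dtype=float)
    mx = channels.max(axis=1)
    out = np.array([BASES[i] for i in channels.argmax(axis=1)], dtype="<U1")
    ambiguous = ((channels == mx[:, None]).sum(axis=1) > 1) | (mx <= 0.0)
    out[ambiguous] = "N"
    return out


@dataclass(frozen=True, eq=False)
class TraceData:
    """Per-position four-channel intensities with called bases.

    Positions are the contiguous 1-based run ``start .. start + len - 1``.
    """

    channels: np.ndarray
    called_base: np.ndarray = field(default=None)  # type: ignore[assignment]
    start: int = 1

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[1] != 4 or ch.shape[0] == 0:
            raise ValueError("channels must be a non-empty (n, 4) array")
        if np.any(ch < 0) or not np.all(np.isfinite(ch)):
            raise ValueError("channel intensities must be finite and >= 0")
        object.__setattr__(self, "channels", ch)
        expected = call_bases(ch)
        if self.called_base is None:
            object.__setattr__(self, "called_base", expected)
        else:
            cb = np.asarray(self.called_base, dtype="<U1")
            if cb.shape != (ch.shape[0],):
                raise ValueError("called_base length does not match channels")
            if not np.array_equal(cb, expected):
                bad = int(np.nonzero(cb != expected)[0][0])
                raise ValueError(
                    f"called_base at position {self.start + bad} is not the "
                    f"argmax channel (got {cb[bad]!r}, expected {expected[bad]!r})"
                )
            object.__setattr__(self, "called_base", cb)

    @classmethod
    def from_channels(cls, channels: np.ndarray, start: int = 1) -> "TraceData":
        return cls(channels=np.asarray(channels, dtype=float), start=start)

    def __len__(self) -> int:
        return self.channels.shape[0]

    @property
    def end(self) -> int:
        """Last 1-based position covered by the trace."""
        return self.start + len(self) - 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self))

    def rows(self, positions: np.ndarray) -> np.ndarray:
        """Channel block for the given 1-based positions (bounds-checked)."""
        idx = np.asarray(positions) - self.start
        if idx.size and (idx.min() < 0 or idx.max() >= len(self)):
            raise IndexError(
                f"positions outside trace bounds [{self.start}, {self.end}]"
            )
        return self.channels[idx]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceData):
            return NotImplemented
        return (
            self.start == other.start
            and np.array_equal(self.channels, other.channels)
            and np.array_equal(self.called_base, other.called_base)
        )


def read_trace_table(path: str | Path) -> TraceData:
    """Parse the TSV trace dialect, reporting the offending line on error."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines or lines[0].rstrip("\r") != TRACE_HEADER:
        raise TraceParseError(
            f"line 1: malformed header (expected {TRACE_HEADER!r})"
        )
    positions: list[int] = []
    channels: list[list[float]] = []
    called: list[str] = []
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\r").split("\t")
        if len(fields) != 6:
            raise TraceParseError(f"line {ln}: expected 6 tab-separated fields")
        try:
            pos = int(fields[0])
            vals = [float(v) for v in fields[1:5]]
        except ValueError as exc:
            raise TraceParseError(f"line {ln}: {exc}") from exc
        for v in vals:
            if not np.isfinite(v) or v < 0:
                raise TraceParseError(
                    f"line {ln}: negative or non-finite intensity {v!r}"
                )
        if positions and pos != positions[-1] + 1:
            raise TraceParseError(
                f"line {ln}: non-contiguous position {pos} "
                f"(previous was {positions[-1]})"
            )
        base = fields[5]
        if base not in "ACGTN":
            raise TraceParseError(f"line {ln}: invalid called_base {base!r}")
        positions.append(pos)
        channels.append(vals)
        called.append(base)
    if not positions:
        raise TraceParseError("line 2: table has no data rows")
    try:
        return TraceData(
            channels=np.array(channels, dtype=float),
            called_base=np.array(called, dtype="<U1"),
            start=positions[0],
        )
    except ValueError as exc:
        raise TraceParseError(str(exc)) from exc


def write_trace_table(trace: TraceData, path: str | Path) -> None:
    """Write the TSV dialect; output is byte-deterministic and re-parses equal.

    Intensities use Python's shortest round-trip float repr, so
    ``read_trace_table(write_trace_table(t))`` is lossless.
    """
    out = [TRACE_HEADER]
    for pos, row, base in zip(trace.positions, trace.channels, trace.called_base):
        out.append(
            f"{int(pos)}\t{float(row[0])!r}\t{float(row[1])!r}"
            f"\t{float(row[2])!r}\t{float(row[3])!r}\t{base}"
        )
    Path(path).write_bytes(("\n".join(out) + "\n").encode("utf-8"))


def read_abif(path: str | Path) -> TraceData:
    """Adapter: extract per-peak channel intensities from an ABIF .ab1 file.

    Uses the analyzed data streams (DATA9-12) sampled at the base-call peak
    locations (PLOC), with the channel order taken from the FWO_ field.
    """
    from Bio import SeqIO  # local import: only needed for .ab1 ingestion

    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]
    order = raw["FWO_1"]
    if isinstance(order, bytes):
        order = order.decode("ascii")
    streams = [np.asarray(raw[f"DATA{i}"], dtype=float) for i in (9, 10, 11, 12)]
    ploc = np.asarray(raw.get("PLOC2", raw.get("PLOC1")), dtype=int)
    channels = np.zeros((len(ploc), 4), dtype=float)
    for stream, base in zip(streams, order):
        channels[:, _BASE_INDEX[base]] = np.clip(stream[ploc], 0.0, None)
    return TraceData.from_channels(channels)
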