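"""Concise-data codec: unicode text <-> binary square bit matrices.

Frequently accessed ("concise") data — the library catalog, short
descriptions, and the PCR primer sequences of the paired archival
file — is stored as a square 0/1 matrix that is physically written as
a nanodot array (1 = protruded dot, 0 = flat site).

Framing: a 32-bit big-endian byte-length header, then the UTF-8
payload bits MSB-first, row-major from the top-left, zero-padded to
the smallest square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, isqrt
from typing import Optional, Sequence

import numpy as np

from ._seq import check_alphabet

HEADER_BITS = 32

__all__ = [
    "BitMatrix",
    "CatalogRecord",
    "ConciseFile",
    "MatrixDecodeError",
    "text_to_matrix",
    "matrix_to_text",
    "encode_catalog",
    "decode_catalog",
    "encode_concise_file",
    "decode_concise_file",
]


class MatrixDecodeError(ValueError):
    """Bit matrix does not contain a well-formed payload."""


@dataclass
class BitMatrix:
    """A 0/1 matrix with optional physical pitch metadata.

    ``bits`` may be rectangular when produced by AFM read-out of a
    non-square array; the text codec requires a square matrix.
    """

    bits: np.ndarray
    pitch_nm: Optional[float] = None
    payload_bit_count: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D array")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bit matrix entries must be 0 or 1")

    @property
    def side(self) -> int:
        r, c = self.bits.shape
        if r != c:
            raise ValueError(f"matrix is {r}x{c}, not square")
        return r

    def __eq__(self, other) -> bool:
        return isinstance(other, BitMatrix) and np.array_equal(self.bits, other.bits)


def text_to_matrix(text: str) -> BitMatrix:
    """Encode a unicode string into the smallest square bit matrix."""
    payload = text.encode("utf-8")
    bits = np.unpackbits(
        np.frombuffer(len(payload).to_bytes(4, "big") + payload, dtype=np.uint8)
    )
    side = max(1, ceil(np.sqrt(len(bits))))
    if side * side < len(bits):  # guard against float rounding
        side += 1
    padded = np.zeros(side * side, dtype=np.uint8)
    padded[: len(bits)] = bits
    return BitMatrix(padded.reshape(side, side), payload_bit_count=len(bits))


def matrix_to_text(m: BitMatrix) -> str:
    """Exact inverse of text_to_matrix; padding bits are ignored."""
    flat = m.bits.ravel()
    if len(flat) < HEADER_BITS:
        raise MatrixDecodeError("matrix smaller than the 32-bit header")
    header = np.packbits(flat[:HEADER_BITS]).tobytes()
    n_bytes = int.from_bytes(header, "big")
    capacity = (len(flat) - HEADER_BITS) // 8
    if n_bytes > capacity:
        raise MatrixDecodeError(
            f"header declares {n_bytes} bytes but matrix holds at most {capacity}"
        )
    body = flat[HEADER_BITS : HEADER_BITS + 8 * n_bytes]
    data = np.packbits(body).tobytes() if n_bytes else b""
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise MatrixDecodeError(f"payload is not valid UTF-8: {exc}") from exc


# --------------------------------------------------------------------------
# catalog


@dataclass(frozen=True)
class CatalogRecord:
    """Position of one storage unit in the library grid."""

    unit_id: int
    file_name: str
    row: int
    col: int

    def __post_init__(self) -> None:
        if self.unit_id < 0:
            raise ValueError("unit_id must be >= 0")
        if "|" in self.file_name or "\n" in self.file_name:
            raise ValueError("file_name may not contain '|' or newlines")


def encode_catalog(records: Sequence[CatalogRecord]) -> BitMatrix:
    """Serialize catalog records, one 'id|name|row|col' line each."""
    ids = [r.unit_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_id in catalog")
    lines = [f"{r.unit_id}|{r.file_name}|{r.row}|{r.col}" for r in records]
    return text_to_matrix("\n".join(lines))


def decode_catalog(m: BitMatrix) -> list[CatalogRecord]:
    text = matrix_to_text(m)
    records = []
    if not text:
        return records
    for lineno, line in enumerate(text.split("\n"), start=1):
        parts = line.split("|")
        if len(parts) != 4:
            raise MatrixDecodeError(f"malformed catalog line {lineno}: {line!r}")
        uid, name, row, col = parts
        records.append(CatalogRecord(int(uid), name, int(row), int(col)))
    return records


# --------------------------------------------------------------------------
# concise files (body + embedded primer pair)


@dataclass
class ConciseFile:
    body: str
    forward_primer: str
    reverse_primer: str


_PRIMER_TAG = "PRIMERS|"


def encode_concise_file(body: str, forward_primer: str, reverse_primer: str) -> BitMatrix:
    """Encode a concise text body plus a trailing 'PRIMERS|fwd|rev' line.

    Body lines that could be mistaken for the trailer (or for an escape)
    get a backslash prefix, so any body round-trips.
    """
    for p in (forward_primer, reverse_primer):
        check_alphabet(p)
        if not p:
            raise ValueError("empty primer")
    escaped = []
    for line in body.split("\n"):
        if line.startswith(_PRIMER_TAG) or line.startswith("\\"):
            line = "\\" + line
        escaped.append(line)
    text = "\n".join(escaped + [f"{_PRIMER_TAG}{forward_primer}|{reverse_primer}"])
    return text_to_matrix(text)


def decode_concise_file(m: BitMatrix) -> ConciseFile:
    text = matrix_to_text(m)
    lines = text.split("\n")
    trailer = lines[-1]
    if not trailer.startswith(_PRIMER_TAG):
        raise MatrixDecodeError("concise file lacks a PRIMERS trailer line")
    parts = trailer.split("|")
    if len(parts) != 3:
        raise MatrixDecodeError(f"malformed PRIMERS trailer: {trailer!r}")
    _, fwd, rev = parts
    check_alphabet(fwd)
    check_alphabet(rev)
    unescaped = [ln[1:] if ln.startswith("\\") else ln for ln in lines[:-1]]
    return ConciseFile("\n".join(unescaped), fwd, rev)
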