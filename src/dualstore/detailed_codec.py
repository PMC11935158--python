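"""Byte-payload <-> constraint-compliant DNA strand codec.

Archival ("detailed") data is stored as short synthetic DNA strands.
Each strand carries, inside a fixed-layout *core*:

    mod_primer_a | modulated(index + payload) | modulated(inner RS parity)
                 | mod_primer_b | seed

and the deliverable *full* strand appends PCR amplification anchors and
an outer Reed-Solomon parity region:

    fwd_primer | core | outer RS parity | revcomp(rev_primer)

Two-bit base mapping (A=00, C=01, G=10, T=11) converts bytes to
nucleotides.  A 4-nt *modulation primer* acts as a cyclically repeated
keystream added position-wise mod 4 (a Vigenere cipher over GF(4));
screening candidate primer pairs and seed paddings against GC-content
and homopolymer constraints turns arbitrary payloads into synthesis-
compatible sequences.  Two RS(GF(256), 0x11D) layers protect the data:
an inner code over index+payload+primer ids and an outer code over the
whole core.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import edlib
import numpy as np
from scipy.optimize import linear_sum_assignment

from ._seq import (
    BASES,
    InvalidAlphabetError,
    check_alphabet,
    gc_fraction,
    ints_to_seq,
    max_homopolymer_run,
    revcomp,
    seq_to_ints,
)
from .rs import RSDecodeError, rs_encode, rs_decode

__all__ = [
    "SequenceLayout",
    "StrandRecord",
    "PrimerPair",
    "DEFAULT_LAYOUT",
    "EncodingError",
    "StrandDecodeError",
    "bytes_to_bases",
    "bases_to_bytes",
    "modulate",
    "demodulate",
    "passes_constraints",
    "modulation_primer_pool",
    "build_core",
    "assemble_strand",
    "encode_file",
    "decode_strand",
    "decode_file",
    "design_primer_pairs",
    "sequence_error_rate",
    "edit_distance",
]


class EncodingError(RuntimeError):
    """Payload could not be mapped onto a constraint-compliant strand."""


class StrandDecodeError(ValueError):
    """A sequence could not be decoded back to (index, payload chunk)."""


# --------------------------------------------------------------------------
# layout


@dataclass(frozen=True)
class SequenceLayout:
    """All strand-structure constants and constraint thresholds.

    Lengths are in nucleotides.  The core regions must tile the printed
    124-nt minimum: 2 modulation primers (4 nt each) + 4-nt index +
    payload + 8-nt inner RS + minimum 4-nt seed.
    """

    mod_primer_len: int = 4
    index_len: int = 4
    payload_len: int = 100
    rs_inner_len: int = 8
    seed_min_len: int = 4
    seed_step: int = 4
    seed_max_len: int = 16
    pcr_primer_len: int = 20
    rs_outer_len: int = 8
    min_core_len: int = 124
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 3

    def __post_init__(self) -> None:
        lens = (
            self.mod_primer_len,
            self.index_len,
            self.payload_len,
            self.rs_inner_len,
            self.seed_min_len,
            self.pcr_primer_len,
            self.rs_outer_len,
        )
        if any(v <= 0 for v in lens):
            raise ValueError("all region lengths must be positive")
        if not 0.0 < self.gc_min < self.gc_max < 1.0:
            raise ValueError("need 0 < gc_min < gc_max < 1")
        core = (
            2 * self.mod_primer_len
            + self.index_len
            + self.payload_len
            + self.rs_inner_len
            + self.seed_min_len
        )
        if core != self.min_core_len:
            raise ValueError(
                f"region lengths sum to {core} nt, not min_core_len={self.min_core_len}"
            )
        if self.payload_len < 60:
            raise ValueError("payload must carry at least 60 nt of information")
        if self.min_core_len % 4 or self.seed_step % 4:
            raise ValueError("min_core_len and seed_step must be multiples of 4")
        if self.seed_max_len < self.seed_min_len:
            raise ValueError("seed_max_len < seed_min_len")

    # handy derived quantities
    @property
    def payload_bytes(self) -> int:
        return self.payload_len // 4

    @property
    def full_overhead(self) -> int:
        """Extra nt appended to a core: two PCR primers + outer RS."""
        return 2 * self.pcr_primer_len + self.rs_outer_len

    @property
    def min_full_len(self) -> int:
        return self.min_core_len + self.full_overhead

    @property
    def max_full_len(self) -> int:
        return self.min_full_len + (self.seed_max_len - self.seed_min_len)

    @property
    def index_capacity(self) -> int:
        return 2 ** (2 * self.index_len)

    @property
    def max_file_bytes(self) -> int:
        # 2-byte length prefix occupies part of the first chunk
        return self.index_capacity * self.payload_bytes - 2

    def to_config(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


DEFAULT_LAYOUT = SequenceLayout()


@dataclass(frozen=True)
class PrimerPair:
    """Orthogonal 20-nt PCR primer pair anchoring one file's strands."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            check_alphabet(p)
            if not passes_constraints(p):
                raise ValueError(f"primer {p} violates GC/homopolymer constraints")
        if self.forward == self.reverse:
            raise ValueError("forward and reverse primers must differ")
        if edit_distance(self.forward, self.reverse) < 8:
            raise ValueError("primer pair too similar (edit distance < 8)")


@dataclass
class StrandRecord:
    """One encoded strand with its annotated regions."""

    file_id: int
    index: int
    mod_primer_a: str
    mod_primer_b: str
    seed: str
    core: str
    full: Optional[str] = None


# --------------------------------------------------------------------------
# primitive operations


def bytes_to_bases(data: bytes) -> str:
    """Map bytes to nucleotides, 2 bits per base, MSB first (A=00 .. T=11)."""
    if len(data) == 0:
        return ""
    arr = np.frombuffer(bytes(data), dtype=np.uint8)
    crumbs = np.empty((len(arr), 4), dtype=np.uint8)
    for i, shift in enumerate((6, 4, 2, 0)):
        crumbs[:, i] = (arr >> shift) & 3
    return ints_to_seq(crumbs.ravel())


def bases_to_bytes(seq: str) -> bytes:
    if len(seq) % 4:
        raise ValueError("sequence length must be a multiple of 4")
    if not seq:
        return b""
    vals = seq_to_ints(seq).reshape(-1, 4)
    out = (vals[:, 0] << 6) | (vals[:, 1] << 4) | (vals[:, 2] << 2) | vals[:, 3]
    return out.astype(np.uint8).tobytes()


def modulate(seq: str, primer: str) -> str:
    """Add the primer keystream, repeated cyclically, position-wise mod 4."""
    if not primer:
        raise ValueError("empty modulation primer")
    s = seq_to_ints(seq)
    p = seq_to_ints(primer)
    key = np.resize(p, len(s))
    return ints_to_seq((s + key) % 4)


def demodulate(seq: str, primer: str) -> str:
    s = seq_to_ints(seq)
    p = seq_to_ints(primer)
    key = np.resize(p, len(s))
    return ints_to_seq((s - key) % 4)


def passes_constraints(
    seq: str,
    gc_min: float = DEFAULT_LAYOUT.gc_min,
    gc_max: float = DEFAULT_LAYOUT.gc_max,
    max_homopolymer: int = DEFAULT_LAYOUT.max_homopolymer,
) -> bool:
    """True iff GC fraction lies in [gc_min, gc_max] and no base run exceeds
    max_homopolymer."""
    check_alphabet(seq)
    if not seq:
        raise ValueError("empty sequence")
    return (
        gc_min <= gc_fraction(seq) <= gc_max
        and max_homopolymer_run(seq) <= max_homopolymer
    )


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance via edlib; -1 if k >= 0 and distance exceeds k."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def modulation_primer_pool(layout: SequenceLayout = DEFAULT_LAYOUT) -> list[str]:
    """Deterministic ordered pool of all constraint-passing 4-nt words."""
    pool = []
    for combo in product(BASES, repeat=layout.mod_primer_len):
        word = "".join(combo)
        if passes_constraints(
            word, layout.gc_min, layout.gc_max, layout.max_homopolymer
        ):
            pool.append(word)
    return pool


def _primer_id(primer: str) -> int:
    return int.from_bytes(bases_to_bytes(primer), "big")


def _index_to_bases(index: int, layout: SequenceLayout) -> str:
    return bytes_to_bases(index.to_bytes(layout.index_len // 4, "big"))


# --------------------------------------------------------------------------
# strand construction


def build_core(
    chunk: bytes,
    index: int,
    layout: SequenceLayout = DEFAULT_LAYOUT,
    primer_pool: Optional[Sequence[str]] = None,
    seed_rng: Optional[np.random.Generator] = None,
    file_id: int = 0,
) -> StrandRecord:
    """Screen modulation primers and seed paddings until the assembled core
    satisfies the GC/homopolymer constraints; first success wins.

    Deterministic given the pool order and the state of ``seed_rng``.
    """
    if not 0 <= index < layout.index_capacity:
        raise ValueError(f"index {index} outside [0, {layout.index_capacity})")
    if len(chunk) != layout.payload_bytes:
        raise ValueError(
            f"chunk must be exactly {layout.payload_bytes} bytes, got {len(chunk)}"
        )
    if primer_pool is None:
        primer_pool = modulation_primer_pool(layout)
    if not primer_pool:
        raise ValueError("empty modulation primer pool")
    if seed_rng is None:
        seed_rng = np.random.default_rng(0)

    index_nt = _index_to_bases(index, layout)
    payload_nt = bytes_to_bases(chunk)
    seed_words = [w for w in primer_pool]  # seed drawn from compliant 4-nt words
    n_seed_lens = (layout.seed_max_len - layout.seed_min_len) // layout.seed_step + 1

    for primer_a, primer_b in product(primer_pool, primer_pool):
        inner_msg = (
            index.to_bytes(layout.index_len // 4, "big")
            + chunk
            + bytes([_primer_id(primer_a), _primer_id(primer_b)])
        )
        parity = rs_encode(inner_msg, layout.rs_inner_len // 4)[len(inner_msg):]
        body = (
            primer_a
            + modulate(index_nt + payload_nt, primer_a)
            + modulate(bytes_to_bases(parity), primer_b)
            + primer_b
        )
        if max_homopolymer_run(body) > layout.max_homopolymer:
            continue  # a violation inside the body cannot be fixed by any seed
        for li in range(n_seed_lens):
            seed_len = layout.seed_min_len + li * layout.seed_step
            n_words = seed_len // layout.seed_step
            for _attempt in range(4):
                picks = seed_rng.integers(0, len(seed_words), size=n_words)
                seed = "".join(seed_words[i] for i in picks)
                core = body + seed
                if passes_constraints(
                    core, layout.gc_min, layout.gc_max, layout.max_homopolymer
                ):
                    return StrandRecord(
                        file_id=file_id,
                        index=index,
                        mod_primer_a=primer_a,
                        mod_primer_b=primer_b,
                        seed=seed,
                        core=core,
                    )
    raise EncodingError(
        f"no constraint-compliant encoding found for chunk at index {index}"
    )


def assemble_strand(
    record: StrandRecord,
    primer_pair: PrimerPair,
    layout: SequenceLayout = DEFAULT_LAYOUT,
) -> StrandRecord:
    """Append PCR anchors and the outer RS parity region to a core."""
    core_bytes = bases_to_bytes(record.core)
    parity = rs_encode(core_bytes, layout.rs_outer_len // 4)[len(core_bytes):]
    record.full = (
        primer_pair.forward
        + record.core
        + bytes_to_bases(parity)
        + revcomp(primer_pair.reverse)
    )
    return record


def encode_file(
    data: bytes,
    file_id: int = 0,
    primer_pair: Optional[PrimerPair] = None,
    layout: SequenceLayout = DEFAULT_LAYOUT,
    seed: int = 0,
) -> list[StrandRecord]:
    """Encode a byte payload into a list of full strands.

    The payload is prefixed with its 2-byte little-endian length, chunked
    into payload-sized blocks (zero-padded tail) and one strand is built
    per block with consecutive indices from 0.
    """
    if len(data) > layout.max_file_bytes:
        raise ValueError(
            f"payload of {len(data)} bytes exceeds the "
            f"{layout.max_file_bytes}-byte index space"
        )
    if primer_pair is None:
        primer_pair = design_primer_pairs(1, seed=seed)[0]
    framed = len(data).to_bytes(2, "little") + bytes(data)
    n_chunks = max(1, -(-len(framed) // layout.payload_bytes))
    framed = framed.ljust(n_chunks * layout.payload_bytes, b"\x00")
    pool = modulation_primer_pool(layout)
    strands = []
    for index in range(n_chunks):
        chunk = framed[index * layout.payload_bytes : (index + 1) * layout.payload_bytes]
        rng = np.random.default_rng([seed & 0x7FFFFFFF, file_id, index])
        rec = build_core(chunk, index, layout, pool, rng, file_id=file_id)
        strands.append(assemble_strand(rec, primer_pair, layout))
    return strands


# --------------------------------------------------------------------------
# decoding


def decode_interior(interior: str, layout: SequenceLayout = DEFAULT_LAYOUT):
    """Decode a primer-trimmed interior (core || outer RS parity).

    Returns (index, chunk_bytes, corrected_interior).
    """
    check_alphabet(interior)
    min_len = layout.min_core_len + layout.rs_outer_len
    max_len = min_len + (layout.seed_max_len - layout.seed_min_len)
    if not min_len <= len(interior) <= max_len or len(interior) % 4:
        raise StrandDecodeError(
            f"interior length {len(interior)} outside [{min_len}, {max_len}]"
        )
    codeword = bases_to_bytes(interior)
    try:
        core_bytes = rs_decode(codeword, layout.rs_outer_len // 4)
    except RSDecodeError as exc:
        raise StrandDecodeError(f"outer RS failure: {exc}") from exc
    core = bytes_to_bases(core_bytes)

    p = 0
    primer_a = core[p : p + layout.mod_primer_len]
    p += layout.mod_primer_len
    mod_region = core[p : p + layout.index_len + layout.payload_len]
    p += layout.index_len + layout.payload_len
    rs_region = core[p : p + layout.rs_inner_len]
    p += layout.rs_inner_len
    primer_b = core[p : p + layout.mod_primer_len]

    plain = demodulate(mod_region, primer_a)
    index_nt, payload_nt = plain[: layout.index_len], plain[layout.index_len :]
    parity = bases_to_bytes(demodulate(rs_region, primer_b))
    inner_cw = (
        bases_to_bytes(index_nt)
        + bases_to_bytes(payload_nt)
        + bytes([_primer_id(primer_a), _primer_id(primer_b)])
        + parity
    )
    try:
        inner_msg = rs_decode(inner_cw, layout.rs_inner_len // 4)
    except RSDecodeError as exc:
        raise StrandDecodeError(f"inner RS failure: {exc}") from exc
    n_index_bytes = layout.index_len // 4
    index = int.from_bytes(inner_msg[:n_index_bytes], "big")
    chunk = inner_msg[n_index_bytes : n_index_bytes + layout.payload_bytes]
    outer_parity = rs_encode(core_bytes, layout.rs_outer_len // 4)[len(core_bytes):]
    corrected = core + bytes_to_bases(outer_parity)
    return index, chunk, corrected


def decode_strand(
    seq: str,
    primer_pair: PrimerPair,
    layout: SequenceLayout = DEFAULT_LAYOUT,
):
    """Strict decode of a full strand with exact PCR primer anchors.

    Returns (index, chunk_bytes).  Fuzzy primer location for noisy reads
    lives in :mod:`dualstore.read_decode`.
    """
    check_alphabet(seq)
    if not layout.min_full_len <= len(seq) <= layout.max_full_len:
        raise StrandDecodeError(
            f"strand length {len(seq)} outside "
            f"[{layout.min_full_len}, {layout.max_full_len}]"
        )
    n = layout.pcr_primer_len
    if seq[:n] != primer_pair.forward:
        raise StrandDecodeError("forward primer mismatch")
    if seq[-n:] != revcomp(primer_pair.reverse):
        raise StrandDecodeError("reverse primer mismatch")
    index, chunk, _ = decode_interior(seq[n:-n], layout)
    return index, chunk


def decode_file(
    strands: Sequence[str],
    primer_pair: PrimerPair,
    layout: SequenceLayout = DEFAULT_LAYOUT,
) -> bytes:
    """Inverse of encode_file on a complete, clean strand set."""
    chunks: dict[int, bytes] = {}
    for s in strands:
        index, chunk = decode_strand(s, primer_pair, layout)
        chunks[index] = chunk
    if not chunks:
        raise StrandDecodeError("no strands decoded")
    missing = set(range(max(chunks) + 1)) - set(chunks)
    if missing:
        raise StrandDecodeError(f"missing strand indices: {sorted(missing)}")
    framed = b"".join(chunks[i] for i in range(len(chunks)))
    length = int.from_bytes(framed[:2], "little")
    if length > len(framed) - 2:
        raise StrandDecodeError("length prefix exceeds decoded payload")
    return framed[2 : 2 + length]


# --------------------------------------------------------------------------
# primer design & evaluation


def design_primer_pairs(
    n: int,
    seed: int = 0,
    layout: SequenceLayout = DEFAULT_LAYOUT,
    min_cross_distance: int = 8,
) -> list[PrimerPair]:
    """Draw n constraint-compliant 20-nt primer pairs, every pair of primers
    in the whole set at edit distance >= min_cross_distance."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    chosen: list[str] = []
    guard = 0
    while len(chosen) < 2 * n:
        guard += 1
        if guard > 20000:
            raise RuntimeError("primer design failed to converge")
        cand = ints_to_seq(rng.integers(0, 4, size=layout.pcr_primer_len))
        if not passes_constraints(cand, layout.gc_min, layout.gc_max, layout.max_homopolymer):
            continue
        if any(
            edit_distance(cand, p, k=min_cross_distance - 1) != -1 for p in chosen
        ):
            continue
        chosen.append(cand)
    return [PrimerPair(chosen[2 * i], chosen[2 * i + 1]) for i in range(n)]


def sequence_error_rate(
    originals: Sequence[str],
    recovered: Sequence[str],
    recovered_indices: Optional[Sequence[Optional[int]]] = None,
) -> float:
    """Edit-distance error rate between an original strand set and a
    recovered set.

    Pairs are matched by decoded index when ``recovered_indices`` is given,
    otherwise by minimum-cost one-to-one assignment on Levenshtein
    distance.  Originals left unmatched count their full length; the rate
    is total edit distance over total original length.
    """
    if not originals:
        raise ValueError("originals must be non-empty")
    total_len = sum(len(s) for s in originals)
    matched_dist = 0.0
    unmatched = set(range(len(originals)))
    rec_rest = []
    if recovered_indices is not None:
        if len(recovered_indices) != len(recovered):
            raise ValueError("recovered_indices length mismatch")
        for seq, idx in zip(recovered, recovered_indices):
            if idx is not None and 0 <= idx < len(originals) and idx in unmatched:
                matched_dist += edit_distance(originals[idx], seq)
                unmatched.discard(idx)
            else:
                rec_rest.append(seq)
    else:
        rec_rest = list(recovered)

    if rec_rest and unmatched:
        rows = sorted(unmatched)
        cost = np.array(
            [[edit_distance(originals[i], r) for r in rec_rest] for i in rows],
            dtype=float,
        )
        ri, ci = linear_sum_assignment(cost)
        for a, b in zip(ri, ci):
            matched_dist += cost[a, b]
            unmatched.discard(rows[a])
    penalty = sum(len(originals[i]) for i in unmatched)
    return (matched_dist + penalty) / total_len
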