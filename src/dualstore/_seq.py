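"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


def check_alphabet(seq: str) -> None:
    for ch in seq:
        if ch not in _BASE_TO_INT:
            raise InvalidAlphabetError(f"invalid base {ch!r}")


def seq_to_ints(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_TO_INT[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise InvalidAlphabetError(f"invalid base {exc.args[0]!r}") from None


def ints_to_seq(vals) -> str:
    return "".join(BASES[int(v) & 3] for v in vals)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best
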