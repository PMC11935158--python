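"""Reed-Solomon codes over GF(256).

Systematic RS encoder/decoder on the field GF(2^8) with the primitive
polynomial x^8 + x^4 + x^3 + x^2 + 1 (0x11D) and generator element
alpha = 2.  n parity symbols correct up to floor(n/2) unknown symbol
errors; uncorrectable words raise instead of mis-decoding silently.

Decoding: syndromes -> Berlekamp-Massey error locator -> Chien search
for positions -> direct linear solve (Vandermonde in the error
locations) for the magnitudes, then a final syndrome re-check.
"""

from __future__ import annotations

_PRIM = 0x11D

# exp table doubled so products of two logs never need an explicit mod 255
_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


class RSDecodeError(ValueError):
    """Received word is beyond the correction capacity of the code."""


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return _EXP[_LOG[a] - _LOG[b] + 255]


def _gf_pow(a: int, e: int) -> int:
    if a == 0:
        return 0
    return _EXP[(_LOG[a] * e) % 255]


def _poly_mul(p, q):
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi:
            for j, qj in enumerate(q):
                out[i + j] ^= _gf_mul(pi, qj)
    return out


def _poly_eval(poly, x):
    # coefficients highest order first
    y = 0
    for c in poly:
        y = _gf_mul(y, x) ^ c
    return y


def _generator_poly(n_parity: int):
    g = [1]
    for i in range(n_parity):
        g = _poly_mul(g, [1, _EXP[i]])
    return g


def rs_encode(message: bytes, n_parity: int = 2) -> bytes:
    """Return the systematic codeword ``message || parity``."""
    if n_parity < 1:
        raise ValueError("n_parity must be >= 1")
    if len(message) + n_parity > 255:
        raise ValueError(
            f"message of {len(message)} bytes + {n_parity} parity exceeds the "
            "255-symbol RS block"
        )
    gen = _generator_poly(n_parity)
    rem = [0] * n_parity
    for byte in message:
        factor = byte ^ rem[0]
        rem = rem[1:] + [0]
        if factor:
            for i in range(n_parity):
                rem[i] ^= _gf_mul(gen[i + 1], factor)
    return bytes(message) + bytes(rem)


def _syndromes(codeword, n_parity: int):
    return [_poly_eval(codeword, _EXP[i]) for i in range(n_parity)]


def _berlekamp_massey(synd):
    err_loc = [1]
    old_loc = [1]
    for i in range(len(synd)):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= _gf_mul(err_loc[-(j + 1)], synd[i - j])
        old_loc.append(0)
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = [_gf_mul(c, delta) for c in old_loc]
                old_loc = [_gf_div(c, delta) for c in err_loc]
                err_loc = new_loc
            err_loc = [0] * (len(old_loc) - len(err_loc)) + err_loc
            for j in range(len(old_loc)):
                err_loc[-(j + 1)] ^= _gf_mul(delta, old_loc[-(j + 1)])
    while err_loc and err_loc[0] == 0:
        err_loc = err_loc[1:]
    return err_loc


def _solve_magnitudes(synd, exponents):
    """Solve S_i = sum_j e_j * alpha^(i*k_j) for the magnitudes e_j."""
    m = len(exponents)
    rows = [[_gf_pow(_EXP[k], i) for k in exponents] + [synd[i]] for i in range(m)]
    # Gaussian elimination over GF(256)
    for col in range(m):
        pivot = next((r for r in range(col, m) if rows[r][col]), None)
        if pivot is None:
            raise RSDecodeError("singular error-location system")
        rows[col], rows[pivot] = rows[pivot], rows[col]
        inv = _gf_div(1, rows[col][col])
        rows[col] = [_gf_mul(v, inv) for v in rows[col]]
        for r in range(m):
            if r != col and rows[r][col]:
                f = rows[r][col]
                rows[r] = [v ^ _gf_mul(f, w) for v, w in zip(rows[r], rows[col])]
    return [rows[j][m] for j in range(m)]


def rs_decode(codeword: bytes, n_parity: int = 2) -> bytes:
    """Correct up to floor(n_parity/2) symbol errors; return the message.

    Raises RSDecodeError when the word cannot be corrected.
    """
    if len(codeword) > 255:
        raise ValueError("codeword longer than 255 symbols")
    if len(codeword) <= n_parity:
        raise ValueError("codeword shorter than its parity region")
    synd = _syndromes(codeword, n_parity)
    if max(synd) == 0:
        return bytes(codeword[:-n_parity])
    err_loc = _berlekamp_massey(synd)
    n_errors = len(err_loc) - 1
    if n_errors * 2 > n_parity or n_errors == 0:
        raise RSDecodeError("too many symbol errors to correct")
    n = len(codeword)
    loc_rev = err_loc[::-1]  # lowest order first for the root search
    positions = []  # indices into the codeword, leftmost symbol first
    for i in range(n):
        if _poly_eval(loc_rev, _EXP[i]) == 0:
            positions.append(n - 1 - i)
    if len(positions) != n_errors:
        raise RSDecodeError("error locator degree does not match its roots")
    exponents = [n - 1 - p for p in positions]  # power of x each symbol carries
    magnitudes = _solve_magnitudes(synd, exponents)
    out = bytearray(codeword)
    for pos, mag in zip(positions, magnitudes):
        out[pos] ^= mag
    if max(_syndromes(out, n_parity)) != 0:
        raise RSDecodeError("correction did not produce a valid codeword")
    return bytes(out[:-n_parity])
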