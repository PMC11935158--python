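"""Physical channels between written strands and observed data.

Three simulators:

* nanopore-like sequencing: Poisson coverage per strand, iid per-base
  substitution/insertion/deletion edits, random read orientation;
* thermal aging: first-order decay with an Arrhenius rate constant,
  each strand copy surviving independently;
* repeated access: in-situ amplification (surface-bound templates are
  copied, never consumed) versus pooled PCR access (a consumed
  fraction per access plus per-strand amplification-efficiency bias
  that accumulates over accesses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._seq import ints_to_seq, revcomp, seq_to_ints

R_GAS = 8.314  # J mol^-1 K^-1

__all__ = [
    "ChannelParams",
    "AccessParams",
    "simulate_reads",
    "age_strands",
    "simulate_repeated_access",
    "R_GAS",
]


@dataclass
class ChannelParams:
    """Sequencing-channel parameters (nanopore-like magnitudes)."""

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.03
    coverage: float = 100.0
    revcomp_prob: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.revcomp_prob <= 1:
            raise ValueError("revcomp_prob must lie in [0, 1]")


def _mutate(codes: np.ndarray, params: ChannelParams, rng: np.random.Generator) -> str:
    n = len(codes)
    out = codes.copy()
    if params.sub_rate > 0:
        sub = rng.random(n) < params.sub_rate
        # shift by 1..3 so a substitution always changes the base
        out[sub] = (out[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    keep = (
        rng.random(n) >= params.del_rate
        if params.del_rate > 0
        else np.ones(n, dtype=bool)
    )
    if params.ins_rate > 0:
        ins = rng.random(n + 1) < params.ins_rate
        ins_bases = rng.integers(0, 4, size=int(ins.sum()))
        pieces = []
        bi = 0
        for i in range(n + 1):
            if ins[i]:
                pieces.append(ins_bases[bi])
                bi += 1
            if i < n and keep[i]:
                pieces.append(out[i])
        return ints_to_seq(pieces)
    return ints_to_seq(out[keep])


def simulate_reads(
    strands: Sequence[str],
    params: ChannelParams = ChannelParams(),
    seed: Optional[int] = None,
) -> list[str]:
    """Draw Poisson(coverage) noisy reads from each strand.

    ``seed`` overrides ``params.seed``; with both None the channel is
    non-reproducible.
    """
    if not strands:
        raise ValueError("strands must be non-empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    reads: list[str] = []
    for strand in strands:
        codes = seq_to_ints(strand)
        for _ in range(int(rng.poisson(params.coverage))):
            read = _mutate(codes, params, rng)
            if rng.random() < params.revcomp_prob:
                read = revcomp(read)
            reads.append(read)
    return reads


def age_strands(
    counts: Sequence[int],
    Ea_kJ_mol: float,
    lnA_per_year: float,
    T_K: float,
    t_years: float,
    seed: Optional[int] = None,
) -> np.ndarray:
    """First-order thermal decay of per-strand copy numbers.

    The rate constant k = exp(lnA - Ea/(R*T)) (per year) sets an
    independent survival probability exp(-k*t) for every copy.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if T_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if t_years < 0:
        raise ValueError("t_years must be non-negative")
    k = np.exp(lnA_per_year - Ea_kJ_mol * 1e3 / (R_GAS * T_K))
    p_survive = float(np.exp(-k * t_years))
    rng = np.random.default_rng(seed)
    return rng.binomial(counts, p_survive)


@dataclass
class AccessParams:
    """Repeated-access model parameters.

    consumed_frac is the template fraction lost per pooled access;
    efficiency_sd the spread of per-strand PCR efficiency (mean 0.9,
    truncated to [0, 1]); cycles the re-amplification cycles after each
    pooled access.
    """

    n_accesses: int = 25
    consumed_frac: float = 0.01
    efficiency_sd: float = 0.05
    cycles: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.consumed_frac < 1:
            raise ValueError("consumed_frac must lie in [0, 1)")
        if self.cycles < 0 or self.n_accesses < 0:
            raise ValueError("cycles and n_accesses must be >= 0")


def simulate_repeated_access(
    initial_counts: Sequence[int],
    mode: str,
    params: AccessParams = AccessParams(),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-strand copy-number trajectories over repeated accesses.

    Returns an array of shape (n_accesses + 1, n_strands); row 0 is the
    initial state.  'in_situ' templates are surface-bound and copied
    without consumption, so the trajectory is exactly constant.
    'pooled' access consumes a binomial fraction and re-amplifies with
    per-strand efficiencies drawn once (a sequence property), which
    makes abundance bias accumulate; totals are renormalized to the
    initial pool size after each access.
    """
    counts = np.asarray(initial_counts, dtype=np.int64)
    if (counts <= 0).any():
        raise ValueError("initial_counts must be positive")
    if mode not in ("in_situ", "pooled"):
        raise ValueError(f"unknown access mode {mode!r}")
    n = len(counts)
    traj = np.empty((params.n_accesses + 1, n), dtype=np.int64)
    traj[0] = counts
    if mode == "in_situ":
        traj[1:] = counts
        return traj

    rng = np.random.default_rng(seed)
    eff = np.clip(rng.normal(0.9, params.efficiency_sd, size=n), 0.0, 1.0)
    gain = (1.0 + eff) ** params.cycles
    total = float(counts.sum())
    state = counts.astype(float)
    for a in range(1, params.n_accesses + 1):
        if params.consumed_frac > 0:
            consumed = rng.binomial(state.astype(np.int64), params.consumed_frac)
            state = state - consumed
        state = state * gain
        state = state * (total / state.sum())
        traj[a] = np.maximum(1, np.round(state)).astype(np.int64)
    return traj
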