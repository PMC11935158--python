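"""Density and stability analytics.

Areal densities: a nanodot lattice at spacing d stores rho = d^-2 bits
per area; immobilized DNA strands carrying L bits each at spacing d
store rho = L * d^-2.  Stability: first-order thermal decay with an
Arrhenius rate constant k = A exp(-Ea/RT); ln k is linear in 1/T, so a
least-squares fit of accelerated-aging rates yields the activation
energy and extrapolated half-lives t1/2 = ln2 / k(T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .channel_sim import R_GAS, age_strands

__all__ = [
    "DensitySpec",
    "AgingObservation",
    "ArrheniusFit",
    "nanodot_density",
    "dna_density",
    "rate_from_survival",
    "arrhenius_fit",
    "half_life",
    "synthetic_aging_observations",
    "DEFAULT_EA_KJ_MOL",
    "DEFAULT_LNA_PER_YEAR",
]

# Defaults emulate surface-immobilized DNA: activation energy just under
# 98 kJ/mol (below the 120-155 kJ/mol of free DNA, since strands can also
# scission at the anchoring bond) and a ~40-year half-life at 0 degC.
DEFAULT_EA_KJ_MOL = 97.81
DEFAULT_LNA_PER_YEAR = float(
    np.log(np.log(2) / 40.0) + DEFAULT_EA_KJ_MOL * 1e3 / (R_GAS * 273.15)
)


def nanodot_density(d_nm: float) -> float:
    """Areal bit density (bit mm^-2) of a dot lattice at spacing d (nm)."""
    if d_nm <= 0:
        raise ValueError("spacing must be positive")
    return (1e6 / d_nm) ** 2


def dna_density(L_bits: float, d_nm: float) -> float:
    """Areal density (bit mm^-2) of strands carrying L bits at spacing d."""
    if L_bits <= 0:
        raise ValueError("L_bits must be positive")
    return L_bits * nanodot_density(d_nm)


@dataclass(frozen=True)
class DensitySpec:
    d_nm: float
    L_bits: float = 1.0

    def __post_init__(self) -> None:
        if self.d_nm <= 0 or self.L_bits <= 0:
            raise ValueError("d_nm and L_bits must be positive")

    @property
    def rho(self) -> float:
        return dna_density(self.L_bits, self.d_nm)


@dataclass(frozen=True)
class AgingObservation:
    """Surviving intact fraction after time t at temperature T."""

    T_K: float
    t_years: float
    survival: float

    def __post_init__(self) -> None:
        if self.T_K <= 0:
            raise ValueError("T_K must be positive")
        if not 0 < self.survival <= 1:
            raise ValueError("survival must lie in (0, 1]")


@dataclass(frozen=True)
class ArrheniusFit:
    Ea_kJ_mol: float
    lnA: float  # ln(rate / year^-1)
    r_squared: float

    def rate(self, T_K: float) -> float:
        """Decay rate constant (per year) at temperature T."""
        return float(np.exp(self.lnA - self.Ea_kJ_mol * 1e3 / (R_GAS * T_K)))


def rate_from_survival(obs: AgingObservation) -> float:
    """First-order rate constant k = -ln(survival)/t (per year)."""
    if obs.t_years <= 0:
        raise ValueError("t_years must be positive")
    if obs.survival >= 1.0:
        return 0.0  # no observed decay; rate indistinguishable from zero
    return float(-np.log(obs.survival) / obs.t_years)


def arrhenius_fit(observations: Sequence[AgingObservation]) -> ArrheniusFit:
    """Least-squares fit of ln k against 1/T over aging observations."""
    temps = {o.T_K for o in observations}
    if len(temps) < 2:
        raise ValueError("need observations at >= 2 distinct temperatures")
    inv_T, ln_k = [], []
    for o in observations:
        k = rate_from_survival(o)
        if k <= 0:
            continue
        inv_T.append(1.0 / o.T_K)
        ln_k.append(np.log(k))
    if len(set(inv_T)) < 2:
        raise ValueError("decay observed at fewer than 2 temperatures")
    res = stats.linregress(inv_T, ln_k)
    return ArrheniusFit(
        Ea_kJ_mol=float(-res.slope * R_GAS / 1e3),
        lnA=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def half_life(fit: ArrheniusFit, T_K: float) -> float:
    """Extrapolated half-life (years) at temperature T."""
    if T_K <= 0:
        raise ValueError("T_K must be positive")
    return float(np.log(2) / fit.rate(T_K))


def synthetic_aging_observations(
    Ea_kJ_mol: float = DEFAULT_EA_KJ_MOL,
    lnA_per_year: float = DEFAULT_LNA_PER_YEAR,
    temps_K: Sequence[float] = (333.15, 343.15, 353.15),
    n_copies: int = 100_000,
    seed: Optional[int] = None,
    half_lives_sampled: float = 1.0,
) -> list[AgingObservation]:
    """Accelerated-aging observations from the stochastic decay channel.

    At each temperature the pool is aged for one (by default) half-life
    predicted by the generating parameters, and the surviving fraction
    of n_copies independent copies is recorded.
    """
    rng = np.random.default_rng(seed)
    obs = []
    for T in temps_K:
        k = float(np.exp(lnA_per_year - Ea_kJ_mol * 1e3 / (R_GAS * T)))
        t = half_lives_sampled * np.log(2) / k
        survivors = age_strands(
            [n_copies], Ea_kJ_mol, lnA_per_year, T, t,
            seed=int(rng.integers(2**31)),
        )[0]
        obs.append(AgingObservation(T_K=T, t_years=t, survival=survivors / n_copies))
    return obs
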