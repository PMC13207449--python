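"""Per-element constitutive evolution laws.

Scaffold elements hydrolyze: the normalized molecular weight ``beta``
decays by pseudo-first-order kinetics whose rate is multiplicatively
accelerated by the local von Mises stress (Zhurkov-type bond-scission
kinetics), and the scaffold modulus follows ``beta`` through a saturating
exponential law anchored at the intact scaffold modulus and the tissue
modulus.  Tissue and interface elements remodel: the daily stress stimulus
drives an apparent-density rate with a dead zone, and density maps to
modulus through the cubic power law E = 3790 * rho^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DegradationParams:
    """Hydrolysis kinetics of the PLA scaffold.

    ``lambda0`` is the zero-stress degradation constant (1/day); ``A`` the
    stress-coupling material constant such that ``A*sigma`` carries J/mol
    with sigma in MPa; ``R`` and ``T`` the gas constant and body
    temperature; ``beta_threshold`` the normalized molecular weight below
    which an element counts as fully degraded and changes phase.
    """

    lambda0: float = 0.0075       # 1/day
    A: float = 22.0
    R: float = 8.314              # J/(mol K)
    T: float = 310.0              # K
    beta_threshold: float = 0.01

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not 0 < self.beta_threshold < 1:
            raise ValueError("beta_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class RemodelingParams:
    """Mechanostat remodeling with a dead zone.

    The daily stimulus for a single load case is
    ``phi = n_cycles**(1/m) * sigma_eq``; the density rate is
    ``B*(phi - (1+omega)*k)`` above the dead zone, zero inside it and
    ``B*(phi - (1-omega)*k)`` below (resorption).  ``coefficient`` is the
    density-modulus prefactor of E = c * rho^3 in MPa per (g/cm^3)^3.
    Density is clamped to ``[rho_min, rho_max]`` to keep the power law
    physical.
    """

    B: float = 1.0                # (g/cm^3) / (MPa day)
    k: float = 50.0               # MPa
    omega: float = 0.1
    n_cycles: float = 1000.0      # per day
    m: float = 4.0                # load weight factor
    coefficient: float = 3790.0   # MPa / (g/cm^3)^3
    rho_min: float = 0.01
    rho_max: float = 2.0

    def __post_init__(self):
        if self.k <= 0 or not 0 < self.omega < 1:
            raise ValueError("require k > 0 and 0 < omega < 1")
        if self.n_cycles < 1 or self.m < 1:
            raise ValueError("require n_cycles >= 1 and m >= 1")

    @property
    def upper_threshold(self) -> float:
        return (1 + self.omega) * self.k

    @property
    def lower_threshold(self) -> float:
        return (1 - self.omega) * self.k


def effective_rate(sigma, p: DegradationParams = DegradationParams()):
    """Stress-accelerated degradation rate, 1/day.

    ``lambda_eff = lambda0 * exp(A*sigma / (R*T))``; equals ``lambda0`` at
    zero stress and increases strictly with sigma.
    """
    sigma = np.asarray(sigma, dtype=float)
    return p.lambda0 * np.exp(p.A * sigma / (p.R * p.T))


def update_beta(beta, sigma, dt: float,
                p: DegradationParams = DegradationParams()):
    """Advance the normalized molecular weight across ``dt`` days.

    Piecewise-constant-stress integration: ``beta' = beta *
    exp(-lambda_eff(sigma) * dt)``, which composes as a semigroup over
    successive increments at fixed stress.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    beta = np.asarray(beta, dtype=float)
    return beta * np.exp(-effective_rate(sigma, p) * dt)


def scaffold_modulus(beta, E_scaffold0: float = 1350.0,
                     E_tissue0: float = 10.0):
    """Scaffold Young's modulus from normalized molecular weight.

    ``E(beta) = (E_S0 - E_T) * e/(e-1) * (1 - exp(-beta)) + E_T`` --
    monotone on [0, 1] with E(1) = E_S0 and E(0) = E_T.  The tissue
    modulus entering this law is the *initial* tissue modulus; osteogenesis
    feeds back only through the stress field.
    """
    beta = np.asarray(beta, dtype=float)
    scale = np.e / (np.e - 1.0)
    return (E_scaffold0 - E_tissue0) * scale * (1.0 - np.exp(-beta)) + E_tissue0


def daily_stimulus(sigma_eq, p: RemodelingParams = RemodelingParams()):
    """Daily stress stimulus for a single load case.

    ``phi = (n * sigma_eq^m)^(1/m) = n^(1/m) * sigma_eq`` in MPa.
    """
    sigma_eq = np.asarray(sigma_eq, dtype=float)
    return p.n_cycles ** (1.0 / p.m) * sigma_eq


def density_rate(phi, p: RemodelingParams = RemodelingParams()):
    """Apparent-density rate (g/cm^3 per day) with dead zone.

    Zero for ``(1-omega)k <= phi <= (1+omega)k``, formation above, and
    resorption below.
    """
    phi = np.asarray(phi, dtype=float)
    hi, lo = p.upper_threshold, p.lower_threshold
    return np.where(
        phi > hi, p.B * (phi - hi),
        np.where(phi < lo, p.B * (phi - lo), 0.0),
    )


def density_to_modulus(rho, p: RemodelingParams = RemodelingParams()):
    """E = c * rho^3 (MPa)."""
    rho = np.asarray(rho, dtype=float)
    return p.coefficient * rho**3


def modulus_to_density(E, p: RemodelingParams = RemodelingParams()):
    """Inverse of the cubic density-modulus law."""
    E = np.asarray(E, dtype=float)
    return np.cbrt(E / p.coefficient)


def update_tissue_modulus(E_prev, drho, p: RemodelingParams = RemodelingParams()):
    """Tissue modulus after one density increment.

    ``E_new = c * (cbrt(E_prev / c) + drho)^3`` with the density clamped to
    ``[rho_min, rho_max]``.
    """
    rho = modulus_to_density(E_prev, p) + np.asarray(drho, dtype=float)
    rho = np.clip(rho, p.rho_min, p.rho_max)
    return density_to_modulus(rho, p)


def apply_state_change(beta, labels, scaffold_mask,
                       p: DegradationParams = DegradationParams()):
    """Mask of scaffold elements that fully degraded this step.

    Elements with ``beta < beta_threshold`` leave the scaffold phase (they
    no longer count toward scaffold volume) and become tissue at the
    initial tissue modulus, eligible for remodeling.  Returns the boolean
    mask of converted elements; the caller mutates its state arrays.
    """
    return scaffold_mask & (np.asarray(beta) < p.beta_threshold)
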