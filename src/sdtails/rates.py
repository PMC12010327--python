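"""Born-Markov relaxation rates and the tail-correction transform.

When the spectral density has no features near the electronic gap Omega,
nonradiative population relaxation is controlled by the resonant value
J(Omega), i.e. by the high-frequency tails of the SD peaks.  The
golden-rule (Born-Markov) decay rate of the excited-state population is

    Gamma = 2 pi alpha_x^2 J(Omega) coth(beta Omega / 2)   [cm^-1],

the sum of downhill and uphill rates, and the equilibrium excited-state
population is the two-level canonical value.  Two simulations that
differ only in the functional form of the SD peaks relax at different
rates Gamma_sim vs Gamma_real; given time-scale separation between
dephasing and relaxation the simulated populations can be mapped onto
the target dynamics after the fact:

    p_real(t) = p_eq + (p_sim(t) - p_eq) * exp(-(Gamma_real - Gamma_sim) t).

This transform leaves the equilibrium fixed, is the identity when the
rates match, and maps an exponential decay at Gamma_sim exactly onto one
at Gamma_real.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .heom import SystemSpec, Trajectory
from .spectral_density import SpectralDensityModel, evaluate_sd
from .units import PS_PER_INV_CM1

__all__ = [
    "RateResult",
    "golden_rule_rate",
    "equilibrium_population",
    "adjust_population",
    "tail_dominance_ratio",
]


@dataclass(frozen=True)
class RateResult:
    """Population decay rate at the electronic gap and derived quantities."""

    gamma_cm1: float
    gamma_per_ps: float
    lifetime_ps: float
    p_eq: float
    j_at_gap: float


def equilibrium_population(system: SystemSpec) -> float:
    """Canonical excited-state population e^-beta*Omega/(1 + e^-beta*Omega)."""
    x = system.beta * system.omega_gap
    return 1.0 / (1.0 + math.exp(x)) if x < 700 else 0.0


def golden_rule_rate(
    system: SystemSpec, model: SpectralDensityModel
) -> RateResult:
    """Born-Markov population decay rate Gamma = 2 pi a_x^2 J(Omega) coth(bO/2).

    The lifetime is reported in ps via tau = 1/(2 pi c Gamma) with Gamma
    in cm^-1 (1 cm^-1 <-> 5.3088 ps).
    """
    j_gap = float(evaluate_sd(model, system.omega_gap)) if len(model.peaks) else 0.0
    x = system.beta * system.omega_gap / 2.0
    coth = 1.0 / math.tanh(x)
    gamma = 2.0 * math.pi * system.alpha_x**2 * j_gap * coth
    if gamma > 0:
        lifetime = PS_PER_INV_CM1 / gamma
        gamma_ps = 1.0 / lifetime
    else:
        lifetime = math.inf
        gamma_ps = 0.0
    return RateResult(
        gamma_cm1=gamma,
        gamma_per_ps=gamma_ps,
        lifetime_ps=lifetime,
        p_eq=equilibrium_population(system),
        j_at_gap=j_gap,
    )


def adjust_population(
    p_sim,
    t_fs,
    gamma_sim_per_ps: float,
    gamma_real_per_ps: float,
    p_eq: float,
) -> np.ndarray:
    """Map a simulated population series onto the target decay rate.

    ``p_sim`` may be a :class:`~sdtails.heom.Trajectory` (its excited
    population is used) or an array matching ``t_fs``.  Rates are in
    ps^-1.  Negative adjusted populations indicate a breach of the
    time-scale-separation assumption and raise.
    """
    if isinstance(p_sim, Trajectory):
        t_fs = p_sim.times
        p = p_sim.excited_population
    else:
        p = np.asarray(p_sim, dtype=float)
    t = np.asarray(t_fs, dtype=float)
    dg = (gamma_real_per_ps - gamma_sim_per_ps) * 1e-3  # ps^-1 -> fs^-1
    out = p_eq + (p - p_eq) * np.exp(-dg * t)
    if np.any(out < -1e-12) or np.any(out > 1.0 + 1e-12):
        raise ValueError(
            "adjusted populations leave [0, 1]; the time-scale separation "
            "assumption behind the tail correction does not hold here"
        )
    return out


def tail_dominance_ratio(
    model: SpectralDensityModel,
    omega_gap: float,
    threshold: float = 1e-2,
    n_grid: int = 40001,
) -> tuple[float, bool]:
    """J(Omega) relative to the tallest SD feature.

    Returns (ratio, tail_dominated) where the ratio is J at the gap over
    the maximum of J up to the highest peak frequency, and the flag is
    true when the ratio is below ``threshold`` -- i.e. the SD has no
    features near the transition and relaxation is tail-dominated.
    """
    if not model.peaks:
        return 0.0, True
    w_top = max(
        max(pk.omega + 5 * pk.gamma for pk in model.peaks),
        max((pk.omega2 or 0.0) + 5 * (pk.gamma2 or 0.0) for pk in model.peaks),
        10.0,
    )
    grid = np.linspace(1e-3, w_top, n_grid)
    j_max = float(np.max(evaluate_sd(model, grid)))
    ratio = float(evaluate_sd(model, omega_gap)) / j_max
    return ratio, bool(ratio < threshold)
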