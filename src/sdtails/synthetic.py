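"""Synthetic peak tables and decay trajectories.

Generators that emulate the statistical structure of the experimentally
derived inputs: a broad low-frequency (< 300 cm^-1) solvent feature plus
a finite number of sharp vibrational peaks in the 300-4000 cm^-1 range,
and excited-state population decays with known rate, oscillatory
transient and measurement-like noise.  They make every analysis stage
testable end to end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticSpec", "generate_peak_table", "generate_decay_trajectory"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling ranges for synthetic peak tables (all in cm^-1).

    Defaults mirror the spans of the thymine-in-water table: vibrational
    peaks in 300-4000 cm^-1 with reorganization energies of tens to a
    few hundred cm^-1 and widths of 5-60 cm^-1; one solvent feature with
    lambda of several hundred cm^-1 and width below 300 cm^-1.
    """

    seed: int
    n_peaks: int = 8
    omega_range: tuple[float, float] = (300.0, 4000.0)
    lambda_range: tuple[float, float] = (10.0, 400.0)
    gamma_range: tuple[float, float] = (5.0, 60.0)
    solvent_lambda_range: tuple[float, float] = (400.0, 1000.0)
    solvent_gamma_range: tuple[float, float] = (30.0, 150.0)

    def __post_init__(self) -> None:
        if self.n_peaks < 0 or self.n_peaks % 2:
            raise ValueError("n_peaks must be a nonnegative even number")
        for name in (
            "omega_range",
            "lambda_range",
            "gamma_range",
            "solvent_lambda_range",
            "solvent_gamma_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")


def generate_peak_table(spec: SyntheticSpec) -> pd.DataFrame:
    """One solvent row (omega = 0) plus n_peaks uniform vibrational rows.

    Deterministic in the seed; n_peaks is kept even so 2-peak pairing is
    always possible.
    """
    rng = np.random.default_rng(spec.seed)
    rows = [
        {
            "feature": "Solvent",
            "omega_cm1": 0.0,
            "lambda_cm1": rng.uniform(*spec.solvent_lambda_range),
            "gamma_cm1": rng.uniform(*spec.solvent_gamma_range),
        }
    ]
    for k in range(spec.n_peaks):
        rows.append(
            {
                "feature": f"Peak {k + 1}",
                "omega_cm1": rng.uniform(*spec.omega_range),
                "lambda_cm1": rng.uniform(*spec.lambda_range),
                "gamma_cm1": rng.uniform(*spec.gamma_range),
            }
        )
    return pd.DataFrame(rows)


def generate_decay_trajectory(
    gamma_per_ps: float,
    p_eq: float,
    t_grid_fs,
    p0: float = 1.0,
    oscillation: tuple[float, float, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Excited-state population with known decay rate.

        p(t) = p_eq + (p0 - p_eq) e^{-Gamma t} (1 + amp e^{-t/tau_d} cos wt)
               + Gaussian noise

    ``oscillation`` is (amplitude, frequency cm^-1, damping time fs);
    noise is the standard deviation of seeded additive Gaussian noise.
    Raises if the noiseless series leaves [0, 1].
    """
    from .units import CM1_TO_RAD_PER_FS

    if gamma_per_ps < 0:
        raise ValueError("decay rate must be nonnegative")
    t = np.asarray(t_grid_fs, dtype=float)
    p = p_eq + (p0 - p_eq) * np.exp(-gamma_per_ps * 1e-3 * t)
    if oscillation is not None:
        amp, freq_cm1, tau_d_fs = oscillation
        p = p_eq + (p - p_eq) * (
            1.0 + amp * np.exp(-t / tau_d_fs) * np.cos(CM1_TO_RAD_PER_FS * freq_cm1 * t)
        )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("parameters produce populations outside [0, 1]")
    if noise:
        p = p + np.random.default_rng(seed).normal(0.0, noise, size=t.shape)
    return p
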