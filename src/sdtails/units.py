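"""Unit conventions and physical constants.

All spectroscopic energies/frequencies are carried in wavenumbers (cm^-1)
and times in femtoseconds; picoseconds appear only in reported lifetimes.
Angular frequencies used in time propagation are obtained as
``omega[rad/fs] = 2*pi*c * nu[cm^-1]``.
"""

import math

#: speed of light in cm/fs
C_CM_PER_FS = 2.99792458e-5

#: Boltzmann constant in cm^-1 / K
KB_CM1_PER_K = 0.6950348

#: conversion factor cm^-1 -> rad/fs
CM1_TO_RAD_PER_FS = 2.0 * math.pi * C_CM_PER_FS

#: lifetime (ps) of a decay whose rate is 1 cm^-1: 1/(2*pi*c * 1 cm^-1)
PS_PER_INV_CM1 = 1.0 / (CM1_TO_RAD_PER_FS * 1000.0)  # = 5.3088 ps


def beta_cm(temperature_K: float) -> float:
    """Inverse temperature in cm (i.e. 1/(k_B T) with k_B in cm^-1/K)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB_CM1_PER_K * temperature_K)
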