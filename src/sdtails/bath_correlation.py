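"""Bath correlation function: exact quadrature and exponential expansion.

The bath correlation function (BCF) of a harmonic bath at inverse
temperature beta is, in this package's convention (lambda = int J/omega,
no 1/pi anywhere),

    C(t) = int_0^inf domega J(omega) [coth(beta omega/2) cos(omega t)
                                      - i sin(omega t)].

HEOM requires C(t) as a finite sum of decaying complex exponentials,
C(t) = sum_j c_j exp(-mu_j t) with mu_j = gamma_j + i omega_j.  Because
every supported spectral-density form is rational with simple poles,
the expansion follows from closing the Fourier contour in the lower
half-plane: each vibrational peak contributes one exponential per pole
pair (two for single-peak forms, four for 2-peak forms, one for the
undisplaced Drude-Lorentz solvent), and the Bose/coth factor contributes
purely decaying low-temperature correction terms located at the poles of
its [N-1/N] Pade spectrum decomposition.

The quadrature route (exact coth, adaptive oscillatory quadrature with
analytic tail corrections) is retained as the independent oracle for the
expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, linalg, special

from .spectral_density import PeakSpec, SpectralDensityModel
from .units import CM1_TO_RAD_PER_FS, beta_cm

__all__ = [
    "BCFTerm",
    "BCFExpansion",
    "pade_decomposition",
    "pade_coth",
    "bcf_expansion",
    "bcf_quadrature",
]


@dataclass(frozen=True)
class BCFTerm:
    """One exponential term c * exp(-(gamma + i*omega) t) of the BCF.

    ``c`` is in cm^-2; ``omega`` (oscillation) and ``gamma`` (decay) in
    cm^-1 with gamma > 0.  ``origin`` tags whether the term stems from a
    spectral-density pole or a Pade pole of the thermal factor.
    """

    c: complex
    omega: float
    gamma: float
    origin: str  # "peak_pole" | "pade_pole"

    @property
    def mu(self) -> complex:
        """Complex decay exponent gamma + i*omega in cm^-1."""
        return self.gamma + 1j * self.omega


@dataclass(frozen=True)
class BCFExpansion:
    """Finite exponential representation of C(t) for a model at temperature T."""

    terms: tuple[BCFTerm, ...]
    temperature: float
    model: SpectralDensityModel

    def __len__(self) -> int:
        return len(self.terms)

    def evaluate(self, t_fs) -> np.ndarray:
        """Reconstruct C(t) (cm^-2) on a time grid in fs."""
        t = np.atleast_1d(np.asarray(t_fs, dtype=float)) * CM1_TO_RAD_PER_FS
        out = np.zeros(t.shape, dtype=complex)
        for term in self.terms:
            out += term.c * np.exp(-term.mu * t)
        return out if np.ndim(t_fs) else out[0]

    def conjugate_coefficients(self) -> np.ndarray:
        """Coefficients cbar_j of C*(t) in the same exponential basis.

        C*(t) = sum_j cbar_j exp(-mu_j t); for every term there is a
        partner term with exponent mu* (itself when omega = 0), so
        cbar_j = conj(c of the partner).
        """
        mus = np.array([term.mu for term in self.terms])
        out = np.empty(len(mus), dtype=complex)
        scale = max(np.abs(mus).max(), 1.0)
        for j, mu in enumerate(mus):
            k = int(np.argmin(np.abs(mus - np.conj(mu))))
            if abs(mus[k] - np.conj(mu)) > 1e-8 * scale:
                raise ValueError("expansion is not closed under conjugation")
            out[j] = np.conj(self.terms[k].c)
        return out


# ---------------------------------------------------------------------------
# [N-1/N] Pade spectrum decomposition of the Bose/coth factor


def pade_decomposition(n_pade: int) -> tuple[np.ndarray, np.ndarray]:
    """Poles and residues of the bosonic [N-1/N] Pade spectrum decomposition.

    Returns (xi, eta) such that, with x = beta*omega (dimensionless),

        1/(e^x - 1)  ~=  1/x - 1/2 + sum_j 2 eta_j x / (x^2 + xi_j^2),

    equivalently  coth(y) ~= 1/y + sum_j 2 eta_j y / (y^2 + (xi_j/2)^2).
    The xi_j are the Pade analogues of the Matsubara frequencies 2*pi*j
    and approach them for j << N.
    """
    if n_pade < 0:
        raise ValueError("n_pade must be >= 0")
    if n_pade == 0:
        return np.empty(0), np.empty(0)
    N = n_pade
    m = np.arange(1, 2 * N)
    b = 1.0 / np.sqrt((2 * m + 1) * (2 * m + 3))
    ev = linalg.eigh_tridiagonal(np.zeros(2 * N), b, eigvals_only=True)
    xi = np.sort(2.0 / ev[ev > 1e-14])[:N]

    if N > 1:
        m2 = np.arange(1, 2 * N - 1)
        b2 = 1.0 / np.sqrt((2 * m2 + 3) * (2 * m2 + 5))
        ev2 = linalg.eigh_tridiagonal(np.zeros(2 * N - 1), b2, eigvals_only=True)
        zeta = np.sort(2.0 / ev2[ev2 > 1e-14])[: N - 1]
    else:
        zeta = np.empty(0)

    eta = np.empty(N)
    pref = 0.5 * N * (2 * N + 3)
    for j in range(N):
        num = np.prod(zeta**2 - xi[j] ** 2)
        den = np.prod(np.delete(xi, j) ** 2 - xi[j] ** 2)
        eta[j] = pref * num / den
    return xi, eta


def pade_coth(y, n_pade: int):
    """[N-1/N] Pade approximant of coth(y); vectorized in y."""
    y = np.asarray(y, dtype=complex)
    xi, eta = pade_decomposition(n_pade)
    out = 1.0 / y
    for x, e in zip(xi, eta):
        out = out + 2.0 * e * y / (y * y + (x / 2.0) ** 2)
    return out


# ---------------------------------------------------------------------------
# exponential expansion by residues


def bcf_expansion(
    model: SpectralDensityModel | PeakSpec,
    temperature: float,
    n_pade: int = 8,
) -> BCFExpansion:
    """Exponential BCF expansion of a composite spectral density.

    Closes C(t) = (1/2) int_-inf^inf J(omega) [coth(beta omega/2) + 1]
    e^{-i omega t} domega in the lower half-plane.  Peak poles at
    +-omega_k - i gamma_k give oscillating terms exp(-(gamma_k -+
    i omega_k) t); the poles of the Pade-approximated coth on the
    negative imaginary axis give purely decaying low-temperature terms.
    The coth factor at the peak poles is evaluated with the same Pade
    approximant, so the expansion is the exact BCF of the approximated
    thermal kernel.
    """
    if isinstance(model, PeakSpec):
        model = SpectralDensityModel([model])
    beta = beta_cm(temperature)
    xi, eta = pade_decomposition(n_pade)
    nu = xi / beta  # Pade pole frequencies in cm^-1

    def thermal_factor(w: complex) -> complex:
        # coth_Pade(beta w / 2) + 1
        return complex(pade_coth(beta * w / 2.0, n_pade)) + 1.0

    terms: list[BCFTerm] = []
    for i, pk in enumerate(model.peaks):
        if not pk.has_simple_poles():
            raise ValueError(
                f"peak {i} ({pk.form}) has non-simple poles; the exponential "
                "BCF expansion requires simple poles"
            )
        num, poles = pk.numerator(), pk.poles()
        for j, p in enumerate(poles):
            if p.imag >= 0:
                continue
            res = np.polynomial.polynomial.polyval(p, num) / np.prod(
                p - np.delete(poles, j)
            )
            c = -1j * math.pi * res * thermal_factor(p)
            terms.append(
                BCFTerm(c=complex(c), omega=p.real, gamma=-p.imag, origin="peak_pole")
            )

    for nu_j, eta_j in zip(nu, eta):
        w = -1j * nu_j
        j_val = _eval_model(model, w)
        c = -1j * math.pi * j_val * 2.0 * eta_j / beta
        if abs(c.imag) > 1e-9 * abs(c.real):  # pragma: no cover - sanity
            raise RuntimeError("Pade term acquired an imaginary part")
        terms.append(BCFTerm(c=complex(c.real), omega=0.0, gamma=nu_j, origin="pade_pole"))

    return BCFExpansion(terms=tuple(terms), temperature=temperature, model=model)


def _eval_model(model: SpectralDensityModel, w: complex) -> complex:
    total = 0.0 + 0.0j
    for pk in model.peaks:
        num, poles = pk.numerator(), pk.poles()
        total += np.polynomial.polynomial.polyval(w, num) / np.prod(w - poles)
    return total


# ---------------------------------------------------------------------------
# quadrature oracle


def bcf_quadrature(
    model: SpectralDensityModel | PeakSpec,
    temperature: float,
    t_grid_fs,
    omega_max: float | None = None,
) -> np.ndarray:
    """C(t) by adaptive oscillatory quadrature with exact coth (the oracle).

    The integral is split at twice the highest peak frequency and carried
    to ``omega_max`` (default 2e5 cm^-1) with QUADPACK's oscillatory
    rule; the residual omega^-1 tail of Lorentzian-type forms is added
    analytically via sine/cosine integrals.  Note that for those forms
    the real part of C(0) diverges logarithmically with the cutoff; the
    oracle is meaningful for t > 0.
    """
    if isinstance(model, PeakSpec):
        model = SpectralDensityModel([model])
    beta = beta_cm(temperature)
    if omega_max is None:
        omega_max = 2.0e5

    w_split = 2.0 * max(
        max((abs(pk.omega) + pk.gamma) for pk in model.peaks),
        max((pk.omega2 or 0.0) + (pk.gamma2 or 0.0) for pk in model.peaks),
        1.0,
    )

    # total omega^-1 tail prefactor (forms with faster tails contribute 0)
    a_tail = 0.0
    for pk in model.peaks:
        num, poles = pk.numerator(), pk.poles()
        deg = int(np.max(np.nonzero(num)))
        if deg - len(poles) == -1:
            a_tail += float(num[deg])

    def j_coth(w):
        # J(w)*coth(beta w/2); J ~ c*w^s (s >= 1) at the origin, so the
        # product is finite there -- evaluate just off zero.
        w = max(w, 1e-7)
        return _eval_model_real(model, w) / np.tanh(beta * w / 2.0)

    def j_only(w):
        return _eval_model_real(model, w)

    pts = sorted(
        {abs(pk.omega) for pk in model.peaks if pk.omega > 0}
        | {pk.omega2 for pk in model.peaks if pk.omega2}
    )

    t_arr = np.atleast_1d(np.asarray(t_grid_fs, dtype=float))
    out = np.empty(t_arr.shape, dtype=complex)
    for i, t in enumerate(t_arr):
        kappa = CM1_TO_RAD_PER_FS * t  # phase = kappa * omega
        re = _osc_quad(j_coth, 0.0, w_split, kappa, "cos", pts)
        re += _osc_quad(j_coth, w_split, omega_max, kappa, "cos", None)
        im = _osc_quad(j_only, 0.0, w_split, kappa, "sin", pts)
        im += _osc_quad(j_only, w_split, omega_max, kappa, "sin", None)
        # analytic omega^-1 tail beyond omega_max (coth ~ 1 there)
        if a_tail and kappa > 0:
            si, ci = special.sici(kappa * omega_max)
            re += -a_tail * ci
            im += a_tail * (math.pi / 2.0 - si)
        out[i] = re - 1j * im  # at t = 0 the 1/omega tail is cutoff-limited

    return out if np.ndim(t_grid_fs) else out[0]


def _eval_model_real(model: SpectralDensityModel, w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    total = np.zeros(w.shape)
    for pk in model.peaks:
        num, poles = pk.numerator(), pk.poles()
        denom = np.ones(w.shape, dtype=complex)
        for p in poles:
            denom = denom * (w - p)
        total = total + np.real(
            np.polynomial.polynomial.polyval(w.astype(complex), num) / denom
        )
    return total


def _osc_quad(f, a, b, kappa, kind, points):
    if kappa == 0.0:
        if kind == "sin":
            return 0.0
        val, _ = integrate.quad(f, a, b, points=points, limit=500)
        return val
    if points:
        # QUADPACK's oscillatory rule does not take breakpoints; integrate
        # each peak-bounded panel separately.
        edges = [a] + [p for p in points if a < p < b] + [b]
        return sum(
            integrate.quad(f, lo, hi, weight=kind, wvar=kappa, limit=500)[0]
            for lo, hi in zip(edges[:-1], edges[1:])
        )
    val, _ = integrate.quad(f, a, b, weight=kind, wvar=kappa, limit=500)
    return val
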