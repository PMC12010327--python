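"""Hierarchical equations of motion for the dissipative two-level system.

The system is a two-level chromophore with electronic gap Omega coupled
to a single harmonic bath through the mixed operator
S = alpha_z * sigma_z + alpha_x * sigma_x, starting from a factorized
system (x) thermal-bath state.  Given the bath correlation function as a
finite sum of decaying exponentials C(t) = sum_j c_j exp(-mu_j t), the
reduced dynamics is propagated exactly (up to hierarchy truncation) with
the standard scaled-ADO hierarchy:

    d rho_n/dt = -i [H_s, rho_n] - (sum_j n_j mu_j) rho_n
                 - i sum_j sqrt((n_j+1)|c_j|) [S, rho_{n+e_j}]
                 - i sum_j sqrt(n_j/|c_j|) (c_j S rho_{n-e_j}
                                            - cbar_j rho_{n-e_j} S)

where cbar_j are the coefficients of C*(t) in the same exponential
basis.  The hierarchy is truncated at a global tier L (sum_j n_j <= L),
optionally with a per-term cap, and terminated by dropping couplings out
of the top tier.  The full right-hand side is assembled once as a sparse
matrix and integrated with an adaptive embedded Dormand-Prince
Runge-Kutta scheme (absolute/relative tolerances 1e-8/1e-5 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .bath_correlation import BCFExpansion
from .units import CM1_TO_RAD_PER_FS, beta_cm

__all__ = [
    "SystemSpec",
    "Trajectory",
    "build_hierarchy",
    "hierarchy_size",
    "propagate",
]

SIGMA_Z = np.array([[-1.0, 0.0], [0.0, 1.0]])  # |0> ground, |1> excited
SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass(frozen=True)
class SystemSpec:
    """Two-level system: gap Omega (cm^-1), couplings, temperature (K)."""

    omega_gap: float
    alpha_z: float
    alpha_x: float
    temperature: float

    def __post_init__(self) -> None:
        if self.omega_gap <= 0:
            raise ValueError("gap must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        """Inverse temperature in cm."""
        return beta_cm(self.temperature)

    def hamiltonian(self) -> np.ndarray:
        """H_s = (Omega/2) sigma_z in cm^-1."""
        return 0.5 * self.omega_gap * SIGMA_Z

    def coupling_operator(self) -> np.ndarray:
        """S = alpha_z sigma_z + alpha_x sigma_x (dimensionless)."""
        return self.alpha_z * SIGMA_Z + self.alpha_x * SIGMA_X


def equal_superposition() -> np.ndarray:
    """Default initial state: (|0> + |1>)/sqrt(2) as a density matrix."""
    return np.full((2, 2), 0.5)


@dataclass
class Trajectory:
    """Reduced density-matrix elements on a time grid (fs)."""

    times: np.ndarray
    rho00: np.ndarray
    rho11: np.ndarray
    rho01: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def coherence(self) -> np.ndarray:
        """|rho01(t)|."""
        return np.abs(self.rho01)

    @property
    def excited_population(self) -> np.ndarray:
        return self.rho11

    def validate(self, tol: float = 1e-6) -> None:
        """Trace conservation and positivity up to truncation error."""
        trace_err = np.max(np.abs(self.rho00 + self.rho11 - 1.0))
        if trace_err > tol:
            raise ValueError(f"trace deviates from 1 by {trace_err:.2e}")
        bound = np.sqrt(np.clip(self.rho00 * self.rho11, 0.0, None)) + tol
        if np.any(self.coherence > bound):
            raise ValueError("coherence exceeds the positivity bound")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_fs": self.times,
                "rho00": self.rho00,
                "rho11": self.rho11,
                "re_rho01": self.rho01.real,
                "im_rho01": self.rho01.imag,
            }
        )


def hierarchy_size(n_terms: int, depth: int) -> int:
    """Number of ADOs under global-tier truncation: C(K + L, L)."""
    return math.comb(n_terms + depth, depth)


def build_hierarchy(
    n_terms: int,
    depth: int,
    cap: int | None = None,
    max_ados: int = 2_000_000,
) -> list[tuple[int, ...]]:
    """Lexicographically ordered ADO multi-indices with tier <= depth.

    ``cap`` additionally limits each index component (the literal
    per-term-cutoff reading of a hierarchy cutoff).  Raises if the
    projected hierarchy exceeds ``max_ados``.
    """
    if n_terms < 1 or depth < 0:
        raise ValueError("need n_terms >= 1 and depth >= 0")
    projected = hierarchy_size(n_terms, depth)
    if projected > max_ados:
        raise MemoryError(
            f"hierarchy would contain {projected} ADOs (budget {max_ados})"
        )
    out: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int, budget: int) -> None:
        if remaining == 0:
            out.append(prefix)
            return
        top = budget if cap is None else min(budget, cap)
        for n in range(top + 1):
            rec(prefix + (n,), remaining - 1, budget - n)

    rec((), n_terms, depth)
    out.sort()
    return out


def _liouvillian(A: np.ndarray) -> np.ndarray:
    """Superoperator of the commutator [A, .] on a row-major-flattened rho."""
    eye = np.eye(2)
    return np.kron(A, eye) - np.kron(eye, A.T)


def build_generator(
    system: SystemSpec,
    expansion: BCFExpansion,
    depth: int,
    cap: int | None = None,
    max_ados: int = 2_000_000,
) -> tuple[sparse.csr_matrix, list[tuple[int, ...]]]:
    """Assemble the sparse HEOM generator in rad/fs.

    Returns the generator matrix acting on the stacked flattened ADOs and
    the ordered multi-index list (the physical density matrix is index of
    the all-zeros tuple).
    """
    terms = expansion.terms
    K = len(terms)
    indices = build_hierarchy(K, depth, cap=cap, max_ados=max_ados)
    pos = {n: i for i, n in enumerate(indices)}
    u = CM1_TO_RAD_PER_FS

    c = np.array([t.c for t in terms]) * u * u  # cm^-2 -> (rad/fs)^2
    cbar = expansion.conjugate_coefficients() * u * u
    mu = np.array([t.mu for t in terms]) * u  # cm^-1 -> rad/fs
    absc = np.abs(c)

    Ls = _liouvillian(system.hamiltonian() * u)
    S = system.coupling_operator()
    eye = np.eye(2)
    S_left = np.kron(S, eye)
    S_right = np.kron(eye, S.T)
    LS = S_left - S_right

    rows: list[int] = []
    cols: list[int] = []
    vals: list[complex] = []

    def add_block(bi: int, bj: int, block: np.ndarray) -> None:
        nz = np.nonzero(block)
        rows.extend(4 * bi + nz[0])
        cols.extend(4 * bj + nz[1])
        vals.extend(block[nz])

    for n, i in pos.items():
        decay = complex(np.dot(n, mu))
        add_block(i, i, -1j * Ls - decay * np.eye(4))
        for j in range(K):
            # raise: coupling to tier above
            up = list(n)
            up[j] += 1
            key = tuple(up)
            if key in pos:
                fac = -1j * math.sqrt((n[j] + 1) * absc[j])
                add_block(i, pos[key], fac * LS)
            # lower: coupling to tier below
            if n[j] > 0:
                dn = list(n)
                dn[j] -= 1
                fac = math.sqrt(n[j] / absc[j])
                block = -1j * fac * (c[j] * S_left - cbar[j] * S_right)
                add_block(i, pos[tuple(dn)], block)

    dim = 4 * len(indices)
    gen = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(dim, dim), dtype=complex)
    )
    return gen, indices


def propagate(
    system: SystemSpec,
    expansion: BCFExpansion,
    depth: int,
    t_final_fs: float,
    rho0: np.ndarray | None = None,
    dt_out_fs: float = 0.25,
    cap: int | None = None,
    atol: float = 1e-8,
    rtol: float = 1e-5,
    max_ados: int = 2_000_000,
) -> Trajectory:
    """Propagate the reduced density matrix with HEOM.

    All auxiliary density operators start at zero (factorized initial
    condition); ``rho0`` defaults to the equal superposition so that both
    dephasing and population relaxation are visible.
    """
    gammas = np.array([t.gamma for t in expansion.terms])
    if np.any(gammas <= 0):
        raise ValueError("every BCF term must decay (gamma > 0)")
    if rho0 is None:
        rho0 = equal_superposition()
    rho0 = np.asarray(rho0, dtype=complex)
    if rho0.shape != (2, 2) or abs(np.trace(rho0) - 1.0) > 1e-10:
        raise ValueError("rho0 must be a trace-one 2x2 density matrix")
    if np.abs(rho0 - rho0.conj().T).max() > 1e-10:
        raise ValueError("rho0 must be Hermitian")

    gen, indices = build_generator(
        system, expansion, depth, cap=cap, max_ados=max_ados
    )
    y0 = np.zeros(gen.shape[0], dtype=complex)
    y0[:4] = rho0.reshape(-1)

    t_eval = np.arange(0.0, t_final_fs + 0.5 * dt_out_fs, dt_out_fs)
    sol = solve_ivp(
        lambda t, y: gen.dot(y),
        (0.0, float(t_final_fs)),
        y0,
        method="RK45",
        t_eval=t_eval,
        atol=atol,
        rtol=rtol,
    )
    if not sol.success:  # pragma: no cover - integrator failure path
        raise RuntimeError(f"HEOM propagation failed: {sol.message}")

    rho = sol.y[:4, :]
    traj = Trajectory(
        times=sol.t,
        rho00=rho[0].real,
        rho11=rho[3].real,
        rho01=rho[1],
        diagnostics={
            "n_ados": len(indices),
            "n_terms": len(expansion.terms),
            "depth": depth,
            "cap": cap,
            "nfev": sol.nfev,
        },
    )
    traj.validate(tol=1e-4)
    return traj
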