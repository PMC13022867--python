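"""AO-basis quantities and restricted Hartree-Fock reference solutions.

The central container is :class:`AOContext`: everything a surrogate program
needs about one geometry (overlap, core Hamiltonian, two-electron integrals,
nuclear repulsion, electron pairs), computed once and reused across every
search iteration. The restricted SCF solver is a conventional DIIS-accelerated
Roothaan iteration and provides the reference energies and converged Fock
matrices that the program search is trained against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .basis import build_basis
from .geometry import Geometry
from . import integrals

__all__ = [
    "AOContext",
    "MOSet",
    "SCFResult",
    "SCFConvergenceError",
    "build_ao_context",
    "generalized_eigensolve",
    "density_from_mos",
    "fock_from_density",
    "hf_energy",
    "reference_scf",
]


class SCFConvergenceError(RuntimeError):
    """Raised when the Roothaan iteration fails to reach the threshold."""


@dataclass(frozen=True)
class MOSet:
    """Molecular-orbital coefficients (columns) and ascending eigenvalues."""

    coeffs: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class AOContext:
    """Per-geometry AO integrals in atomic units."""

    S: np.ndarray
    Hcore: np.ndarray
    eri: np.ndarray  # (nao,)*4, chemists' notation (mu nu | lam sig)
    E_nuc: float
    n_ao: int
    n_occ: int
    basis_label: str
    geometry: Geometry = None
    V_per_atom: np.ndarray = None  # kept for gradient evaluation
    T_kin: np.ndarray = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.linalg.eigvalsh(self.S)
        if w.min() < 1e-8:
            raise ValueError(
                f"near-linear dependence in basis (min overlap eigenvalue {w.min():.3e})"
            )


def build_ao_context(geometry: Geometry, basis_label: str = "STO-3G") -> AOContext:
    """Compute S, Hcore, two-electron integrals and E_nuc for a geometry."""
    basis = build_basis(geometry, basis_label)
    S, T = integrals.overlap_kinetic_kernel(
        basis.centers, basis.shell_l, basis.alphas, basis.coefs, basis.ao_offset,
        integrals._COMP,
    )
    xyz = geometry.coords_bohr()
    charges = geometry.charges
    V_at = integrals.nuclear_attraction(basis, xyz, charges)
    eri = integrals.electron_repulsion(basis)
    e_nuc = 0.0
    for i in range(geometry.natom):
        for j in range(i):
            e_nuc += charges[i] * charges[j] / np.linalg.norm(xyz[i] - xyz[j])
    nelec = geometry.n_electrons
    ctx = AOContext(
        S=S,
        Hcore=T + V_at.sum(axis=0),
        eri=eri,
        E_nuc=float(e_nuc),
        n_ao=S.shape[0],
        n_occ=nelec // 2,
        basis_label=basis.label,
        geometry=geometry,
        V_per_atom=V_at,
        T_kin=T,
    )
    if ctx.n_occ > ctx.n_ao:
        raise ValueError("more electron pairs than basis functions")
    return ctx


def _fix_eigvec_signs(c: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """First nonzero entry of every column made positive (determinism)."""
    c = c.copy()
    for j in range(c.shape[1]):
        col = c[:, j]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if len(nz) and col[nz[0]] < 0:
            c[:, j] = -col
    return c


def generalized_eigensolve(M: np.ndarray, S: np.ndarray, symmetry_tol: float = 1e-10) -> MOSet:
    """Solve M c = S c eps with S-orthonormal columns, ascending eigenvalues."""
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite workspace matrix")
    if np.max(np.abs(M - M.T)) > symmetry_tol * max(1.0, np.max(np.abs(M))):
        raise ValueError("workspace matrix is not symmetric")
    w, c = scipy.linalg.eigh((M + M.T) / 2.0, S)
    return MOSet(coeffs=_fix_eigvec_signs(c), eigenvalues=w)


def density_from_mos(mos: MOSet, n_occ: int) -> np.ndarray:
    """P = 2 C_occ C_occ^T over the n_occ lowest orbitals."""
    nao = mos.coeffs.shape[0]
    if n_occ > nao:
        raise ValueError("n_occ exceeds basis dimension")
    occ = mos.coeffs[:, :n_occ]
    return 2.0 * occ @ occ.T


def fock_from_density(P: np.ndarray, ctx: AOContext) -> np.ndarray:
    """F = Hcore + J[P] - K[P]/2 via contraction with the cached integrals."""
    if P.shape != (ctx.n_ao, ctx.n_ao):
        raise ValueError("density matrix shape mismatch")
    J = np.einsum("pqrs,rs->pq", ctx.eri, P, optimize=True)
    K = np.einsum("prqs,rs->pq", ctx.eri, P, optimize=True)
    F = ctx.Hcore + J - 0.5 * K
    return (F + F.T) / 2.0


def coulomb_exchange(P: np.ndarray, ctx: AOContext) -> tuple[np.ndarray, np.ndarray]:
    J = np.einsum("pqrs,rs->pq", ctx.eri, P, optimize=True)
    K = np.einsum("prqs,rs->pq", ctx.eri, P, optimize=True)
    return J, K


def hf_energy(P: np.ndarray, F: np.ndarray, ctx: AOContext) -> float:
    """Total energy E = 1/2 Tr[P (Hcore + F)] + E_nuc."""
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(F))):
        raise ValueError("non-finite density or Fock matrix")
    return float(0.5 * np.sum(P * (ctx.Hcore + F)) + ctx.E_nuc)


@dataclass(frozen=True)
class SCFResult:
    energy: float
    fock: np.ndarray
    mos: MOSet
    density: np.ndarray
    n_iter: int
    converged: bool
    method: str = "rhf"


def reference_scf(
    geometry_or_ctx,
    basis_label: str = "STO-3G",
    method: str = "rhf",
    conv_tol: float = 1e-10,
    max_iter: int = 200,
    P0: np.ndarray | None = None,
) -> SCFResult:
    """Converged restricted SCF (RHF, or restricted KS for 'dft:<functional>').

    Returns the total energy, the converged operator matrix in the AO basis
    and the S-orthonormal MO set. DIIS-accelerated, with level-shifted
    retries for hard cases (stretched bonds); raises SCFConvergenceError with
    diagnostics if every attempt fails. P0 seeds the density (warm starts
    along a scan).
    """
    ctx = geometry_or_ctx
    if isinstance(ctx, Geometry):
        ctx = build_ao_context(ctx, basis_label)
    method = method.lower()
    if method.startswith("dft:"):
        from .dft import reference_rks

        return reference_rks(ctx, functional=method.split(":", 1)[1],
                             conv_tol=conv_tol, max_iter=max_iter)
    if method != "rhf":
        raise ValueError(f"unknown method {method!r}")

    last_exc = None
    for shift, damping in ((0.0, 0.0), (0.3, 0.3), (1.0, 0.5)):
        try:
            return _rhf_iterations(ctx, conv_tol, max_iter, P0, shift, damping)
        except SCFConvergenceError as exc:
            last_exc = exc
    raise last_exc


def _rhf_iterations(ctx, conv_tol, max_iter, P0, level_shift, damping) -> SCFResult:
    S, H = ctx.S, ctx.Hcore
    n_occ = ctx.n_occ
    if P0 is not None:
        P = P0
    else:
        P = density_from_mos(generalized_eigensolve(H, S), n_occ)
    e_old = None
    errs, focks = [], []
    for it in range(1, max_iter + 1):
        F = fock_from_density(P, ctx)
        err = F @ P @ S - S @ P @ F  # DIIS residual (AO commutator)
        errs.append(err.ravel())
        focks.append(F)
        if len(focks) > 8:
            errs.pop(0)
            focks.pop(0)
        Fd = F
        if len(focks) > 1:
            m = len(focks)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = errs[i] @ errs[j]
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                Fd = sum(c * f for c, f in zip(coef, focks))
            except np.linalg.LinAlgError:
                pass
        if level_shift > 0.0:
            # raise the virtual manifold: F + mu (S - S P S / 2)
            Fd = Fd + level_shift * (S - S @ (P / 2.0) @ S)
        mos = generalized_eigensolve(Fd, S)
        P_new = density_from_mos(mos, n_occ)
        if damping > 0.0:
            P_new = damping * P + (1.0 - damping) * P_new
        P = P_new
        F_true = fock_from_density(P, ctx)
        e = hf_energy(P, F_true, ctx)
        d_err = np.max(np.abs(F_true @ P @ S - S @ P @ F_true))
        if e_old is not None and abs(e - e_old) < conv_tol and d_err < 1e-7:
            return SCFResult(e, F_true, generalized_eigensolve(F_true, S), P, it, True)
        e_old = e
    raise SCFConvergenceError(
        f"SCF not converged in {max_iter} iterations "
        f"(level_shift={level_shift}, last dE={abs(e - e_old) if e_old is not None else np.nan:.2e}, "
        f"|FPS-SPF|={d_err:.2e})"
    )
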