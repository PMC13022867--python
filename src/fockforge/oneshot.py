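"""One-shot (SCF-free) total energies from an arbitrary workspace matrix.

Given a symmetric workspace matrix M for a molecule, the one-shot energy is
obtained by (i) solving the generalized eigenproblem M c = S c e, (ii)
occupying the n_occ lowest orbitals to form the density P, (iii) building one
exact Fock matrix F[P] (or the Kohn-Sham energy functional at P), and (iv)
evaluating the standard total-energy expression. No SCF cycles are performed.

Because any matrix function f(F) that is monotone on the occupied spectrum
shares F's generalized eigenvectors, one_shot_energy(f(F)) reproduces the
converged SCF energy exactly; the search exploits precisely this freedom.

The energy in step (iv) is evaluated at F[P(M)], not at M itself: M may carry
arbitrarily rescaled eigenvalues, so only the rebuilt Fock matrix makes the
expression the true Hartree-Fock energy functional of the predicted density.

A :class:`MoleculeBatch` holds every geometry of one molecule as stacked
arrays so a program can be scored on all of them with batched linear algebra;
this is what makes ~10^4-iteration annealing runs affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._eig import eigh_batch
from .scf import AOContext, MOSet, density_from_mos, fock_from_density, hf_energy

__all__ = ["OneShotResult", "one_shot_energy", "one_shot_energy_dft", "MoleculeBatch"]

#: frontier degeneracy below which occupation is ambiguous -> invalid program
GAP_TOL = 1e-10

#: Frobenius-norm guard: larger workspace matrices are flagged invalid
NORM_MAX = 1e8


@dataclass
class OneShotResult:
    energy: float
    mos: MOSet | None
    density: np.ndarray | None
    valid: bool
    reason: str = ""


def _invalid(reason: str) -> OneShotResult:
    return OneShotResult(energy=np.inf, mos=None, density=None, valid=False, reason=reason)


def one_shot_energy(M: np.ndarray, ctx: AOContext, gap_tol: float = GAP_TOL) -> OneShotResult:
    """HF total energy from a single diagonalization of M (never raises
    inside the search loop; invalid programs get a +inf sentinel)."""
    if not np.all(np.isfinite(M)):
        return _invalid("non-finite workspace matrix")
    try:
        from .scf import generalized_eigensolve

        mos = generalized_eigensolve(M, ctx.S)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return _invalid(str(exc))
    if ctx.n_occ < ctx.n_ao:
        gap = mos.eigenvalues[ctx.n_occ] - mos.eigenvalues[ctx.n_occ - 1]
        if gap < gap_tol:
            return _invalid(f"degenerate frontier gap ({gap:.2e})")
    P = density_from_mos(mos, ctx.n_occ)
    F = fock_from_density(P, ctx)
    e = hf_energy(P, F, ctx)
    if not np.isfinite(e):
        return _invalid("non-finite energy")
    return OneShotResult(energy=e, mos=mos, density=P, valid=True)


def one_shot_energy_dft(
    M: np.ndarray, ctx: AOContext, functional: str = "lda", gap_tol: float = GAP_TOL
) -> OneShotResult:
    """Kohn-Sham total energy evaluated once at the density predicted by M."""
    from .dft import _check_functional, _grid_for_ctx, rks_energy_from_density

    _check_functional(functional)
    if not np.all(np.isfinite(M)):
        return _invalid("non-finite workspace matrix")
    try:
        from .scf import generalized_eigensolve

        mos = generalized_eigensolve(M, ctx.S)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return _invalid(str(exc))
    if ctx.n_occ < ctx.n_ao:
        gap = mos.eigenvalues[ctx.n_occ] - mos.eigenvalues[ctx.n_occ - 1]
        if gap < gap_tol:
            return _invalid(f"degenerate frontier gap ({gap:.2e})")
    P = density_from_mos(mos, ctx.n_occ)
    grid = _grid_for_ctx(ctx)
    e = rks_energy_from_density(P, ctx, grid)
    if not np.isfinite(e):
        return _invalid("non-finite energy")
    return OneShotResult(energy=e, mos=mos, density=P, valid=True)


class MoleculeBatch:
    """Stacked AO data for all geometries of a single molecular species.

    Two-electron contractions are precomputed into (G, nao^2, nao^2) matrices
    when the memory cost is modest; otherwise J/K fall back to per-geometry
    einsum over the cached integral tensors.
    """

    def __init__(self, contexts: list[AOContext], e_ref: np.ndarray | None = None,
                 max_precontract_bytes: int = 2 * 10**8):
        n = {c.n_ao for c in contexts}
        if len(n) != 1:
            raise ValueError("all geometries of a species must share the basis dimension")
        self.contexts = contexts
        self.n_ao = contexts[0].n_ao
        self.n_occ = contexts[0].n_occ
        self.G = len(contexts)
        self.S = np.stack([c.S for c in contexts])
        self.Hcore = np.stack([c.Hcore for c in contexts])
        self.E_nuc = np.array([c.E_nuc for c in contexts])
        self.e_ref = np.asarray(e_ref, float) if e_ref is not None else None
        self.composition = contexts[0].geometry.composition() if contexts[0].geometry else {}
        n2 = self.n_ao**2
        # S^{-1/2} per geometry (generalized -> standard transform)
        self.X = np.empty_like(self.S)
        self.Sinv = np.empty_like(self.S)
        for g, c in enumerate(contexts):
            w, v = np.linalg.eigh(c.S)
            self.X[g] = (v / np.sqrt(w)) @ v.T
            self.Sinv[g] = (v / w) @ v.T
        # symmetry-packed J/K kernels: both the Coulomb kernel (pq|rs) and the
        # symmetrized exchange kernel [(pr|qs)+(ps|qr)]/2 are symmetric in
        # (p,q) and in (r,s), so contraction runs over packed triangles --
        # a quarter of the memory traffic of the naive nao^2 x nao^2 matmul.
        n = self.n_ao
        iu, ju = np.triu_indices(n)
        self._iu, self._ju = iu, ju
        self._mult = np.where(iu == ju, 1.0, 2.0)
        nt = len(iu)
        nbytes = 2 * self.G * nt * nt * 8
        self._pre = nbytes <= max_precontract_bytes
        if self._pre:
            jk = np.empty((self.G, 2 * nt, nt))
            for g, c in enumerate(contexts):
                jk[g, :nt] = c.eri[iu[:, None], ju[:, None], iu[None, :], ju[None, :]]
                A = c.eri.transpose(0, 2, 1, 3)[iu, ju]  # (nt, n, n) = (pr|qs) rows
                jk[g, nt:] = 0.5 * (A[:, iu, ju] + A[:, ju, iu])
            jk[:, :, :] *= self._mult[None, None, :]
            self.eri_jk = jk

    # -- batched primitives used by the program interpreter -----------------

    def eigh_gen(self, M: np.ndarray):
        """Batched generalized symmetric eigensolve; returns (w, C)."""
        A = self.X.transpose(0, 2, 1) @ M @ self.X
        A = (A + A.transpose(0, 2, 1)) / 2.0
        w, y = eigh_batch(A)
        return w, self.X @ y

    def density(self, M: np.ndarray):
        """Aufbau density from each workspace matrix; returns (P, gap)."""
        w, C = self.eigh_gen(M)
        occ = C[:, :, : self.n_occ]
        P = 2.0 * occ @ occ.transpose(0, 2, 1)
        if self.n_occ < self.n_ao:
            gap = w[:, self.n_occ] - w[:, self.n_occ - 1]
        else:
            gap = np.full(self.G, np.inf)
        return P, gap

    def _unpack(self, packed: np.ndarray) -> np.ndarray:
        out = np.empty((self.G, self.n_ao, self.n_ao))
        out[:, self._iu, self._ju] = packed
        out[:, self._ju, self._iu] = packed
        return out

    def _jk_packed(self, P: np.ndarray):
        Pt = np.ascontiguousarray(P[:, self._iu, self._ju])
        return self.eri_jk @ Pt[:, :, None]

    def coulomb(self, P: np.ndarray) -> np.ndarray:
        if self._pre:
            nt = len(self._iu)
            return self._unpack(self._jk_packed(P)[:, :nt, 0])
        return np.stack(
            [np.einsum("pqrs,rs->pq", c.eri, P[g], optimize=True) for g, c in enumerate(self.contexts)]
        )

    def exchange(self, P: np.ndarray) -> np.ndarray:
        if self._pre:
            nt = len(self._iu)
            return self._unpack(self._jk_packed(P)[:, nt:, 0])
        return np.stack(
            [np.einsum("prqs,rs->pq", c.eri, P[g], optimize=True) for g, c in enumerate(self.contexts)]
        )

    def fock(self, P: np.ndarray) -> np.ndarray:
        if self._pre:
            nt = len(self._iu)
            jk = self._jk_packed(P)[:, :, 0]
            F = self.Hcore + self._unpack(jk[:, :nt] - 0.5 * jk[:, nt:])
        else:
            F = self.Hcore + self.coulomb(P) - 0.5 * self.exchange(P)
        return (F + F.transpose(0, 2, 1)) / 2.0

    def one_shot_energies(self, M: np.ndarray, gap_tol: float = GAP_TOL):
        """(energies (G,), valid (G,)) for a stack of workspace matrices."""
        finite = np.all(np.isfinite(M.reshape(self.G, -1)), axis=1)
        if not finite.all():
            e = np.full(self.G, np.inf)
            return e, finite & False
        P, gap = self.density(M)
        F = self.fock(P)
        e = 0.5 * np.einsum("gij,gij->g", P, self.Hcore + F) + self.E_nuc
        valid = (gap >= gap_tol) & np.isfinite(e)
        e = np.where(valid, e, np.inf)
        return e, valid
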