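"""Geometry relaxation and harmonic normal-mode analysis.

The Hessian is assembled by central finite differences of the analytic
gradient, mass-weighted, and purged of rigid-body translations/rotations by
projection before diagonalization. Frequencies come out in atomic units
(hartree-based angular frequency); displacement vectors are returned both
mass-weighted (orthonormal) and in Cartesian form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .constants import AMU_TO_ME, ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, HARTREE_TO_WAVENUMBER
from .geometry import Geometry, canonical_frame
from .grad import rhf_gradient
from .scf import build_ao_context, reference_scf

__all__ = ["NormalModeBasis", "optimize_geometry", "compute_normal_modes"]


class ImaginaryFrequencyError(RuntimeError):
    pass


@dataclass
class NormalModeBasis:
    """Harmonic modes at a verified minimum.

    frequencies: omega_k in atomic units, ascending.
    modes_mw: (nmode, 3N) orthonormal mass-weighted displacement vectors.
    """

    equilibrium: Geometry
    frequencies: np.ndarray
    modes_mw: np.ndarray
    energy: float
    method: str
    basis_label: str

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def frequencies_wavenumber(self) -> np.ndarray:
        return self.frequencies * HARTREE_TO_WAVENUMBER

    def cartesian_displacement(self, q: np.ndarray) -> np.ndarray:
        """Cartesian displacement (bohr, (natom,3)) for mode amplitudes q (a.u.)."""
        masses_me = np.repeat(self.equilibrium.masses, 3) * AMU_TO_ME
        dx = (self.modes_mw.T @ q) / np.sqrt(masses_me)
        return dx.reshape(-1, 3)

    def displaced_geometry(self, q: np.ndarray) -> Geometry:
        xyz = self.equilibrium.coords_bohr() + self.cartesian_displacement(q)
        g = self.equilibrium.with_coords(xyz * BOHR_TO_ANGSTROM)
        return canonical_frame(g)


def _energy_grad(coords_flat, geom, basis_label):
    g = geom.with_coords(coords_flat.reshape(-1, 3) * BOHR_TO_ANGSTROM)
    ctx = build_ao_context(g, basis_label)
    res = reference_scf(ctx)
    return res.energy, rhf_gradient(ctx, res).ravel()


def optimize_geometry(
    geom: Geometry,
    basis_label: str = "STO-3G",
    method: str = "rhf",
    gtol: float = 3e-6,
    maxiter: int = 200,
) -> Geometry:
    """Relax to the nearest minimum with BFGS on the analytic gradient."""
    if method != "rhf":
        raise ValueError("geometry relaxation is implemented for RHF only")
    x0 = geom.coords_bohr().ravel()
    res = scipy.optimize.minimize(
        _energy_grad, x0, args=(geom, basis_label), jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    if np.max(np.abs(res.jac)) > 10 * gtol:
        raise RuntimeError(f"geometry optimization stalled (|g|max={np.max(np.abs(res.jac)):.2e})")
    out = geom.with_coords(res.x.reshape(-1, 3) * BOHR_TO_ANGSTROM)
    out = canonical_frame(out)
    out.metadata["E_opt"] = float(res.fun)
    return out


_SYM_CANDIDATES = [
    np.diag([1.0, 1.0, -1.0]),
    np.diag([1.0, -1.0, 1.0]),
    np.diag([-1.0, 1.0, 1.0]),
    np.diag([-1.0, -1.0, 1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([1.0, -1.0, -1.0]),
    -np.eye(3),
]


def detect_point_symmetry(geom: Geometry, tol: float = 1e-3):
    """Axis-aligned mirror/C2/inversion operations the geometry obeys.

    Returns a list of (R, perm) with coords[perm[a]] - c = R (coords[a] - c)
    to within tol (angstrom), c the centroid. Canonical-frame molecules carry
    their planes/axes along the coordinate axes, which is the only case the
    candidate set needs to cover.
    """
    xyz = geom.coords
    c = xyz.mean(axis=0)
    X = xyz - c
    ops = []
    for R in _SYM_CANDIDATES:
        Y = X @ R.T
        perm = np.full(geom.natom, -1)
        used = set()
        for a in range(geom.natom):
            for b in range(geom.natom):
                if b in used or geom.elements[b] != geom.elements[a]:
                    continue
                if np.max(np.abs(Y[a] - X[b])) < tol:
                    perm[a] = b
                    used.add(b)
                    break
            if perm[a] < 0:
                break
        else:
            if not np.array_equal(perm, np.arange(geom.natom)):
                ops.append((R, perm))
    return ops


def _symmetry_orbits(natom: int, ops):
    """(representatives, derivation map atom -> (R, source atom))."""
    rep = list(range(natom))

    def find(a):
        while rep[a] != a:
            rep[a] = rep[rep[a]]
            a = rep[a]
        return a

    for _, perm in ops:
        for a in range(natom):
            ra, rb = find(a), find(perm[a])
            if ra != rb:
                rep[max(ra, rb)] = min(ra, rb)
    reps = sorted({find(a) for a in range(natom)})
    derive = {}
    frontier = list(reps)
    while frontier:
        a = frontier.pop()
        for R, perm in ops:
            b = perm[a]
            if b not in reps and b not in derive:
                derive[b] = (R, perm, a)
                frontier.append(b)
    return reps, derive


def hessian_fd(
    geom: Geometry,
    basis_label: str = "STO-3G",
    step: float = 5e-3,
    scheme: str = "central",
    use_symmetry: bool = True,
) -> np.ndarray:
    """Finite differences of the analytic gradient (hartree/bohr^2).

    With use_symmetry (default), rows are differentiated only for
    symmetry-unique atoms; rows of their images follow exactly from
    H[pi(a), pi(b)] = R H[a, b] R^T for every detected mirror/C2/inversion
    operation. scheme='forward' halves the cost at O(step) accuracy but
    cannot resolve soft torsional modes; 'central' is the default.
    """
    x0 = geom.coords_bohr()
    natom = geom.natom
    n = 3 * natom
    H = np.zeros((n, n))
    ops = detect_point_symmetry(geom) if (use_symmetry and natom > 2) else []
    reps, derive = _symmetry_orbits(natom, ops)
    if scheme == "forward":
        ctx0 = build_ao_context(geom, basis_label)
        g0 = rhf_gradient(ctx0, reference_scf(ctx0)).ravel()
    signs = (1.0, -1.0) if scheme == "central" else (1.0,)
    for a in reps:
        for d in range(3):
            i = 3 * a + d
            gp = np.zeros(n)
            for sgn in signs:
                x = x0.copy().ravel()
                x[i] += sgn * step
                g = geom.with_coords(x.reshape(-1, 3) * BOHR_TO_ANGSTROM)
                ctx = build_ao_context(g, basis_label)
                res = reference_scf(ctx)
                gp += sgn * rhf_gradient(ctx, res).ravel()
            if scheme == "central":
                H[i] = gp / (2.0 * step)
            else:
                H[i] = (gp - g0) / step
    # fill the image atoms' row blocks, walking derivations in BFS order
    pending = dict(derive)
    done = set(reps)
    while pending:
        progressed = False
        for aprime in list(pending):
            R, perm, a = pending[aprime]
            if a not in done:
                continue
            for b in range(natom):
                bprime = perm[b]
                H[3 * aprime:3 * aprime + 3, 3 * bprime:3 * bprime + 3] = (
                    R @ H[3 * a:3 * a + 3, 3 * b:3 * b + 3] @ R.T
                )
            done.add(aprime)
            del pending[aprime]
            progressed = True
        if not progressed:
            raise RuntimeError("symmetry derivation did not close")
    return (H + H.T) / 2.0


def _rigid_body_projector(geom: Geometry) -> np.ndarray:
    """Orthonormal basis of mass-weighted translations/rotations (6 or 5 vectors)."""
    xyz = geom.coords_bohr()
    masses = geom.masses * AMU_TO_ME
    com = (masses[:, None] * xyz).sum(0) / masses.sum()
    x = xyz - com
    sq = np.sqrt(masses)
    vecs = []
    for d in range(3):
        v = np.zeros((geom.natom, 3))
        v[:, d] = sq
        vecs.append(v.ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        v = np.cross(x, axis) * sq[:, None]
        vecs.append(v.ravel())
    V = np.array(vecs).T
    q, r = np.linalg.qr(V)
    keep = np.abs(np.diag(r)) > 1e-8
    return q[:, keep]


def compute_normal_modes(
    geom: Geometry,
    basis_label: str = "STO-3G",
    method: str = "rhf",
    relax: bool = True,
    imag_tol: float = -1e-6,
    step: float = 5e-3,
    scheme: str = "central",
) -> NormalModeBasis:
    """Harmonic analysis at (or after relaxing to) a local minimum.

    Raises ImaginaryFrequencyError naming the offending mode if any projected
    eigenvalue is significantly negative.
    """
    if relax:
        geom = optimize_geometry(geom, basis_label, method)
    H = hessian_fd(geom, basis_label, step=step, scheme=scheme)
    masses = np.repeat(geom.masses, 3) * AMU_TO_ME
    Hmw = H / np.sqrt(np.outer(masses, masses))
    B = _rigid_body_projector(geom)
    P = np.eye(len(masses)) - B @ B.T
    Hp = P @ Hmw @ P
    w, v = np.linalg.eigh(Hp)
    # drop the projected-out rigid-body space (eigenvalues ~ 0 by construction)
    n_rigid = B.shape[1]
    order = np.argsort(np.abs(w))
    internal = np.sort(order[n_rigid:])
    w_int = w[internal]
    v_int = v[:, internal]
    if w_int.min() < imag_tol:
        k = int(np.argmin(w_int))
        raise ImaginaryFrequencyError(
            f"imaginary frequency in mode {k} (eigenvalue {w_int.min():.3e} au)"
        )
    freqs = np.sqrt(np.clip(w_int, 0.0, None))
    order = np.argsort(freqs)
    ctx = build_ao_context(geom, basis_label)
    e0 = reference_scf(ctx).energy
    return NormalModeBasis(
        equilibrium=geom,
        frequencies=freqs[order],
        modes_mw=v_int[:, order].T.copy(),
        energy=e0,
        method=method,
        basis_label=basis_label,
    )
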