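"""Training/testing geometry generation.

Diatomics: a geometric bond-length grid is scanned at the reference level,
the curve minimum is refined, and points are subselected to spread roughly
uniformly in energy over both the repulsive inner wall and the dissociation
branch, below a threshold E_max.

Polyatomics: configurations are drawn in normal-mode space on "shells" of the
local quadratic energy. For each sample a target energy eps ~ U[0, E_max]
defines the radius r = sqrt(2 eps) of the iso-energy hyper-ellipsoid; a
uniform unit direction u over the chosen mode subset is scaled as
q_k = u_k r / omega_k, making the quadratic energy exactly eps. A second
ab initio filter then removes samples whose true reference energy exceeds the
threshold (sampling slightly above the filter threshold keeps the retained
energy distribution approximately uniform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .constants import COVALENT_RADIUS
from .geometry import Geometry
from .modes import NormalModeBasis
from .scf import SCFConvergenceError, build_ao_context, reference_scf

__all__ = [
    "ShellSample",
    "diatomic_training_scan",
    "sample_quadratic_shell",
    "filter_by_reference_energy",
]


@dataclass
class ShellSample:
    epsilon: float
    radius: float
    u: np.ndarray
    q: np.ndarray  # full-length mode amplitude vector (zeros outside subset)
    geometry: Geometry
    e_ref: float | None = None


def _scan_energy(el1, el2, r, basis, method, P0=None):
    g = Geometry((el1, el2), [[0.0, 0.0, 0.0], [r, 0.0, 0.0]], frame_canonical=True)
    res = reference_scf(build_ao_context(g, basis), method=method, P0=P0)
    return res.energy, res.density


#: per-process cache of scanned curves keyed by (elements, basis, method,
#: n_grid); training and testing selections reuse the same grid energies
_curve_cache: dict = {}


def _scan_curve(el1, el2, basis, method, n_grid):
    key = (el1, el2, basis, method, n_grid)
    if key in _curve_cache:
        return _curve_cache[key]
    r0 = COVALENT_RADIUS[el1] + COVALENT_RADIUS[el2]
    grid = np.geomspace(0.55 * r0, 6.0 * r0, n_grid)
    energies, radii = [], []
    P_prev = None
    for r in grid:
        try:
            e, P_prev = _scan_energy(el1, el2, r, basis, method, P0=P_prev)
            energies.append(e)
            radii.append(r)
        except (SCFConvergenceError, ValueError) as exc:
            warnings.warn(f"{el1}{el2} scan point r={r:.3f} skipped: {exc}")
    energies = np.array(energies)
    radii = np.array(radii)
    imin = int(np.argmin(energies))
    lo = radii[max(imin - 1, 0)]
    hi = radii[min(imin + 1, len(radii) - 1)]
    res = scipy.optimize.minimize_scalar(
        lambda r: _scan_energy(el1, el2, r, basis, method)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-4},
    )
    e_min = min(float(res.fun), float(energies[imin]))
    r_min = float(res.x)
    _curve_cache[key] = (radii, energies, r_min, e_min)
    return _curve_cache[key]


def diatomic_training_scan(
    el1: str,
    el2: str,
    basis: str = "STO-3G",
    method: str = "rhf",
    E_max: float = 0.25,
    n: int = 15,
    seed: int = 0,
    n_grid: int = 160,
    inner_fraction: float = 1.0 / 3.0,
) -> list[Geometry]:
    """n diatomic geometries with reference energies within E_max of the
    curve minimum, spread over both branches of the potential curve."""
    if n < 1:
        raise ValueError("n must be >= 1")
    radii, energies, r_min, e_min = _scan_curve(el1, el2, basis, method, n_grid)
    rel = energies - e_min
    eligible = rel <= E_max
    if E_max == 0.0:
        if n != 1:
            raise ValueError("E_max = 0 admits only the minimum-energy point (n must be 1)")
        g = Geometry((el1, el2), [[0, 0, 0], [r_min, 0, 0]], frame_canonical=True)
        g.metadata["E_ref"] = e_min
        return [g]
    rng = np.random.default_rng(seed)
    inner = eligible & (radii < r_min)
    outer = eligible & (radii >= r_min)
    n_inner = max(1, int(round(n * inner_fraction))) if inner.any() else 0
    n_outer = n - n_inner
    chosen: list[int] = []

    def pick(branch_mask, k):
        idx = np.nonzero(branch_mask)[0]
        if len(idx) == 0 or k <= 0:
            return
        # stratified-uniform energy targets within [0, E_max]
        edges = np.linspace(0.0, E_max, k + 1)
        targets = rng.uniform(edges[:-1], edges[1:])
        for t in targets:
            free = [i for i in idx if i not in chosen]
            if not free:
                break
            j = min(free, key=lambda i: abs(rel[i] - t))
            chosen.append(j)

    pick(inner, n_inner)
    pick(outer, n_outer)
    # top up from any eligible points if a branch was too sparse
    spare = [i for i in np.nonzero(eligible)[0] if i not in chosen]
    while len(chosen) < n and spare:
        chosen.append(spare.pop(len(spare) // 2))
    if len(chosen) < n:
        raise RuntimeError(f"only {len(chosen)} grid points below E_max; requested {n}")
    out = []
    for i in sorted(chosen, key=lambda i: radii[i]):
        g = Geometry((el1, el2), [[0, 0, 0], [radii[i], 0, 0]], frame_canonical=True)
        g.metadata["E_ref"] = float(energies[i])
        g.metadata["E_min_curve"] = e_min
        out.append(g)
    return out


def sample_quadratic_shell(
    nm: NormalModeBasis,
    E_max: float,
    mode_ids: list[int],
    n: int,
    seed: int = 0,
) -> list[ShellSample]:
    """n shell samples over a subset of modes; quadratic energy uniform on
    [0, E_max]."""
    if E_max <= 0:
        raise ValueError("E_max must be positive")
    mode_ids = list(mode_ids)
    if not mode_ids:
        raise ValueError("mode subset must be nonempty")
    omega = nm.frequencies[mode_ids]
    if np.any(omega <= 0):
        raise ValueError("zero/negative frequency in the selected mode subset")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        eps = rng.uniform(0.0, E_max)
        u = rng.normal(size=len(mode_ids))
        u /= np.linalg.norm(u)
        r = np.sqrt(2.0 * eps)
        q_sub = u * r / omega
        q = np.zeros(nm.n_modes)
        q[mode_ids] = q_sub
        out.append(ShellSample(epsilon=float(eps), radius=float(r), u=u, q=q,
                               geometry=nm.displaced_geometry(q)))
    return out


def filter_by_reference_energy(
    samples: list[ShellSample],
    basis: str,
    method: str,
    E_max: float,
    e_equilibrium: float,
    contexts_cache: dict | None = None,
    P0=None,
) -> tuple[list[ShellSample], dict]:
    """Keep samples whose reference energy lies within E_max of equilibrium.

    Returns (filtered samples with e_ref attached, counters). A
    contexts_cache dict lets callers reuse the AO integrals of retained
    geometries; P0 warm-starts each SCF (e.g. from the equilibrium density)."""
    kept: list[ShellSample] = []
    counters = {"kept": 0, "above_threshold": 0, "scf_failed": 0}
    for s in samples:
        try:
            ctx = build_ao_context(s.geometry, basis)
            e = reference_scf(ctx, method=method, P0=P0).energy
        except (SCFConvergenceError, ValueError) as exc:
            warnings.warn(f"sample dropped, SCF failure: {exc}")
            counters["scf_failed"] += 1
            continue
        if e - e_equilibrium > E_max:
            counters["above_threshold"] += 1
            continue
        s.e_ref = float(e)
        s.geometry.metadata["E_ref"] = float(e)
        if contexts_cache is not None:
            contexts_cache[s.geometry.key(basis)] = ctx
        kept.append(s)
    counters["kept"] = len(kept)
    if not kept:
        warnings.warn("energy filter removed every sample")
    return kept, counters
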