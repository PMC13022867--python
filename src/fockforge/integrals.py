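"""McMurchie-Davidson evaluation of Gaussian one- and two-electron integrals.

All kernels are numba-compiled and operate on the flattened shell arrays of
:class:`~fockforge.basis.BasisSet` (s and p shells, three primitives each).
Cartesian p components are ordered x, y, z. Derivative kernels implement
analytic nuclear gradients by angular-momentum raising/lowering on the bra/ket
centers, with operator-center terms recovered through translational
invariance.

The Hermite-expansion recurrences:

    E(i+1,j,t) = E(i,j,t-1)/(2p) + XPA*E(i,j,t) + (t+1)*E(i,j,t+1)
    R(n;t+1,u,v) = t*R(n+1;t-1,u,v) + XPC*R(n+1;t,u,v)

with the Boys function closing the Coulomb recursion.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Cartesian components per shell type; COMP[l, m] = (lx, ly, lz)
_COMP = np.zeros((2, 3, 3), dtype=np.int64)
_COMP[1, 0, 0] = 1
_COMP[1, 1, 1] = 1
_COMP[1, 2, 2] = 1


# Boys-function table: F_m(T) on a uniform grid, consumed by 6th-order Taylor
# interpolation (grid spacing 0.05 -> |error| < 1e-12); the large-T branch uses
# the closed form for F_0 with stable upward recursion.
_BOYS_STEP = 0.05
_BOYS_TMAX = 36.0
_BOYS_MMAX = 18


def _make_boys_table():
    from scipy.special import hyp1f1

    ts = np.arange(0.0, _BOYS_TMAX + 10 * _BOYS_STEP, _BOYS_STEP)
    ms = np.arange(_BOYS_MMAX + 1)
    tab = hyp1f1(ms[:, None] + 0.5, ms[:, None] + 1.5, -ts[None, :]) / (2 * ms[:, None] + 1)
    return np.ascontiguousarray(tab)


_BOYS_TABLE = _make_boys_table()


@njit(cache=True, fastmath=True)
def _boys(nmax, T, out):
    """Fill out[0..nmax] with Boys functions F_n(T)."""
    if T < _BOYS_TMAX:
        idx = int(T / _BOYS_STEP + 0.5)
        delta = T - idx * _BOYS_STEP
        for n in range(nmax + 1):
            # 6th-order Taylor: F_n(T0 + d) = sum_k F_{n+k}(T0) (-d)^k / k!
            acc = _BOYS_TABLE[n + 6, idx]
            acc = _BOYS_TABLE[n + 5, idx] - delta * acc / 6.0
            acc = _BOYS_TABLE[n + 4, idx] - delta * acc / 5.0
            acc = _BOYS_TABLE[n + 3, idx] - delta * acc / 4.0
            acc = _BOYS_TABLE[n + 2, idx] - delta * acc / 3.0
            acc = _BOYS_TABLE[n + 1, idx] - delta * acc / 2.0
            out[n] = _BOYS_TABLE[n, idx] - delta * acc
    else:
        expT = math.exp(-T)
        out[0] = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
        for n in range(nmax):
            out[n + 1] = ((2 * n + 1) * out[n] - expT) / (2.0 * T)


@njit(cache=True, fastmath=True)
def _build_E(imax, jmax, a, b, AB, E):
    """Hermite expansion coefficients for a 1D primitive pair.

    E has shape at least (imax+1, jmax+1, imax+jmax+2); entries above
    t = i + j are zeroed by construction.
    """
    p = a + b
    mu = a * b / p
    XPA = -b * AB / p
    XPB = a * AB / p
    for i in range(imax + 1):
        for j in range(jmax + 1):
            for t in range(imax + jmax + 2):
                E[i, j, t] = 0.0
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    for i in range(imax):
        for t in range(i + 2):
            v = XPA * E[i, 0, t]
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(imax + 1):
        for j in range(jmax):
            for t in range(i + j + 2):
                v = XPB * E[i, j, t]
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True, fastmath=True)
def _build_R(L, alpha, X, Y, Z, R, Fbuf, Rn):
    """Hermite Coulomb integrals R(0;t,u,v) for t+u+v <= L.

    Rn is a preallocated (>=L+1,)*4 work buffer indexed [n, t, u, v].
    """
    T = alpha * (X * X + Y * Y + Z * Z)
    _boys(L, T, Fbuf)
    m = 1.0
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = m * Fbuf[n]
        m *= -2.0 * alpha
    for n in range(L - 1, -1, -1):
        lim = L - n
        for t in range(lim + 1):
            for u in range(lim - t + 1):
                for v in range(lim - t - u + 1):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    for t in range(L + 1):
        for u in range(L - t + 1):
            for v in range(L - t - u + 1):
                R[t, u, v] = Rn[0, t, u, v]


@njit(cache=True, fastmath=True)
def _ovlp_1d(i, j, E, p):
    return E[i, j, 0] * math.sqrt(math.pi / p)


@njit(cache=True, fastmath=True)
def overlap_kinetic_kernel(centers, shell_l, alphas, coefs, ao_off, comp):
    nsh = len(shell_l)
    nao = ao_off[nsh - 1] + 2 * shell_l[nsh - 1] + 1
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    E = np.zeros((3, 4, 6, 10))  # [dim, i, j, t]
    for sa in range(nsh):
        la = shell_l[sa]
        na = 2 * la + 1
        for sb in range(sa + 1):
            lb = shell_l[sb]
            nb = 2 * lb + 1
            AB = centers[sa] - centers[sb]
            for ip in range(3):
                a = alphas[sa, ip]
                ca = coefs[sa, ip]
                for jp in range(3):
                    b = alphas[sb, jp]
                    cb = coefs[sb, jp]
                    p = a + b
                    cc = ca * cb
                    for d in range(3):
                        _build_E(la + 1, lb + 2, a, b, AB[d], E[d])
                    for ma in range(na):
                        for mb in range(nb):
                            sv = 1.0
                            s1 = np.zeros(3)
                            for d in range(3):
                                s1[d] = _ovlp_1d(comp[la, ma, d], comp[lb, mb, d], E[d], p)
                                sv *= s1[d]
                            tv = 0.0
                            for d in range(3):
                                jd = comp[lb, mb, d]
                                idd = comp[la, ma, d]
                                t1 = -2.0 * b * b * _ovlp_1d(idd, jd + 2, E[d], p)
                                t1 += b * (2 * jd + 1) * s1[d]
                                if jd >= 2:
                                    t1 -= 0.5 * jd * (jd - 1) * _ovlp_1d(idd, jd - 2, E[d], p)
                                prod = t1
                                for d2 in range(3):
                                    if d2 != d:
                                        prod *= s1[d2]
                                tv += prod
                            ia = ao_off[sa] + ma
                            ib = ao_off[sb] + mb
                            S[ia, ib] += cc * sv
                            T[ia, ib] += cc * tv
    for i in range(nao):
        for j in range(i + 1):
            S[j, i] = S[i, j]
            T[j, i] = T[i, j]
    return S, T


@njit(cache=True, fastmath=True)
def nuclear_kernel(centers, shell_l, alphas, coefs, ao_off, comp, atom_xyz, charges):
    """Per-nucleus attraction matrices V[c] = -Z_c * (mu|1/r_C|nu)."""
    nsh = len(shell_l)
    natom = len(charges)
    nao = ao_off[nsh - 1] + 2 * shell_l[nsh - 1] + 1
    V = np.zeros((natom, nao, nao))
    E = np.zeros((3, 4, 6, 10))
    R = np.zeros((8, 8, 8))
    Fbuf = np.zeros(9)
    Rn = np.zeros((8, 8, 8, 8))
    for sa in range(nsh):
        la = shell_l[sa]
        na = 2 * la + 1
        for sb in range(sa + 1):
            lb = shell_l[sb]
            nb = 2 * lb + 1
            AB = centers[sa] - centers[sb]
            L = la + lb
            for ip in range(3):
                a = alphas[sa, ip]
                ca = coefs[sa, ip]
                for jp in range(3):
                    b = alphas[sb, jp]
                    cb = coefs[sb, jp]
                    p = a + b
                    cc = ca * cb
                    P = (a * centers[sa] + b * centers[sb]) / p
                    for d in range(3):
                        _build_E(la, lb, a, b, AB[d], E[d])
                    pref = 2.0 * math.pi / p
                    for c in range(natom):
                        PC = P - atom_xyz[c]
                        _build_R(L, p, PC[0], PC[1], PC[2], R, Fbuf, Rn)
                        for ma in range(na):
                            for mb in range(nb):
                                ix = comp[la, ma, 0]
                                iy = comp[la, ma, 1]
                                iz = comp[la, ma, 2]
                                jx = comp[lb, mb, 0]
                                jy = comp[lb, mb, 1]
                                jz = comp[lb, mb, 2]
                                val = 0.0
                                for t in range(ix + jx + 1):
                                    for u in range(iy + jy + 1):
                                        for v in range(iz + jz + 1):
                                            val += (
                                                E[0, ix, jx, t]
                                                * E[1, iy, jy, u]
                                                * E[2, iz, jz, v]
                                                * R[t, u, v]
                                            )
                                ia = ao_off[sa] + ma
                                ib = ao_off[sb] + mb
                                V[c, ia, ib] += -charges[c] * cc * pref * val
    for c in range(natom):
        for i in range(nao):
            for j in range(i + 1):
                V[c, j, i] = V[c, i, j]
    return V


@njit(cache=True, fastmath=True)
def eri_kernel(centers, shell_l, alphas, coefs, ao_off, comp):
    nsh = len(shell_l)
    nao = ao_off[nsh - 1] + 2 * shell_l[nsh - 1] + 1
    eri = np.zeros((nao, nao, nao, nao))
    Eab = np.zeros((9, 3, 4, 6, 10))
    Ecd = np.zeros((9, 3, 4, 6, 10))
    pab = np.zeros(9)
    qcd = np.zeros(9)
    Pab = np.zeros((9, 3))
    Qcd = np.zeros((9, 3))
    ccab = np.zeros(9)
    cccd = np.zeros(9)
    kab = np.zeros(9)
    kcd = np.zeros(9)
    keep_ab = np.zeros(9, dtype=np.int64)
    keep_cd = np.zeros(9, dtype=np.int64)
    R = np.zeros((8, 8, 8))
    Fbuf = np.zeros(9)
    Rn = np.zeros((8, 8, 8, 8))
    block = np.zeros((3, 3, 3, 3))
    for sa in range(nsh):
        la = shell_l[sa]
        na = 2 * la + 1
        for sb in range(sa + 1):
            lb = shell_l[sb]
            nb = 2 * lb + 1
            AB = centers[sa] - centers[sb]
            # primitive pair data for (sa, sb)
            for ip in range(3):
                for jp in range(3):
                    idx = ip * 3 + jp
                    a = alphas[sa, ip]
                    b = alphas[sb, jp]
                    pab[idx] = a + b
                    Pab[idx] = (a * centers[sa] + b * centers[sb]) / (a + b)
                    ccab[idx] = coefs[sa, ip] * coefs[sb, jp]
                    for d in range(3):
                        _build_E(la + 1, lb + 1, a, b, AB[d], Eab[idx, d])
                    kab[idx] = abs(ccab[idx]) * (
                        Eab[idx, 0, 0, 0, 0] * Eab[idx, 1, 0, 0, 0] * Eab[idx, 2, 0, 0, 0]
                    ) / pab[idx] ** 1.5
            nk_ab = 0
            for idx in range(9):
                if kab[idx] > 1e-15:
                    keep_ab[nk_ab] = idx
                    nk_ab += 1
            if nk_ab == 0:
                continue
            for sc in range(sa + 1):
                lc = shell_l[sc]
                nc = 2 * lc + 1
                for sd in range(sc + 1):
                    if sc * (sc + 1) // 2 + sd > sa * (sa + 1) // 2 + sb:
                        continue
                    ld = shell_l[sd]
                    nd = 2 * ld + 1
                    CD = centers[sc] - centers[sd]
                    for kp in range(3):
                        for lp in range(3):
                            idx = kp * 3 + lp
                            c = alphas[sc, kp]
                            dd = alphas[sd, lp]
                            qcd[idx] = c + dd
                            Qcd[idx] = (c * centers[sc] + dd * centers[sd]) / (c + dd)
                            cccd[idx] = coefs[sc, kp] * coefs[sd, lp]
                            for d in range(3):
                                _build_E(lc + 1, ld + 1, c, dd, CD[d], Ecd[idx, d])
                            kcd[idx] = abs(cccd[idx]) * (
                                Ecd[idx, 0, 0, 0, 0] * Ecd[idx, 1, 0, 0, 0] * Ecd[idx, 2, 0, 0, 0]
                            ) / qcd[idx] ** 1.5
                    nk_cd = 0
                    for idx in range(9):
                        if kcd[idx] > 1e-15:
                            keep_cd[nk_cd] = idx
                            nk_cd += 1
                    if nk_cd == 0:
                        continue
                    L = la + lb + lc + ld
                    for ma in range(3):
                        for mb in range(3):
                            for mc in range(3):
                                for md in range(3):
                                    block[ma, mb, mc, md] = 0.0
                    for i1 in range(nk_ab):
                        u1 = keep_ab[i1]
                        p = pab[u1]
                        for i2 in range(nk_cd):
                            u2 = keep_cd[i2]
                            if kab[u1] * kcd[u2] < 2e-14:
                                continue
                            q = qcd[u2]
                            alpha = p * q / (p + q)
                            PQ0 = Pab[u1, 0] - Qcd[u2, 0]
                            PQ1 = Pab[u1, 1] - Qcd[u2, 1]
                            PQ2 = Pab[u1, 2] - Qcd[u2, 2]
                            _build_R(L, alpha, PQ0, PQ1, PQ2, R, Fbuf, Rn)
                            pref = (
                                ccab[u1]
                                * cccd[u2]
                                * 2.0
                                * math.pi ** 2.5
                                / (p * q * math.sqrt(p + q))
                            )
                            for ma in range(na):
                                ix = comp[la, ma, 0]
                                iy = comp[la, ma, 1]
                                iz = comp[la, ma, 2]
                                for mb in range(nb):
                                    jx = comp[lb, mb, 0]
                                    jy = comp[lb, mb, 1]
                                    jz = comp[lb, mb, 2]
                                    for mc in range(nc):
                                        kx = comp[lc, mc, 0]
                                        ky = comp[lc, mc, 1]
                                        kz = comp[lc, mc, 2]
                                        for md in range(nd):
                                            lx = comp[ld, md, 0]
                                            ly = comp[ld, md, 1]
                                            lz = comp[ld, md, 2]
                                            val = 0.0
                                            for t in range(ix + jx + 1):
                                                e1 = Eab[u1, 0, ix, jx, t]
                                                if e1 == 0.0:
                                                    continue
                                                for u in range(iy + jy + 1):
                                                    e2 = e1 * Eab[u1, 1, iy, jy, u]
                                                    if e2 == 0.0:
                                                        continue
                                                    for v in range(iz + jz + 1):
                                                        e3 = e2 * Eab[u1, 2, iz, jz, v]
                                                        if e3 == 0.0:
                                                            continue
                                                        for tt in range(kx + lx + 1):
                                                            f1 = Ecd[u2, 0, kx, lx, tt]
                                                            if f1 == 0.0:
                                                                continue
                                                            sgn_t = -1.0 if tt % 2 else 1.0
                                                            for uu in range(ky + ly + 1):
                                                                f2 = f1 * Ecd[u2, 1, ky, ly, uu]
                                                                if f2 == 0.0:
                                                                    continue
                                                                sgn_u = -sgn_t if uu % 2 else sgn_t
                                                                for vv in range(kz + lz + 1):
                                                                    f3 = f2 * Ecd[u2, 2, kz, lz, vv]
                                                                    if f3 == 0.0:
                                                                        continue
                                                                    sgn = -sgn_u if vv % 2 else sgn_u
                                                                    val += (
                                                                        e3
                                                                        * f3
                                                                        * sgn
                                                                        * R[t + tt, u + uu, v + vv]
                                                                    )
                                            block[ma, mb, mc, md] += pref * val
                    for ma in range(na):
                        ia = ao_off[sa] + ma
                        for mb in range(nb):
                            ib = ao_off[sb] + mb
                            for mc in range(nc):
                                ic = ao_off[sc] + mc
                                for md in range(nd):
                                    idx2 = ao_off[sd] + md
                                    v = block[ma, mb, mc, md]
                                    eri[ia, ib, ic, idx2] = v
                                    eri[ib, ia, ic, idx2] = v
                                    eri[ia, ib, idx2, ic] = v
                                    eri[ib, ia, idx2, ic] = v
                                    eri[ic, idx2, ia, ib] = v
                                    eri[idx2, ic, ia, ib] = v
                                    eri[ic, idx2, ib, ia] = v
                                    eri[idx2, ic, ib, ia] = v
    return eri


def compute_integrals(basis):
    """Return (S, T, V_per_atom, eri) for a BasisSet."""
    S, T = overlap_kinetic_kernel(
        basis.centers, basis.shell_l, basis.alphas, basis.coefs, basis.ao_offset, _COMP
    )
    # atom coordinates from shell centers
    natom = int(basis.shell_atom.max()) + 1
    atom_xyz = np.zeros((natom, 3))
    for ish in range(basis.nsh):
        atom_xyz[basis.shell_atom[ish]] = basis.centers[ish]
    return S, T, atom_xyz


def nuclear_attraction(basis, atom_xyz, charges):
    return nuclear_kernel(
        basis.centers,
        basis.shell_l,
        basis.alphas,
        basis.coefs,
        basis.ao_offset,
        _COMP,
        atom_xyz,
        np.asarray(charges, float),
    )


def electron_repulsion(basis):
    return eri_kernel(
        basis.centers, basis.shell_l, basis.alphas, basis.coefs, basis.ao_offset, _COMP
    )
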