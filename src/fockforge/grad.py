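"""Analytic nuclear gradients for restricted Hartree-Fock.

dE/dR = sum_P dHcore + 1/2 sum Gamma dERI - sum W dS + dE_nuc, with the
energy-weighted density W = 2 C_occ eps_occ C_occ^T and the symmetrized
two-particle density Gamma built from P. Center derivatives of contracted
Gaussians are evaluated by angular-momentum raising/lowering
(d/dA x^i e^{-a r^2} -> 2a*[i+1] - i*[i-1]); nuclear-center terms of the
attraction integrals follow from translational invariance.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import build_basis
from .integrals import _COMP, _build_E, _build_R, _ovlp_1d

__all__ = ["rhf_gradient"]


@njit(cache=True, fastmath=True)
def _prim_S3(iv, jv, E, p):
    return (
        _ovlp_1d(iv[0], jv[0], E[0], p)
        * _ovlp_1d(iv[1], jv[1], E[1], p)
        * _ovlp_1d(iv[2], jv[2], E[2], p)
    )


@njit(cache=True, fastmath=True)
def _prim_T3(iv, jv, E, p, b):
    s0 = _ovlp_1d(iv[0], jv[0], E[0], p)
    s1 = _ovlp_1d(iv[1], jv[1], E[1], p)
    s2 = _ovlp_1d(iv[2], jv[2], E[2], p)
    s = (s0, s1, s2)
    tv = 0.0
    for d in range(3):
        jd = jv[d]
        t1 = -2.0 * b * b * _ovlp_1d(iv[d], jd + 2, E[d], p)
        if d == 0:
            t1 += b * (2 * jd + 1) * s0
            if jd >= 2:
                t1 -= 0.5 * jd * (jd - 1) * _ovlp_1d(iv[d], jd - 2, E[d], p)
            tv += t1 * s1 * s2
        elif d == 1:
            t1 += b * (2 * jd + 1) * s1
            if jd >= 2:
                t1 -= 0.5 * jd * (jd - 1) * _ovlp_1d(iv[d], jd - 2, E[d], p)
            tv += t1 * s0 * s2
        else:
            t1 += b * (2 * jd + 1) * s2
            if jd >= 2:
                t1 -= 0.5 * jd * (jd - 1) * _ovlp_1d(iv[d], jd - 2, E[d], p)
            tv += t1 * s0 * s1
    return tv


@njit(cache=True, fastmath=True)
def grad_1e_kernel(centers, shell_l, alphas, coefs, ao_off, comp, shell_atom, W, P, grad):
    """Overlap (contracted with -W) and kinetic (with P) gradient terms."""
    nsh = len(shell_l)
    E = np.zeros((3, 5, 7, 12))
    iv = np.zeros(3, dtype=np.int64)
    jv = np.zeros(3, dtype=np.int64)
    i2 = np.zeros(3, dtype=np.int64)
    for sa in range(nsh):
        la = shell_l[sa]
        na = 2 * la + 1
        A = shell_atom[sa]
        for sb in range(nsh):
            lb = shell_l[sb]
            nb = 2 * lb + 1
            B = shell_atom[sb]
            if A == B:
                continue
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
                        _build_E(la + 2, lb + 2, a, b, AB[d], E[d])
                    for ma in range(na):
                        for d in range(3):
                            iv[d] = comp[la, ma, d]
                        for mb in range(nb):
                            for d in range(3):
                                jv[d] = comp[lb, mb, d]
                            ia = ao_off[sa] + ma
                            ib = ao_off[sb] + mb
                            wij = W[ia, ib]
                            pij = P[ia, ib]
                            for d in range(3):
                                i2[0] = iv[0]
                                i2[1] = iv[1]
                                i2[2] = iv[2]
                                i2[d] += 1
                                dS = 2.0 * a * _prim_S3(i2, jv, E, p)
                                dT = 2.0 * a * _prim_T3(i2, jv, E, p, b)
                                if iv[d] > 0:
                                    i2[d] -= 2
                                    dS -= iv[d] * _prim_S3(i2, jv, E, p)
                                    dT -= iv[d] * _prim_T3(i2, jv, E, p, b)
                                g = cc * (pij * dT - wij * dS)
                                grad[A, d] += g
                                grad[B, d] -= g


@njit(cache=True, fastmath=True)
def _prim_V3(iv, jv, E, R):
    val = 0.0
    for t in range(iv[0] + jv[0] + 1):
        e1 = E[0, iv[0], jv[0], t]
        for u in range(iv[1] + jv[1] + 1):
            e2 = e1 * E[1, iv[1], jv[1], u]
            for v in range(iv[2] + jv[2] + 1):
                val += e2 * E[2, iv[2], jv[2], v] * R[t, u, v]
    return val


@njit(cache=True, fastmath=True)
def grad_nuc_kernel(centers, shell_l, alphas, coefs, ao_off, comp, shell_atom,
                    atom_xyz, charges, P, grad):
    """Nuclear-attraction gradient; operator-center term via translational invariance."""
    nsh = len(shell_l)
    natom = len(charges)
    E = np.zeros((3, 5, 7, 12))
    R = np.zeros((8, 8, 8))
    Fbuf = np.zeros(9)
    Rn = np.zeros((8, 8, 8, 8))
    iv = np.zeros(3, dtype=np.int64)
    jv = np.zeros(3, dtype=np.int64)
    i2 = np.zeros(3, dtype=np.int64)
    j2 = np.zeros(3, dtype=np.int64)
    for sa in range(nsh):
        la = shell_l[sa]
        na = 2 * la + 1
        A = shell_atom[sa]
        for sb in range(nsh):
            lb = shell_l[sb]
            nb = 2 * lb + 1
            B = shell_atom[sb]
            AB = centers[sa] - centers[sb]
            L = la + lb + 1
            for ip in range(3):
                a = alphas[sa, ip]
                ca = coefs[sa, ip]
                for jp in range(3):
                    b = alphas[sb, jp]
                    cb = coefs[sb, jp]
                    p = a + b
                    cc = ca * cb
                    Px = (a * centers[sa] + b * centers[sb]) / p
                    for d in range(3):
                        _build_E(la + 2, lb + 2, a, b, AB[d], E[d])
                    pref = 2.0 * math.pi / p
                    for c in range(natom):
                        PC0 = Px[0] - atom_xyz[c, 0]
                        PC1 = Px[1] - atom_xyz[c, 1]
                        PC2 = Px[2] - atom_xyz[c, 2]
                        _build_R(L, p, PC0, PC1, PC2, R, Fbuf, Rn)
                        zc = -charges[c]
                        for ma in range(na):
                            for d in range(3):
                                iv[d] = comp[la, ma, d]
                            for mb in range(nb):
                                for d in range(3):
                                    jv[d] = comp[lb, mb, d]
                                ia = ao_off[sa] + ma
                                ib = ao_off[sb] + mb
                                pij = P[ia, ib]
                                if pij == 0.0:
                                    continue
                                w = cc * pref * zc * pij
                                for d in range(3):
                                    i2[0] = iv[0]
                                    i2[1] = iv[1]
                                    i2[2] = iv[2]
                                    j2[0] = jv[0]
                                    j2[1] = jv[1]
                                    j2[2] = jv[2]
                                    i2[d] += 1
                                    dA = 2.0 * a * _prim_V3(i2, jv, E, R)
                                    if iv[d] > 0:
                                        i2[d] -= 2
                                        dA -= iv[d] * _prim_V3(i2, jv, E, R)
                                    j2[d] += 1
                                    dB = 2.0 * b * _prim_V3(iv, j2, E, R)
                                    if jv[d] > 0:
                                        j2[d] -= 2
                                        dB -= jv[d] * _prim_V3(iv, j2, E, R)
                                    grad[A, d] += w * dA
                                    grad[B, d] += w * dB
                                    grad[c, d] -= w * (dA + dB)


@njit(cache=True, fastmath=True)
def _hsum(Eab, Ecd, iv, jv, kv, lv, R):
    val = 0.0
    for t in range(iv[0] + jv[0] + 1):
        e1 = Eab[0, iv[0], jv[0], t]
        if e1 == 0.0:
            continue
        for u in range(iv[1] + jv[1] + 1):
            e2 = e1 * Eab[1, iv[1], jv[1], u]
            if e2 == 0.0:
                continue
            for v in range(iv[2] + jv[2] + 1):
                e3 = e2 * Eab[2, iv[2], jv[2], v]
                if e3 == 0.0:
                    continue
                for tt in range(kv[0] + lv[0] + 1):
                    f1 = Ecd[0, kv[0], lv[0], tt]
                    if f1 == 0.0:
                        continue
                    s1 = -e3 * f1 if tt % 2 else e3 * f1
                    for uu in range(kv[1] + lv[1] + 1):
                        f2 = Ecd[1, kv[1], lv[1], uu]
                        if f2 == 0.0:
                            continue
                        s2 = -s1 * f2 if uu % 2 else s1 * f2
                        for vv in range(kv[2] + lv[2] + 1):
                            f3 = Ecd[2, kv[2], lv[2], vv]
                            if f3 == 0.0:
                                continue
                            s3 = -s2 * f3 if vv % 2 else s2 * f3
                            val += s3 * R[t + tt, u + uu, v + vv]
    return val


@njit(cache=True, fastmath=True)
def grad_eri_kernel(centers, shell_l, alphas, coefs, ao_off, comp, shell_atom,
                    Gsym, qpair, gpair, thresh, grad):
    """1/2 sum Gamma_sym dERI/dR over unique shell quartets (Schwarz-screened).

    Per primitive quartet, the ket side is contracted into a Hermite-space
    table Tcd (and the bra side into Tab); the symmetrized two-particle
    density is then folded in once, so each center derivative reduces to a
    short sum over raised/lowered expansion coefficients.
    """
    nsh = len(shell_l)
    Eab = np.zeros((9, 3, 5, 7, 12))
    Ecd = np.zeros((9, 3, 5, 7, 12))
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
    gq = np.zeros((4, 3))
    Tcd = np.zeros((9, 4, 4, 4))
    Tab = np.zeros((9, 4, 4, 4))
    V = np.zeros((9, 4, 4, 4))
    W = np.zeros((9, 4, 4, 4))
    for sa in range(nsh):
        la = shell_l[sa]
        na = 2 * la + 1
        A = shell_atom[sa]
        for sb in range(sa + 1):
            lb = shell_l[sb]
            nb = 2 * lb + 1
            B = shell_atom[sb]
            AB = centers[sa] - centers[sb]
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
                C = shell_atom[sc]
                for sd in range(sc + 1):
                    if sc * (sc + 1) // 2 + sd > sa * (sa + 1) // 2 + sb:
                        continue
                    if qpair[sa, sb] * qpair[sc, sd] * gpair[sa, sb, sc, sd] < thresh:
                        continue
                    ld = shell_l[sd]
                    nd = 2 * ld + 1
                    D = shell_atom[sd]
                    if A == B and B == C and C == D:
                        continue  # one-center: derivatives cancel exactly
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
                    deg = 1.0
                    if sa != sb:
                        deg *= 2.0
                    if sc != sd:
                        deg *= 2.0
                    if sa * (sa + 1) // 2 + sb != sc * (sc + 1) // 2 + sd:
                        deg *= 2.0
                    L = la + lb + lc + ld + 1
                    nta = la + lb + 2  # bra Hermite range incl. raising
                    ntc = lc + ld + 2
                    for i4 in range(4):
                        for d in range(3):
                            gq[i4, d] = 0.0
                    for i1 in range(nk_ab):
                        u1 = keep_ab[i1]
                        p = pab[u1]
                        a = alphas[sa, u1 // 3]
                        b = alphas[sb, u1 % 3]
                        for i2 in range(nk_cd):
                            u2 = keep_cd[i2]
                            if kab[u1] * kcd[u2] < 2e-14:
                                continue
                            q = qcd[u2]
                            c = alphas[sc, u2 // 3]
                            alpha = p * q / (p + q)
                            _build_R(
                                L, alpha,
                                Pab[u1, 0] - Qcd[u2, 0],
                                Pab[u1, 1] - Qcd[u2, 1],
                                Pab[u1, 2] - Qcd[u2, 2],
                                R, Fbuf, Rn,
                            )
                            pref = (
                                ccab[u1] * cccd[u2] * 2.0 * math.pi ** 2.5
                                / (p * q * math.sqrt(p + q))
                            )
                            # ket-contracted Hermite tables
                            for mc in range(nc):
                                kx = comp[lc, mc, 0]
                                ky = comp[lc, mc, 1]
                                kz = comp[lc, mc, 2]
                                for md in range(nd):
                                    lx = comp[ld, md, 0]
                                    ly = comp[ld, md, 1]
                                    lz = comp[ld, md, 2]
                                    mi = mc * 3 + md
                                    for t in range(nta):
                                        for u in range(nta):
                                            for v in range(nta):
                                                s = 0.0
                                                for tt in range(kx + lx + 1):
                                                    f1 = Ecd[u2, 0, kx, lx, tt]
                                                    if f1 == 0.0:
                                                        continue
                                                    s1 = -f1 if tt % 2 else f1
                                                    for uu in range(ky + ly + 1):
                                                        f2 = Ecd[u2, 1, ky, ly, uu]
                                                        if f2 == 0.0:
                                                            continue
                                                        s2 = -s1 * f2 if uu % 2 else s1 * f2
                                                        for vv in range(kz + lz + 1):
                                                            f3 = Ecd[u2, 2, kz, lz, vv]
                                                            if f3 == 0.0:
                                                                continue
                                                            s3 = -s2 * f3 if vv % 2 else s2 * f3
                                                            s += s3 * R[t + tt, u + uu, v + vv]
                                                Tcd[mi, t, u, v] = s
                            # bra-contracted Hermite tables
                            for ma in range(na):
                                ix = comp[la, ma, 0]
                                iy = comp[la, ma, 1]
                                iz = comp[la, ma, 2]
                                for mb in range(nb):
                                    jx = comp[lb, mb, 0]
                                    jy = comp[lb, mb, 1]
                                    jz = comp[lb, mb, 2]
                                    mi = ma * 3 + mb
                                    for tt in range(ntc):
                                        for uu in range(ntc):
                                            for vv in range(ntc):
                                                s = 0.0
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
                                                            s += e3 * R[t + tt, u + uu, v + vv]
                                                Tab[mi, tt, uu, vv] = s
                            # fold in the two-particle density
                            for ma in range(na):
                                for mb in range(nb):
                                    mi = ma * 3 + mb
                                    for t in range(nta):
                                        for u in range(nta):
                                            for v in range(nta):
                                                V[mi, t, u, v] = 0.0
                                    for mc in range(nc):
                                        for md in range(nd):
                                            g = Gsym[
                                                ao_off[sa] + ma,
                                                ao_off[sb] + mb,
                                                ao_off[sc] + mc,
                                                ao_off[sd] + md,
                                            ]
                                            if abs(g) < 1e-13:
                                                continue
                                            mj = mc * 3 + md
                                            for t in range(nta):
                                                for u in range(nta):
                                                    for v in range(nta):
                                                        V[mi, t, u, v] += g * Tcd[mj, t, u, v]
                            for mc in range(nc):
                                for md in range(nd):
                                    mj = mc * 3 + md
                                    for t in range(ntc):
                                        for u in range(ntc):
                                            for v in range(ntc):
                                                W[mj, t, u, v] = 0.0
                                    for ma in range(na):
                                        for mb in range(nb):
                                            g = Gsym[
                                                ao_off[sa] + ma,
                                                ao_off[sb] + mb,
                                                ao_off[sc] + mc,
                                                ao_off[sd] + md,
                                            ]
                                            if abs(g) < 1e-13:
                                                continue
                                            mi = ma * 3 + mb
                                            for t in range(ntc):
                                                for u in range(ntc):
                                                    for v in range(ntc):
                                                        W[mj, t, u, v] += g * Tab[mi, t, u, v]
                            # bra-center derivatives
                            for ma in range(na):
                                ix = comp[la, ma, 0]
                                iy = comp[la, ma, 1]
                                iz = comp[la, ma, 2]
                                for mb in range(nb):
                                    jx = comp[lb, mb, 0]
                                    jy = comp[lb, mb, 1]
                                    jz = comp[lb, mb, 2]
                                    mi = ma * 3 + mb
                                    for d in range(3):
                                        dA = 0.0
                                        dB = 0.0
                                        if d == 0:
                                            for t in range(ix + jx + 2):
                                                ea_r = 2.0 * a * Eab[u1, 0, ix + 1, jx, t]
                                                if ix > 0:
                                                    ea_r -= ix * Eab[u1, 0, ix - 1, jx, t]
                                                eb_r = 2.0 * b * Eab[u1, 0, ix, jx + 1, t]
                                                if jx > 0:
                                                    eb_r -= jx * Eab[u1, 0, ix, jx - 1, t]
                                                if ea_r == 0.0 and eb_r == 0.0:
                                                    continue
                                                for u in range(iy + jy + 1):
                                                    e2 = Eab[u1, 1, iy, jy, u]
                                                    if e2 == 0.0:
                                                        continue
                                                    for v in range(iz + jz + 1):
                                                        e3 = e2 * Eab[u1, 2, iz, jz, v]
                                                        if e3 == 0.0:
                                                            continue
                                                        vv = V[mi, t, u, v]
                                                        dA += ea_r * e3 * vv
                                                        dB += eb_r * e3 * vv
                                        elif d == 1:
                                            for u in range(iy + jy + 2):
                                                ea_r = 2.0 * a * Eab[u1, 1, iy + 1, jy, u]
                                                if iy > 0:
                                                    ea_r -= iy * Eab[u1, 1, iy - 1, jy, u]
                                                eb_r = 2.0 * b * Eab[u1, 1, iy, jy + 1, u]
                                                if jy > 0:
                                                    eb_r -= jy * Eab[u1, 1, iy, jy - 1, u]
                                                if ea_r == 0.0 and eb_r == 0.0:
                                                    continue
                                                for t in range(ix + jx + 1):
                                                    e2 = Eab[u1, 0, ix, jx, t]
                                                    if e2 == 0.0:
                                                        continue
                                                    for v in range(iz + jz + 1):
                                                        e3 = e2 * Eab[u1, 2, iz, jz, v]
                                                        if e3 == 0.0:
                                                            continue
                                                        vv = V[mi, t, u, v]
                                                        dA += ea_r * e3 * vv
                                                        dB += eb_r * e3 * vv
                                        else:
                                            for v in range(iz + jz + 2):
                                                ea_r = 2.0 * a * Eab[u1, 2, iz + 1, jz, v]
                                                if iz > 0:
                                                    ea_r -= iz * Eab[u1, 2, iz - 1, jz, v]
                                                eb_r = 2.0 * b * Eab[u1, 2, iz, jz + 1, v]
                                                if jz > 0:
                                                    eb_r -= jz * Eab[u1, 2, iz, jz - 1, v]
                                                if ea_r == 0.0 and eb_r == 0.0:
                                                    continue
                                                for t in range(ix + jx + 1):
                                                    e2 = Eab[u1, 0, ix, jx, t]
                                                    if e2 == 0.0:
                                                        continue
                                                    for u in range(iy + jy + 1):
                                                        e3 = e2 * Eab[u1, 1, iy, jy, u]
                                                        if e3 == 0.0:
                                                            continue
                                                        vv = V[mi, t, u, v]
                                                        dA += ea_r * e3 * vv
                                                        dB += eb_r * e3 * vv
                                        gq[0, d] += pref * dA
                                        gq[1, d] += pref * dB
                                        gq[3, d] -= pref * (dA + dB)
                            # ket-center derivative (C); D via translational invariance
                            for mc in range(nc):
                                kx = comp[lc, mc, 0]
                                ky = comp[lc, mc, 1]
                                kz = comp[lc, mc, 2]
                                for md in range(nd):
                                    lx = comp[ld, md, 0]
                                    ly = comp[ld, md, 1]
                                    lz = comp[ld, md, 2]
                                    mj = mc * 3 + md
                                    for d in range(3):
                                        dC = 0.0
                                        if d == 0:
                                            for tt in range(kx + lx + 2):
                                                ec_r = 2.0 * c * Ecd[u2, 0, kx + 1, lx, tt]
                                                if kx > 0:
                                                    ec_r -= kx * Ecd[u2, 0, kx - 1, lx, tt]
                                                if ec_r == 0.0:
                                                    continue
                                                s1 = -ec_r if tt % 2 else ec_r
                                                for uu in range(ky + ly + 1):
                                                    f2 = Ecd[u2, 1, ky, ly, uu]
                                                    if f2 == 0.0:
                                                        continue
                                                    s2 = -s1 * f2 if uu % 2 else s1 * f2
                                                    for vv in range(kz + lz + 1):
                                                        f3 = Ecd[u2, 2, kz, lz, vv]
                                                        if f3 == 0.0:
                                                            continue
                                                        s3 = -s2 * f3 if vv % 2 else s2 * f3
                                                        dC += s3 * W[mj, tt, uu, vv]
                                        elif d == 1:
                                            for uu in range(ky + ly + 2):
                                                ec_r = 2.0 * c * Ecd[u2, 1, ky + 1, ly, uu]
                                                if ky > 0:
                                                    ec_r -= ky * Ecd[u2, 1, ky - 1, ly, uu]
                                                if ec_r == 0.0:
                                                    continue
                                                s1 = -ec_r if uu % 2 else ec_r
                                                for tt in range(kx + lx + 1):
                                                    f2 = Ecd[u2, 0, kx, lx, tt]
                                                    if f2 == 0.0:
                                                        continue
                                                    s2 = -s1 * f2 if tt % 2 else s1 * f2
                                                    for vv in range(kz + lz + 1):
                                                        f3 = Ecd[u2, 2, kz, lz, vv]
                                                        if f3 == 0.0:
                                                            continue
                                                        s3 = -s2 * f3 if vv % 2 else s2 * f3
                                                        dC += s3 * W[mj, tt, uu, vv]
                                        else:
                                            for vv in range(kz + lz + 2):
                                                ec_r = 2.0 * c * Ecd[u2, 2, kz + 1, lz, vv]
                                                if kz > 0:
                                                    ec_r -= kz * Ecd[u2, 2, kz - 1, lz, vv]
                                                if ec_r == 0.0:
                                                    continue
                                                s1 = -ec_r if vv % 2 else ec_r
                                                for tt in range(kx + lx + 1):
                                                    f2 = Ecd[u2, 0, kx, lx, tt]
                                                    if f2 == 0.0:
                                                        continue
                                                    s2 = -s1 * f2 if tt % 2 else s1 * f2
                                                    for uu in range(ky + ly + 1):
                                                        f3 = Ecd[u2, 1, ky, ly, uu]
                                                        if f3 == 0.0:
                                                            continue
                                                        s3 = -s2 * f3 if uu % 2 else s2 * f3
                                                        dC += s3 * W[mj, tt, uu, vv]
                                        gq[2, d] += pref * dC
                                        gq[3, d] -= pref * dC
                    for d in range(3):
                        grad[A, d] += 0.5 * deg * gq[0, d]
                        grad[B, d] += 0.5 * deg * gq[1, d]
                        grad[C, d] += 0.5 * deg * gq[2, d]
                        grad[D, d] += 0.5 * deg * gq[3, d]


def _symmetrized_gamma(P: np.ndarray) -> np.ndarray:
    G = np.einsum("ij,kl->ijkl", P, P) - 0.5 * np.einsum("ik,jl->ijkl", P, P)
    G = G + G.transpose(1, 0, 2, 3) + G.transpose(0, 1, 3, 2) + G.transpose(1, 0, 3, 2)
    G = G + G.transpose(2, 3, 0, 1)
    return G / 8.0


def rhf_gradient(ctx, scf_result) -> np.ndarray:
    """Nuclear gradient (hartree/bohr, shape (natom, 3)) of the RHF energy."""
    geom = ctx.geometry
    basis = build_basis(geom, ctx.basis_label)
    P = scf_result.density
    occ = scf_result.mos.coeffs[:, : ctx.n_occ]
    eps = scf_result.mos.eigenvalues[: ctx.n_occ]
    W = 2.0 * (occ * eps) @ occ.T
    grad = np.zeros((geom.natom, 3))
    args = (basis.centers, basis.shell_l, basis.alphas, basis.coefs,
            basis.ao_offset, _COMP, basis.shell_atom)
    grad_1e_kernel(*args, W, P, grad)
    xyz = geom.coords_bohr()
    charges = geom.charges
    grad_nuc_kernel(*args, xyz, charges, P, grad)
    Gsym = _symmetrized_gamma(P)
    # Schwarz-style pair bound from the cached integrals, plus the maximal
    # two-particle-density magnitude per shell quartet (block-max of Gsym)
    nsh = basis.nsh
    qpair = np.zeros((nsh, nsh))
    lo = basis.ao_offset
    hi = basis.ao_offset + 2 * basis.shell_l + 1
    for sa in range(nsh):
        for sb in range(nsh):
            block = ctx.eri[lo[sa]:hi[sa], lo[sb]:hi[sb], lo[sa]:hi[sa], lo[sb]:hi[sb]]
            diag = np.abs(np.einsum("ijij->ij", block))
            qpair[sa, sb] = np.sqrt(diag.max()) if diag.size else 0.0
    # reduce |Gsym| to per-shell blocks via a segmented max
    seg = np.zeros(basis.nao, dtype=np.int64)
    for ish in range(nsh):
        seg[lo[ish]:hi[ish]] = ish
    gabs = np.abs(Gsym)
    red = np.zeros((nsh, basis.nao, basis.nao, basis.nao))
    np.maximum.at(red, (seg[:, None, None, None],
                        np.arange(basis.nao)[None, :, None, None],
                        np.arange(basis.nao)[None, None, :, None],
                        np.arange(basis.nao)[None, None, None, :]), gabs)
    gpair = red
    for axis in (1, 2, 3):
        out_shape = list(gpair.shape)
        out_shape[axis] = nsh
        nxt = np.zeros(out_shape)
        idx = [slice(None)] * 4
        for ish in range(nsh):
            sl = list(idx)
            sl[axis] = slice(lo[ish], hi[ish])
            tl = list(idx)
            tl[axis] = ish
            nxt[tuple(tl)] = gpair[tuple(sl)].max(axis=axis)
        gpair = nxt
    grad_eri_kernel(*args, Gsym, qpair, gpair, 5e-12, grad)
    # nuclear repulsion
    for i in range(geom.natom):
        for j in range(geom.natom):
            if i == j:
                continue
            rij = xyz[i] - xyz[j]
            grad[i] -= charges[i] * charges[j] * rij / np.linalg.norm(rij) ** 3
    return grad
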