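"""Independent closed-form oracles used by the tests.

The s-orbital Gaussian integral formulas below (overlap, kinetic, nuclear
attraction, two-electron) are the standard closed forms for 1s primitives;
they share no code with the McMurchie-Davidson kernels they check.
"""

import math

import numpy as np
from scipy.special import erf


def boys0(t):
    if t < 1e-12:
        return 1.0 - t / 3.0
    return 0.5 * math.sqrt(math.pi / t) * erf(math.sqrt(t))


def s_norm(a):
    return (2.0 * a / math.pi) ** 0.75


def s_overlap(a, A, b, B):
    """<1s_a(A)|1s_b(B)> for normalized primitives."""
    A, B = np.asarray(A), np.asarray(B)
    p = a + b
    r2 = float(np.sum((A - B) ** 2))
    return s_norm(a) * s_norm(b) * (math.pi / p) ** 1.5 * math.exp(-a * b / p * r2)


def s_kinetic(a, A, b, B):
    A, B = np.asarray(A), np.asarray(B)
    p = a + b
    mu = a * b / p
    r2 = float(np.sum((A - B) ** 2))
    return mu * (3.0 - 2.0 * mu * r2) * s_overlap(a, A, b, B)


def s_nuclear(a, A, b, B, C, Z):
    """-Z <1s_a(A)|1/r_C|1s_b(B)>."""
    A, B, C = np.asarray(A), np.asarray(B), np.asarray(C)
    p = a + b
    P = (a * A + b * B) / p
    r2ab = float(np.sum((A - B) ** 2))
    r2pc = float(np.sum((P - C) ** 2))
    pref = -Z * 2.0 * math.pi / p * math.exp(-a * b / p * r2ab)
    return s_norm(a) * s_norm(b) * pref * boys0(p * r2pc)


def s_eri(a, A, b, B, c, C, d, D):
    """(1s_a 1s_b | 1s_c 1s_d) in chemists' notation, normalized primitives."""
    A, B, C, D = map(np.asarray, (A, B, C, D))
    p = a + b
    q = c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    r2ab = float(np.sum((A - B) ** 2))
    r2cd = float(np.sum((C - D) ** 2))
    r2pq = float(np.sum((P - Q) ** 2))
    pref = (
        2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
        * math.exp(-a * b / p * r2ab - c * d / q * r2cd)
    )
    alpha = p * q / (p + q)
    norm = s_norm(a) * s_norm(b) * s_norm(c) * s_norm(d)
    return norm * pref * boys0(alpha * r2pq)
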