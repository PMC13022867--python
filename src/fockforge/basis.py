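"""Minimal Gaussian basis sets built from Slater-fit expansions.

The STO-3G family is constructed, not tabulated: a universal three-Gaussian
least-squares expansion of each zeta=1 Slater shell (1s, 2s/2p with shared
exponents, 3s/3p with shared exponents) is scaled per element by the published
Slater exponents (alpha_i = u_i * zeta**2). The universal expansion constants
below were obtained by re-running that least-squares fit (see the package
tests, which repeat the fit and reproduce these numbers); they agree with the
standard tabulated STO-3G parameters to ~1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry

__all__ = ["BasisSet", "build_basis", "SUPPORTED_ELEMENTS"]

# universal zeta=1 expansions: (exponents, coeffs) for normalized primitives
_U_1S = (
    np.array([2.227660923, 0.405771186, 0.109817519]),
    np.array([0.154328951, 0.535328120, 0.444634580]),
)
_U_2SP = (
    np.array([0.994202400, 0.231031301, 0.075138562]),
    np.array([-0.099967219, 0.399512849, 0.700115438]),  # 2s
    np.array([0.155916334, 0.607683684, 0.391957359]),  # 2p
)
_U_3SP = (
    np.array([0.482854069, 0.134715053, 0.052726562]),
    np.array([-0.219620367, 0.225595452, 0.900398407]),  # 3s
    np.array([0.010587624, 0.595167022, 0.462000975]),  # 3p
)

# Slater exponents (1s, 2sp[, 3sp]) per element; standard STO-3G scale factors.
_ZETA = {
    "H": (1.24,),
    "He": (1.69,),
    "Li": (2.69, 0.80),
    "Be": (3.68, 1.15),
    "B": (4.68, 1.50),
    "C": (5.67, 1.72),
    "N": (6.67, 1.95),
    "O": (7.66, 2.25),
    "F": (8.65, 2.55),
    "Ne": (9.64, 2.88),
    "Na": (10.61, 3.48, 1.75),
    "Cl": (16.43, 6.26, 2.10),
}

SUPPORTED_ELEMENTS = frozenset(_ZETA)


def _primitive_norm(alpha: float, l: int) -> float:
    """Normalization of a Cartesian primitive x^l exp(-alpha r^2) (l<=1)."""
    n = (2.0 * alpha / np.pi) ** 0.75
    if l == 1:
        n *= 2.0 * np.sqrt(alpha)
    return n


@dataclass
class BasisSet:
    """Flattened shell arrays consumed by the integral kernels.

    Each shell holds three primitives; ``coef`` are contraction coefficients
    for *unnormalized* Cartesian primitives, scaled so every contracted AO is
    unit-normalized.
    """

    label: str
    centers: np.ndarray  # (nsh, 3) bohr
    shell_l: np.ndarray  # (nsh,) 0=s, 1=p
    alphas: np.ndarray  # (nsh, 3)
    coefs: np.ndarray  # (nsh, 3)
    shell_atom: np.ndarray  # (nsh,) atom index
    ao_offset: np.ndarray  # (nsh,) first AO index of the shell

    @property
    def nsh(self) -> int:
        return len(self.shell_l)

    @property
    def nao(self) -> int:
        return int(self.ao_offset[-1] + 2 * self.shell_l[-1] + 1)


def _element_shells(el: str):
    zetas = _ZETA[el]
    shells = []  # (l, alphas, coeffs-for-normalized-primitives)
    shells.append((0, _U_1S[0] * zetas[0] ** 2, _U_1S[1]))
    if len(zetas) >= 2:
        a = _U_2SP[0] * zetas[1] ** 2
        shells.append((0, a, _U_2SP[1]))
        shells.append((1, a, _U_2SP[2]))
    if len(zetas) >= 3:
        a = _U_3SP[0] * zetas[2] ** 2
        shells.append((0, a, _U_3SP[1]))
        shells.append((1, a, _U_3SP[2]))
    return shells


def build_basis(geom: Geometry, label: str = "STO-3G") -> BasisSet:
    if label.upper().replace(" ", "") != "STO-3G":
        raise ValueError(f"unknown basis label {label!r}; supported: STO-3G")
    for el in geom.elements:
        if el not in _ZETA:
            raise ValueError(f"element {el} not available in {label}")
    centers, ls, alphas, coefs, atoms, offsets = [], [], [], [], [], []
    xyz = geom.coords_bohr()
    nao = 0
    for ia, el in enumerate(geom.elements):
        for l, a, c in _element_shells(el):
            cc = c * np.array([_primitive_norm(ai, l) for ai in a])
            # renormalize the contracted function
            ss = 0.0
            for i in range(3):
                for j in range(3):
                    p = a[i] + a[j]
                    s = (np.pi / p) ** 1.5
                    if l == 1:
                        s *= 0.5 / p
                    ss += cc[i] * cc[j] * s
            cc = cc / np.sqrt(ss)
            centers.append(xyz[ia])
            ls.append(l)
            alphas.append(a)
            coefs.append(cc)
            atoms.append(ia)
            offsets.append(nao)
            nao += 2 * l + 1
    return BasisSet(
        label="STO-3G",
        centers=np.array(centers),
        shell_l=np.array(ls, dtype=np.int64),
        alphas=np.array(alphas),
        coefs=np.array(coefs),
        shell_atom=np.array(atoms, dtype=np.int64),
        ao_offset=np.array(offsets, dtype=np.int64),
    )
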