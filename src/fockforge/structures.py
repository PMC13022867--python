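"""Idealized starting structures for the molecules studied here.

Diatomics are built from covalent-radius estimates and relaxed by a bond scan;
alkanes are built as ideal tetrahedral zigzag chains (r_CC = 1.54 A,
r_CH = 1.09 A, staggered) and then relaxed with the analytic gradient. These
are starting points only — every equilibrium used by the samplers is
re-optimized at the requested level of theory.
"""

from __future__ import annotations

import numpy as np

from .constants import COVALENT_RADIUS
from .geometry import Geometry, canonical_frame

__all__ = ["diatomic", "alkane", "initial_structure"]

_R_CC = 1.54
_R_CH = 1.09
_ANG_CCC = np.deg2rad(112.0)
_ANG_HCH = np.deg2rad(107.8)
_TETRA = np.deg2rad(109.471)


def diatomic(el1: str, el2: str, r: float | None = None) -> Geometry:
    if r is None:
        r = COVALENT_RADIUS[el1] + COVALENT_RADIUS[el2]
    return Geometry((el1, el2), [[0.0, 0.0, 0.0], [r, 0.0, 0.0]], frame_canonical=True)


def _methyl_hydrogens(c: np.ndarray, axis: np.ndarray, ref_perp: np.ndarray,
                      phase: float = np.pi):
    """Three H on a terminal carbon, rotated by `phase` about -axis."""
    axis = axis / np.linalg.norm(axis)
    w = ref_perp - np.dot(ref_perp, axis) * axis
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(axis, [0.0, 1.0, 0.0])
    w = w / np.linalg.norm(w)
    v = np.cross(axis, w)
    hs = []
    for k in range(3):
        phi = phase + 2.0 * np.pi * k / 3.0
        d = -np.cos(np.pi - _TETRA) * axis + np.sin(np.pi - _TETRA) * (
            np.cos(phi) * w + np.sin(phi) * v
        )
        hs.append(c + _R_CH * d / np.linalg.norm(d))
    return hs


def alkane(n_carbon: int) -> Geometry:
    """n-alkane C_nH_(2n+2); anti zigzag backbone in the xz plane."""
    if n_carbon < 1:
        raise ValueError("need at least one carbon")
    if n_carbon == 1:
        d = _R_CH / np.sqrt(3.0)
        coords = [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
        return canonical_frame(Geometry(("C",) + ("H",) * 4, np.array(coords)))
    # backbone
    half = _ANG_CCC / 2.0
    cs = []
    for i in range(n_carbon):
        cs.append([i * _R_CC * np.sin(half), 0.0, (i % 2) * _R_CC * np.cos(half)])
    cs = np.array(cs)
    elements = ["C"] * n_carbon
    coords = list(cs)
    for i in range(n_carbon):
        if i == 0:
            axis = cs[0] - cs[1]
            ref = np.array([0.0, 0.0, 1.0]) if n_carbon == 2 else cs[2] - cs[1]
            coords.extend(_methyl_hydrogens(cs[0], axis, ref))
            elements.extend(["H"] * 3)
        elif i == n_carbon - 1:
            axis = cs[i] - cs[i - 1]
            ref = np.array([0.0, 0.0, 1.0]) if n_carbon == 2 else cs[i - 2] - cs[i - 1]
            # for ethane the two methyls share the reference axis: offset the
            # second by 60 degrees so the conformer is staggered, not eclipsed
            phase = np.pi + (np.pi / 3.0 if n_carbon == 2 else 0.0)
            coords.extend(_methyl_hydrogens(cs[i], axis, ref, phase=phase))
            elements.extend(["H"] * 3)
        else:
            d1 = cs[i - 1] - cs[i]
            d2 = cs[i + 1] - cs[i]
            b = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
            b /= np.linalg.norm(b)
            w = np.cross(d1, d2)
            w /= np.linalg.norm(w)
            for sgn in (1.0, -1.0):
                d = -np.cos(_ANG_HCH / 2.0) * b + sgn * np.sin(_ANG_HCH / 2.0) * w
                coords.append(cs[i] + _R_CH * d / np.linalg.norm(d))
                elements.append("H")
    return canonical_frame(Geometry(tuple(elements), np.array(coords)))


# RHF/STO-3G equilibrium structures (angstrom), relaxed with this package's
# analytic gradients; used as the standard input structures so that runtime
# re-relaxation converges in a handful of steps.
_EQ_RHF_STO3G = {
    "CH4": (
        ("C", "H", "H", "H", "H"),
        [[0.0, 0.0, 0.0], [1.08301085, 0.0, 0.0],
         [-0.36100362, 1.02107242, 0.0], [-0.36100362, -0.51053621, 0.88427466],
         [-0.36100362, -0.51053621, -0.88427466]],
    ),
    "C2H6": (  # staggered conformer
        ("C", "C", "H", "H", "H", "H", "H", "H"),
        [[0.0, 0.0, 0.0], [1.53765978, 0.0, 0.0],
         [-0.3844493, 1.01572169, 0.0], [-0.3844493, -0.50786084, -0.87964078],
         [-0.3844493, -0.50786084, 0.87964078], [1.92210908, 0.50786084, 0.87964078],
         [1.92210908, -1.01572169, 0.0], [1.92210908, 0.50786084, -0.87964078]],
    ),
    "C3H8": (
        ("C", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H"),
        [[0.0, 0.0, 0.0], [1.54119056, 0.0, 0.0], [2.13073663, 1.42397464, 0.0],
         [-0.38239267, -1.01645131, 0.0], [-0.38420414, 0.508056, 0.87959908],
         [-0.38420414, 0.508056, -0.87959908], [1.90039426, -0.53748743, -0.87583333],
         [1.90039426, -0.53748743, 0.87583333], [3.21615659, 1.38846482, 0.0],
         [1.80828928, 1.9733028, -0.87959908], [1.80828928, 1.9733028, 0.87959908]],
    ),
    "C4H10": (
        ("C", "C", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H", "H", "H"),
        [[0.0, 0.0, 0.0], [1.54109885, 0.0, 0.0], [2.13117016, 1.42788786, 0.0],
         [3.67226901, 1.42788786, 0.0], [-0.38224042, -1.01652487, 0.0],
         [-0.38464293, 0.50774581, 0.87957864], [-0.38464293, 0.50774581, -0.87957864],
         [1.90101712, -0.53702354, -0.87575711], [1.90101712, -0.53702354, 0.87575711],
         [1.77125189, 1.96491139, 0.87575711], [1.77125189, 1.96491139, -0.87575711],
         [4.05450944, 2.44441272, 0.0], [4.05691194, 0.92014205, 0.87957864],
         [4.05691194, 0.92014205, -0.87957864]],
    ),
}


def initial_structure(name: str) -> Geometry:
    """Named starting structures: 'CH4', 'C2H6', ..., or 'LiCl' style diatomics."""
    if name in _EQ_RHF_STO3G:
        els, coords = _EQ_RHF_STO3G[name]
        return canonical_frame(Geometry(els, np.array(coords)))
    alkanes = {"CH4": 1, "C2H6": 2, "C3H8": 3, "C4H10": 4, "C8H18": 8}
    if name in alkanes:
        return alkane(alkanes[name])
    import re

    m = re.fullmatch(r"([A-Z][a-z]?)([A-Z][a-z]?)", name)
    if m:
        return diatomic(m.group(1), m.group(2))
    raise ValueError(f"unknown structure {name!r}")
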