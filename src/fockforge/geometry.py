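"""Molecular geometries, XYZ I/O and the canonical molecular frame.

A single canonical orientation is used for every geometry seen by the search:
atom 1 sits at the origin, atom 2 on the +x axis, and the first non-collinear
atom in the upper half of the xy-plane. Fixing the frame removes global
rotation/translation from the learning problem, so a surrogate program never
has to discover the invariance itself.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ANGSTROM_TO_BOHR, ELEMENT_MASS, ELEMENT_Z

__all__ = ["Geometry", "canonical_frame", "read_xyz", "write_xyz"]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class Geometry:
    """Elements plus Cartesian coordinates in angstrom.

    Only closed-shell neutral/charged species with an even electron count are
    accepted; odd-electron systems are rejected on construction.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (natom, 3), angstrom
    charge: int = 0
    frame_canonical: bool = False
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(len(self.elements), 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) < 1:
            raise ValueError("geometry needs at least one atom")
        for el in self.elements:
            if el not in ELEMENT_Z:
                raise ValueError(f"unsupported element {el!r}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if self.n_electrons % 2 != 0 and not self.metadata.get("allow_open_shell"):
            raise ValueError(
                f"odd electron count ({self.n_electrons}); only closed-shell "
                "species are supported"
            )

    @property
    def natom(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return sum(ELEMENT_Z[el] for el in self.elements) - self.charge

    @property
    def charges(self) -> np.ndarray:
        return np.array([ELEMENT_Z[el] for el in self.elements], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASS[el] for el in self.elements])

    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR

    def composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for el in self.elements:
            comp[el] = comp.get(el, 0) + 1
        return comp

    def with_coords(self, coords: np.ndarray, frame_canonical: bool = False) -> "Geometry":
        return replace(self, coords=np.asarray(coords, float), frame_canonical=frame_canonical)

    def key(self, basis_label: str = "") -> str:
        """Content hash used to key integral caches."""
        h = hashlib.sha256()
        h.update(",".join(self.elements).encode())
        h.update(np.round(self.coords, 10).tobytes())
        h.update(str(self.charge).encode())
        h.update(basis_label.encode())
        return h.hexdigest()[:16]


def canonical_frame(geom: Geometry) -> Geometry:
    """Rotate/translate a geometry into the canonical molecular frame.

    Atom 1 at the origin; atom 2 along +x; the first atom that is not
    collinear with that axis is placed in the y > 0 half of the xy-plane.
    Idempotent, and invariant under any proper or improper input rotation up
    to the fixed handedness convention.
    """
    xyz = geom.coords - geom.coords[0]
    meta = dict(geom.metadata)
    if geom.natom == 1:
        return geom.with_coords(xyz, frame_canonical=True)

    # x axis along atom 0 -> 1
    ex = xyz[1]
    nx = np.linalg.norm(ex)
    if nx < _COLLINEAR_TOL:
        raise ValueError("atoms 1 and 2 coincide; cannot fix the frame")
    ex = ex / nx

    # first atom with a component off the x axis defines the xy-plane
    ey = None
    for idx in range(2, geom.natom):
        perp = xyz[idx] - np.dot(xyz[idx], ex) * ex
        if np.linalg.norm(perp) > _COLLINEAR_TOL:
            ey = perp / np.linalg.norm(perp)
            if idx != 2:
                meta["frame_plane_atom"] = idx
            break
    if ey is None:
        # linear molecule: any perpendicular completes the frame
        trial = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(trial, ex)) > 0.9:
            trial = np.array([0.0, 0.0, 1.0])
        ey = trial - np.dot(trial, ex) * ex
        ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    rot = np.stack([ex, ey, ez])  # rows are the new basis vectors
    out = xyz @ rot.T
    # exact zeros for the constrained entries keep the frame bitwise stable
    out[0] = 0.0
    out[1, 1:] = 0.0
    return Geometry(geom.elements, out, geom.charge, frame_canonical=True, metadata=meta)


def read_xyz(path) -> list[Geometry]:
    """Read one or more concatenated XYZ blocks.

    A ``E_ref=<hartree>`` token in the comment line is parsed into
    ``metadata['E_ref']``.
    """
    geoms = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natom = int(lines[i].strip())
        comment = lines[i + 1]
        elements, coords = [], []
        for ln in lines[i + 2 : i + 2 + natom]:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        meta = {}
        for token in comment.split():
            if token.startswith("E_ref="):
                meta["E_ref"] = float(token.split("=", 1)[1])
        geoms.append(Geometry(tuple(elements), np.array(coords), metadata=meta))
        i += 2 + natom
    return geoms


def write_xyz(path, geoms, comments=None) -> None:
    if isinstance(geoms, Geometry):
        geoms = [geoms]
    with open(path, "w") as fh:
        for k, g in enumerate(geoms):
            if comments is not None:
                comment = comments[k]
            elif "E_ref" in g.metadata:
                comment = f"E_ref={g.metadata['E_ref']:.17g}"
            else:
                comment = ""
            fh.write(f"{g.natom}\n{comment}\n")
            for el, (x, y, z) in zip(g.elements, g.coords):
                fh.write(f"{el:3s} {x: .17g} {y: .17g} {z: .17g}\n")
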