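"""On-disk cache for AO integral contexts.

One HDF5 container holds any number of AOContext records, keyed by the
geometry content hash combined with the basis label. Integral evaluation is
the dominant fixed cost of every pipeline stage, so long-running workflows
(or interrupted ones picking up from checkpoints) can reuse earlier work.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import Geometry
from .scf import AOContext, build_ao_context

__all__ = ["ContextCache"]


class ContextCache:
    """HDF5-backed store of per-geometry AO quantities."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def _key(self, geometry: Geometry, basis_label: str) -> str:
        return geometry.key(basis_label)

    def has(self, geometry: Geometry, basis_label: str = "STO-3G") -> bool:
        if not self.path.exists():
            return False
        with h5py.File(self.path, "r") as fh:
            return self._key(geometry, basis_label) in fh

    def store(self, ctx: AOContext) -> str:
        key = self._key(ctx.geometry, ctx.basis_label)
        with h5py.File(self.path, "a") as fh:
            if key in fh:
                return key
            grp = fh.create_group(key)
            grp.create_dataset("S", data=ctx.S)
            grp.create_dataset("Hcore", data=ctx.Hcore)
            grp.create_dataset("eri", data=ctx.eri)
            grp.create_dataset("V_per_atom", data=ctx.V_per_atom)
            grp.create_dataset("T_kin", data=ctx.T_kin)
            grp.create_dataset("coords", data=ctx.geometry.coords)
            grp.attrs["elements"] = ",".join(ctx.geometry.elements)
            grp.attrs["charge"] = ctx.geometry.charge
            grp.attrs["E_nuc"] = ctx.E_nuc
            grp.attrs["n_occ"] = ctx.n_occ
            grp.attrs["basis_label"] = ctx.basis_label
        return key

    def load(self, geometry: Geometry, basis_label: str = "STO-3G") -> AOContext:
        key = self._key(geometry, basis_label)
        with h5py.File(self.path, "r") as fh:
            if key not in fh:
                raise KeyError(f"no cached context for {key}")
            grp = fh[key]
            ctx = AOContext(
                S=grp["S"][...],
                Hcore=grp["Hcore"][...],
                eri=grp["eri"][...],
                E_nuc=float(grp.attrs["E_nuc"]),
                n_ao=grp["S"].shape[0],
                n_occ=int(grp.attrs["n_occ"]),
                basis_label=str(grp.attrs["basis_label"]),
                geometry=geometry,
                V_per_atom=grp["V_per_atom"][...],
                T_kin=grp["T_kin"][...],
            )
        return ctx

    def get_or_build(self, geometry: Geometry, basis_label: str = "STO-3G") -> AOContext:
        """Load if present, otherwise compute and store."""
        if self.has(geometry, basis_label):
            return self.load(geometry, basis_label)
        ctx = build_ao_context(geometry, basis_label)
        self.store(ctx)
        return ctx
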