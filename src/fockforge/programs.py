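"""Programs: ordered function sequences, their interpreter, and serialization.

A program of length N_f is one input function, N_f - 2 internal functions and
one output function. Interpretation is deterministic: the same program,
geometry and catalogue hash yield a bitwise-identical workspace matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import library
from .oneshot import GAP_TOL, MoleculeBatch
from .scf import MOSet

__all__ = ["Program", "run_program", "run_program_batched", "program_energies",
           "save_program", "load_program", "CatalogueMismatchError"]

DEFAULT_N_F = 15


class CatalogueMismatchError(RuntimeError):
    pass


@dataclass(frozen=True)
class Program:
    function_ids: tuple[str, ...]

    def __post_init__(self):
        ids = tuple(self.function_ids)
        object.__setattr__(self, "function_ids", ids)
        if len(ids) < 3:
            raise ValueError("a program needs at least input, one internal, output")
        roles = [library.get_function(f)[0] for f in ids]
        if roles[0] != "input":
            raise ValueError(f"position 0 must be an input function, got {ids[0]!r}")
        if roles[-1] != "output":
            raise ValueError(f"last position must be an output function, got {ids[-1]!r}")
        for k, r in enumerate(roles[1:-1], start=1):
            if r != "internal":
                raise ValueError(f"position {k} must be internal, got {ids[k]!r}")

    @property
    def n_f(self) -> int:
        return len(self.function_ids)

    @property
    def input_id(self) -> str:
        return self.function_ids[0]

    @property
    def internal_ids(self) -> tuple[str, ...]:
        return self.function_ids[1:-1]

    @property
    def output_id(self) -> str:
        return self.function_ids[-1]


def run_program_batched(program: Program, batch: MoleculeBatch):
    """Interpret a program on every geometry of a batch.

    Returns (M, mos_factory, valid): the stacked workspace matrices, a
    callable producing per-geometry MOSets under the program's output
    convention, and the per-geometry validity mask.
    """
    _, init = library.get_function(program.input_id)
    M = init(batch)
    valid = library._validity(M)
    for fid in program.internal_ids:
        if not valid.any():
            break
        _, f = library.get_function(fid)
        M, ok = f(library._sanitize(M, valid), batch)
        valid = valid & library._validity(M)
        if ok is not None:
            valid = valid & ok
    return M, valid


def run_program_layers(program: Program, batch: MoleculeBatch, layers=None, start=0):
    """Interpret a program, keeping the (M, valid) state after every layer.

    ``layers[j]`` is the state after applying ``function_ids[j]``
    (j = 0 is the input layer). Passing the stored layers of a previous,
    partially identical program together with the first differing position
    lets the annealer skip the unchanged prefix.
    """
    n_internal_end = program.n_f - 1
    out: list = list(layers[:start]) if layers else []
    if start == 0 or not out:
        _, init = library.get_function(program.input_id)
        M = init(batch)
        valid = library._validity(M)
        out = [(M, valid)]
        start = 1
    else:
        M, valid = out[-1]
    for k in range(start, n_internal_end):
        fid = program.function_ids[k]
        if valid.any():
            _, f = library.get_function(fid)
            M, ok = f(library._sanitize(M, valid), batch)
            valid = valid & library._validity(M)
            if ok is not None:
                valid = valid & ok
        out.append((M, valid))
    return out


def energies_from_layers(program: Program, batch: MoleculeBatch, layers,
                         gap_tol: float = GAP_TOL):
    """One-shot energies given the stored final internal layer."""
    M, valid = layers[-1]
    M = library._sanitize(M, valid)
    w, C = _mos_from_output(program.output_id, M, batch)
    occ = C[:, :, : batch.n_occ]
    P = 2.0 * occ @ occ.transpose(0, 2, 1)
    if batch.n_occ < batch.n_ao:
        gap = w[:, batch.n_occ] - w[:, batch.n_occ - 1]
        valid = valid & (gap >= gap_tol)
    F = batch.fock(P)
    e = 0.5 * np.einsum("gij,gij->g", P, batch.Hcore + F) + batch.E_nuc
    valid = valid & np.isfinite(e)
    return np.where(valid, e, np.inf), valid


def _mos_from_output(output_id: str, M: np.ndarray, batch: MoleculeBatch):
    """Batched MO coefficients/eigenvalues under the output convention."""
    if output_id == "out_gen_eig":
        w, C = batch.eigh_gen(M)
    elif output_id == "out_lowdin_eig":
        from ._eig import eigh_batch

        w, y = eigh_batch((M + M.transpose(0, 2, 1)) / 2.0)
        C = batch.X @ y
    else:
        raise KeyError(output_id)
    return w, C


def program_energies(program: Program, batch: MoleculeBatch, gap_tol: float = GAP_TOL):
    """One-shot HF energies of a program over a batch: (E (G,), valid (G,))."""
    M, valid = run_program_batched(program, batch)
    M = library._sanitize(M, valid)
    w, C = _mos_from_output(program.output_id, M, batch)
    occ = C[:, :, : batch.n_occ]
    P = 2.0 * occ @ occ.transpose(0, 2, 1)
    if batch.n_occ < batch.n_ao:
        gap = w[:, batch.n_occ] - w[:, batch.n_occ - 1]
        valid = valid & (gap >= gap_tol)
    F = batch.fock(P)
    e = 0.5 * np.einsum("gij,gij->g", P, batch.Hcore + F) + batch.E_nuc
    valid = valid & np.isfinite(e)
    return np.where(valid, e, np.inf), valid


def program_densities(program: Program, batch: MoleculeBatch, gap_tol: float = GAP_TOL):
    """Predicted one-shot density matrices over a batch: (P (G,n,n), valid)."""
    M, valid = run_program_batched(program, batch)
    M = library._sanitize(M, valid)
    w, C = _mos_from_output(program.output_id, M, batch)
    occ = C[:, :, : batch.n_occ]
    P = 2.0 * occ @ occ.transpose(0, 2, 1)
    if batch.n_occ < batch.n_ao:
        gap = w[:, batch.n_occ] - w[:, batch.n_occ - 1]
        valid = valid & (gap >= gap_tol)
    return P, valid


def run_program(program: Program, ctx):
    """Single-geometry interpretation: (workspace M, MOSet, valid flag)."""
    batch = MoleculeBatch([ctx])
    M, valid = run_program_batched(program, batch)
    ok = bool(valid[0])
    if not ok:
        return M[0], None, False
    w, C = _mos_from_output(program.output_id, M, batch)
    from .scf import _fix_eigvec_signs

    mos = MOSet(coeffs=_fix_eigvec_signs(C[0]), eigenvalues=w[0])
    return M[0], mos, True


# serialization --------------------------------------------------------------

def save_program(path, program: Program, shifts: dict[str, float], basis_label: str,
                 method: str, provenance: dict | None = None) -> None:
    rec = {
        "format": "fockforge-program-v1",
        "n_f": program.n_f,
        "function_ids": list(program.function_ids),
        "shifts_hartree": dict(shifts),
        "basis_label": basis_label,
        "method": method,
        "catalogue_hash": library.catalogue_hash(),
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        json.dump(rec, fh, indent=1, sort_keys=True)


def load_program(path):
    """Load (program, shifts, record); refuses stale catalogue hashes."""
    with open(path) as fh:
        rec = json.load(fh)
    have = library.catalogue_hash()
    if rec.get("catalogue_hash") != have:
        raise CatalogueMismatchError(
            f"program was produced with catalogue {rec.get('catalogue_hash')}, "
            f"current catalogue is {have}; refusing to reinterpret it"
        )
    prog = Program(tuple(rec["function_ids"]))
    return prog, dict(rec["shifts_hartree"]), rec
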