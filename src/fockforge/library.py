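"""The catalogue of parameter-free workspace-matrix functions.

A program is a path input -> internals -> output. Input functions initialize
the workspace matrix from AO-basis data (core Hamiltonian, overlap, a
Wolfsberg-Helmholz extended-Hueckel guess, one-Fock-build guesses); internal
functions apply generic symmetric-matrix transformations grouped in families
(context-matrix combinations, S-metric powers, elementwise and spectral scalar
maps, normalizations, Hadamard products, Roothaan steps, identity); the two
output functions fix the diagonalization convention (generalized S-metric
eigensolve, or a plain eigensolve in the Loewdin-orthogonalized basis).

Every function is parameter-free: the only embedded constants are universal
(the Hueckel factor 1.75 and the exponential clipping bound). All operations
act on stacked (G, nao, nao) workspace arrays for a :class:`MoleculeBatch`
and return a per-geometry validity mask; non-finite or norm-exploding results
flag the geometry invalid instead of raising.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .oneshot import GAP_TOL, NORM_MAX, MoleculeBatch

__all__ = [
    "FunctionSpec",
    "catalog",
    "catalogue_hash",
    "get_function",
    "init_workspace",
    "apply_internal",
    "ids_by_role",
]

#: Wolfsberg-Helmholz constant of the extended-Hueckel guess; with the 1/2 of
#: the symmetrized average it enters as 0.875.
HUCKEL_K = 1.75

_EXP_CLIP = 20.0


@dataclass(frozen=True)
class FunctionSpec:
    id: str
    layer_role: str  # input | internal | output
    description: str
    safety: str = ""
    searchable: bool = True


def _sym(M):
    return (M + M.transpose(0, 2, 1)) / 2.0


def _validity(M):
    # one fused reduction: the squared Frobenius norm is NaN/inf exactly when
    # the matrix is non-finite, and the <= comparison is then False
    flat = M.reshape(M.shape[0], -1)
    sq = np.einsum("gi,gi->g", flat, flat)
    return sq <= NORM_MAX * NORM_MAX


def _sanitize(M, valid):
    """Replace invalid geometries' workspaces with I so eigensolvers don't blow up."""
    if valid.all():
        return M
    out = M.copy()
    eye = np.eye(M.shape[1])
    out[~valid] = eye
    return out


# ---------------------------------------------------------------------------
# input layer
# ---------------------------------------------------------------------------

def _in_hcore(batch):
    return batch.Hcore.copy()


def _in_overlap(batch):
    return batch.S.copy()


def _in_gwh(batch):
    hd = np.einsum("gii->gi", batch.Hcore)
    M = 0.5 * HUCKEL_K * batch.S * (hd[:, :, None] + hd[:, None, :])
    for g in range(M.shape[0]):
        np.fill_diagonal(M[g], hd[g])
    return M


def _in_core_fock(batch):
    P, _ = batch.density(batch.Hcore.copy())
    return batch.fock(P)


def _in_sinv_h(batch):
    return _sym(batch.Sinv @ batch.Hcore)


def _in_sad_fock(batch):
    from .atoms import atomic_density_blocks

    P = atomic_density_blocks(batch)
    return batch.fock(P)


_INPUTS = {
    "in_hcore": (_in_hcore, "M = Hcore"),
    "in_overlap": (_in_overlap, "M = S"),
    "in_huckel": (_in_gwh, "Wolfsberg-Helmholz guess: M_uv = 0.875 S_uv (H_uu + H_vv), M_uu = H_uu"),
    "in_core_fock": (_in_core_fock, "M = F[P(Hcore)] (one Fock build from the core guess)"),
    "in_sinv_hcore": (_in_sinv_h, "M = (S^-1 Hcore + Hcore S^-1)/2"),
    "in_sad_fock": (_in_sad_fock, "M = F[P_atoms] (superposition of atomic densities)"),
}


# ---------------------------------------------------------------------------
# internal layer
# ---------------------------------------------------------------------------

def _ctx_matrix(name, M, batch):
    """Context matrices; M-dependent ones carry their own validity."""
    if name == "hcore":
        return batch.Hcore, None
    if name == "s":
        return batch.S, None
    if name == "sinv":
        return batch.Sinv, None
    if name == "identity":
        return np.broadcast_to(np.eye(batch.n_ao), M.shape), None
    if name == "density":
        P, gap = batch.density(M)
        return P, gap >= GAP_TOL
    if name == "fock":
        P, gap = batch.density(M)
        return batch.fock(P), gap >= GAP_TOL
    if name == "coulomb":
        P, gap = batch.density(M)
        return batch.coulomb(P), gap >= GAP_TOL
    if name == "exchange":
        P, gap = batch.density(M)
        return batch.exchange(P), gap >= GAP_TOL
    raise KeyError(name)


def _make_combine(xname, mode):
    def op(M, batch):
        X, valid = _ctx_matrix(xname, M, batch)
        if mode == "add":
            out = M + X
        elif mode == "sub":
            out = M - X
        elif mode == "symprod":
            out = _sym(M @ X)
        else:  # replace
            out = X + 0.0 * M  # broadcast copy
        return _sym(out), valid

    return op


_SCALAR_MAPS = {
    "square": lambda x: x**2,
    "cube": lambda x: x**3,
    "signed_sqrt": lambda x: np.sign(x) * np.sqrt(np.abs(x)),
    "tanh": np.tanh,
    "sin": np.sin,
    "exp": lambda x: np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP)),
    "signed_log": lambda x: np.sign(x) * np.log1p(np.abs(x)),
    "abs": np.abs,
    "soft": lambda x: x / (1.0 + np.abs(x)),
}

#: scalar maps that are monotone increasing on the whole real line: spectral
#: versions of these provably preserve the one-shot energy
MONOTONE_MAPS = ("cube", "signed_sqrt", "tanh", "exp", "signed_log", "soft")


def _make_elementwise(mname):
    f = _SCALAR_MAPS[mname]

    def op(M, batch):
        return _sym(f(M)), None

    return op


def _make_spectral(mname):
    f = _SCALAR_MAPS[mname]

    def op(M, batch):
        valid = _validity(M)
        w, C = batch.eigh_gen(_sanitize(M, valid))
        SC = batch.S @ C
        out = (SC * f(w)[:, None, :]) @ SC.transpose(0, 2, 1)
        return _sym(out), valid

    return op


def _op_smetric_square(M, batch):
    return _sym(M @ batch.Sinv @ M), None


def _op_smetric_cube(M, batch):
    MS = M @ batch.Sinv
    return _sym(MS @ MS @ M), None


def _op_norm_fro(M, batch):
    n = np.linalg.norm(M.reshape(M.shape[0], -1), axis=1)
    ok = n > 1e-300
    return M / np.where(ok, n, 1.0)[:, None, None], ok


def _op_norm_max(M, batch):
    n = np.max(np.abs(M.reshape(M.shape[0], -1)), axis=1)
    ok = n > 1e-300
    return M / np.where(ok, n, 1.0)[:, None, None], ok


def _op_norm_trace(M, batch):
    n = np.abs(np.einsum("gij,gji->g", M, batch.S))
    ok = n > 1e-12
    return M / np.where(ok, n, 1.0)[:, None, None], ok


def _op_had_s(M, batch):
    return M * batch.S, None


def _op_had_hcore(M, batch):
    return M * batch.Hcore, None


def _op_had_sign_hcore(M, batch):
    return _sym(M * np.sign(batch.Hcore)), None


def _op_roothaan(M, batch):
    P, gap = batch.density(M)
    return batch.fock(P), gap >= GAP_TOL


def _op_roothaan_avg(M, batch):
    P, gap = batch.density(M)
    return _sym(0.5 * (M + batch.fock(P))), gap >= GAP_TOL


def _op_identity(M, batch):
    return M, None


def _build_internal_table():
    table = {}
    ctx_names = ("hcore", "s", "sinv", "identity", "density", "fock", "coulomb", "exchange")
    mode_desc = {
        "add": "M + {x}",
        "sub": "M - {x}",
        "symprod": "(M {x} + {x} M)/2",
        "replace": "M <- {x}",
    }
    for x in ctx_names:
        for mode in ("add", "sub", "symprod", "replace"):
            table[f"{mode}_{x}"] = (_make_combine(x, mode), mode_desc[mode].format(x=x.upper()))
    table["smetric_square"] = (_op_smetric_square, "M S^-1 M")
    table["smetric_cube"] = (_op_smetric_cube, "M S^-1 M S^-1 M")
    for m in _SCALAR_MAPS:
        table[f"ew_{m}"] = (_make_elementwise(m), f"elementwise {m}, symmetrized")
    for m in _SCALAR_MAPS:
        table[f"sp_{m}"] = (
            _make_spectral(m),
            f"spectral {m}: apply to generalized eigenvalues, eigenvector-preserving",
        )
    table["norm_fro"] = (_op_norm_fro, "M / ||M||_F")
    table["norm_max"] = (_op_norm_max, "M / max|M_uv|")
    table["norm_trace"] = (_op_norm_trace, "M / |Tr(M S)|")
    table["had_s"] = (_op_had_s, "Hadamard product with S")
    table["had_hcore"] = (_op_had_hcore, "Hadamard product with Hcore")
    table["had_sign_hcore"] = (_op_had_sign_hcore, "Hadamard product with sign(Hcore)")
    table["roothaan"] = (_op_roothaan, "M -> F[P(M)] (one Roothaan step)")
    table["roothaan_avg"] = (_op_roothaan_avg, "M -> (M + F[P(M)])/2 (damped Roothaan step)")
    table["identity"] = (_op_identity, "identity")
    return table


_INTERNALS = _build_internal_table()

_OUTPUTS = {
    "out_gen_eig": "generalized eigensolve M c = S c e (S-metric)",
    "out_lowdin_eig": "plain eigensolve of M; coefficients mapped back by S^-1/2",
}

# test-only input: the SCF-converged Fock matrix itself (excluded from the
# searchable catalogue; used by invariance tests)
_TEST_ONLY_INPUTS = ("in_oracle_fock",)


def catalog(include_test_only: bool = False) -> list[FunctionSpec]:
    specs = [
        FunctionSpec(fid, "input", desc) for fid, (_, desc) in sorted(_INPUTS.items())
    ]
    if include_test_only:
        specs += [
            FunctionSpec("in_oracle_fock", "input",
                         "SCF-converged Fock matrix (test-only oracle)", searchable=False)
        ]
    specs += [
        FunctionSpec(fid, "internal", desc,
                     safety="result flagged invalid if non-finite or ||.||_F > 1e8")
        for fid, (_, desc) in sorted(_INTERNALS.items())
    ]
    specs += [FunctionSpec(fid, "output", desc) for fid, desc in sorted(_OUTPUTS.items())]
    return specs


def catalogue_hash() -> str:
    h = hashlib.sha256()
    for s in catalog():
        h.update(f"{s.id}|{s.layer_role}|{s.description};".encode())
    return h.hexdigest()[:16]


def ids_by_role(role: str, subset: list[str] | None = None) -> list[str]:
    ids = [s.id for s in catalog() if s.layer_role == role]
    if subset is not None:
        ids = [i for i in ids if i in subset]
    return ids


def get_function(fid: str):
    """(role, callable) for a function id; input callables take a batch."""
    if fid in _INPUTS:
        return "input", _INPUTS[fid][0]
    if fid == "in_oracle_fock":
        return "input", _in_oracle_fock
    if fid in _INTERNALS:
        return "internal", _INTERNALS[fid][0]
    if fid in _OUTPUTS:
        return "output", fid
    raise KeyError(f"unknown function id {fid!r}")


def _in_oracle_fock(batch):
    from .scf import reference_scf

    return np.stack([reference_scf(c).fock for c in batch.contexts])


# single-geometry convenience API -------------------------------------------

def _batch_of_one(ctx):
    return MoleculeBatch([ctx])


def init_workspace(input_id: str, ctx) -> np.ndarray:
    role, f = get_function(input_id)
    if role != "input":
        raise ValueError(f"{input_id!r} is not an input function")
    return f(_batch_of_one(ctx))[0]


def apply_internal(internal_id: str, M: np.ndarray, ctx):
    """Apply one internal function to a single workspace matrix.

    Returns (M', valid: bool)."""
    role, f = get_function(internal_id)
    if role != "internal":
        raise ValueError(f"{internal_id!r} is not an internal function")
    batch = _batch_of_one(ctx)
    Mb = M[None, :, :]
    out, valid = f(Mb, batch)
    ok = _validity(out)
    if valid is not None:
        ok &= valid
    return out[0], bool(ok[0])
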