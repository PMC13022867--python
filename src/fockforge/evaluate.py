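"""Hold-out evaluation of trained programs, MO comparison and ablation.

Test-time evaluation never refits the per-element shifts: the shifts learned
in training are reused, which is what makes transfer to molecules absent
from training (same element set) a meaningful test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anneal import ShiftModel, TrainingSet, loss_mse
from .constants import HARTREE_TO_KCAL
from .oneshot import MoleculeBatch
from .programs import Program, program_energies, run_program
from .scf import MOSet

__all__ = ["EvalReport", "evaluate_program", "compare_mos", "ablate"]


@dataclass
class EvalReport:
    rmse_kcal: float
    max_abs_kcal: float
    r2: float
    per_molecule: dict[str, dict]
    residuals_kcal: dict[str, np.ndarray]
    n_geometries: int
    rmse_kcal_per_atom: float

    def __str__(self):
        lines = [
            f"pooled RMSE          {self.rmse_kcal:8.3f} kcal/mol",
            f"max |error|          {self.max_abs_kcal:8.3f} kcal/mol",
            f"R^2                  {self.r2:8.5f}",
            f"geometries           {self.n_geometries:8d}",
        ]
        for name, rec in self.per_molecule.items():
            lines.append(
                f"  {name:10s} rmse {rec['rmse_kcal']:7.3f}  max {rec['max_abs_kcal']:7.3f}  "
                f"R^2 {rec['r2']:.5f}  (n={rec['n']})"
            )
        return "\n".join(lines)


def evaluate_program(
    program: Program,
    shifts: ShiftModel,
    species_data: dict[str, MoleculeBatch],
    d_refs: dict[str, float],
    compositions: dict[str, dict[str, int]] | None = None,
    allow_partial: bool = False,
) -> EvalReport:
    """Frozen-shift evaluation on hold-out geometries.

    species_data maps molecule name -> MoleculeBatch (with e_ref set);
    d_refs maps name -> independent-atom energy sum D_i. By default any
    invalid geometry raises; with allow_partial the metrics cover the valid
    subset and the per-molecule record carries n_valid alongside n.
    """
    per_molecule = {}
    residuals = {}
    all_res, all_y, all_yhat = [], [], []
    n_tot = 0
    atom_weighted = 0.0
    for name, batch in species_data.items():
        comp = (compositions or {}).get(name) or batch.composition
        dbar = shifts.molecular_shift(comp)  # raises if an element is missing
        e_pred, valid = program_energies(program, batch)
        if not valid.all():
            if not allow_partial or not valid.any():
                raise RuntimeError(
                    f"program invalid on {int((~valid).sum())} geometries of {name}")
        y = (batch.e_ref - d_refs[name])[valid]
        yhat = (e_pred - dbar)[valid]
        r = (yhat - y) * HARTREE_TO_KCAL
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot if ss_tot > 0 else math.nan
        per_molecule[name] = {
            "rmse_kcal": float(np.sqrt(np.mean(r**2))),
            "max_abs_kcal": float(np.max(np.abs(r))),
            "r2": r2,
            "n": batch.G,
            "n_valid": int(valid.sum()),
            "natom": sum(comp.values()),
        }
        residuals[name] = r
        all_res.append(r)
        all_y.append(y)
        all_yhat.append(yhat)
        n_tot += int(valid.sum())
        atom_weighted += float(np.sum(np.abs(r))) / sum(comp.values())
    res = np.concatenate(all_res)
    y = np.concatenate(all_y)
    yhat = np.concatenate(all_yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot if ss_tot > 0 else math.nan
    return EvalReport(
        rmse_kcal=float(np.sqrt(np.mean(res**2))),
        max_abs_kcal=float(np.max(np.abs(res))),
        r2=r2,
        per_molecule=per_molecule,
        residuals_kcal=residuals,
        n_geometries=n_tot,
        rmse_kcal_per_atom=atom_weighted / n_tot,
    )


def compare_mos(pred: MOSet, ref: MOSet, S: np.ndarray, fock: np.ndarray):
    """Match predicted to reference MOs by maximal |c_i^T S c_j|.

    Returns (matched overlaps (n,), predicted MO energies (n,), permutation).
    Predicted orbital energies are Rayleigh quotients c^T F c with the Fock
    matrix rebuilt from the predicted density — the workspace matrix's own
    eigenvalues live on an arbitrary surrogate scale and are not physical.
    """
    if pred.coeffs.shape != ref.coeffs.shape:
        raise ValueError("MO set dimension mismatch")
    ov = np.abs(pred.coeffs.T @ S @ ref.coeffs)  # |<pred_i | ref_j>|_S
    n = ov.shape[0]
    perm = np.full(n, -1)
    used = np.zeros(n, bool)
    # greedy assignment from the largest overlap down
    order = np.dstack(np.unravel_index(np.argsort(-ov, axis=None), ov.shape))[0]
    assigned = 0
    for i, j in order:
        if perm[i] < 0 and not used[j]:
            perm[i] = j
            used[j] = True
            assigned += 1
            if assigned == n:
                break
    overlaps = ov[np.arange(n), perm]
    energies = np.einsum("ij,jk,ki->i", pred.coeffs.T, fock, pred.coeffs)
    return overlaps, energies, perm


def ablate(program: Program, shifts: ShiftModel, training: TrainingSet) -> np.ndarray:
    """Fitness change (hartree RMSE) when each internal position is replaced
    by the identity function; shifts stay fixed throughout."""

    def fitness(p: Program) -> float:
        parts = []
        for sp in training.species:
            e, valid = program_energies(p, sp.batch)
            if not valid.all():
                return math.inf
            parts.append(e)
        return loss_mse(np.concatenate(parts), training, shifts).rmse

    base = fitness(program)
    deltas = np.empty(program.n_f - 2)
    for k in range(1, program.n_f - 1):
        ids = list(program.function_ids)
        ids[k] = "identity"
        deltas[k - 1] = fitness(Program(tuple(ids))) - base
    return deltas
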