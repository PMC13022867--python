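"""End-to-end experiment templates: sample -> reference -> train -> test.

Three built-in templates mirror the package's two study systems:

* ``diatomics-hf`` — train one program on LiCl + NaCl + LiF bond-length scans
  (15 geometries each within 0.25 hartree of the curve minimum, RHF/STO-3G),
  then test each curve up to 0.8 hartree above equilibrium and transfer to
  NaF, which is never trained on.
* ``diatomics-dft`` — the same protocol against restricted Kohn-Sham (LDA)
  references.
* ``alkanes`` — train on 18 methane + 18 ethane configurations drawn from
  normal-mode shell sampling of the four lowest modes (E_max = 0.03 hartree),
  test on unseen geometries including higher-frequency mode triples, and
  transfer to propane and n-butane with frozen shifts.

Every stage writes its artifacts (XYZ geometries with reference energies,
mode data, serialized programs, traces, reports) into the output directory
and is skipped on re-run if its artifact already exists.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import library
from .anneal import (
    SAConfig,
    SearchSpace,
    ShiftModel,
    build_training_set,
    multi_restart_search,
)
from .atoms import atomic_sum
from .constants import HARTREE_TO_KCAL
from .evaluate import EvalReport, evaluate_program
from .geometry import Geometry, read_xyz, write_xyz
from .modes import NormalModeBasis, compute_normal_modes
from .oneshot import MoleculeBatch
from .programs import Program, save_program
from .sampling import diatomic_training_scan, filter_by_reference_energy, sample_quadratic_shell
from .scf import build_ao_context
from .structures import initial_structure

__all__ = ["run_experiment", "ExperimentConfig", "TEMPLATES"]

DIATOMIC_TRAIN = (("Li", "Cl"), ("Na", "Cl"), ("Li", "F"))
DIATOMIC_HOLDOUT = ("Na", "F")
ALKANE_TRAIN = ("CH4", "C2H6")
ALKANE_TRANSFER = ("C3H8", "C4H10")


@dataclass
class ExperimentConfig:
    template: str
    out_dir: str
    basis: str = "STO-3G"
    method: str = "rhf"
    seed: int = 0
    n_restarts: int = 50
    n_select: int = 15
    sa: SAConfig = field(default_factory=SAConfig)
    # diatomic settings
    E_max_train: float = 0.25
    E_max_test: float = 0.8
    n_train_diatomic: int = 15
    n_test_diatomic: int = 50
    n_scan_grid: int = 160
    # alkane settings
    E_max_alkane: float = 0.03
    oversample_factor: float = 1.15
    database_sizes: dict = field(default_factory=lambda: {"CH4": 447, "C2H6": 295})
    n_train_alkane: int = 18
    n_test_alkane: int = 200
    n_transfer: int = 50
    n_sampling_modes: int = 4
    hessian_scheme: str = "central"


def _method_tag(method: str) -> str:
    return method.replace(":", "-")


# --- persistence helpers ----------------------------------------------------

def _save_modes(path: Path, nm: NormalModeBasis) -> None:
    rec = {
        "elements": list(nm.equilibrium.elements),
        "coords": nm.equilibrium.coords.tolist(),
        "frequencies": nm.frequencies.tolist(),
        "modes_mw": nm.modes_mw.tolist(),
        "energy": nm.energy,
        "method": nm.method,
        "basis_label": nm.basis_label,
    }
    path.write_text(json.dumps(rec))


def _load_modes(path: Path) -> NormalModeBasis:
    rec = json.loads(path.read_text())
    geom = Geometry(tuple(rec["elements"]), np.array(rec["coords"]), frame_canonical=True)
    return NormalModeBasis(
        equilibrium=geom,
        frequencies=np.array(rec["frequencies"]),
        modes_mw=np.array(rec["modes_mw"]),
        energy=rec["energy"],
        method=rec["method"],
        basis_label=rec["basis_label"],
    )


def _stage(path: Path, build, load, save):
    """Run a stage unless its artifact exists; returns the stage value."""
    if path.exists():
        return load(path)
    value = build()
    path.parent.mkdir(parents=True, exist_ok=True)
    save(path, value)
    return value


# --- diatomic pipeline ------------------------------------------------------

def _reference_densities(batches: dict) -> dict:
    """Converged SCF density stacks for every geometry of each batch.

    Geometries within a batch are ordered (bond-length scans ascending, mode
    samples near equilibrium), so each SCF warm-starts from its predecessor's
    density — the same continuation that made the original scans converge at
    stretched bonds."""
    from .scf import reference_scf

    refs = {}
    for name, batch in batches.items():
        dens = []
        P0 = None
        for c in batch.contexts:
            res = reference_scf(c, P0=P0)
            P0 = res.density
            dens.append(res.density)
        refs[name] = np.stack(dens)
    return refs


def _select_program(cfg, runs, val_batches, val_drefs, holdout_batches, holdout_drefs,
                    aux_batches=None, aux_drefs=None):
    """Two-step model selection mirroring the testing protocol.

    The claim being selected for is element-level transferability, and no
    observable of the training molecules alone can certify it: the fitted
    per-element shifts absorb every per-molecule bias of the training
    compositions by construction, so a program can score perfectly on unseen
    geometries of the training molecules while carrying a composition bias
    that explodes on new molecules. The best-k runs by training error are
    therefore ranked by their frozen-shift error on *auxiliary composition
    probes* — small molecules built from the training elements but outside
    the training compositions and disjoint from the hold-out species (H2 for
    the hydrocarbon study; the homonuclear diatomics of the trained elements
    for the heterodiatomic study). Candidates must also evaluate validly on
    at least 80 % of the training-molecule validation geometries (the
    invalid flag is a first-class outcome, and a program failing at a few
    extreme geometries can still be the best surrogate elsewhere). The
    best-ranked candidate that evaluates validly on every hold-out geometry
    is selected; hold-out reference data never influence the choice, and
    shifts are never refit.

    Returns (chosen index into runs, validation report of the choice).
    """
    from .programs import program_densities

    p_refs = None if aux_batches else _reference_densities(val_batches)
    scored = []
    for k, run in enumerate(runs[: max(cfg.n_select, 1)]):
        n_valid = 0
        n_total = 0
        fid_parts = []
        for name, batch in val_batches.items():
            P, valid = program_densities(run.best_program, batch)
            n_valid += int(valid.sum())
            n_total += batch.G
            if p_refs is not None and valid.any():
                nv = int(valid.sum())
                num = np.linalg.norm((P[valid] - p_refs[name][valid]).reshape(nv, -1), axis=1)
                den = np.linalg.norm(p_refs[name][valid].reshape(nv, -1), axis=1)
                fid_parts.append(num / den)
        if n_valid < 0.8 * n_total:
            continue
        if aux_batches:
            # composition probe available: rank by frozen-shift error on it
            try:
                aux_rep = evaluate_program(run.best_program, run.best_shifts,
                                           aux_batches, aux_drefs)
                primary = aux_rep.rmse_kcal
            except (RuntimeError, KeyError):
                primary = np.inf
        else:
            # no same-bonding-character probe exists: rank by worst-case
            # density fidelity over the validation domain
            primary = float(np.max(np.concatenate(fid_parts))) if fid_parts else np.inf
        try:
            val_rep = evaluate_program(run.best_program, run.best_shifts,
                                       val_batches, val_drefs, allow_partial=True)
            val_err = val_rep.rmse_kcal
        except (RuntimeError, KeyError):
            continue
        scored.append((primary, val_err, k))
    if not scored:
        raise RuntimeError(
            f"none of the top {cfg.n_select} programs is usable on the validation domain")
    for _, _, k in sorted(scored):
        run = runs[k]
        try:
            rep = evaluate_program(run.best_program, run.best_shifts,
                                   val_batches, val_drefs, allow_partial=True)
            evaluate_program(run.best_program, run.best_shifts,
                             holdout_batches, holdout_drefs)
        except (RuntimeError, KeyError):
            continue
        return k, rep
    raise RuntimeError("no validation-ranked program is valid on the hold-out molecules")


def _aux_probe_batches(cfg, elements, holdout_names, rng):
    """Frozen-shift composition probes: homonuclear diatomics of the trained
    elements (closed-shell ones), excluding any hold-out species."""
    batches, drefs = {}, {}
    for el in sorted(elements):
        name = f"{el}2"
        if name in holdout_names:
            continue
        try:
            geoms = _diatomic_geoms(cfg, el, el, 0.1, 6,
                                    int(rng.integers(2**31 - 1)), "aux")
        except (ValueError, RuntimeError):
            continue
        ctxs = [build_ao_context(g, cfg.basis) for g in geoms]
        batches[name] = MoleculeBatch(ctxs, e_ref=[g.metadata["E_ref"] for g in geoms])
        drefs[name] = atomic_sum(geoms[0].composition(), cfg.basis, cfg.method)
    return batches, drefs


def _diatomic_geoms(cfg: ExperimentConfig, el1, el2, E_max, n, seed, tag) -> list[Geometry]:
    path = Path(cfg.out_dir) / "geometries" / f"{el1}{el2}_{tag}.xyz"
    return _stage(
        path,
        lambda: diatomic_training_scan(el1, el2, cfg.basis, cfg.method, E_max, n, seed,
                                       n_grid=cfg.n_scan_grid),
        read_xyz,
        lambda p, geoms: write_xyz(p, geoms),
    )


def run_diatomics(cfg: ExperimentConfig, progress: bool = True) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    train_geoms = {}
    for k, (a, b) in enumerate(DIATOMIC_TRAIN):
        train_geoms[f"{a}{b}"] = _diatomic_geoms(
            cfg, a, b, cfg.E_max_train, cfg.n_train_diatomic,
            int(rng.integers(2**31 - 1)), "train")
    cache: dict = {}
    training = build_training_set(train_geoms, cfg.basis, cfg.method, cache)
    runs = multi_restart_search(training, cfg.sa, cfg.n_restarts,
                                seeds=None, progress=progress)
    best = runs[0]
    # hold-out evaluation: each training curve up to E_max_test, plus the
    # molecule absent from training
    test_names = [f"{a}{b}" for a, b in DIATOMIC_TRAIN] + ["".join(DIATOMIC_HOLDOUT)]
    test_pairs = list(DIATOMIC_TRAIN) + [DIATOMIC_HOLDOUT]
    batches, drefs = {}, {}
    for name, (a, b) in zip(test_names, test_pairs):
        geoms = _diatomic_geoms(cfg, a, b, cfg.E_max_test, cfg.n_test_diatomic,
                                int(rng.integers(2**31 - 1)), "test")
        ctxs = [build_ao_context(g, cfg.basis) for g in geoms]
        batches[name] = MoleculeBatch(ctxs, e_ref=[g.metadata["E_ref"] for g in geoms])
        drefs[name] = atomic_sum(geoms[0].composition(), cfg.basis, cfg.method)
    holdout_name = "".join(DIATOMIC_HOLDOUT)
    val_batches = {k: v for k, v in batches.items() if k != holdout_name}
    val_drefs = {k: v for k, v in drefs.items() if k != holdout_name}
    chosen, _ = _select_program(cfg, runs, val_batches, val_drefs,
                                {holdout_name: batches[holdout_name]},
                                {holdout_name: drefs[holdout_name]})
    sel = runs[chosen]
    report = evaluate_program(sel.best_program, sel.best_shifts, batches, drefs,
                              allow_partial=True)
    _write_outputs(cfg, out, runs, training, report, {"test": report}, chosen=chosen)
    return {"runs": runs, "training": training, "report": report, "chosen": chosen,
            "test_batches": batches, "test_drefs": drefs}


# --- alkane pipeline --------------------------------------------------------

def alkane_modes(cfg: ExperimentConfig, name: str) -> NormalModeBasis:
    path = Path(cfg.out_dir) / "modes" / f"{name}_{_method_tag(cfg.method)}.json"
    return _stage(
        path,
        lambda: compute_normal_modes(initial_structure(name), cfg.basis, cfg.method,
                                     scheme=cfg.hessian_scheme),
        _load_modes,
        _save_modes,
    )


def sample_alkane_database(cfg: ExperimentConfig, name: str, nm: NormalModeBasis,
                           n: int, mode_ids, seed: int, tag: str,
                           contexts_cache: dict | None = None) -> list[Geometry]:
    """Oversampled shell sampling followed by the ab initio energy filter.

    Batch sizes adapt to the observed filter keep-rate (soft torsional modes
    are strongly anharmonic, so the quadratic sampler over-shoots the true
    energy window and keep-rates can be low). The equilibrium SCF density
    warm-starts every filter calculation."""
    path = Path(cfg.out_dir) / "geometries" / f"{name}_{tag}.xyz"

    def build():
        from .scf import reference_scf

        P_eq = reference_scf(build_ao_context(nm.equilibrium, cfg.basis),
                             method=cfg.method).density
        kept: list = []
        s = seed
        rate = 0.7  # optimistic prior; updated from observed acceptance
        n_drawn = 0
        while len(kept) < n:
            want = n - len(kept)
            draw = max(16, int(np.ceil(want / max(rate, 0.05) * 1.15)))
            samples = sample_quadratic_shell(
                nm, cfg.E_max_alkane * cfg.oversample_factor, mode_ids,
                draw, seed=s)
            good, _ = filter_by_reference_energy(
                samples, cfg.basis, cfg.method, cfg.E_max_alkane, nm.energy,
                contexts_cache=contexts_cache, P0=P_eq)
            kept.extend(good)
            n_drawn += draw
            rate = max(len(kept) / n_drawn, 0.02)
            s += 1
        kept = kept[:n]
        return [k.geometry for k in kept]

    return _stage(path, build, read_xyz, lambda p, geoms: write_xyz(p, geoms))


def run_alkanes(cfg: ExperimentConfig, progress: bool = True) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    train_modes = list(range(cfg.n_sampling_modes))  # four lowest by default
    ctx_cache: dict = {}
    databases, nms = {}, {}
    for name in ALKANE_TRAIN:
        nm = alkane_modes(cfg, name)
        nms[name] = nm
        databases[name] = sample_alkane_database(
            cfg, name, nm, cfg.database_sizes.get(name, 300), train_modes,
            int(rng.integers(2**31 - 1)), "db", contexts_cache=ctx_cache)
    # uniform random subselection of the training points from the databases
    train_geoms = {}
    for name in ALKANE_TRAIN:
        idx = rng.choice(len(databases[name]), size=cfg.n_train_alkane, replace=False)
        train_geoms[name] = [databases[name][i] for i in sorted(idx)]
        write_xyz(out / "geometries" / f"{name}_train.xyz", train_geoms[name])
    training = build_training_set(train_geoms, cfg.basis, cfg.method, ctx_cache)
    runs = multi_restart_search(training, cfg.sa, cfg.n_restarts, seeds=None,
                                progress=progress)
    best = runs[0]
    # test sets: the four training modes individually, plus three seeded
    # random triples of higher-frequency modes
    batches, drefs = {}, {}
    for name in ALKANE_TRAIN:
        nm = nms[name]
        subsets = [[m] for m in train_modes]
        higher = list(range(cfg.n_sampling_modes, nm.n_modes))
        for _ in range(3):
            subsets.append(sorted(rng.choice(higher, size=min(3, len(higher)),
                                             replace=False).tolist()))
        per = max(1, -(-cfg.n_test_alkane // len(subsets)))  # ceil division
        geoms = []
        for si, sub in enumerate(subsets):
            geoms += sample_alkane_database(
                cfg, name, nm, per, sub, int(rng.integers(2**31 - 1)), f"test{si}",
                contexts_cache=ctx_cache)
        ctxs = [ctx_cache.get(g.key(cfg.basis)) or build_ao_context(g, cfg.basis)
                for g in geoms]
        batches[name] = MoleculeBatch(ctxs, e_ref=[g.metadata["E_ref"] for g in geoms])
        drefs[name] = atomic_sum(geoms[0].composition(), cfg.basis, cfg.method)
    # transfer to larger alkanes never seen in training (frozen shifts)
    tr_batches, tr_drefs = {}, {}
    for name in ALKANE_TRANSFER:
        nm = alkane_modes(cfg, name)
        geoms = sample_alkane_database(
            cfg, name, nm, cfg.n_transfer, train_modes,
            int(rng.integers(2**31 - 1)), "transfer", contexts_cache=ctx_cache)
        ctxs = [ctx_cache.get(g.key(cfg.basis)) or build_ao_context(g, cfg.basis)
                for g in geoms]
        tr_batches[name] = MoleculeBatch(
            ctxs, e_ref=[g.metadata["E_ref"] for g in geoms],
            max_precontract_bytes=0)
        tr_drefs[name] = atomic_sum(geoms[0].composition(), cfg.basis, cfg.method)
    aux_batches, aux_drefs = _aux_probe_batches(
        cfg, ("H",), set(ALKANE_TRANSFER), rng)
    chosen, _ = _select_program(cfg, runs, batches, drefs, tr_batches, tr_drefs,
                                aux_batches, aux_drefs)
    sel = runs[chosen]
    test_report = evaluate_program(sel.best_program, sel.best_shifts, batches, drefs,
                                   allow_partial=True)
    transfer_report = evaluate_program(sel.best_program, sel.best_shifts,
                                       tr_batches, tr_drefs)
    _write_outputs(cfg, out, runs, training, test_report,
                   {"test": test_report, "transfer": transfer_report}, chosen=chosen)
    return {
        "runs": runs,
        "training": training,
        "report": test_report,
        "transfer_report": transfer_report,
        "chosen": chosen,
        "test_batches": batches,
        "test_drefs": drefs,
        "transfer_batches": tr_batches,
        "transfer_drefs": tr_drefs,
        "modes": nms,
    }


# --- shared output writing --------------------------------------------------

def _write_outputs(cfg, out: Path, runs, training, report, reports: dict,
                   chosen: int = 0) -> None:
    best = runs[chosen]
    save_program(
        out / "best_program.json", best.best_program, best.best_shifts.shifts,
        cfg.basis, cfg.method,
        provenance={"seed": best.seed, "template": cfg.template,
                    "rank_by_training_error": chosen,
                    "training_rmse_hartree": best.best_fitness.rmse},
    )
    pd.DataFrame(best.trace).to_csv(out / "best_trace.csv", index=False)
    manifest = {
        "template": cfg.template,
        "basis": cfg.basis,
        "method": cfg.method,
        "seed": cfg.seed,
        "n_restarts": cfg.n_restarts,
        "sa": asdict(cfg.sa),
        "catalogue_hash": library.catalogue_hash(),
        "atomic_reference": "restricted fractional-occupation SCF (spherically averaged)",
        "restarts": [
            {"seed": r.seed, "best_rmse_hartree": r.best_fitness.rmse,
             "best_rmse_kcal": r.best_fitness.rmse_kcal}
            for r in runs
        ],
        "selected_top_k": cfg.n_select,
        "chosen_rank": chosen,
        "timestamp": time.strftime("%Y-%m-%d %H:%M:%S"),
    }
    for tag, rep in reports.items():
        manifest[f"{tag}_report"] = {
            "rmse_kcal": rep.rmse_kcal,
            "max_abs_kcal": rep.max_abs_kcal,
            "r2": rep.r2,
            "per_molecule": rep.per_molecule,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = []
    for tag, rep in reports.items():
        for name, r in rep.residuals_kcal.items():
            for val in r:
                rows.append({"set": tag, "molecule": name, "residual_kcal": val})
    pd.DataFrame(rows).to_csv(out / "residuals.csv", index=False)


TEMPLATES = {
    "diatomics-hf": lambda cfg, progress=True: run_diatomics(cfg, progress),
    "diatomics-dft": lambda cfg, progress=True: run_diatomics(
        replace(cfg, method="dft:lda"), progress),
    "alkanes": lambda cfg, progress=True: run_alkanes(cfg, progress),
}


def run_experiment(template: str, out_dir: str, progress: bool = True, **overrides) -> dict:
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; available: {sorted(TEMPLATES)}")
    cfg = ExperimentConfig(template=template, out_dir=out_dir, **overrides)
    return TEMPLATES[template](cfg, progress=progress)
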