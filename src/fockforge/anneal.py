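"""Simulated-annealing search over programs.

Fitness is the mean squared deviation between shifted predicted and shifted
reference energies,

    F_E = (1/(Nm Np)) sum_ij [ (Ebar_ij - Dbar_i) - (E_ij - D_i) ]^2,

with the per-element shifts Dbar_i refit in closed form (linear least squares
on the composition design matrix) at every iteration. The annealer reports
and compares sqrt(F_E) in hartree; the Metropolis rule accepts an uphill move
of dF (hartree) with probability exp(-dF / (k_B T)), T decreasing linearly.
Invalid programs carry a +inf sentinel and never displace a finite incumbent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import library
from .constants import HARTREE_TO_KCAL, KB_HARTREE
from .oneshot import MoleculeBatch
from .programs import Program, program_energies

__all__ = [
    "SpeciesData",
    "TrainingSet",
    "ShiftModel",
    "SAConfig",
    "FitnessReport",
    "SearchSpace",
    "build_training_set",
    "loss_mse",
    "optimal_shifts",
    "mutate",
    "metropolis_accept",
    "anneal",
    "multi_restart_search",
]


@dataclass
class SpeciesData:
    name: str
    composition: dict[str, int]
    batch: MoleculeBatch
    e_ref: np.ndarray  # (G,) reference total energies (hartree)
    d_ref: float  # independent-atom sum D_i (hartree)


@dataclass
class TrainingSet:
    species: list[SpeciesData]
    basis_label: str
    method: str

    def __post_init__(self):
        els = set()
        for sp in self.species:
            els |= set(sp.composition)
            if not np.all(np.isfinite(sp.e_ref)):
                raise ValueError(f"non-finite reference energy for {sp.name}")
        self.elements: tuple[str, ...] = tuple(sorted(els))
        self._eval_groups = None

    def eval_groups(self):
        """Species grouped by basis dimension for merged program evaluation.

        Species sharing n_ao are stacked into one MoleculeBatch so the
        interpreter runs fewer, larger batched operations per iteration;
        returns [(merged_batch, [(species_index, slice), ...]), ...]. Built
        lazily and cached."""
        if self._eval_groups is None:
            from .oneshot import MoleculeBatch

            by_nao: dict = {}
            for i, sp in enumerate(self.species):
                by_nao.setdefault(sp.batch.n_ao, []).append(i)
            groups = []
            for nao, idxs in sorted(by_nao.items()):
                if len(idxs) == 1:
                    sp = self.species[idxs[0]]
                    groups.append((sp.batch, [(idxs[0], slice(0, sp.batch.G))]))
                else:
                    ctxs, spans, k = [], [], 0
                    for i in idxs:
                        g = self.species[i].batch.G
                        ctxs.extend(self.species[i].batch.contexts)
                        spans.append((i, slice(k, k + g)))
                        k += g
                    groups.append((MoleculeBatch(ctxs), spans))
            self._eval_groups = groups
        return self._eval_groups

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_geometries(self) -> int:
        return sum(sp.batch.G for sp in self.species)

    def design_matrix(self) -> np.ndarray:
        """Composition counts, one row per geometry, one column per element."""
        rows = []
        for sp in self.species:
            row = [sp.composition.get(el, 0) for el in self.elements]
            rows.extend([row] * sp.batch.G)
        return np.array(rows, dtype=float)


@dataclass
class ShiftModel:
    shifts: dict[str, float]

    def molecular_shift(self, composition: dict[str, int]) -> float:
        missing = [el for el in composition if el not in self.shifts]
        if missing:
            raise KeyError(f"no trained shift for element(s) {missing}")
        return sum(n * self.shifts[el] for el, n in composition.items())


@dataclass
class FitnessReport:
    mse: float  # hartree^2
    rmse: float  # hartree
    rmse_kcal: float
    per_molecule_rmse: dict[str, float]
    valid: bool

    @classmethod
    def invalid(cls):
        return cls(math.inf, math.inf, math.inf, {}, False)


@dataclass
class SAConfig:
    n_f: int = 15
    n_iter: int = 10_000
    T_init: float = 250e3  # kelvin
    T_floor: float = 1.0
    max_mutations: int = 3
    seed: int = 0
    max_init_retries: int = 200

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter >= 1")
        if not (1 <= self.max_mutations <= self.n_f):
            raise ValueError("1 <= max_mutations <= n_f")


@dataclass
class SearchSpace:
    input_ids: tuple[str, ...]
    internal_ids: tuple[str, ...]
    output_ids: tuple[str, ...]

    @classmethod
    def default(cls):
        return cls(
            tuple(library.ids_by_role("input")),
            tuple(library.ids_by_role("internal")),
            tuple(library.ids_by_role("output")),
        )

    def random_program(self, n_f: int, rng) -> Program:
        ids = (
            [self.input_ids[rng.integers(len(self.input_ids))]]
            + [self.internal_ids[rng.integers(len(self.internal_ids))] for _ in range(n_f - 2)]
            + [self.output_ids[rng.integers(len(self.output_ids))]]
        )
        return Program(tuple(ids))


def build_training_set(species_geometries, basis_label="STO-3G", method="rhf",
                       contexts_cache=None) -> TrainingSet:
    """Assemble a TrainingSet from {name: [geometries with E_ref metadata]}."""
    from .atoms import atomic_sum
    from .scf import build_ao_context

    species = []
    for name, geoms in species_geometries.items():
        ctxs = []
        for g in geoms:
            key = g.key(basis_label)
            if contexts_cache is not None and key in contexts_cache:
                ctxs.append(contexts_cache[key])
            else:
                c = build_ao_context(g, basis_label)
                if contexts_cache is not None:
                    contexts_cache[key] = c
                ctxs.append(c)
        e_ref = np.array([g.metadata["E_ref"] for g in geoms])
        comp = geoms[0].composition()
        species.append(
            SpeciesData(
                name=name,
                composition=comp,
                batch=MoleculeBatch(ctxs, e_ref=e_ref),
                e_ref=e_ref,
                d_ref=atomic_sum(comp, basis_label, method),
            )
        )
    return TrainingSet(species=species, basis_label=basis_label, method=method)


def _shifted_targets(training: TrainingSet) -> np.ndarray:
    """Per-geometry (E_ij - D_i) in training order."""
    return np.concatenate([sp.e_ref - sp.d_ref for sp in training.species])


def optimal_shifts(e_pred: np.ndarray, training: TrainingSet) -> ShiftModel:
    """Closed-form minimizer of the loss over per-element shifts
    (minimum-norm solution when compositions are collinear)."""
    A = training.design_matrix()
    y = np.asarray(e_pred, float) - _shifted_targets(training)
    d, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ShiftModel({el: float(v) for el, v in zip(training.elements, d)})


def loss_mse(e_pred: np.ndarray, training: TrainingSet, shifts: ShiftModel) -> FitnessReport:
    """Evaluate the loss for given predictions and shifts."""
    e_pred = np.asarray(e_pred, float)
    if len(e_pred) != training.n_geometries:
        raise ValueError("predictions misaligned with the training set")
    if not np.all(np.isfinite(e_pred)):
        return FitnessReport.invalid()
    resid = []
    per_mol = {}
    k = 0
    for sp in training.species:
        r = (e_pred[k : k + sp.batch.G] - shifts.molecular_shift(sp.composition)) - (
            sp.e_ref - sp.d_ref
        )
        per_mol[sp.name] = float(np.sqrt(np.mean(r**2)))
        resid.append(r)
        k += sp.batch.G
    resid = np.concatenate(resid)
    mse = float(np.mean(resid**2))
    rmse = math.sqrt(mse)
    return FitnessReport(mse, rmse, rmse * HARTREE_TO_KCAL, per_mol, True)


def evaluate_fitness(program: Program, training: TrainingSet):
    """(FitnessReport, ShiftModel | None) with shift refit included."""
    e_parts = []
    for sp in training.species:
        e, valid = program_energies(program, sp.batch)
        if not valid.all():
            return FitnessReport.invalid(), None
        e_parts.append(e)
    e_pred = np.concatenate(e_parts)
    shifts = optimal_shifts(e_pred, training)
    return loss_mse(e_pred, training, shifts), shifts


def _evaluate_incremental(program: Program, training: TrainingSet,
                          ref_program: Program | None, ref_layers: list | None):
    """Like evaluate_fitness, but reuses the unchanged program prefix.

    ref_layers is a per-species list of layer stores from the reference
    program's evaluation; layers up to (excluding) the first differing slot
    carry over unchanged. Returns (fitness, shifts, layers_per_species).
    """
    from .programs import energies_from_layers, run_program_layers

    if ref_program is None or ref_layers is None:
        start = 0
    else:
        start = program.n_f - 1
        for k in range(program.n_f):
            if program.function_ids[k] != ref_program.function_ids[k]:
                start = k
                break
        start = min(start, program.n_f - 2)
    groups = training.eval_groups()
    layers_out = []
    e_by_species: dict = {}
    for gi, (batch, spans) in enumerate(groups):
        prev = ref_layers[gi] if ref_layers is not None else None
        layers = run_program_layers(program, batch, prev, start)
        layers_out.append(layers)
        e, valid = energies_from_layers(program, batch, layers)
        if not valid.all():
            return FitnessReport.invalid(), None, layers_out
        for i, sl in spans:
            e_by_species[i] = e[sl]
    e_pred = np.concatenate([e_by_species[i] for i in range(len(training.species))])
    shifts = optimal_shifts(e_pred, training)
    return loss_mse(e_pred, training, shifts), shifts, layers_out


def mutate(program: Program, rng, space: SearchSpace, max_mutations: int = 3) -> Program:
    """Replace r ~ U{1..max_mutations} positions with role-matched draws."""
    r = int(rng.integers(1, max_mutations + 1))
    n_f = program.n_f
    positions = rng.choice(n_f, size=min(r, n_f), replace=False)
    ids = list(program.function_ids)
    for pos in positions:
        if pos == 0:
            pool = space.input_ids
        elif pos == n_f - 1:
            pool = space.output_ids
        else:
            pool = space.internal_ids
        ids[pos] = pool[rng.integers(len(pool))]
    return Program(tuple(ids))


def metropolis_accept(f_new: float, f_old: float, T: float, rng) -> bool:
    """Accept if not worse; otherwise with probability exp(-dF/(k_B T))."""
    if math.isinf(f_new):
        return False
    if f_new <= f_old:
        return True
    p = math.exp(-(f_new - f_old) / (KB_HARTREE * max(T, 1e-300)))
    return bool(rng.random() < p)


@dataclass
class SARun:
    best_program: Program
    best_shifts: ShiftModel
    best_fitness: FitnessReport
    trace: dict[str, np.ndarray]
    seed: int
    config: SAConfig


def anneal(training: TrainingSet, config: SAConfig, space: SearchSpace | None = None) -> SARun:
    """One annealing run; returns the best-so-far program and its trace."""
    if training.n_species == 0:
        raise ValueError("empty training set")
    space = space or SearchSpace.default()
    rng = np.random.default_rng(config.seed)
    current = None
    for _ in range(config.max_init_retries):
        cand = space.random_program(config.n_f, rng)
        fit, shifts, layers = _evaluate_incremental(cand, training, None, None)
        if fit.valid:
            current, f_cur, s_cur, l_cur = cand, fit, shifts, layers
            break
    if current is None:
        raise RuntimeError("could not initialize a valid program")
    best, f_best, s_best = current, f_cur, s_cur
    n = config.n_iter
    tr_cur = np.empty(n)
    tr_best = np.empty(n)
    tr_T = np.empty(n)
    for k in range(n):
        T = max(config.T_floor, config.T_init * (1.0 - k / n))
        cand = mutate(current, rng, space, config.max_mutations)
        fit, shifts, layers = _evaluate_incremental(cand, training, current, l_cur)
        if metropolis_accept(fit.rmse, f_cur.rmse, T, rng):
            current, f_cur, s_cur, l_cur = cand, fit, shifts, layers
            if fit.rmse < f_best.rmse:
                best, f_best, s_best = cand, fit, shifts
        tr_cur[k] = f_cur.rmse
        tr_best[k] = f_best.rmse
        tr_T[k] = T
    return SARun(
        best_program=best,
        best_shifts=s_best,
        best_fitness=f_best,
        trace={"iteration": np.arange(n), "current_rmse": tr_cur,
               "best_rmse": tr_best, "temperature": tr_T},
        seed=config.seed,
        config=config,
    )


def multi_restart_search(
    training: TrainingSet,
    config: SAConfig,
    n_restarts: int = 50,
    seeds: list[int] | None = None,
    space: SearchSpace | None = None,
    progress: bool = False,
) -> list[SARun]:
    """Independent annealing runs, sorted ascending by training RMSE."""
    if seeds is None:
        root = np.random.default_rng(config.seed)
        seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_restarts)]
    if len(seeds) != n_restarts:
        raise ValueError("need one seed per restart")
    runs = []
    from dataclasses import replace

    for s in seeds:
        runs.append(anneal(training, replace(config, seed=s), space))
        if progress:
            print(f"  restart seed={s}: best RMSE = {runs[-1].best_fitness.rmse_kcal:.3f} kcal/mol")
    return sorted(runs, key=lambda r: r.best_fitness.rmse)
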