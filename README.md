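# fockforge

**Stochastic synthesis of SCF-free, one-shot surrogates for the Fock matrix.**

Hartree–Fock theory determines molecular orbitals from the generalized
eigenproblem **F c** = **S c** ε, but the Fock matrix **F** depends on its own
eigenvectors, so standard codes iterate to self-consistency. `fockforge`
searches for short *programs* — sequences of parameter-free matrix operations
on AO-basis ingredients (core Hamiltonian, overlap, Hückel-type guesses,
Coulomb/exchange builds, spectral and elementwise maps) — whose output
"workspace matrix" **M** already has the right eigenvectors. One
diagonalization of **M**, one density build P = 2·C_occ C_occᵀ, and one Fock
build then give a total energy

E = ½ Tr[P(H<sup>core</sup> + F[P])] + E_nuc

with **no SCF cycles at all**. The search works because every matrix function
f(**F**) that is monotone on the occupied spectrum shares **F**'s generalized
eigenvectors: the target is a large equivalence class, not a single matrix.

The search itself is simulated annealing over a catalogue of 6 input, 61
internal and 2 output functions: programs of N_f = 15 slots are mutated
(1–3 random slots per step) and scored by the RMSE between shifted predicted
and shifted reference energies,

F_E = (1/N) Σ_ij [ (Ē_ij − D̄_i) − (E_ij − D_i) ]²,

where D_i is the independent-atom energy of molecule *i* and D̄_i is a sum of
per-element shifts — the only fitted continuous parameters, refit in closed
form each iteration and frozen at test time. Because shifts are per-element,
a trained program transfers to molecules it never saw, provided they contain
the same elements.

Everything runs on an in-package quantum-chemistry engine: generated STO-3G
basis (H–Ne, Na, Cl), numba-compiled McMurchie–Davidson integrals, RHF with
DIIS, analytic nuclear gradients, harmonic normal modes, and a grid-based
LDA Kohn–Sham path. See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

Train a surrogate for the LiF potential curve (15 energy-stratified
geometries within 0.25 hartree of equilibrium) and evaluate it on the same
curve:

```python
from fockforge.sampling import diatomic_training_scan
from fockforge.anneal import SAConfig, build_training_set, multi_restart_search
from fockforge.evaluate import evaluate_program
from fockforge.atoms import atomic_sum

geoms = diatomic_training_scan("Li", "F", E_max=0.25, n=15, seed=3)
training = build_training_set({"LiF": geoms})
runs = multi_restart_search(training, SAConfig(n_iter=2000, seed=0),
                            n_restarts=4)
best = runs[0]
print("training RMSE:", round(best.best_fitness.rmse_kcal, 2), "kcal/mol")
print("program:", " -> ".join(best.best_program.function_ids))
print("shifts (hartree):", {k: round(v, 4) for k, v in best.best_shifts.shifts.items()})
```

Output (deterministic for these seeds):

```
training RMSE: 3.04 kcal/mol
program: in_sinv_hcore -> replace_density -> ew_sin -> ew_abs -> ew_abs -> sp_sin ->
  sub_sinv -> norm_fro -> sp_signed_log -> norm_max -> ew_tanh -> add_hcore ->
  symprod_identity -> add_fock -> out_lowdin_eig
shifts (hartree): {'F': -52.3129, 'Li': -52.3129}
```

The training RMSE (3.04 kcal/mol after this small 4-restart search) is the
annealer's loss √F_E in energy units. The per-element shifts reference LiF's
predicted energies to the independent-atom limit; with a single molecule the
two shifts are determined only up to their sum, and the fit returns the
minimum-norm split. A 15-step program like the one above evaluates with a
single diagonalization per geometry — no SCF iterations.

The full study pipelines (multi-molecule diatomic training with a NaF
hold-out; methane/ethane normal-mode training with propane/butane transfer)
are available as templates:

```bash
fockforge run diatomics-hf --n-restarts 50 --n-iter 10000 --seed 0 --out-dir out/
fockforge run alkanes      --n-restarts 50 --n-iter 10000 --seed 0 --out-dir out/
```

plus the lower-level subcommands `sample-diatomic`, `sample-modes`,
`reference`, `train`, `test` and `ablate` (term-importance analysis).

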