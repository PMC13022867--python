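"""Loss, closed-form shifts, mutation, Metropolis rule and annealing."""

import math

import numpy as np
import pytest

from fockforge.anneal import (
    SAConfig,
    SearchSpace,
    ShiftModel,
    anneal,
    build_training_set,
    evaluate_fitness,
    loss_mse,
    metropolis_accept,
    multi_restart_search,
    mutate,
    optimal_shifts,
)
from fockforge.constants import HARTREE_TO_KCAL, KB_HARTREE
from fockforge.geometry import Geometry
from fockforge.programs import Program


def _h2_training(e_ref, d_ref=0.0):
    """Tiny real training set (H2 at two bond lengths) with doctored
    reference energies so loss arithmetic can be checked exactly."""
    geoms = []
    for k, r in enumerate((0.70, 0.76)):
        g = Geometry(("H", "H"), [[0, 0, 0], [r, 0, 0]])
        g.metadata["E_ref"] = e_ref[k]
        geoms.append(g)
    ts = build_training_set({"H2": geoms})
    ts.species[0].d_ref = d_ref
    ts.species[0].e_ref = np.asarray(e_ref, float)
    return ts


class TestLoss:
    def test_perfect_predictions_zero_loss(self):
        ts = _h2_training([-1.1, -1.0], d_ref=0.0)
        rep = loss_mse(np.array([-1.1, -1.0]), ts, ShiftModel({"H": 0.0}))
        assert rep.mse == pytest.approx(0.0, abs=1e-30)
        assert rep.valid

    def test_single_species_arithmetic(self):
        # shifted references (E - D) = (-0.2, -0.1); shifted predictions
        # (Ebar - Dbar) = (-0.1, -0.05) -> mean of (0.1^2, 0.05^2) = 0.00625
        ts = _h2_training([-0.2, -0.1], d_ref=0.0)
        rep = loss_mse(np.array([-0.1, -0.05]), ts, ShiftModel({"H": 0.0}))
        assert rep.mse == pytest.approx(0.00625, abs=1e-15)
        assert rep.rmse_kcal == pytest.approx(math.sqrt(0.00625) * HARTREE_TO_KCAL, abs=1e-9)

    def test_nonfinite_prediction_gives_sentinel(self):
        ts = _h2_training([-1.1, -1.0])
        rep = loss_mse(np.array([np.nan, -1.0]), ts, ShiftModel({"H": 0.0}))
        assert not rep.valid and math.isinf(rep.mse)

    def test_misaligned_predictions_rejected(self):
        ts = _h2_training([-1.1, -1.0])
        with pytest.raises(ValueError):
            loss_mse(np.array([-1.0]), ts, ShiftModel({"H": 0.0}))


class TestOptimalShifts:
    def test_constant_residual_split_over_atoms(self):
        # H2: constant offset k between prediction and shifted reference
        k = 0.35
        ts = _h2_training([-1.1, -1.0], d_ref=0.0)
        shifts = optimal_shifts(np.array([-1.1 + k, -1.0 + k]), ts)
        assert shifts.shifts["H"] == pytest.approx(k / 2.0, abs=1e-12)
        rep = loss_mse(np.array([-1.1 + k, -1.0 + k]), ts, shifts)
        assert rep.mse == pytest.approx(0.0, abs=1e-24)

    def test_zero_residuals_give_zero_shifts(self):
        ts = _h2_training([-1.1, -1.0], d_ref=0.0)
        shifts = optimal_shifts(np.array([-1.1, -1.0]), ts)
        assert shifts.shifts["H"] == pytest.approx(0.0, abs=1e-14)

    def test_matches_brute_force_grid_on_two_element_toy(self, two_element_toy):
        ts, e_pred = two_element_toy
        shifts = optimal_shifts(e_pred, ts)
        import scipy.optimize

        def f(d):
            return loss_mse(e_pred, ts, ShiftModel(dict(zip(ts.elements, d)))).mse

        d0 = [shifts.shifts[el] for el in ts.elements]
        grid = scipy.optimize.brute(
            f, [(d - 0.05, d + 0.05) for d in d0], Ns=21,
            finish=scipy.optimize.fmin)
        for el, v in zip(ts.elements, grid):
            assert shifts.shifts[el] == pytest.approx(v, abs=1e-6)

    def test_shift_optimality_convexity(self, two_element_toy):
        ts, e_pred = two_element_toy
        shifts = optimal_shifts(e_pred, ts)
        base = loss_mse(e_pred, ts, shifts).mse
        for el in ts.elements:
            for d in (1e-4, -1e-4):
                pert = dict(shifts.shifts)
                pert[el] += d
                assert loss_mse(e_pred, ts, ShiftModel(pert)).mse >= base - 1e-18


@pytest.fixture(scope="module")
def two_element_toy():
    """Three Li/F molecules with distinct compositions and synthetic
    predictions, so the shift fit is a genuine 2-parameter problem."""
    rng = np.random.default_rng(21)
    species = {}
    for name, pair in (("LiF", ("Li", "F")),):
        geoms = []
        for r in (1.35, 1.50, 1.70):
            g = Geometry(pair, [[0, 0, 0], [r, 0, 0]])
            g.metadata["E_ref"] = -105.3 + 0.1 * (r - 1.5) ** 2
            geoms.append(g)
        species[name] = geoms
    g = Geometry(("Li", "Li"), [[0, 0, 0], [2.7, 0, 0]])
    g.metadata["E_ref"] = -14.6
    species["Li2"] = [g]
    g = Geometry(("F", "F"), [[0, 0, 0], [1.4, 0, 0]])
    g.metadata["E_ref"] = -195.0
    species["F2"] = [g]
    ts = build_training_set(species)
    e_pred = np.concatenate([sp.e_ref for sp in ts.species]) + rng.normal(
        scale=0.05, size=5) + 0.3
    return ts, e_pred


class TestMutation:
    def test_single_mutation_changes_at_most_one_position(self):
        space = SearchSpace.default()
        rng = np.random.default_rng(0)
        p = space.random_program(15, rng)
        for _ in range(50):
            q = mutate(p, rng, space, max_mutations=1)
            diff = sum(a != b for a, b in zip(p.function_ids, q.function_ids))
            assert diff <= 1

    def test_changed_count_bounded_and_roles_preserved(self):
        space = SearchSpace.default()
        rng = np.random.default_rng(1)
        p = space.random_program(15, rng)
        from fockforge import library

        for _ in range(300):
            q = mutate(p, rng, space, max_mutations=3)
            diff = sum(a != b for a, b in zip(p.function_ids, q.function_ids))
            assert 0 <= diff <= 3
            assert library.get_function(q.input_id)[0] == "input"
            assert library.get_function(q.output_id)[0] == "output"
            p = q


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(1.0, 2.0, 10.0, rng)
        assert metropolis_accept(2.0, 2.0, 10.0, rng)  # ties accepted

    def test_acceptance_rate_at_kT_ln2(self):
        T = 1e5
        dF = KB_HARTREE * T * math.log(2.0)
        rng = np.random.default_rng(123)
        acc = sum(metropolis_accept(1.0 + dF, 1.0, T, rng) for _ in range(10_000))
        assert acc / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_invalid_candidates_rejected(self):
        rng = np.random.default_rng(0)
        assert not metropolis_accept(math.inf, 1.0, 1e6, rng)
        assert not metropolis_accept(math.inf, math.inf, 1e6, rng)
        assert metropolis_accept(1.0, math.inf, 1e6, rng)


@pytest.fixture(scope="module")
def h2_real_training():
    geoms = []
    for r in (0.60, 0.70, 0.74, 0.80, 0.95, 1.20):
        g = Geometry(("H", "H"), [[0, 0, 0], [r, 0, 0]])
        from fockforge.scf import build_ao_context, reference_scf

        g.metadata["E_ref"] = reference_scf(build_ao_context(g)).energy
        geoms.append(g)
    return build_training_set({"H2": geoms})


class TestAnneal:
    def test_best_trace_non_increasing_and_deterministic(self, h2_real_training):
        cfg = SAConfig(n_f=6, n_iter=150, seed=42)
        run1 = anneal(h2_real_training, cfg)
        run2 = anneal(h2_real_training, cfg)
        assert np.all(np.diff(run1.trace["best_rmse"]) <= 0)
        assert np.array_equal(run1.trace["current_rmse"], run2.trace["current_rmse"])
        assert run1.best_program == run2.best_program

    def test_greedy_limit_monotone_accepted_sequence(self, h2_real_training):
        cfg = SAConfig(n_f=6, n_iter=150, seed=5, T_init=0.0, T_floor=0.0)
        run = anneal(h2_real_training, cfg)
        cur = run.trace["current_rmse"]
        assert np.all(np.diff(cur) <= 1e-15)

    def test_temperature_schedule_linear(self, h2_real_training):
        cfg = SAConfig(n_f=5, n_iter=100, seed=3, T_init=1000.0, T_floor=1.0)
        run = anneal(h2_real_training, cfg)
        T = run.trace["temperature"]
        assert T[0] == pytest.approx(1000.0)
        k = 40
        assert T[k] == pytest.approx(max(1.0, 1000.0 * (1 - k / 100)), abs=1e-9)

    def test_multi_restart_sorted_with_seeds(self, h2_real_training):
        cfg = SAConfig(n_f=5, n_iter=60, seed=9)
        runs = multi_restart_search(h2_real_training, cfg, n_restarts=3)
        fits = [r.best_fitness.rmse for r in runs]
        assert fits == sorted(fits)
        assert len({r.seed for r in runs}) == 3

    def test_rmse_unit_consistency(self, h2_real_training):
        cfg = SAConfig(n_f=5, n_iter=40, seed=2)
        run = anneal(h2_real_training, cfg)
        fr = run.best_fitness
        assert fr.rmse_kcal == pytest.approx(math.sqrt(fr.mse) * HARTREE_TO_KCAL, rel=1e-12)
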