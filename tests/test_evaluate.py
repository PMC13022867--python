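"""Hold-out metrics, MO comparison and term-importance ablation."""

import numpy as np
import pytest

from fockforge.anneal import ShiftModel, build_training_set
from fockforge.constants import HARTREE_TO_KCAL
from fockforge.evaluate import ablate, compare_mos, evaluate_program
from fockforge.geometry import Geometry
from fockforge.oneshot import MoleculeBatch
from fockforge.programs import Program
from fockforge.scf import build_ao_context, generalized_eigensolve


def _h2_batch(e_ref):
    ctxs = []
    for r in (0.68, 0.74, 0.82, 0.95):
        ctxs.append(build_ao_context(Geometry(("H", "H"), [[0, 0, 0], [r, 0, 0]])))
    return MoleculeBatch(ctxs, e_ref=e_ref)


#: a program equivalent to a short SCF from the Hueckel guess: essentially
#: exact for H2, which makes "perfect prediction" fixtures easy to build
_GOOD = Program(("in_huckel",) + ("roothaan",) * 10 + ("out_gen_eig",))


class TestEvaluateProgram:
    def test_perfect_predictions(self):
        from fockforge.programs import program_energies

        batch = _h2_batch(np.zeros(4))
        e, valid = program_energies(_GOOD, batch)
        assert valid.all()
        batch.e_ref = e  # references equal to the program's own predictions
        rep = evaluate_program(_GOOD, ShiftModel({"H": 0.0}), {"H2": batch}, {"H2": 0.0})
        assert rep.rmse_kcal == pytest.approx(0.0, abs=1e-8)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)

    def test_known_residual_pattern(self):
        from fockforge.programs import program_energies

        batch = _h2_batch(np.zeros(4))
        e, _ = program_energies(_GOOD, batch)
        pattern = np.array([1.0, -1.0, 1.0, -1.0]) / HARTREE_TO_KCAL
        batch.e_ref = e - pattern  # predictions sit 1 kcal/mol off, alternating
        rep = evaluate_program(_GOOD, ShiftModel({"H": 0.0}), {"H2": batch}, {"H2": 0.0})
        assert rep.rmse_kcal == pytest.approx(1.0, abs=1e-6)
        assert rep.max_abs_kcal == pytest.approx(1.0, abs=1e-6)

    def test_missing_element_shift_fails(self):
        batch = _h2_batch(np.full(4, -1.1))
        with pytest.raises(KeyError, match="H"):
            evaluate_program(_GOOD, ShiftModel({"Li": 0.0}), {"H2": batch}, {"H2": 0.0})

    def test_pooled_rmse_is_weighted_mean_of_per_molecule(self):
        from fockforge.programs import program_energies

        b1 = _h2_batch(np.zeros(4))
        e1, _ = program_energies(_GOOD, b1)
        b1.e_ref = e1 - 1.0 / HARTREE_TO_KCAL
        ctxs = [build_ao_context(Geometry(("H", "H"), [[0, 0, 0], [r, 0, 0]]))
                for r in (0.70, 0.78)]
        b2 = MoleculeBatch(ctxs, e_ref=np.zeros(2))
        e2, _ = program_energies(_GOOD, b2)
        b2.e_ref = e2 - 2.0 / HARTREE_TO_KCAL
        rep = evaluate_program(_GOOD, ShiftModel({"H": 0.0}),
                               {"a": b1, "b": b2}, {"a": 0.0, "b": 0.0})
        pooled_sq = (4 * rep.per_molecule["a"]["rmse_kcal"] ** 2
                     + 2 * rep.per_molecule["b"]["rmse_kcal"] ** 2) / 6
        assert rep.rmse_kcal**2 == pytest.approx(pooled_sq, rel=1e-10)


class TestCompareMOs:
    def test_identical_sets_and_sign_flips(self, lif_ctx, lif_scf):
        mos = lif_scf.mos
        ov, en, perm = compare_mos(mos, mos, lif_ctx.S, lif_scf.fock)
        assert np.allclose(ov, 1.0, atol=1e-10)
        assert np.array_equal(perm, np.arange(lif_ctx.n_ao))
        flipped = type(mos)(coeffs=-mos.coeffs, eigenvalues=mos.eigenvalues)
        ov2, _, _ = compare_mos(flipped, mos, lif_ctx.S, lif_scf.fock)
        assert np.allclose(ov2, 1.0, atol=1e-10)

    def test_rayleigh_energies_match_scf_eigenvalues(self, lif_ctx, lif_scf):
        ov, en, perm = compare_mos(lif_scf.mos, lif_scf.mos, lif_ctx.S, lif_scf.fock)
        assert np.allclose(en, lif_scf.mos.eigenvalues, atol=1e-8)

    def test_dimension_mismatch(self, lif_scf, h2_scf, lif_ctx):
        with pytest.raises(ValueError):
            compare_mos(lif_scf.mos, h2_scf.mos, lif_ctx.S, lif_scf.fock)


@pytest.fixture(scope="module")
def training():
    from fockforge.scf import reference_scf

    geoms = []
    for r in (0.66, 0.74, 0.85):
        g = Geometry(("H", "H"), [[0, 0, 0], [r, 0, 0]])
        g.metadata["E_ref"] = reference_scf(build_ao_context(g)).energy
        geoms.append(g)
    return build_training_set({"H2": geoms})


class TestAblate:
    def test_identity_position_has_zero_delta(self, training):
        p = Program(("in_huckel", "roothaan", "identity", "ew_tanh", "out_gen_eig"))
        deltas = ablate(p, ShiftModel({"H": 0.0}), training)
        assert len(deltas) == 3
        assert deltas[1] == 0.0  # replacing identity by identity changes nothing

    def test_deterministic(self, training):
        p = Program(("in_huckel", "roothaan", "sp_cube", "out_gen_eig"))
        d1 = ablate(p, ShiftModel({"H": 0.0}), training)
        d2 = ablate(p, ShiftModel({"H": 0.0}), training)
        assert np.array_equal(d1, d2)
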