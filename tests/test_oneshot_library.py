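"""One-shot energy contracts and the function catalogue."""

import numpy as np
import pytest

from fockforge import library
from fockforge.oneshot import MoleculeBatch, one_shot_energy, one_shot_energy_dft
from fockforge.programs import (
    CatalogueMismatchError,
    Program,
    load_program,
    program_energies,
    run_program,
    save_program,
)
from fockforge.scf import reference_scf


class TestOneShot:
    def test_identity_on_converged_fock(self, lif_ctx, lif_scf):
        r = one_shot_energy(lif_scf.fock, lif_ctx)
        assert r.valid
        assert r.energy == pytest.approx(lif_scf.energy, abs=1e-8)

    def test_scale_invariance(self, lif_ctx, lif_scf):
        for alpha in (0.03, 1.0, 250.0):
            r = one_shot_energy(alpha * lif_scf.fock, lif_ctx)
            assert r.energy == pytest.approx(lif_scf.energy, abs=1e-8)

    def test_core_guess_is_above_scf(self, h2_ctx, h2_scf):
        r = one_shot_energy(h2_ctx.Hcore, h2_ctx)
        assert r.energy >= h2_scf.energy - 1e-8

    def test_nonfinite_gives_sentinel_not_exception(self, h2_ctx):
        M = np.full((2, 2), np.inf)
        r = one_shot_energy(M, h2_ctx)
        assert not r.valid and r.energy == np.inf
        r2 = one_shot_energy_dft(M, h2_ctx)
        assert not r2.valid and r2.energy == np.inf

    def test_electron_conservation(self, ch4_ctx):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = rng.normal(size=(ch4_ctx.n_ao,) * 2)
            r = one_shot_energy((A + A.T) / 2, ch4_ctx)
            if r.valid:
                assert np.sum(r.density * ch4_ctx.S) == pytest.approx(
                    2 * ch4_ctx.n_occ, abs=1e-8)

    def test_batch_agrees_with_single_geometry_path(self, lif_ctx, lif_scf):
        batch = MoleculeBatch([lif_ctx])
        e, valid = batch.one_shot_energies(lif_scf.fock[None])
        assert valid[0]
        assert e[0] == pytest.approx(lif_scf.energy, abs=1e-9)


class TestCatalogue:
    def test_role_counts(self):
        specs = library.catalog()
        roles = {}
        for s in specs:
            roles[s.layer_role] = roles.get(s.layer_role, 0) + 1
        assert roles["input"] == 6
        assert roles["output"] == 2
        assert roles["internal"] >= 60

    def test_ids_unique_and_resolvable(self):
        specs = library.catalog(include_test_only=True)
        ids = [s.id for s in specs]
        assert len(ids) == len(set(ids))
        for fid in ids:
            role, f = library.get_function(fid)
            assert role in ("input", "internal", "output")

    def test_oracle_input_excluded_from_search(self):
        assert "in_oracle_fock" not in [s.id for s in library.catalog()]

    def test_catalogue_hash_stable(self):
        assert library.catalogue_hash() == library.catalogue_hash()

    def test_internal_closure_on_random_symmetric_matrices(self, lif_ctx):
        """Symmetric-in => symmetric-out or a per-geometry invalid flag."""
        batch = MoleculeBatch([lif_ctx])
        rng = np.random.default_rng(11)
        internals = library.ids_by_role("internal")
        n = lif_ctx.n_ao
        mats = rng.normal(scale=2.0, size=(1000, n, n))
        mats = (mats + mats.transpose(0, 2, 1)) / 2.0
        k = 0
        for fid in internals:
            _, f = library.get_function(fid)
            for _ in range(1000 // len(internals) + 1):
                M = mats[k % len(mats)][None]
                k += 1
                out, ok = f(M.copy(), batch)
                finite = np.all(np.isfinite(out))
                if finite:
                    assert np.max(np.abs(out - out.transpose(0, 2, 1))) < 1e-8 * max(
                        1.0, np.max(np.abs(out)))
                else:
                    assert library._validity(out)[0] == False  # noqa: E712

    def test_huckel_guess_formula(self, h2_ctx):
        M = library.init_workspace("in_huckel", h2_ctx)
        h = np.diag(h2_ctx.Hcore)
        assert M[0, 1] == pytest.approx(0.875 * h2_ctx.S[0, 1] * (h[0] + h[1]), abs=1e-12)
        assert M[0, 0] == pytest.approx(h[0], abs=1e-12)

    def test_input_functions_symmetric(self, lif_ctx):
        for fid in library.ids_by_role("input"):
            M = library.init_workspace(fid, lif_ctx)
            assert np.max(np.abs(M - M.T)) < 1e-12

    def test_hcore_input_exact(self, lif_ctx):
        assert np.array_equal(library.init_workspace("in_hcore", lif_ctx), lif_ctx.Hcore)

    def test_elementwise_square_example(self, h2_ctx):
        M = np.array([[1.0, -2.0], [-2.0, 3.0]])
        out, ok = library.apply_internal("ew_square", M, h2_ctx)
        assert np.allclose(out, [[1.0, 4.0], [4.0, 9.0]])
        assert ok

    def test_roothaan_step_equals_first_scf_iteration(self, h2_ctx):
        from fockforge.scf import density_from_mos, fock_from_density, generalized_eigensolve

        out, ok = library.apply_internal("roothaan", h2_ctx.Hcore, h2_ctx)
        mos = generalized_eigensolve(h2_ctx.Hcore, h2_ctx.S)
        F1 = fock_from_density(density_from_mos(mos, h2_ctx.n_occ), h2_ctx)
        assert ok
        assert np.max(np.abs(out - F1)) < 1e-10

    @pytest.mark.parametrize("map_name", library.MONOTONE_MAPS)
    def test_monotone_spectral_maps_preserve_one_shot_energy(self, lif_ctx, lif_scf, map_name):
        out, ok = library.apply_internal(f"sp_{map_name}", lif_scf.fock, lif_ctx)
        assert ok
        r = one_shot_energy(out, lif_ctx)
        assert r.energy == pytest.approx(lif_scf.energy, abs=1e-8)

    def test_spectral_map_preserves_eigenvectors(self, lif_ctx, lif_scf):
        """sp_cube cubes the generalized spectrum without touching the
        eigenvector subspaces (degenerate pi levels may rotate internally,
        so subspaces are compared through the occupied projector)."""
        from fockforge.scf import density_from_mos, generalized_eigensolve

        out, ok = library.apply_internal("sp_cube", lif_scf.fock, lif_ctx)
        m0 = generalized_eigensolve(lif_scf.fock, lif_ctx.S)
        m1 = generalized_eigensolve(out, lif_ctx.S)
        assert np.allclose(m1.eigenvalues, m0.eigenvalues**3, atol=1e-8)
        P0 = density_from_mos(m0, lif_ctx.n_occ)
        P1 = density_from_mos(m1, lif_ctx.n_occ)
        assert np.max(np.abs(P0 - P1)) < 1e-8


class TestPrograms:
    def test_role_validation(self):
        with pytest.raises(ValueError):
            Program(("identity", "identity", "out_gen_eig"))
        with pytest.raises(ValueError):
            Program(("in_hcore", "identity", "identity"))
        with pytest.raises(ValueError):
            Program(("in_hcore", "in_hcore", "out_gen_eig"))

    def test_identity_chain_reproduces_core_guess(self, h2_ctx):
        from fockforge.scf import generalized_eigensolve

        p = Program(("in_hcore",) + ("identity",) * 13 + ("out_gen_eig",))
        M, mos, ok = run_program(p, h2_ctx)
        assert ok
        assert np.array_equal(M, h2_ctx.Hcore)
        ref = generalized_eigensolve(h2_ctx.Hcore, h2_ctx.S)
        assert np.allclose(mos.coeffs, ref.coeffs, atol=1e-10)

    def test_interpreter_deterministic(self, lif_ctx):
        p = Program(("in_huckel", "roothaan", "ew_tanh", "smetric_square", "out_gen_eig"))
        M1, _, _ = run_program(p, lif_ctx)
        M2, _, _ = run_program(p, lif_ctx)
        assert np.array_equal(M1, M2)

    def test_overflow_flags_invalid_without_crash(self, lif_ctx):
        # repeated clipped exponentials blow the norm guard
        p = Program(("in_hcore",) + ("ew_exp", "ew_square", "ew_square", "ew_square",
                                     "ew_square", "ew_square") + ("out_gen_eig",))
        M, mos, ok = run_program(p, lif_ctx)
        assert not ok
        batch = MoleculeBatch([lif_ctx])
        e, valid = program_energies(p, batch)
        assert not valid[0] and e[0] == np.inf

    def test_lowdin_output_conserves_electrons(self, lif_ctx):
        p = Program(("in_huckel", "roothaan", "out_lowdin_eig"))
        batch = MoleculeBatch([lif_ctx])
        M, valid = __import__("fockforge.programs", fromlist=["run_program_batched"]).run_program_batched(p, batch)
        from fockforge.programs import _mos_from_output

        w, C = _mos_from_output("out_lowdin_eig", M, batch)
        P = 2.0 * C[:, :, : batch.n_occ] @ C[:, :, : batch.n_occ].transpose(0, 2, 1)
        assert np.sum(P[0] * lif_ctx.S) == pytest.approx(2 * lif_ctx.n_occ, abs=1e-8)

    def test_serialization_round_trip(self, tmp_path):
        p = Program(("in_huckel", "roothaan", "identity", "out_gen_eig"))
        shifts = {"Li": 0.1234, "F": -0.5}
        path = tmp_path / "prog.json"
        save_program(path, p, shifts, "STO-3G", "rhf", provenance={"seed": 1})
        p2, s2, rec = load_program(path)
        assert p2 == p
        assert s2 == shifts
        assert rec["basis_label"] == "STO-3G"
        assert rec["method"] == "rhf"

    def test_stale_catalogue_rejected(self, tmp_path):
        import json

        p = Program(("in_huckel", "roothaan", "out_gen_eig"))
        path = tmp_path / "prog.json"
        save_program(path, p, {"H": 0.0}, "STO-3G", "rhf")
        rec = json.loads(path.read_text())
        rec["catalogue_hash"] = "deadbeef"
        path.write_text(json.dumps(rec))
        with pytest.raises(CatalogueMismatchError):
            load_program(path)
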