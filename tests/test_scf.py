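"""Restricted SCF, gradients and the Kohn-Sham path."""

import numpy as np
import pytest
import scipy.linalg

from fockforge.geometry import Geometry
from fockforge.grad import rhf_gradient
from fockforge.scf import (
    build_ao_context,
    density_from_mos,
    fock_from_density,
    generalized_eigensolve,
    hf_energy,
    reference_scf,
    MOSet,
)

BOHR = 0.52917721092


class TestReferenceEnergies:
    """Frozen literature anchors for RHF/STO-3G."""

    def test_h2(self, h2_scf):
        assert h2_scf.energy == pytest.approx(-1.1167, abs=5e-4)

    def test_helium(self):
        res = reference_scf(Geometry(("He",), [[0, 0, 0]]))
        assert res.energy == pytest.approx(-2.80778, abs=5e-5)

    def test_methane_at_optimized_geometry(self, ch4_scf):
        assert ch4_scf.energy == pytest.approx(-39.72686, abs=5e-5)


class TestSCFContracts:
    def test_mo_orthonormality_and_density(self, lif_ctx, lif_scf):
        C = lif_scf.mos.coeffs
        S = lif_ctx.S
        assert np.max(np.abs(C.T @ S @ C - np.eye(lif_ctx.n_ao))) < 1e-8
        P = lif_scf.density
        assert np.sum(P * S) == pytest.approx(2 * lif_ctx.n_occ, abs=1e-8)
        assert np.max(np.abs(P @ S @ P - 2 * P)) < 1e-8

    def test_converged_fock_self_consistency(self, lif_ctx, lif_scf):
        F = fock_from_density(lif_scf.density, lif_ctx)
        assert np.max(np.abs(F - lif_scf.fock)) < 1e-7
        comm = F @ lif_scf.density @ lif_ctx.S - lif_ctx.S @ lif_scf.density @ F
        assert np.max(np.abs(comm)) < 1e-6

    def test_zero_density_limits(self, h2_ctx):
        P0 = np.zeros((2, 2))
        assert np.allclose(fock_from_density(P0, h2_ctx), h2_ctx.Hcore)
        assert hf_energy(P0, h2_ctx.Hcore, h2_ctx) == pytest.approx(h2_ctx.E_nuc)

    def test_density_from_unit_coefficients(self):
        mos = MOSet(coeffs=np.eye(2), eigenvalues=np.array([0.0, 1.0]))
        assert np.allclose(density_from_mos(mos, 1), [[2, 0], [0, 0]])
        with pytest.raises(ValueError):
            density_from_mos(mos, 3)

    def test_shape_mismatch_rejected(self, h2_ctx):
        with pytest.raises(ValueError):
            fock_from_density(np.zeros((3, 3)), h2_ctx)

    def test_nonfinite_energy_rejected(self, h2_ctx):
        P = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            hf_energy(P, h2_ctx.Hcore, h2_ctx)


class TestGeneralizedEigensolve:
    def test_diagonal_case(self):
        mos = generalized_eigensolve(np.diag([3.0, 1.0, 2.0]), np.eye(3))
        assert np.allclose(mos.eigenvalues, [1.0, 2.0, 3.0])

    def test_against_scipy(self, h2_ctx):
        mos = generalized_eigensolve(h2_ctx.Hcore, h2_ctx.S)
        w = scipy.linalg.eigvalsh(h2_ctx.Hcore, h2_ctx.S)
        assert np.allclose(mos.eigenvalues, w, atol=1e-12)
        assert np.max(np.abs(mos.coeffs.T @ h2_ctx.S @ mos.coeffs - np.eye(2))) < 1e-8

    def test_sign_convention(self, lif_ctx):
        mos = generalized_eigensolve(lif_ctx.Hcore, lif_ctx.S)
        for j in range(lif_ctx.n_ao):
            col = mos.coeffs[:, j]
            nz = np.nonzero(np.abs(col) > 1e-12)[0]
            assert col[nz[0]] > 0

    def test_nonsymmetric_rejected(self):
        M = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            generalized_eigensolve(M, np.eye(2))


class TestGradient:
    def test_matches_finite_differences(self, water):
        ctx = build_ao_context(water)
        res = reference_scf(ctx)
        grad = rhf_gradient(ctx, res)
        h = 1e-4
        for (i, d) in [(0, 0), (1, 1), (2, 2), (2, 0)]:
            num = 0.0
            for sgn in (1.0, -1.0):
                c = water.coords.copy()
                c[i, d] += sgn * h * BOHR
                num += sgn * reference_scf(build_ao_context(water.with_coords(c)),
                                           conv_tol=1e-12).energy
            num /= 2 * h
            assert grad[i, d] == pytest.approx(num, abs=5e-6)

    def test_translational_sum_rule(self, ch4_ctx, ch4_scf):
        grad = rhf_gradient(ch4_ctx, ch4_scf)
        assert np.max(np.abs(grad.sum(axis=0))) < 1e-8


class TestKohnSham:
    def test_rks_converges_and_counts_electrons(self, lif_ctx):
        res = reference_scf(lif_ctx, method="dft:lda")
        assert res.converged
        assert np.sum(res.density * lif_ctx.S) == pytest.approx(12.0, abs=1e-8)
        # LDA total energy close to, but distinct from, the HF value
        assert res.energy == pytest.approx(-105.0, abs=2.0)

    def test_unknown_functional(self, lif_ctx):
        with pytest.raises(ValueError, match="functional"):
            reference_scf(lif_ctx, method="dft:b3lyp")

    def test_xc_functional_derivative_consistency(self, h2_ctx):
        from fockforge.dft import build_grid, xc_energy_matrix

        grid = build_grid(h2_ctx.geometry)
        rng = np.random.default_rng(3)
        P = np.eye(2) * 0.7
        e0, V = xc_energy_matrix(P, grid)
        dP = rng.normal(size=(2, 2)) * 1e-6
        dP = dP + dP.T
        e1, _ = xc_energy_matrix(P + dP, grid)
        assert e1 - e0 == pytest.approx(np.sum(V * dP), abs=1e-11)

    def test_grid_integrates_gaussian_exchange_closed_form(self, h2_ctx):
        from fockforge.dft import build_grid, _CX

        grid = build_grid(Geometry(("He",), [[0, 0, 0]]))
        a, q = 0.8, 2.0
        N = q * (2 * a / np.pi) ** 1.5
        r2 = np.einsum("ij,ij->i", grid.points, grid.points)
        rho = N * np.exp(-2 * a * r2)
        ex_grid = np.sum(grid.weights * rho * (-_CX * rho ** (1.0 / 3.0)))
        from scipy.integrate import quad

        ex_exact = -_CX * quad(
            lambda r: (N * np.exp(-2 * a * r * r)) ** (4 / 3) * 4 * np.pi * r * r, 0, 20
        )[0]
        assert ex_grid == pytest.approx(ex_exact, abs=1e-8)
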