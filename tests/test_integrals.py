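"""Integral engine checks against independent closed forms and invariances."""

import numpy as np
import pytest
from scipy.integrate import quad

from fockforge.basis import BasisSet, build_basis, _U_1S, _U_2SP, _U_3SP
from fockforge.geometry import Geometry
from fockforge import integrals
from fockforge.scf import build_ao_context, reference_scf

import oracles


def _s_only_basis(alphas, centers):
    """Single-primitive s shells (two padding primitives with zero weight)."""
    nsh = len(alphas)
    A = np.zeros((nsh, 3))
    C = np.zeros((nsh, 3))
    for i, a in enumerate(alphas):
        A[i] = (a, a * 2.0, a * 3.0)  # padding exponents, weight zero
        C[i] = (oracles.s_norm(a), 0.0, 0.0)
    return BasisSet(
        label="STO-3G",
        centers=np.asarray(centers, float),
        shell_l=np.zeros(nsh, dtype=np.int64),
        alphas=A,
        coefs=C,
        shell_atom=np.arange(nsh, dtype=np.int64),
        ao_offset=np.arange(nsh, dtype=np.int64),
    )


class TestSOnlyClosedForms:
    """McMurchie-Davidson vs the textbook 1s closed forms."""

    def setup_method(self):
        rng = np.random.default_rng(42)
        self.alphas = [0.31, 1.7, 0.8, 2.4]
        self.centers = rng.normal(scale=1.2, size=(4, 3))
        self.basis = _s_only_basis(self.alphas, self.centers)

    def test_overlap_kinetic(self):
        S, T = integrals.overlap_kinetic_kernel(
            self.basis.centers, self.basis.shell_l, self.basis.alphas,
            self.basis.coefs, self.basis.ao_offset, integrals._COMP)
        for i, (a, A) in enumerate(zip(self.alphas, self.centers)):
            for j, (b, B) in enumerate(zip(self.alphas, self.centers)):
                assert S[i, j] == pytest.approx(oracles.s_overlap(a, A, b, B), abs=1e-12)
                assert T[i, j] == pytest.approx(oracles.s_kinetic(a, A, b, B), abs=1e-12)

    def test_nuclear(self):
        xyz = self.centers[:2]
        Z = np.array([3.0, 9.0])
        V = integrals.nuclear_attraction(self.basis, xyz, Z)
        for c in range(2):
            for i, (a, A) in enumerate(zip(self.alphas, self.centers)):
                for j, (b, B) in enumerate(zip(self.alphas, self.centers)):
                    ref = oracles.s_nuclear(a, A, b, B, xyz[c], Z[c])
                    assert V[c, i, j] == pytest.approx(ref, abs=1e-12)

    def test_eri(self):
        eri = integrals.electron_repulsion(self.basis)
        rng = np.random.default_rng(0)
        for _ in range(25):
            i, j, k, l = rng.integers(0, 4, size=4)
            ref = oracles.s_eri(
                self.alphas[i], self.centers[i], self.alphas[j], self.centers[j],
                self.alphas[k], self.centers[k], self.alphas[l], self.centers[l])
            assert eri[i, j, k, l] == pytest.approx(ref, abs=1e-12)


class TestBasisConstruction:
    def test_stored_expansions_are_least_squares_optima(self):
        """For the frozen exponents, the linear-optimal Slater-overlap
        coefficients must reproduce the stored contraction coefficients."""

        def radial_norm(f):
            return 1.0 / np.sqrt(quad(lambda r: f(r) ** 2 * r * r, 0, 60, limit=200)[0])

        def check(alphas, coeffs, n, l, min_overlap):
            sto_raw = lambda r: r ** (n - 1) * np.exp(-r)
            Ns = radial_norm(sto_raw)
            sto = lambda r: Ns * sto_raw(r)
            gs = []
            for a in alphas:
                graw = lambda r, a=a: r**l * np.exp(-a * r * r)
                Ng = radial_norm(graw)
                gs.append(lambda r, g=graw, N=Ng: N * g(r))
            v = np.array([quad(lambda r: g(r) * sto(r) * r * r, 0, 60, limit=200)[0] for g in gs])
            Smat = np.array([[quad(lambda r: gi(r) * gj(r) * r * r, 0, 60, limit=200)[0]
                              for gj in gs] for gi in gs])
            c = np.linalg.solve(Smat, v)
            c = c / np.sqrt(c @ Smat @ c)
            assert np.allclose(c, coeffs, atol=2e-6)
            assert v @ c > min_overlap

        check(_U_1S[0], _U_1S[1], 1, 0, 0.9998)
        check(_U_2SP[0], _U_2SP[1], 2, 0, 0.9996)
        check(_U_2SP[0], _U_2SP[2], 2, 1, 0.9998)
        check(_U_3SP[0], _U_3SP[1], 3, 0, 0.9998)
        check(_U_3SP[0], _U_3SP[2], 3, 1, 0.9998)

    @pytest.mark.parametrize(
        "elements,coords,nao,nocc",
        [
            (("H", "H"), [[0, 0, 0], [0.7414, 0, 0]], 2, 1),
            (("He",), [[0, 0, 0]], 1, 1),
            (("C", "H", "H", "H", "H"),
             [[0, 0, 0], [0.63, 0.63, 0.63], [0.63, -0.63, -0.63],
              [-0.63, 0.63, -0.63], [-0.63, -0.63, 0.63]], 9, 5),
        ],
    )
    def test_context_dimensions(self, elements, coords, nao, nocc):
        ctx = build_ao_context(Geometry(elements, coords))
        assert ctx.n_ao == nao
        assert ctx.n_occ == nocc

    def test_h2_textbook_values(self, h2_ctx):
        # worked-example values for H2/STO-3G at 1.4 bohr
        assert h2_ctx.S[0, 1] == pytest.approx(0.6593, abs=2e-4)
        assert h2_ctx.T_kin[0, 0] == pytest.approx(0.7600, abs=2e-4)
        assert h2_ctx.eri[0, 0, 0, 0] == pytest.approx(0.7746, abs=2e-4)
        assert h2_ctx.eri[0, 0, 1, 1] == pytest.approx(0.5697, abs=2e-4)
        assert h2_ctx.eri[0, 1, 0, 1] == pytest.approx(0.2970, abs=2e-4)

    def test_helium_single_function(self):
        ctx = build_ao_context(Geometry(("He",), [[0, 0, 0]]))
        assert ctx.S == pytest.approx(np.array([[1.0]]), abs=1e-12)

    def test_unknown_basis_and_element(self, h2):
        with pytest.raises(ValueError, match="basis"):
            build_basis(h2, "6-311G")
        with pytest.raises(ValueError):
            Geometry(("Xx",), [[0, 0, 0]])

    def test_linear_dependence_detected(self):
        # two H atoms nearly on top of each other
        g = Geometry(("H", "H"), [[0, 0, 0], [1e-5, 0, 0]])
        with pytest.raises(ValueError, match="linear dependence"):
            build_ao_context(g)


class TestInvariances:
    def test_eri_permutational_symmetry(self, lif_ctx):
        e = lif_ctx.eri
        assert np.allclose(e, e.transpose(1, 0, 2, 3), atol=1e-12)
        assert np.allclose(e, e.transpose(0, 1, 3, 2), atol=1e-12)
        assert np.allclose(e, e.transpose(2, 3, 0, 1), atol=1e-12)

    def test_energy_rotation_translation_invariance(self, water):
        e0 = reference_scf(build_ao_context(water)).energy
        rng = np.random.default_rng(7)
        for _ in range(2):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = water.with_coords(water.coords @ Q.T + rng.normal(size=3))
            e1 = reference_scf(build_ao_context(moved)).energy
            assert e1 == pytest.approx(e0, abs=1e-10)


class TestContextCache:
    def test_round_trip_and_reuse(self, tmp_path, lif, lif_ctx):
        from fockforge.cache import ContextCache

        cache = ContextCache(tmp_path / "ao_cache.h5")
        assert not cache.has(lif)
        cache.store(lif_ctx)
        assert cache.has(lif)
        back = cache.load(lif)
        assert np.array_equal(back.S, lif_ctx.S)
        assert np.array_equal(back.eri, lif_ctx.eri)
        assert back.E_nuc == lif_ctx.E_nuc
        assert back.n_occ == lif_ctx.n_occ
        # get_or_build hits the cache (bitwise-identical quantities)
        again = cache.get_or_build(lif)
        assert np.array_equal(again.Hcore, lif_ctx.Hcore)

    def test_distinct_geometries_do_not_collide(self, tmp_path, lif_ctx, h2_ctx):
        from fockforge.cache import ContextCache

        cache = ContextCache(tmp_path / "ao_cache.h5")
        cache.store(lif_ctx)
        cache.store(h2_ctx)
        assert cache.load(h2_ctx.geometry).n_ao == 2
        assert cache.load(lif_ctx.geometry).n_ao == 10
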