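"""Canonical frames, diatomic scans, normal modes and shell sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fockforge.constants import AMU_TO_ME, ANGSTROM_TO_BOHR, ELEMENT_MASS
from fockforge.geometry import Geometry, canonical_frame, read_xyz, write_xyz
from fockforge.modes import compute_normal_modes
from fockforge.sampling import (
    diatomic_training_scan,
    filter_by_reference_energy,
    sample_quadratic_shell,
)
from fockforge.scf import build_ao_context, reference_scf
from fockforge.structures import initial_structure


class TestCanonicalFrame:
    def test_idempotent(self, ch4):
        g1 = canonical_frame(ch4)
        g2 = canonical_frame(g1)
        assert np.allclose(g1.coords, g2.coords, atol=1e-12)

    def test_diatomic_on_x_axis(self):
        g = canonical_frame(Geometry(("Li", "F"), [[1.0, 2.0, 3.0], [1.2, 2.5, 3.1]]))
        assert np.allclose(g.coords[0], 0.0)
        assert g.coords[1, 0] > 0
        assert np.allclose(g.coords[1, 1:], 0.0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rotation_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        base = initial_structure("CH4")
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]  # proper rotation only
        moved = base.with_coords(base.coords @ Q.T + rng.normal(size=3))
        g1 = canonical_frame(base)
        g2 = canonical_frame(moved)
        assert np.allclose(g1.coords, g2.coords, atol=1e-9)

    def test_collinear_first_three_falls_back(self):
        # first three atoms on a line; fourth defines the plane
        g = Geometry(("C", "C", "C", "O", "H", "H"),
                     [[0, 0, 0], [1.3, 0, 0], [2.6, 0, 0], [3.2, 1.0, 0.3],
                      [-0.9, 0.4, 0.2], [3.0, -1.2, -0.4]],
                     metadata={"allow_open_shell": True})
        out = canonical_frame(g)
        assert out.metadata.get("frame_plane_atom") == 3
        assert abs(out.coords[3, 2]) < 1e-10 and out.coords[3, 1] > 0


class TestXYZRoundTrip:
    def test_round_trip_with_reference_energy(self, tmp_path):
        g = initial_structure("CH4")
        g.metadata["E_ref"] = -39.72686374
        path = tmp_path / "geoms.xyz"
        write_xyz(path, [g, g])
        back = read_xyz(path)
        assert len(back) == 2
        assert back[0].elements == g.elements
        assert np.allclose(back[0].coords, g.coords, atol=1e-9)
        assert back[0].metadata["E_ref"] == pytest.approx(-39.72686374, abs=1e-10)


@pytest.fixture(scope="module")
def licl():
    return diatomic_training_scan("Li", "Cl", n=15, seed=3, n_grid=80)


class TestDiatomicScan:

    def test_count_and_energy_window(self, licl):
        assert len(licl) == 15
        e = np.array([g.metadata["E_ref"] for g in licl])
        e_min = licl[0].metadata["E_min_curve"]
        assert np.all(e - e_min <= 0.25 + 1e-12)

    def test_both_branches_covered(self, licl):
        radii = np.array([g.coords[1, 0] for g in licl])
        e = np.array([g.metadata["E_ref"] for g in licl])
        r_eq = radii[np.argmin(e)]
        assert (radii < r_eq).sum() >= 3
        assert (radii > r_eq).sum() >= 5

    def test_reproducible(self):
        a = diatomic_training_scan("Li", "F", n=6, seed=9, n_grid=50)
        b = diatomic_training_scan("Li", "F", n=6, seed=9, n_grid=50)
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))

    def test_degenerate_threshold(self):
        with pytest.raises(ValueError):
            diatomic_training_scan("Li", "F", E_max=0.0, n=5, n_grid=40)
        only = diatomic_training_scan("Li", "F", E_max=0.0, n=1, n_grid=40)
        assert len(only) == 1


class TestNormalModes:
    def test_h2_frequency_matches_energy_curvature_oracle(self):
        nm = compute_normal_modes(Geometry(("H", "H"), [[0, 0, 0], [0.71, 0, 0]]))
        assert nm.n_modes == 1
        # central-difference curvature of E(r) at the minimum
        r0 = np.linalg.norm(nm.equilibrium.coords[1] - nm.equilibrium.coords[0]) * ANGSTROM_TO_BOHR
        h = 0.01

        def e_of(r_bohr):
            g = Geometry(("H", "H"), [[0, 0, 0], [r_bohr / ANGSTROM_TO_BOHR, 0, 0]])
            return reference_scf(build_ao_context(g), conv_tol=1e-12).energy

        k = (e_of(r0 + h) - 2 * e_of(r0) + e_of(r0 - h)) / h**2
        mu = ELEMENT_MASS["H"] / 2 * AMU_TO_ME
        omega_oracle = np.sqrt(k / mu)
        assert nm.frequencies[0] == pytest.approx(omega_oracle, rel=0.01)

    def test_shipped_ethane_is_staggered(self):
        # dihedral H-C-C-H of the stored equilibrium must be ~60 deg; the
        # eclipsed rotamer is a torsional saddle point, not a minimum
        g = initial_structure("C2H6")
        c = {el_i: xyz for el_i, xyz in enumerate(g.coords)}
        b1 = g.coords[2] - g.coords[0]
        ax = g.coords[1] - g.coords[0]
        b2 = g.coords[5] - g.coords[1]
        ax_u = ax / np.linalg.norm(ax)
        p1 = b1 - b1 @ ax_u * ax_u
        p2 = b2 - b2 @ ax_u * ax_u
        cosd = p1 @ p2 / np.linalg.norm(p1) / np.linalg.norm(p2)
        dihedral = np.rad2deg(np.arccos(np.clip(cosd, -1, 1)))
        assert min(dihedral, abs(120 - dihedral)) == pytest.approx(60.0, abs=2.0)

    def test_ch4_mode_count_and_orthonormality(self, ch4):
        nm = compute_normal_modes(ch4, relax=True)
        assert nm.n_modes == 9
        G = nm.modes_mw @ nm.modes_mw.T
        assert np.max(np.abs(G - np.eye(9))) < 1e-8
        assert np.all(nm.frequencies > 0)

    def test_symmetry_derived_hessian_matches_full(self):
        from fockforge.modes import detect_point_symmetry, hessian_fd, optimize_geometry

        g = optimize_geometry(initial_structure("CH4"))
        ops = detect_point_symmetry(g)
        assert len(ops) >= 1  # the canonical frame exposes a mirror plane
        Hs = hessian_fd(g, use_symmetry=True)
        Hf = hessian_fd(g, use_symmetry=False)
        assert np.max(np.abs(Hs - Hf)) < 1e-9


@pytest.fixture(scope="module")
def ch4_nm(ch4):
    return compute_normal_modes(ch4, relax=True)


class TestShellSampling:

    def test_quadratic_energy_exact_and_bounded(self, ch4_nm):
        samples = sample_quadratic_shell(ch4_nm, 0.03, [0, 1, 2, 3], 50, seed=1)
        for s in samples:
            quad = 0.5 * np.sum(ch4_nm.frequencies**2 * s.q**2)
            assert quad == pytest.approx(s.epsilon, abs=1e-10)
            assert s.epsilon <= 0.03

    def test_single_mode_amplitude(self, ch4_nm):
        samples = sample_quadratic_shell(ch4_nm, 0.02, [2], 20, seed=4)
        for s in samples:
            assert abs(s.q[2]) == pytest.approx(
                np.sqrt(2 * s.epsilon) / ch4_nm.frequencies[2], abs=1e-12)

    def test_reproducible_bitwise(self, ch4_nm):
        a = sample_quadratic_shell(ch4_nm, 0.03, [0, 1], 10, seed=7)
        b = sample_quadratic_shell(ch4_nm, 0.03, [0, 1], 10, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.geometry.coords, y.geometry.coords)

    def test_invalid_mode_subset(self, ch4_nm):
        with pytest.raises(ValueError):
            sample_quadratic_shell(ch4_nm, 0.03, [], 5, seed=0)

    def test_filter_removes_high_energy_points(self, ch4_nm):
        samples = sample_quadratic_shell(ch4_nm, 0.05, [0, 1, 2, 3], 30, seed=2)
        kept, counters = filter_by_reference_energy(
            samples, "STO-3G", "rhf", 0.02, ch4_nm.energy)
        assert counters["kept"] == len(kept)
        assert counters["kept"] + counters["above_threshold"] + counters["scf_failed"] == 30
        for s in kept:
            assert s.e_ref - ch4_nm.energy <= 0.02
        assert counters["above_threshold"] > 0  # oversampled window must prune

    def test_filter_passthrough_when_all_below(self, ch4_nm):
        samples = sample_quadratic_shell(ch4_nm, 0.005, [0, 1], 8, seed=3)
        kept, counters = filter_by_reference_energy(
            samples, "STO-3G", "rhf", 0.05, ch4_nm.energy)
        assert len(kept) == 8 and counters["above_threshold"] == 0
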