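"""Chain geometry, elastic energetics and electrostatics of the DNA model."""

import numpy as np
import pytest

import nucwrap as nw
from nucwrap import _kernels as K
from nucwrap.dna_model import DNAParams

from conftest import random_chain, perturb_with_transport

KBT = 4.114  # pN*nm at 298 K (two significant checks rely on this value)


class TestBuildStraightChain:
    def test_standard_chain_dimensions(self, dna_params):
        ch = nw.build_straight_chain(100, dna_params)
        assert ch.n_segments == 100
        assert np.isclose(ch.vertices[-1, 2] - ch.vertices[0, 2], 340.0)
        seg = np.diff(ch.vertices, axis=0)
        assert np.allclose(np.linalg.norm(seg, axis=1), 3.4)

    def test_frames_orthonormal_and_angles_zero(self, dna_params):
        ch = nw.build_straight_chain(2, dna_params)
        for fr in ch.frames:
            assert np.allclose(fr @ fr.T, np.eye(3), atol=1e-12)
            assert np.allclose(np.cross(fr[0], fr[1]), fr[2], atol=1e-12)
        geom = nw.update_geometry(ch)
        assert geom.bend_angles[1] == pytest.approx(0.0, abs=1e-12)
        assert geom.twist_angles[1] == pytest.approx(0.0, abs=1e-12)

    def test_arbitrary_axis_end_to_end(self, dna_params):
        ch = nw.build_straight_chain(10, dna_params, axis=(1, 0, 0))
        assert np.linalg.norm(ch.vertices[-1] - ch.vertices[0]) == \
            pytest.approx(34.0)

    def test_too_short_rejected(self, dna_params):
        with pytest.raises(ValueError):
            nw.build_straight_chain(1, dna_params)


class TestUpdateGeometry:
    def test_pure_twist_about_common_axis(self, dna_params):
        ch = nw.build_straight_chain(4, dna_params)
        K.rotate_frame_about_e(ch.frames, 2, 0.3)
        geom = nw.update_geometry(ch)
        assert geom.twist_angles[2] == pytest.approx(0.3, abs=1e-12)
        assert geom.twist_angles[3] == pytest.approx(-0.3, abs=1e-12)
        assert np.allclose(geom.bend_angles, 0.0, atol=1e-12)

    def test_right_angle_bend_pure_transport(self, dna_params):
        ch = nw.build_straight_chain(2, dna_params)
        ch.vertices[2] = ch.vertices[1] + np.array([3.4, 0.0, 0.0])
        s = np.empty((2, 3)); slen = np.empty(2); e = np.empty((2, 3))
        K.chain_tangents(ch.vertices, s, slen, e)
        K.transport_frames(ch.frames, e)
        geom = nw.update_geometry(ch)
        assert geom.bend_angles[1] == pytest.approx(np.pi / 2, abs=1e-12)
        assert geom.twist_angles[1] == pytest.approx(0.0, abs=1e-9)

    def test_twist_matches_rotation_decomposition_oracle(self):
        # independent oracle: decompose the joint rotation into the minimal
        # (parallel-transport) rotation e1->e2 followed by a spin about e2;
        # the spin angle is the twist
        ch = random_chain(12, seed=7)
        geom = nw.update_geometry(ch)
        for i in range(1, 12):
            f1, g1, e1 = ch.frames[i - 1]
            f2, g2, e2 = ch.frames[i]
            v = np.cross(e1, e2)
            c = float(np.dot(e1, e2))
            if np.linalg.norm(v) < 1e-15:
                f_t = f1
            else:
                vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                               [-v[1], v[0], 0.0]])
                R = np.eye(3) + vx + vx @ vx / (1.0 + c)
                f_t = R @ f1
            theta = np.arctan2(np.dot(np.cross(f_t, f2), e2),
                               np.dot(f_t, f2))
            assert geom.twist_angles[i] == pytest.approx(theta, abs=1e-10)

    def test_zero_length_segment_rejected(self, dna_params):
        ch = nw.build_straight_chain(3, dna_params)
        ch.vertices[2] = ch.vertices[1]
        with pytest.raises(ValueError, match="degenerate"):
            nw.update_geometry(ch)


class TestElasticEnergy:
    def test_equilibrium_is_zero(self, dna_params):
        ch = nw.build_straight_chain(10, dna_params)
        geom = nw.update_geometry(ch)
        stretch, bend, twist = nw.elastic_energy(ch, geom, dna_params)
        assert stretch == pytest.approx(0.0, abs=1e-12)
        assert bend == pytest.approx(0.0, abs=1e-12)
        assert twist == pytest.approx(0.0, abs=1e-12)

    def test_ten_percent_stretch_costs_half_kbt(self, dna_params):
        # (l0 - s)^2 / (2 (l0 a_s)^2) with s = 1.1 l0 and a_s = 0.1 -> kBT/2
        ch = nw.build_straight_chain(3, dna_params)
        ch.vertices[3, 2] += 0.34
        s = np.empty((3, 3)); slen = np.empty(3); e = np.empty((3, 3))
        K.chain_tangents(ch.vertices, s, slen, e)
        K.transport_frames(ch.frames, e)
        geom = nw.update_geometry(ch)
        stretch, bend, twist = nw.elastic_energy(ch, geom, dna_params)
        assert stretch == pytest.approx(0.5 * dna_params.kbt, rel=1e-12)
        assert bend == 0.0 and twist == 0.0

    def test_single_twist_energy_value(self, dna_params):
        # a_t/(2 l0) * theta^2 = 400/(6.8) * 0.01 = 0.588 pN*nm
        ch = nw.build_straight_chain(2, dna_params)
        K.rotate_frame_about_e(ch.frames, 1, 0.1)
        geom = nw.update_geometry(ch)
        _, _, twist = nw.elastic_energy(ch, geom, dna_params)
        assert twist == pytest.approx(400.0 / 6.8 * 0.01, rel=1e-12)


class TestElasticForces:
    def test_straight_chain_has_no_forces(self, dna_params):
        ch = nw.build_straight_chain(8, dna_params)
        geom = nw.update_geometry(ch)
        F, T = nw.elastic_forces_torques(ch, geom, dna_params)
        assert np.allclose(F, 0.0, atol=1e-12)
        assert np.allclose(T, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_forces_match_numerical_gradient(self, dna_params, seed):
        ch = random_chain(10, seed)
        geom = nw.update_geometry(ch)
        F, _ = nw.elastic_forces_torques(ch, geom, dna_params)
        h = 1e-6
        for k in (0, 4, 10):
            for ax in range(3):
                ep = sum(nw.elastic_energy(
                    c := perturb_with_transport(ch, k, ax, h),
                    nw.update_geometry(c), dna_params))
                em = sum(nw.elastic_energy(
                    c := perturb_with_transport(ch, k, ax, -h),
                    nw.update_geometry(c), dna_params))
                fnum = -(ep - em) / (2 * h)
                assert F[k, ax] == pytest.approx(fnum, rel=1e-6, abs=1e-5)

    def test_torques_match_numerical_gradient(self, dna_params):
        ch = random_chain(8, seed=5)
        geom = nw.update_geometry(ch)
        _, T = nw.elastic_forces_torques(ch, geom, dna_params)
        h = 1e-6
        for i in range(8):
            cp = ch.copy(); K.rotate_frame_about_e(cp.frames, i, h)
            cm = ch.copy(); K.rotate_frame_about_e(cm.frames, i, -h)
            ep = sum(nw.elastic_energy(cp, nw.update_geometry(cp), dna_params))
            em = sum(nw.elastic_energy(cm, nw.update_geometry(cm), dna_params))
            assert T[i] == pytest.approx(-(ep - em) / (2 * h),
                                         rel=1e-6, abs=1e-6)

    def test_uniform_twist_telescopes_to_end_torques(self, dna_params):
        # equal twist at every joint: interior torques cancel, the ends
        # carry +-(a_t/l0) * c
        n, c = 10, 0.05
        ch = nw.build_straight_chain(n, dna_params)
        for i in range(n):
            K.rotate_frame_about_e(ch.frames, i, c * i)
        geom = nw.update_geometry(ch)
        assert np.allclose(geom.twist_angles[1:], c)
        _, T = nw.elastic_forces_torques(ch, geom, dna_params)
        scale = dna_params.alpha_t / dna_params.l0
        assert T[0] == pytest.approx(scale * c, rel=1e-9)
        assert T[-1] == pytest.approx(-scale * c, rel=1e-9)
        assert np.allclose(T[1:-1], 0.0, atol=1e-9)

    def test_net_elastic_force_vanishes(self, dna_params):
        ch = random_chain(10, seed=9)
        geom = nw.update_geometry(ch)
        F, _ = nw.elastic_forces_torques(ch, geom, dna_params)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)


class TestPointCharges:
    def test_counts_and_charge(self, dna_params):
        ch = nw.build_straight_chain(100, dna_params)
        sites = nw.place_point_charges(ch, dna_params)
        assert sites.shape == (500, 3)
        assert dna_params.site_charge == pytest.approx(8.01 * 3.4 / 5)

    def test_single_charge_sits_at_midpoint(self):
        p = DNAParams(lam=1)
        ch = nw.build_straight_chain(4, p)
        sites = nw.place_point_charges(ch, p)
        mids = 0.5 * (ch.vertices[:-1] + ch.vertices[1:])
        assert np.allclose(sites, mids)

    def test_uniform_spacing_on_straight_chain(self, dna_params):
        ch = nw.build_straight_chain(10, dna_params)
        sites = nw.place_point_charges(ch, dna_params)
        gaps = np.linalg.norm(np.diff(sites, axis=0), axis=1)
        assert np.allclose(gaps, 0.68)


class TestElectrostatics:
    def test_prefactor_is_debye_hueckel_calibrated(self, dna_params):
        # two unit charges in 150 mM: U = kBT * lB * exp(-kr)/r
        assert dna_params.dh_prefactor == pytest.approx(
            dna_params.kbt * 0.714)

    def test_pair_beyond_cutoff_contributes_nothing(self, dna_params):
        phys = np.zeros(K.NPHYS)
        phys[K.IQQ] = dna_params.dh_prefactor
        phys[K.IKAPPA] = dna_params.kappa
        phys[K.IRC] = dna_params.r_cutoff
        sites = np.array([[0.0, 0, 0], [dna_params.r_cutoff + 1e-3, 0, 0]])
        Fs = np.zeros_like(sites)
        E, _ = K.pair_forces(sites, np.array([0]), np.array([1]), 1, phys, Fs)
        assert E == 0.0 and np.all(Fs == 0.0)

    def test_single_pair_closed_form_at_debye_length(self, dna_params):
        r = 1.0 / dna_params.kappa
        phys = np.zeros(K.NPHYS)
        phys[K.IQQ] = 1.0
        phys[K.IKAPPA] = dna_params.kappa
        phys[K.IRC] = dna_params.r_cutoff
        sites = np.array([[0.0, 0, 0], [r, 0, 0]])
        Fs = np.zeros_like(sites)
        E, _ = K.pair_forces(sites, np.array([0]), np.array([1]), 1, phys, Fs)
        assert E == pytest.approx(np.exp(-1.0) * dna_params.kappa, rel=1e-12)

    def test_pair_list_matches_brute_force_enumeration(self, dna_params):
        ch = random_chain(20, seed=11, displacement=1.0, twist=0.0)
        sites = nw.place_point_charges(ch, dna_params)
        M = len(sites)
        pi = np.empty(M * M, np.int64)
        pj = np.empty(M * M, np.int64)
        npair = K.build_pairs(sites, ch.vertices, dna_params.lam,
                              dna_params.r_cutoff, pi, pj)
        got = {(a, b) for a, b in zip(pi[:npair], pj[:npair])}
        expect = set()
        for a in range(M):
            for b in range(a + 1, M):
                if b // 5 - a // 5 <= 1:
                    continue  # same or adjacent segment: bonded exclusion
                if np.linalg.norm(sites[a] - sites[b]) < dna_params.r_cutoff:
                    expect.add((a, b))
        assert got == expect

    def test_forces_match_numerical_gradient(self, dna_params):
        # helical arc brings non-bonded charges inside the cutoff
        n = 12
        ch = nw.build_straight_chain(n, dna_params)
        t = np.linspace(0, 4.5, n + 1)
        ch.vertices = np.column_stack([5 * np.cos(t), 5 * np.sin(t), 2.1 * t])
        s = np.empty((n, 3)); slen = np.empty(n); e = np.empty((n, 3))
        K.chain_tangents(ch.vertices, s, slen, e)
        K.transport_frames(ch.frames, e)
        E0, F = nw.electrostatic_energy_forces(ch, dna_params)
        assert E0 > 0
        h = 1e-6
        for k in (3, 7):
            for ax in range(3):
                cp = perturb_with_transport(ch, k, ax, h)
                cm = perturb_with_transport(ch, k, ax, -h)
                ep, _ = nw.electrostatic_energy_forces(cp, dna_params)
                em, _ = nw.electrostatic_energy_forces(cm, dna_params)
                assert F[k, ax] == pytest.approx(-(ep - em) / (2 * h),
                                                 rel=1e-6, abs=1e-6)


class TestSelfExclusion:
    def test_force_magnitude_inside_and_outside_threshold(self, dna_params):
        phys = np.zeros(K.NPHYS)
        phys[K.IFEX] = dna_params.f_ex
        phys[K.IREX] = dna_params.overlap_distance
        phys[K.IRC] = dna_params.r_cutoff
        for r, expect in ((2.1, 0.0), (1.0, 15.0)):
            sites = np.array([[0.0, 0, 0], [r, 0, 0]])
            Fs = np.zeros_like(sites)
            K.pair_forces(sites, np.array([0]), np.array([1]), 1, phys, Fs)
            assert np.linalg.norm(Fs[0]) == pytest.approx(expect, abs=1e-12)
            assert np.allclose(Fs[0], -Fs[1])

    def test_straight_chain_has_no_excluded_pairs(self, dna_params):
        ch = nw.build_straight_chain(50, dna_params)
        F = nw.dna_self_exclusion(ch, dna_params)
        assert np.all(F == 0.0)
        # brute-force scan: nearest non-bonded approach exceeds 2 nm
        sites = nw.place_point_charges(ch, dna_params)
        M = len(sites)
        dmin = min(np.linalg.norm(sites[a] - sites[b])
                   for a in range(M) for b in range(a + 1, M)
                   if b // 5 - a // 5 > 1)
        assert dmin >= 2.0
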