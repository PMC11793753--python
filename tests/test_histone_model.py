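"""Histone geometry, adsorption energetics and rigid-body Langevin steps."""

import numpy as np
import pytest

import nucwrap as nw
from nucwrap.histone_model import (BindingGeometry, HistoneParams,
                                   HistoneState, build_binding_geometry,
                                   world_sites, morse_energy_forces,
                                   histone_dna_exclusion,
                                   histone_histone_exclusion,
                                   histone_translate_step,
                                   histone_rotate_step)


class TestBindingGeometry:
    def test_site_count_and_axial_extent(self):
        g = build_binding_geometry(4.5)
        assert g.n_sites == 22
        z = g.body_sites[:, 2]
        assert z.max() - z.min() == pytest.approx(5.5)

    def test_end_diameters_and_containment(self):
        g = build_binding_geometry(4.5)
        rho = np.hypot(g.body_sites[:, 0], g.body_sites[:, 1])
        assert 2 * rho[0] == pytest.approx(8.0)
        assert 2 * rho[-1] == pytest.approx(8.0)
        assert np.all(np.linalg.norm(g.body_sites, axis=1)
                      < g.core_radius + 1.0)

    def test_left_handed_two_turns(self):
        g = build_binding_geometry(4.5)
        phi = np.unwrap(np.arctan2(g.body_sites[:, 1], g.body_sites[:, 0]))
        winding = (phi[-1] - phi[0]) / (2 * np.pi)
        assert winding == pytest.approx(-2.0, rel=0.05)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            build_binding_geometry(-1.0)


class TestWorldSites:
    def test_identity_orientation_at_origin(self):
        h = HistoneState.from_axis(center=(0, 0, 0))
        assert np.allclose(world_sites(h), h.geometry.body_sites)

    def test_spin_periodicity(self):
        h1 = HistoneState.from_axis(center=(1, 2, 3), axis=(0.6, 0, 0.8),
                                    psi=0.7)
        h2 = HistoneState.from_axis(center=(1, 2, 3), axis=(0.6, 0, 0.8),
                                    psi=0.7 + 2 * np.pi)
        assert np.allclose(world_sites(h1), world_sites(h2), atol=1e-12)

    def test_rigid_motion_is_isometric(self):
        rng = np.random.default_rng(0)
        h = HistoneState.from_axis(center=rng.normal(size=3),
                                   axis=rng.normal(size=3), psi=1.3)
        W = world_sites(h)
        body = h.geometry.body_sites
        dw = np.linalg.norm(W[:, None] - W[None, :], axis=2)
        db = np.linalg.norm(body[:, None] - body[None, :], axis=2)
        assert np.allclose(dw, db, atol=1e-9)
        assert np.allclose(np.linalg.norm(W - h.center, axis=1),
                           np.linalg.norm(body, axis=1), atol=1e-9)


def _isolated_pair(r, params):
    """One DNA site at distance r from the apical binding site, oriented so
    every other site is far outside the interaction cutoff."""
    h = HistoneState.from_axis(center=(0, 0, 0))
    top = world_sites(h)[-1]
    outward = top / np.linalg.norm(top)
    return h, np.array([top + r * outward])


class TestMorse:
    def test_minimum_depth_and_zero_force(self, hist_params):
        h, dna = _isolated_pair(hist_params.morse_delta, hist_params)
        E, Fs, hF, hT = morse_energy_forces(h, dna, hist_params)
        assert E == pytest.approx(-hist_params.epsilon, rel=1e-12)
        assert np.allclose(Fs, 0.0, atol=1e-9)

    def test_detachment_limit(self, hist_params):
        h, dna = _isolated_pair(50.0, hist_params)
        E, Fs, hF, hT = morse_energy_forces(h, dna, hist_params)
        assert E == 0.0
        assert np.all(Fs == 0.0)

    def test_three_quarter_depth_at_half_decay(self, hist_params):
        r = hist_params.morse_delta + np.log(2.0) / hist_params.morse_alpha
        h, dna = _isolated_pair(r, hist_params)
        E, *_ = morse_energy_forces(h, dna, hist_params)
        assert E == pytest.approx(-0.75 * hist_params.epsilon, rel=1e-9)

    def test_newtons_third_law_and_torque(self, hist_params):
        rng = np.random.default_rng(1)
        h = HistoneState.from_axis(center=(0, 0, 0), axis=rng.normal(size=3))
        dna = rng.normal(scale=4.0, size=(40, 3))
        E, Fs, hF, hT = morse_energy_forces(h, dna, hist_params)
        assert np.allclose(Fs.sum(axis=0) + hF, 0.0, atol=1e-10)
        # torque equals sum of site-offset x site-force transmitted to body
        num = np.zeros(3)
        eps = 1e-6
        from nucwrap import _kernels as K
        for ax in range(3):
            rho = np.zeros(3); rho[ax] = eps
            hp = h.copy(); K.apply_rotation(hp.orientation, *rho)
            hm = h.copy(); K.apply_rotation(hm.orientation, *(-rho))
            Ep, *_ = morse_energy_forces(hp, dna, hist_params)
            Em, *_ = morse_energy_forces(hm, dna, hist_params)
            num[ax] = -(Ep - Em) / (2 * eps)
        assert np.allclose(hT, num, rtol=1e-5, atol=1e-6)


class TestExclusion:
    def test_contact_boundary_is_free(self, hist_params):
        h = HistoneState.from_axis(center=(0, 0, 0))
        dna = np.array([[5.5, 0.0, 0.0]])
        E, Fs, hF = histone_dna_exclusion(h, dna, hist_params)
        assert E == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(Fs, 0.0)

    def test_one_nm_overlap_costs_four_kbt(self, hist_params):
        h = HistoneState.from_axis(center=(0, 0, 0))
        dna = np.array([[4.5, 0.0, 0.0]])
        E, Fs, hF = histone_dna_exclusion(h, dna, hist_params)
        assert E == pytest.approx(0.5 * 8.0 * hist_params.kbt, rel=1e-12)

    def test_force_points_outward(self, hist_params):
        rng = np.random.default_rng(2)
        h = HistoneState.from_axis(center=rng.normal(size=3))
        d = h.center + 3.0 * np.array([0.6, 0.64, 0.48]) / 1.0
        E, Fs, hF = histone_dna_exclusion(h, d[None, :], hist_params)
        outward = (d - h.center) / np.linalg.norm(d - h.center)
        assert np.dot(Fs[0], outward) > 0
        # matches the numerical radial gradient
        R = np.linalg.norm(d - h.center)
        expect = hist_params.exclusion_k * (5.5 - R)
        assert np.linalg.norm(Fs[0]) == pytest.approx(expect, rel=1e-9)


class TestHistoneHistone:
    def test_no_force_beyond_two_radii(self, hist_params):
        h1 = HistoneState.from_axis(center=(0, 0, 0))
        h2 = HistoneState.from_axis(center=(9.5, 0, 0))
        E, F1, F2 = histone_histone_exclusion(h1, h2, hist_params)
        assert E == 0.0 and np.all(F1 == 0.0)

    def test_harmonic_gradient_inside(self, hist_params):
        h1 = HistoneState.from_axis(center=(0, 0, 0))
        h2 = HistoneState.from_axis(center=(8.0, 0, 0))
        E, F1, F2 = histone_histone_exclusion(h1, h2, hist_params)
        k = hist_params.exclusion_k
        assert np.linalg.norm(F1) == pytest.approx(k * 1.0, rel=1e-12)
        assert np.allclose(F1, -F2)
        assert F1[0] < 0  # repulsive


class TestTranslateStep:
    def test_zero_force_no_noise_is_static(self, hist_params):
        h = HistoneState.from_axis(center=(1, 2, 3))
        out = histone_translate_step(h, np.zeros(3), 1e-9, hist_params)
        assert np.allclose(out.center, h.center)

    def test_stokes_drag_drift(self, hist_params):
        # zeta = 6 pi eta |a| = 8.482e-8 pN*s/nm for eta = 1e-3 kg/(m s)
        zeta = 6 * np.pi * 1e-9 * 4.5
        assert hist_params.zeta == pytest.approx(zeta)
        F = np.array([2.0, 0.0, 0.0])
        dt = 1e-9
        out = histone_translate_step(HistoneState.from_axis((0, 0, 0)),
                                     F, dt, hist_params)
        assert out.center[0] == pytest.approx(F[0] * dt / zeta, rel=1e-12)

    def test_free_diffusion_msd(self, hist_params):
        rng = np.random.default_rng(3)
        dt = 1e-9
        nstep, nrep = 150, 300
        disp2 = []
        for _ in range(nrep):
            h = HistoneState.from_axis((0, 0, 0))
            for _ in range(nstep):
                h = histone_translate_step(h, np.zeros(3), dt, hist_params,
                                           rng)
            disp2.append(np.sum(h.center ** 2))
        msd = np.mean(disp2)
        expect = 6.0 * hist_params.kbt / hist_params.zeta * nstep * dt
        assert msd == pytest.approx(expect, rel=0.10)

    def test_non_finite_force_rejected(self, hist_params):
        with pytest.raises(FloatingPointError):
            histone_translate_step(HistoneState.from_axis((0, 0, 0)),
                                   np.array([np.nan, 0, 0]), 1e-9,
                                   hist_params)


class TestRotateStep:
    def test_zero_torque_is_static(self, hist_params):
        h = HistoneState.from_axis((0, 0, 0), axis=(0.6, 0, 0.8), psi=0.4)
        out = histone_rotate_step(h, np.zeros(3), 1e-9, hist_params)
        assert np.allclose(out.axis, h.axis)
        assert out.psi == h.psi

    def test_axial_torque_advances_spin_only(self, hist_params):
        A = np.array([0.6, 0.0, 0.8])
        h = HistoneState.from_axis((0, 0, 0), axis=A)
        T = 3.0 * A
        dt = 1e-9
        out = histone_rotate_step(h, T, dt, hist_params)
        assert np.allclose(out.axis, A, atol=1e-12)
        assert out.psi - h.psi == pytest.approx(3.0 * dt / hist_params.zeta_rot,
                                                rel=1e-9)
        assert np.allclose(out.orientation @ out.orientation.T, np.eye(3),
                           atol=1e-12)

    def test_rotational_diffusion_decay_rate(self, hist_params):
        # <A(t).A(0)> = exp(-2 D_rot t), D_rot = kBT/zeta_rot
        rng = np.random.default_rng(4)
        D = hist_params.kbt / hist_params.zeta_rot
        dt = 0.02 / D          # 50 steps per decay time
        nstep, nrep = 60, 150
        acc = np.zeros(nstep)
        for _ in range(nrep):
            h = HistoneState.from_axis((0, 0, 0))
            A0 = h.axis
            for k in range(nstep):
                h = histone_rotate_step(h, np.zeros(3), dt, hist_params, rng)
                acc[k] += np.dot(h.axis, A0)
        acc /= nrep
        t = dt * np.arange(1, nstep + 1)
        rate = -np.polyfit(t, np.log(np.clip(acc, 1e-3, None)), 1)[0]
        assert rate == pytest.approx(2.0 * D, rel=0.15)


class TestBoltzmannSampling:
    def test_radial_distribution_in_morse_well(self):
        """A free particle diffusing in a single adsorption well samples
        p(r) proportional to r^2 exp(-U(r)/kBT) (KS distance < 5%)."""
        geom = BindingGeometry(np.zeros((1, 3)), 4.5, 0.0, 0.0, 0.0)
        params = HistoneParams(epsilon_kbt=3.0, exclusion_k_kbt=0.0)
        h = HistoneState.from_axis((0, 0, 0), geometry=geom)
        kbt = params.kbt
        D = 1.679e8  # nm^2/s, the DNA-site diffusion constant
        dt = 2.5e-11
        rng = np.random.default_rng(5)
        P = 400
        x = np.tile([[1.0, 0.0, 0.0]], (P, 1))
        samples = []
        for step in range(2500):
            _, Fs, _, _ = morse_energy_forces(h, x, params)
            x = x + D * dt / kbt * Fs + rng.normal(
                0.0, np.sqrt(2 * D * dt), size=x.shape)
            # reflective shell keeps the ensemble inside the well region
            r = np.linalg.norm(x, axis=1)
            over = r > 3.5
            x[over] *= (3.5 / r[over])[:, None]
            if step >= 500 and step % 10 == 0:
                samples.append(np.linalg.norm(x, axis=1))
        r = np.concatenate(samples)
        # exact radial CDF on (0, 3.5]
        grid = np.linspace(1e-3, 3.5, 2000)
        a, d_, e_ = params.morse_alpha, params.morse_delta, params.epsilon
        U = e_ * ((np.exp(-a * (grid - d_)) - 1) ** 2 - 1)
        w = grid ** 2 * np.exp(-U / kbt)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(r), grid) / len(r)
        ks = np.max(np.abs(emp - cdf))
        assert ks < 0.05
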