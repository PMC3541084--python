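"""Dipole forward model: potentials, rod discretization, mirrors, recordings."""

import numpy as np
import pytest

import vfrkit.forward as fwd
from vfrkit.decomposition import compute_weights, solve_alpha_psi
from vfrkit.gating import segment_beats


class TestDipolePotential:
    def test_zero_in_perpendicular_plane(self):
        p = np.array([0.0, 0.0, 1e-5])  # moment along z
        assert fwd.dipole_potential(p, (0, 0, 0), (30.0, 40.0, 0.0)) == pytest.approx(0.0)

    def test_inverse_square_falloff(self):
        p = np.array([0.0, 0.0, 1e-5])
        v1 = fwd.dipole_potential(p, (0, 0, 0), (0.0, 0.0, 100.0))
        v2 = fwd.dipole_potential(p, (0, 0, 0), (0.0, 0.0, 200.0))
        assert v1 / v2 == pytest.approx(4.0, rel=1e-12)

    def test_matches_two_monopole_limit(self):
        # oracle: charges +-q/eps at +-h/2 along z, potential q/(4 pi eps r)
        r_mm, q_over_eps = 50.0, 3.0e-4  # V m
        h_mm = r_mm / 1e6
        moment = np.array([0.0, 0.0, q_over_eps * h_mm * 1e-3])
        direct = fwd.dipole_potential(moment, (0, 0, 0), (0.0, 0.0, r_mm))

        def mono(z_src_mm):
            r = abs(r_mm - z_src_mm) * 1e-3
            return q_over_eps / (4.0 * np.pi * r)

        oracle = mono(h_mm / 2) - mono(-h_mm / 2)
        assert direct == pytest.approx(oracle, rel=1e-5)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError):
            fwd.dipole_potential(np.ones(3), (1, 2, 3), (1, 2, 3))


class TestRodDiscretization:
    def test_zero_change_gives_empty_set(self, model, sources):
        d = fwd.volume_change_to_dipoles(sources[1], 0.0, model)
        assert len(d) == 0

    @pytest.mark.parametrize("n_rods", [4, 8, 16, 32])
    @pytest.mark.parametrize("dv", [10.0, -25.0])
    def test_volume_bookkeeping_exact(self, model, sources, n_rods, dv):
        rods = fwd.volume_change_to_dipoles(sources[1], dv, model, n_rods=n_rods)
        assert fwd.bookkeeping_volume_ml(sources[1], rods, model) == pytest.approx(
            dv, rel=1e-3
        )

    def test_moments_parallel_to_incident_field(self, model, sources):
        rods = fwd.volume_change_to_dipoles(sources[1], 10.0, model, n_rods=6)
        e0 = np.asarray(model.e0_direction)
        cross = np.cross(rods.moments, e0)
        np.testing.assert_allclose(cross, 0.0, atol=1e-20)

    def test_scaling_dv_scales_heights_and_far_field(self, model, sources):
        lam = 3.0
        r1 = fwd.volume_change_to_dipoles(sources[1], 5.0, model, n_rods=8)
        r2 = fwd.volume_change_to_dipoles(sources[1], lam * 5.0, model, n_rods=8)
        np.testing.assert_allclose(r2.positions, r1.positions)  # geometry fixed
        np.testing.assert_allclose(r2.moments, lam * r1.moments, rtol=1e-12)
        pt = np.array([[10.0, 0.0, -400.0]])
        p1 = fwd.dipole_set_potential(r1, pt)[0]
        p2 = fwd.dipole_set_potential(r2, pt)[0]
        assert p2 / p1 == pytest.approx(lam, rel=1e-12)

    def test_richardson_convergence_of_far_field(self, model, sources):
        pt = np.array([[0.0, 0.0, -420.0]])
        vals = [
            fwd.dipole_set_potential(
                fwd.volume_change_to_dipoles(sources[1], 20.0, model, n_rods=n), pt
            )[0]
            for n in (8, 16, 32)
        ]
        # refinement must shrink the increment
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])

    def test_unphysical_volume_rejected(self, model, sources):
        with pytest.raises(ValueError, match="unphysical"):
            fwd.volume_change_to_dipoles(sources[0], -5000.0, model)


class TestSpherePerturbation:
    def test_no_contrast_no_perturbation(self, sources):
        model = fwd.ThoraxModel(sigma_tissue=0.5, sigma_blood=0.5)
        assert fwd.sphere_perturbation_exact(sources[1], model, (0, 60.0, -400.0)) == 0.0

    def test_polar_and_equatorial_surface_ratios(self, model):
        s = fwd.SphereSource(center=(0.0, 0.0, 0.0), volume_ml=100.0, compartment="ventricular")
        R = s.radius_mm
        k = model.sphere_contrast
        pole = fwd.sphere_perturbation_exact(s, model, (0.0, 0.0, R))
        equator = fwd.sphere_perturbation_exact(s, model, (R, 0.0, 0.0))
        assert pole == pytest.approx(2.0 * abs(k), rel=1e-12)
        assert equator == pytest.approx(abs(k), rel=1e-12)

    def test_matches_finite_difference_of_dipole_potential(self, model):
        """Independent check: numerically differentiate the equivalent central
        dipole's potential and compare the field-magnitude ratio."""
        s = fwd.SphereSource(center=(0.0, 0.0, 0.0), volume_ml=100.0, compartment="ventricular")
        dip = fwd._static_equivalent_dipoles(model, [s])
        pt = np.array([35.0, 20.0, 55.0])
        h = 1e-3  # mm
        grad = np.empty(3)
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            grad[i] = (
                fwd.dipole_set_potential(dip, (pt + e)[None, :])[0]
                - fwd.dipole_set_potential(dip, (pt - e)[None, :])[0]
            ) / (2 * h * 1e-3)
        ratio_fd = np.linalg.norm(grad) / model.e0
        ratio = fwd.sphere_perturbation_exact(s, model, pt)
        assert ratio == pytest.approx(ratio_fd, rel=1e-5)

    def test_decays_to_zero_far_away(self, model, sources):
        assert fwd.sphere_perturbation_exact(sources[1], model, (0, 60.0, -5000.0)) < 1e-5

    def test_inside_sphere_rejected(self, model, sources):
        with pytest.raises(ValueError):
            fwd.sphere_perturbation_exact(sources[1], model, sources[1].center)


class TestMirrorSources:
    def test_reflection_geometry(self):
        d = fwd.DipoleSet(positions=[[0.0, 30.0, -100.0]], moments=[[0.0, 0.0, -1e-6]])
        out = fwd.mirror_sources(d, skin_plane_y=0.0)
        assert len(out) == 2
        np.testing.assert_allclose(out.positions[1], [0.0, -30.0, -100.0])
        np.testing.assert_allclose(out.moments[1], [0.0, 0.0, -1e-6])

    def test_normal_moment_component_flips(self):
        d = fwd.DipoleSet(positions=[[0.0, 30.0, 0.0]], moments=[[1e-6, 2e-6, 3e-6]])
        out = fwd.mirror_sources(d, skin_plane_y=0.0)
        np.testing.assert_allclose(out.moments[1], [1e-6, -2e-6, 3e-6])

    def test_disabled_plane_returns_input(self):
        d = fwd.DipoleSet(positions=[[0.0, 30.0, 0.0]], moments=[[0.0, 0.0, 1e-6]])
        assert fwd.mirror_sources(d, skin_plane_y=None) is d

    def test_source_on_plane_rejected(self):
        d = fwd.DipoleSet(positions=[[0.0, 0.0, 0.0]], moments=[[0.0, 0.0, 1e-6]])
        with pytest.raises(ValueError):
            fwd.mirror_sources(d, skin_plane_y=0.0)

    def test_zero_normal_derivative_on_plane(self, model, sources, rng):
        rods = fwd.volume_change_to_dipoles(sources[1], 30.0, model, n_rods=8)
        mirrored = fwd.mirror_sources(rods, skin_plane_y=0.0)
        pts = np.column_stack(
            [
                rng.uniform(-150, 150, 100),
                np.zeros(100),
                rng.uniform(-250, 50, 100),
            ]
        )
        h = 0.5  # mm
        up = pts.copy()
        up[:, 1] += h
        dn = pts.copy()
        dn[:, 1] -= h
        phi_up = fwd.dipole_set_potential(mirrored, up)
        phi_dn = fwd.dipole_set_potential(mirrored, dn)
        scale = np.abs(phi_up) + np.abs(phi_dn) + 1e-30
        assert np.max(np.abs(phi_up - phi_dn) / scale) < 1e-6


class TestWaveform:
    def test_anchored_at_zero_and_dips_to_minus_sv(self):
        f = np.linspace(0, 1, 1000, endpoint=False)
        dv = fwd.ventricular_waveform(f, 75.0)
        assert dv[0] == 0.0
        assert dv.min() == pytest.approx(-75.0, rel=1e-4)
        assert dv[-1] == pytest.approx(0.0, abs=0.05)

    def test_phase_fraction_validation(self):
        with pytest.raises(ValueError):
            fwd.BeatWaveformSpec(phase_fractions=(0.5, 0.5, 0.1, 0.1, 0.1, 0.1))


class TestSimulateRecording:
    def test_same_seed_bit_identical(self, model, sources, layout):
        spec = fwd.BeatWaveformSpec(noise_sd=0.01, respiration_depth=0.02)
        r1 = fwd.simulate_recording(spec, model, sources, layout, n_beats=3, seed=7)
        r2 = fwd.simulate_recording(spec, model, sources, layout, n_beats=3, seed=7)
        assert np.array_equal(r1.phi, r2.phi)
        assert np.array_equal(r1.r_peaks_ms, r2.r_peaks_ms)

    def test_noise_free_closure_recovers_truth(self, model, sources, layout, fingerprints):
        spec = fwd.BeatWaveformSpec(noise_sd=0.0, respiration_depth=0.0, atrial_amplitude_ml=0.0)
        rec = fwd.simulate_recording(spec, model, sources, layout, n_beats=4, seed=1)
        f_a, f_v = fingerprints
        w = compute_weights(f_a, f_v)
        for beat in segment_beats(rec.phi, rec.r_peaks_ms):
            _, psi = solve_alpha_psi(beat.phi_rel, w)
            i0 = int(round(beat.r_peak_ms / 5.0))
            truth = rec.psi_true[i0 : i0 + beat.tau_grid.size]
            assert np.max(np.abs(psi - truth)) <= 1e-6 * max(1.0, np.abs(truth).max())

    def test_doubling_sv_doubles_psi_amplitude(self, model, sources, layout, fingerprints):
        f_a, f_v = fingerprints
        w = compute_weights(f_a, f_v)
        amps = []
        for sv in (60.0, 120.0):
            spec = fwd.BeatWaveformSpec(sv_ml=sv, noise_sd=0.0, respiration_depth=0.0, atrial_amplitude_ml=0.0)
            rec = fwd.simulate_recording(spec, model, sources, layout, n_beats=2, seed=3)
            beat = segment_beats(rec.phi, rec.r_peaks_ms)[0]
            _, psi = solve_alpha_psi(beat.phi_rel, w)
            amps.append(np.abs(psi).max())
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=1e-9)

    def test_relative_change_invariant_to_e0(self, sources, layout):
        spec = fwd.BeatWaveformSpec(noise_sd=0.0, respiration_depth=0.0)
        recs = []
        for e0 in (1.0, 17.0):
            model = fwd.ThoraxModel(e0=e0)
            rec = fwd.simulate_recording(spec, model, sources, layout, n_beats=2, seed=5)
            beat = segment_beats(rec.phi, rec.r_peaks_ms)[0]
            recs.append(beat.phi_rel)
        np.testing.assert_allclose(recs[0], recs[1], rtol=1e-9, atol=1e-15)

    def test_voltage_changes_linear_in_e0(self, sources, layout):
        spec = fwd.BeatWaveformSpec(noise_sd=0.0, respiration_depth=0.0)
        deltas = []
        for e0 in (1.0, 4.0):
            model = fwd.ThoraxModel(e0=e0)
            rec = fwd.simulate_recording(spec, model, sources, layout, n_beats=1, seed=5)
            deltas.append(rec.phi - rec.phi[:, [0]])
        np.testing.assert_allclose(deltas[1], 4.0 * deltas[0], rtol=1e-9, atol=1e-18)


class TestFingerprintExperiment:
    def test_zero_calibration_volume_before_equals_after(self, model, sources):
        grids = fwd.simulate_fingerprint_experiment(
            model, sources[0], sources[1], calib_volume=0.0
        )
        np.testing.assert_array_equal(
            grids["ventric_before"].values, grids["ventric_after"].values
        )

    def test_each_experiment_perturbs_one_compartment(self, model, sources, fingerprint_grids):
        g = fingerprint_grids
        # the two 'before' grids are the same physical baseline
        np.testing.assert_allclose(g["ventric_before"].values, g["atrial_before"].values)
        dv_v = g["ventric_after"].values - g["ventric_before"].values
        dv_a = g["atrial_after"].values - g["atrial_before"].values
        assert np.linalg.norm(dv_v) > 0 and np.linalg.norm(dv_a) > 0
        # the patterns differ: caudally-shifted source, different spatial structure
        cos = np.sum(dv_v * dv_a) / (np.linalg.norm(dv_v) * np.linalg.norm(dv_a))
        assert abs(cos) < 0.9

    def test_ventricular_epicenter_caudal_of_atrial(self, fingerprint_grids):
        from vfrkit.geometry import compute_m_map

        g = fingerprint_grids
        m_v = compute_m_map(g["ventric_before"], g["ventric_after"])
        m_a = compute_m_map(g["atrial_before"], g["atrial_after"])
        (_, z_v), (_, z_a) = m_v.extremum_position(), m_a.extremum_position()
        assert z_v < z_a  # caudal = more negative z
        assert 60.0 <= (z_a - z_v) <= 240.0  # order of the reported ~120 mm
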