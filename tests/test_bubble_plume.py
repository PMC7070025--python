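import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seepflux import bubble_plume as bp
from seepflux import synthetic_data as sd
from conftest import dist_from_radii


class TestEquivalentRadius:
    def test_sphere(self):
        assert bp.equivalent_radius(1000.0, 1000.0) == pytest.approx(1000.0)

    def test_oblate_closed_form(self):
        # r = (a^2 b)^(1/3) = (4e6 * 1e3)^(1/3)
        assert bp.equivalent_radius(2000.0, 1000.0) == pytest.approx(1587.401, rel=1e-5)

    def test_axis_order_violation(self):
        with pytest.raises(ValueError):
            bp.equivalent_radius(1000.0, 2000.0)

    def test_non_positive_axes(self):
        with pytest.raises(ValueError):
            bp.equivalent_radius(1000.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(b=st.floats(1.0, 5000.0), ratio=st.floats(1.0, 3.0))
    def test_radius_between_axes(self, b, ratio):
        a = b * ratio
        r = bp.equivalent_radius(a, b)
        assert b - 1e-9 <= r <= a + 1e-9


class TestVelocityModel:
    @staticmethod
    def _tracks(r, vx):
        return pd.DataFrame({"track_id": np.arange(len(r)), "r": r, "vx": vx,
                             "n_frames": 5})

    def test_constant_model_degree_zero(self):
        tracks = self._tracks(np.linspace(1000, 2000, 10), np.full(10, 10.0))
        model = bp.fit_velocity_model(tracks, degree=0)
        assert model(1500.0) == pytest.approx(10.0)

    def test_linear_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(500, 3000, 200)
        vx = 2.0 + 0.01 * r + rng.normal(0, 0.1, r.size)
        model = bp.fit_velocity_model(self._tracks(r, vx), degree=1)
        assert abs(model.coeffs[0] - 0.01) < 3 * model.coeff_se[0]
        assert abs(model.coeffs[1] - 2.0) < 3 * model.coeff_se[1]

    def test_tilt_projection_halves_velocities(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(500, 3000, 50)
        vx = 5.0 + 0.005 * r
        m0 = bp.fit_velocity_model(self._tracks(r, vx), degree=1, tilt_deg=0.0)
        m60 = bp.fit_velocity_model(self._tracks(r, vx), degree=1, tilt_deg=60.0)
        assert m60(1500.0) == pytest.approx(0.5 * m0(1500.0))

    def test_insufficient_tracks(self):
        with pytest.raises(ValueError, match="at least"):
            bp.fit_velocity_model(self._tracks(np.array([1000.0]),
                                               np.array([10.0])), degree=2)

    def test_refuses_non_positive_fitted_velocity(self):
        r = np.linspace(500, 3000, 20)
        vx = 10.0 - 0.004 * r  # goes negative within range
        with pytest.raises(ValueError, match="non-positive"):
            bp.fit_velocity_model(self._tracks(r, vx), degree=1)


class TestEmissionDistribution:
    def test_multiple_count_correction_arithmetic(self):
        # 1200 detections of 25 cm/s bubbles in a 5 cm fov at 60 fps over
        # 10 s: each bubble is seen 12 times -> 100 bubbles, 10 s^-1
        obs = pd.DataFrame({
            "track_id": np.repeat(np.arange(100), 12),
            "frame": np.tile(np.arange(12), 100),
            "t_s": np.linspace(0, 10, 1200, endpoint=False),
            "x_cm": 1.0, "a_um": 1530.0, "b_um": 1530.0})
        model = bp.VelocityModel(coeffs=np.array([25.0]), degree=0, tilt_deg=0.0,
                                 resid_scale=0.0, r_range=(1400.0, 1600.0))
        dist = bp.emission_distribution(obs, model, fov_height=5.0, fps=60.0,
                                        duration=10.0)
        assert dist.total_rate() == pytest.approx(10.0)

    def test_oracle_equivalence_with_track_counting(self, clean_stream,
                                                    clean_stream_analysis):
        spec, obs = clean_stream
        dist = clean_stream_analysis["distribution"]
        n_tracks = obs["track_id"].nunique()
        emitted = dist.total_rate() * dist.duration
        assert emitted == pytest.approx(n_tracks, rel=0.02)

    def test_zero_detections_gives_zero_phi(self):
        model = bp.VelocityModel(coeffs=np.array([25.0]), degree=0, tilt_deg=0.0,
                                 resid_scale=0.0, r_range=(1000.0, 2000.0))
        dist = bp.emission_distribution(pd.DataFrame(columns=sd.TRACK_COLUMNS),
                                        model, fov_height=5.0, fps=60.0)
        assert np.all(dist.phi == 0)

    def test_radius_outside_model_support_raises(self):
        obs = pd.DataFrame({"track_id": [0, 0], "frame": [0, 1],
                            "t_s": [0.0, 0.1], "x_cm": [0.0, 1.0],
                            "a_um": [3000.0, 3000.0], "b_um": [3000.0, 3000.0]})
        model = bp.VelocityModel(coeffs=np.array([25.0]), degree=0, tilt_deg=0.0,
                                 resid_scale=0.0, r_range=(1000.0, 1200.0))
        with pytest.raises(ValueError, match="outside the velocity model"):
            bp.emission_distribution(obs, model, fov_height=5.0, fps=60.0)

    def test_time_resolved_phi_carries_pulsing_warning(self, clean_stream):
        spec, obs = clean_stream
        tracks = bp.tracks_from_observations(obs)
        model = bp.fit_velocity_model(tracks)
        with pytest.warns(UserWarning, match="30%"):
            dist = bp.emission_distribution(obs, model, fov_height=5.0,
                                            fps=60.0, duration=10.0,
                                            time_window=2.0)
        assert dist.phi_t.shape[0] >= 5
        # detection bookkeeping: summed windowed counts equal the global ones
        np.testing.assert_allclose(dist.phi_t.sum(axis=0) * 2.0,
                                   dist.phi * dist.duration, rtol=1e-9)


class TestFluxIntegration:
    def test_monodisperse_closed_form(self):
        # 87 bubbles/s at r = 1530 um
        edges = np.array([1480.0, 1580.0])
        dist = bp.EmissionSizeDistribution(bin_edges=edges,
                                           phi=np.array([0.87]), duration=1.0)
        fx = bp.integrate_fluxes(dist)
        r_cm = 1530.0e-4
        assert fx.q == pytest.approx(87 * 4 / 3 * np.pi * 1530.0**3 / 1e12)
        assert fx.a == pytest.approx(87 * 4 * np.pi * 1530.0**2 / 1e8)
        assert fx.a_over_q == pytest.approx(3.0 / r_cm)
        assert fx.q == pytest.approx(1.31, abs=0.01)
        assert fx.a == pytest.approx(25.6, abs=0.1)

    def test_zero_distribution(self):
        dist = bp.EmissionSizeDistribution(bin_edges=np.array([0.0, 100.0]),
                                           phi=np.zeros(1), duration=1.0)
        fx = bp.integrate_fluxes(dist)
        assert fx.q == 0 and fx.a == 0 and np.isnan(fx.a_over_q)

    def test_a_over_q_equals_3_over_sauter_radius_for_mixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            edges = np.arange(500.0, 3000.0, 100.0)
            phi = rng.uniform(0, 1, len(edges) - 1)
            dist = bp.EmissionSizeDistribution(bin_edges=edges, phi=phi,
                                               duration=1.0)
            fx = bp.integrate_fluxes(dist)
            assert fx.a_over_q == pytest.approx(3.0 / (dist.sauter_radius() * 1e-4))

    def test_q_conserves_generated_gas_volume(self, clean_stream,
                                              clean_stream_analysis):
        spec, obs = clean_stream
        fx = clean_stream_analysis["fluxes"]
        generated = sd.emitted_gas_volume(obs) / spec.duration
        assert fx.q == pytest.approx(generated, rel=0.05)


class TestModeFitting:
    def test_single_planted_mode_recovered_within_5_percent(self):
        rng = np.random.default_rng(21)
        r = sd.sample_radii_gaussian_mixture([(1530.0, 150.0, 1.0)], 2500, rng)
        fit = bp.fit_modes(dist_from_radii(r))
        assert fit.dominant_mode == pytest.approx(1530.0, rel=0.05)

    def test_two_planted_modes_recovered_with_order(self):
        rng = np.random.default_rng(22)
        r = sd.sample_radii_gaussian_mixture(
            [(1660.0, 150.0, 0.75), (2750.0, 180.0, 0.25)], 4000, rng)
        fit = bp.fit_modes(dist_from_radii(r))
        modes = fit.mode_radii
        assert len(modes) >= 2
        # both planted modes recovered; the heavier one is dominant
        assert min(abs(modes - 1660.0)) < 0.05 * 1660.0
        assert min(abs(modes - 2750.0)) < 0.05 * 2750.0
        assert fit.dominant_mode == pytest.approx(1660.0, rel=0.05)

    def test_power_law_sample_prefers_power_law(self):
        rng = np.random.default_rng(23)
        r = sd.sample_radii_power_law(3000, rng)
        fit = bp.fit_modes(dist_from_radii(r))
        assert fit.power_aicc < fit.gaussian_aicc

    def test_too_few_bins_raises(self):
        dist = bp.EmissionSizeDistribution(
            bin_edges=np.arange(0.0, 500.0, 100.0),
            phi=np.array([1.0, 2.0, 0.0, 0.0]), duration=1.0)
        with pytest.raises(ValueError, match="nonzero bins"):
            bp.fit_modes(dist)


class TestClassification:
    def test_gaussian_stream_classifies_minor(self, clean_stream_analysis):
        assert clean_stream_analysis["fluxes"].classification == "minor"

    def test_power_law_stream_classifies_major(self):
        rng = np.random.default_rng(40)
        r = sd.sample_radii_power_law(2500, rng)
        assert bp.classify_plume(bp.fit_modes(dist_from_radii(r))) == "major"

    def test_tie_breaks_to_minor_with_warning(self):
        fit = bp.ModeFit(gaussian_params=np.array([[1.0, 1500.0, 100.0]]),
                         gaussian_aicc=5.0, power_params=(1.0, 3.0),
                         power_aicc=5.0)
        with pytest.warns(UserWarning, match="tie"):
            assert bp.classify_plume(fit) == "minor"


class TestUpwelling:
    @pytest.mark.parametrize("cleanliness,v_up", [("clean", 1.0),
                                                  ("dirty", 4.0),
                                                  ("clean", 0.0)])
    def test_planted_upwelling_and_cleanliness_recovered(self, cleanliness, v_up):
        spec = sd.StreamSpec(modes=[(1200.0, 120.0, 0.5), (2200.0, 200.0, 0.5)],
                             emission_rate=120.0, duration=8.0,
                             cleanliness=cleanliness, v_up=v_up, seed=17)
        obs = sd.simulate_bubble_stream(spec)
        tracks = bp.tracks_from_observations(obs)
        est_v_up, est_clean = bp.estimate_upwelling(tracks)
        assert est_clean == cleanliness
        assert est_v_up == pytest.approx(v_up, abs=0.3)

    def test_insufficient_radius_spread(self):
        tracks = pd.DataFrame({"track_id": [0, 1], "r": [1500.0, 1510.0],
                               "vx": [25.0, 25.0], "n_frames": [5, 5]})
        with pytest.raises(ValueError, match="radius bins"):
            bp.estimate_upwelling(tracks)


def test_full_vent_pipeline_recovers_planted_stream(clean_stream,
                                                    clean_stream_analysis):
    spec, obs = clean_stream
    res = clean_stream_analysis
    assert res["fluxes"].classification == "minor"
    assert res["fluxes"].cleanliness == "clean"
    assert res["fluxes"].v_up == pytest.approx(1.0, abs=0.3)
    assert res["mode_fit"].dominant_mode == pytest.approx(1530.0, rel=0.05)
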