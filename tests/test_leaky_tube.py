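"""Leaky-tube velocity model and unloading-zone fitting."""

import numpy as np
import pytest

from phloemflow import (
    LeakyTubeParams,
    TubeGeometry,
    VelocityProfile,
    axial_flow_fraction,
    fit_unloading_zone,
    predict_velocity,
    synth_velocity_profile,
    volumetric_flow,
)


class TestPredictVelocity:
    def test_linear_decline_midpoint(self):
        # uniform leak from 350 um to PSE zero: half the velocity at 175 um
        params = LeakyTubeParams(u0_um_s=22.6, zone_start_um=350.0,
                                 zone_length_um=350.0)
        profile = predict_velocity(params, [0.0, 175.0, 350.0, 600.0])
        assert profile.velocities_um_s == pytest.approx([0.0, 11.3, 22.6, 22.6])

    def test_impermeable_limit_constant(self):
        params = LeakyTubeParams(u0_um_s=22.6, zone_start_um=350.0,
                                 zone_length_um=0.0)
        profile = predict_velocity(params, np.linspace(0, 600, 7))
        assert np.all(profile.velocities_um_s == 22.6)

    def test_zone_ending_above_pse_zero(self):
        params = LeakyTubeParams(u0_um_s=20.0, zone_start_um=400.0,
                                 zone_length_um=300.0)
        profile = predict_velocity(params, [0.0, 50.0, 100.0, 250.0, 400.0])
        assert profile.velocities_um_s[0] == 0.0
        assert profile.velocities_um_s[1] == 0.0  # apical of the zone end
        assert profile.velocities_um_s[3] == pytest.approx(10.0)

    def test_total_efflux_matches_tube_flow(self):
        # mass conservation: everything flowing in at the plateau unloads
        params = LeakyTubeParams(u0_um_s=22.6, zone_start_um=350.0,
                                 zone_length_um=350.0)
        tube = TubeGeometry()
        q_in = volumetric_flow(tube)
        frac = axial_flow_fraction(params, [0.0, 350.0])
        efflux = q_in * (frac[1] - frac[0])
        assert efflux == pytest.approx(q_in)

    def test_mass_conservation_pointwise(self):
        # drop in axial flow between any two positions = cumulative leak,
        # which for the uniform law is proportional to the zone overlap
        params = LeakyTubeParams(u0_um_s=22.6, zone_start_um=350.0,
                                 zone_length_um=350.0)
        x = np.linspace(0.0, 600.0, 61)
        frac = axial_flow_fraction(params, x)
        leak_density = 1.0 / 350.0  # fraction of Q per um inside the zone
        inside = np.clip(np.minimum(x, 350.0), 0.0, None)
        expected = inside * leak_density
        assert frac == pytest.approx(expected)

    def test_exponential_leak_law(self):
        params = LeakyTubeParams(u0_um_s=10.0, zone_start_um=350.0,
                                 zone_length_um=100.0)
        profile = predict_velocity(params, [250.0, 350.0, 500.0],
                                   leak_law="exponential")
        assert profile.velocities_um_s[1:] == pytest.approx([10.0, 10.0])
        assert profile.velocities_um_s[0] == pytest.approx(10.0 * np.exp(-1.0))

    def test_invalid_zone_rejected(self):
        with pytest.raises(ValueError, match="zone_start_um"):
            LeakyTubeParams(u0_um_s=10.0, zone_start_um=100.0, zone_length_um=200.0)


class TestVelocityProfileContainer:
    def test_requires_increasing_positions(self):
        with pytest.raises(ValueError, match="increasing"):
            VelocityProfile(np.array([0.0, 0.0, 1.0]), np.zeros(3))

    def test_csv_round_trip(self, tmp_path):
        profile = predict_velocity(LeakyTubeParams(), np.linspace(0, 600, 13))
        path = tmp_path / "profile.csv"
        profile.to_csv(path)
        back = VelocityProfile.from_csv(path)
        assert back.positions_um == pytest.approx(profile.positions_um)
        assert back.velocities_um_s == pytest.approx(profile.velocities_um_s)


class TestFitUnloadingZone:
    truth = LeakyTubeParams(u0_um_s=22.6, zone_start_um=350.0, zone_length_um=350.0)

    def test_exact_recovery_on_noise_free_data(self):
        positions = np.linspace(0.0, 700.0, 29)
        profile = predict_velocity(self.truth, positions)
        fit = fit_unloading_zone(profile, n_boot=0)
        assert not fit.degenerate
        assert fit.params.u0_um_s == pytest.approx(22.6, rel=1e-6)
        assert fit.params.zone_start_um == pytest.approx(350.0, rel=1e-6)
        assert fit.params.zone_length_um == pytest.approx(350.0, rel=1e-6)

    def test_u0_bias_small_on_coarse_grid(self):
        positions = np.linspace(0.0, 700.0, 10)
        fit = fit_unloading_zone(predict_velocity(self.truth, positions), n_boot=0)
        assert abs(fit.params.u0_um_s - 22.6) / 22.6 < 0.02

    def test_constant_profile_flags_degeneracy(self):
        profile = VelocityProfile(np.linspace(0, 500, 8), np.full(8, 22.6))
        fit = fit_unloading_zone(profile, n_boot=0)
        assert fit.degenerate
        assert fit.params.zone_length_um == 0.0
        assert fit.params.u0_um_s == pytest.approx(22.6)

    def test_too_few_points_rejected(self):
        profile = VelocityProfile(np.array([0.0, 100.0, 200.0, 300.0]),
                                  np.array([0.0, 10.0, 20.0, 20.0]))
        with pytest.raises(ValueError, match="at least 5"):
            fit_unloading_zone(profile)

    def test_bootstrap_intervals_cover_truth(self):
        profile = synth_velocity_profile(self.truth, np.linspace(0, 700, 30),
                                         noise_sd_um_s=1.0, seed=7)
        fit = fit_unloading_zone(profile, n_boot=60, seed=3)
        assert set(fit.ci) == {"u0_um_s", "zone_start_um", "zone_length_um"}
        lo, hi = fit.ci["u0_um_s"]
        assert lo < 22.6 * 1.1 and hi > 22.6 * 0.9
        assert lo < hi

    def test_recovery_under_noise(self):
        # smaller companion of the 100-seed study in the acceptance suite
        errs = []
        for seed in range(20):
            profile = synth_velocity_profile(self.truth, np.linspace(0, 700, 30),
                                             noise_sd_um_s=2.0, seed=seed)
            fit = fit_unloading_zone(profile, n_boot=0)
            errs.append(abs(fit.params.zone_start_um - 350.0) / 350.0)
        assert np.median(errs) < 0.10
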