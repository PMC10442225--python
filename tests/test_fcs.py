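import numpy as np
import pytest

from xcdyn.core_io import ValidationError
from xcdyn.fcs import (
    CalibrationFit,
    ConfocalVolume,
    FcsFit,
    FcsModelParams,
    autocorrelation_model,
    calibrate_stack,
    concentration_from_occupancy,
    diffusion_from_tau,
    estimate_confocal_volume,
    fit_fcs_autocorrelation,
    fit_intensity_calibration,
    free_diffusion_coefficient,
    molecule_count,
    summarize_region_concentration,
)
from xcdyn.simulate import SimGeometry, build_geometry, simulate_fcs_curve


def one_component_fit(tau1=25e-6, kappa=5.0, N=1.0):
    return FcsFit(
        params=FcsModelParams(N=N, f1=1.0, tau1=tau1, kappa=kappa),
        residual_rms=0.0,
        n_points=100,
        converged=True,
    )


class TestAutocorrelationFit:
    FIX = ("kappa", "triplet_fraction", "triplet_tau")

    def test_noiseless_two_component_recovery(self):
        truth = FcsModelParams(
            N=4.0, f1=0.65, tau1=30e-6, alpha1=1.0, tau2=4e-3, alpha2=0.9, kappa=5.0
        )
        curve = simulate_fcs_curve(truth, noise_sd=0.0)
        fit = fit_fcs_autocorrelation(
            curve,
            n_components=2,
            fix=self.FIX,
            init=FcsModelParams(N=2.0, f1=0.5, tau1=1e-5, tau2=1e-3, kappa=5.0),
        )
        for name in ("N", "f1", "tau1", "tau2", "alpha1", "alpha2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            )

    def test_one_component_mode_fixes_f1(self):
        truth = FcsModelParams(N=2.0, f1=1.0, tau1=25e-6, kappa=5.0)
        curve = simulate_fcs_curve(truth, noise_sd=0.0, label="dye")
        fit = fit_fcs_autocorrelation(
            curve, n_components=1, fix=self.FIX + ("alpha1",),
            init=FcsModelParams(N=1.0, tau1=1e-5, kappa=5.0),
        )
        assert fit.params.f1 == 1.0
        assert fit.params.tau1 == pytest.approx(25e-6, rel=1e-6)
        assert fit.params.N == pytest.approx(2.0, rel=1e-6)

    def test_dye_label_truncates_lag_range(self):
        truth = FcsModelParams(N=2.0, f1=1.0, tau1=25e-6, kappa=5.0)
        curve = simulate_fcs_curve(truth, noise_sd=0.0, label="dye")
        fit = fit_fcs_autocorrelation(curve, n_components=1, fix=self.FIX)
        assert fit.n_points == int((curve.lag <= 10239e-6).sum())

    def test_triplet_free_data_sends_triplet_to_zero(self):
        truth = FcsModelParams(N=3.0, f1=1.0, tau1=30e-6, kappa=5.0)
        curve = simulate_fcs_curve(truth, noise_sd=0.0)
        fit = fit_fcs_autocorrelation(
            curve, n_components=1, fix=("kappa", "alpha1"),
            init=FcsModelParams(N=1.0, tau1=1e-5, kappa=5.0, triplet_fraction=0.1,
                                triplet_tau=5e-6),
        )
        assert fit.params.triplet_fraction == pytest.approx(0.0, abs=0.02)

    def test_amplitude_matches_inverse_occupancy(self):
        truth = FcsModelParams(N=5.0, f1=1.0, tau1=30e-6, kappa=5.0)
        curve = simulate_fcs_curve(truth, noise_sd=0.0)
        fit = fit_fcs_autocorrelation(curve, n_components=1, fix=self.FIX + ("alpha1",))
        # smallest simulated lag is 1 μs, where G has already decayed by
        # (lag/tau1)^alpha ≈ 3%; the fitted amplitude sits just above it
        assert 1.0 / fit.params.N == pytest.approx(float(curve.G[0]), rel=0.05)
        assert 1.0 / fit.params.N >= float(curve.G[0])

    def test_short_curve_rejected(self):
        truth = FcsModelParams(N=2.0)
        curve = simulate_fcs_curve(truth, noise_sd=0.0, n_lags=5)
        with pytest.raises(ValidationError):
            fit_fcs_autocorrelation(curve)


class TestConfocalVolume:
    def test_printed_example_values(self):
        vol = estimate_confocal_volume([one_component_fit()], d_dye=521.46)
        assert vol.w0 == pytest.approx(0.2284, abs=5e-4)
        assert vol.volume == pytest.approx(0.3316, abs=5e-4)

    def test_volume_identity_holds_exactly(self):
        vol = estimate_confocal_volume([one_component_fit()])
        assert vol.volume == np.pi**1.5 * vol.kappa * vol.w0**3

    def test_two_identical_fits_average_to_single_value(self):
        single = estimate_confocal_volume([one_component_fit()])
        double = estimate_confocal_volume([one_component_fit(), one_component_fit()])
        assert double.w0 == single.w0
        assert double.volume == single.volume

    def test_empty_or_degenerate_input_rejected(self):
        with pytest.raises(ValidationError):
            estimate_confocal_volume([])
        with pytest.raises(ValidationError):
            estimate_confocal_volume([one_component_fit(tau1=0.0)])

    def test_diffusion_round_trip_is_identity(self):
        # w0 from a known D and tau, then back: D = (w0/2)^2 / tau exactly
        vol = estimate_confocal_volume([one_component_fit(tau1=25e-6)], d_dye=521.46)
        assert diffusion_from_tau(vol, 25e-6) == pytest.approx(521.46, rel=1e-12)

    def test_diffusion_inverse_in_tau(self):
        vol = estimate_confocal_volume([one_component_fit()])
        assert diffusion_from_tau(vol, 50e-6) == pytest.approx(
            diffusion_from_tau(vol, 25e-6) / 2
        )

    def test_free_component_uses_smallest_tau(self):
        vol = estimate_confocal_volume([one_component_fit()])
        fit = FcsFit(
            params=FcsModelParams(N=1, f1=0.6, tau1=4e-3, tau2=3e-5),
            residual_rms=0.0, n_points=50, converged=True,
        )
        assert free_diffusion_coefficient(vol, fit) == diffusion_from_tau(vol, 3e-5)

    def test_nonpositive_tau_rejected(self):
        vol = estimate_confocal_volume([one_component_fit()])
        with pytest.raises(ValidationError):
            diffusion_from_tau(vol, 0.0)

    def test_occupancy_to_concentration(self):
        vol = ConfocalVolume(w0=0.2284, kappa=5.0, d_dye=521.46)
        # N=1 in 0.3316 fL → 1/(N_A·0.3316e-15 L) mol/L ≈ 5.0 nM
        assert concentration_from_occupancy(vol, 1.0) == pytest.approx(5.0, rel=0.01)


class TestIntensityCalibration:
    def test_noiseless_line_recovered_exactly(self):
        rng = np.random.default_rng(0)
        I = rng.uniform(20, 200, 50)
        C = 2.0 * (I - 10.0) + 5.0
        fit = fit_intensity_calibration(I, C, np.full(10, 10.0))
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_concentration_gives_zero_slope(self):
        I = np.array([20.0, 50.0, 90.0])
        fit = fit_intensity_calibration(I, np.full(3, 42.0), np.array([10.0]))
        assert fit.slope == 0.0
        assert fit.intercept == 42.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        I = rng.uniform(20, 200, 30)
        C = 1.5 * (I - 8.0) + 3.0 + rng.normal(0, 5, 30)
        perm = rng.permutation(30)
        a = fit_intensity_calibration(I, C, np.array([8.0]))
        b = fit_intensity_calibration(I[perm], C[perm], np.array([8.0]))
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)

    def test_affine_equivariance_of_inferred_concentrations(self):
        # scaling intensities and background by c rescales a by 1/c and
        # leaves inferred concentrations unchanged
        rng = np.random.default_rng(2)
        I = rng.uniform(20, 200, 40)
        C = 2.0 * (I - 10.0) + 5.0 + rng.normal(0, 3, 40)
        neg = np.full(5, 10.0)
        fit1 = fit_intensity_calibration(I, C, neg)
        fit3 = fit_intensity_calibration(3 * I, C, 3 * neg)
        assert fit3.slope == pytest.approx(fit1.slope / 3)
        stack = rng.uniform(20, 200, (2, 4, 4))
        c1 = calibrate_stack(stack, fit1, 0.1, 0.5).concentrations
        c3 = calibrate_stack(3 * stack, fit3, 0.1, 0.5).concentrations
        np.testing.assert_allclose(c1, c3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_intensity_calibration(np.array([1.0]), np.array([2.0]), np.array([0.0]))

    def test_zero_intensity_variance_rejected(self):
        with pytest.raises(ValidationError):
            fit_intensity_calibration(
                np.full(5, 50.0), np.linspace(1, 5, 5), np.array([10.0])
            )

    def test_calibration_unbiased_across_noisy_replicates(self):
        # intensity noise at 2% of the mean; residual attenuation bias of
        # the regression is second order (σ²/var(I) ≈ 0.2%)
        errs_a, errs_b = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            I = rng.uniform(20, 200, 200)
            C = 2.0 * (I - 10.0) + 5.0
            I_noisy = I + rng.normal(0, 0.02 * I.mean(), I.size)
            fit = fit_intensity_calibration(I_noisy, C, np.full(20, 10.0))
            errs_a.append(fit.slope - 2.0)
            errs_b.append(fit.intercept - 5.0)
        assert abs(np.mean(errs_a)) / 2.0 < 0.01
        assert abs(np.mean(errs_b)) < 2.0


class TestCalibrateStack:
    FIT = CalibrationFit(slope=2.0, intercept=5.0, background=10.0, r_squared=1.0, n_points=10)

    def test_direct_formula(self):
        out = calibrate_stack(np.full((1, 2, 2), 110.0), self.FIT, 0.0991, 0.48)
        np.testing.assert_allclose(out.concentrations, 205.0)

    def test_background_intensity_maps_to_intercept(self):
        out = calibrate_stack(np.full((1, 2, 2), 10.0), self.FIT, 0.0991, 0.48)
        np.testing.assert_allclose(out.concentrations, 5.0)

    def test_invalid_voxel_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_stack(np.zeros((1, 2, 2)), self.FIT, 0.0991, 0.0)


class TestRegionConcentration:
    def test_uniform_region_matches_closed_form_count(self):
        # 207 nM over 9.34 μm³ → 1164 molecules
        assert molecule_count(207.0, 9.34) == pytest.approx(1164.3, abs=0.5)

    def _maskset_and_conc(self, value=207.0):
        geom = SimGeometry(shape=(64, 64), nucleus_semiaxes=(3.0, 2.5), xc_radius=1.0)
        masks = build_geometry(geom)
        conc = calibrate_stack(
            np.full(masks.shape, (value - 5.0) / 2.0 + 10.0),
            CalibrationFit(2.0, 5.0, 10.0, 1.0, 10),
            geom.pixel_size,
            0.48,
        )
        return masks, conc

    def test_uniform_concentration_summary(self):
        masks, conc = self._maskset_and_conc(207.0)
        out = summarize_region_concentration(conc, masks)
        xc = out["xc"]
        assert xc.mean_nM == pytest.approx(207.0)
        assert xc.volume_um3 == pytest.approx(xc.n_voxels * conc.voxel_volume)
        assert xc.n_molecules == pytest.approx(molecule_count(207.0, xc.volume_um3))
        assert xc.ci95_nM == pytest.approx(0.0, abs=1e-12)

    def test_zero_concentration_zero_molecules(self):
        masks, conc = self._maskset_and_conc(0.0)
        out = summarize_region_concentration(conc, masks)
        assert out["xc"].n_molecules == pytest.approx(0.0)

    def test_counts_additive_over_disjoint_regions(self):
        masks, conc = self._maskset_and_conc(100.0)
        out = summarize_region_concentration(conc, masks)
        total = out["xc"].n_molecules + out["nucleoplasm"].n_molecules
        union_volume = (masks.xc.sum() + masks.nucleoplasm.sum()) * conc.voxel_volume
        assert total == pytest.approx(molecule_count(100.0, union_volume))

    def test_empty_region_flagged(self):
        masks, conc = self._maskset_and_conc()
        assert masks.nucleoli.sum() == 0
        out = summarize_region_concentration(conc, masks)
        assert np.isnan(out["nucleoli"].mean_nM)
        assert out["nucleoli"].n_voxels == 0
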