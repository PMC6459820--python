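"""Multi-component autocorrelation model: evaluation, fitting, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cytofcs as c
from cytofcs.acf import MultiComponentACFModel, acf_components
from cytofcs.errors import CalibrationError
from cytofcs.simulate import multitau_lag_grid


def single_component_spec(kappa=5.0, **kw):
    return c.ACFModelSpec(components=(c.ACFComponentSpec(**kw),), kappa=kappa)


class TestModelEvaluation:
    def test_zero_lag_limit_is_sum_of_amplitudes_over_N(self):
        spec = single_component_spec(amplitude=1.0, tau_d_s=1e-3)
        g = c.model_acf(np.array([1e-9]), spec, N=10.0)
        assert g[0] == pytest.approx(0.1, rel=1e-5)

    def test_value_at_tau_d(self):
        # single component, N=1, alpha=1, kappa=5, tau = tau_D -> 0.5/sqrt(1.04)
        spec = single_component_spec(amplitude=1.0, tau_d_s=2e-3)
        g = c.model_acf(np.array([2e-3]), spec, N=1.0)
        assert g[0] == pytest.approx(0.4903, abs=1e-4)

    def test_linear_in_amplitudes(self):
        lags = multitau_lag_grid(1e-6, 12, 8)
        two = c.ACFModelSpec(
            components=(c.ACFComponentSpec(amplitude=0.5, tau_d_s=1e-3),
                        c.ACFComponentSpec(amplitude=0.5, tau_d_s=1e-3)),
            kappa=5.0)
        one = single_component_spec(amplitude=1.0, tau_d_s=1e-3)
        np.testing.assert_allclose(c.model_acf(lags, two, 5.0),
                                   c.model_acf(lags, one, 5.0), rtol=1e-12)

    def test_positive_and_decaying(self):
        lags = multitau_lag_grid(1e-6, 20, 16)
        spec = single_component_spec(amplitude=1.0, tau_d_s=5e-4)
        g = c.model_acf(lags, spec, N=3.0)
        assert np.all(g > 0)
        assert np.all(np.diff(g) < 0)
        assert g[-1] < 1e-3 * g[0]

    def test_triplet_factor_raises_short_lags(self):
        lags = np.array([1e-7, 1.0])
        base = single_component_spec(amplitude=1.0, tau_d_s=1e-3)
        with_t = c.ACFModelSpec(
            components=base.components, kappa=5.0,
            triplet=c.TripletSpec(fraction=0.2, tau_s=2e-4))
        g0 = c.model_acf(lags, base, 1.0)
        g1 = c.model_acf(lags, with_t, 1.0)
        assert g1[0] / g0[0] == pytest.approx(1.0 + 0.2 / 0.8, rel=1e-3)

    def test_out_of_bounds_parameters_rejected(self):
        spec = single_component_spec()
        with pytest.raises(ValueError):
            c.model_acf(np.array([1e-3]), spec, N=10.0,
                        values={"amp0": 1.0, "tau0": -1e-3, "alpha0": 1.0})
        with pytest.raises(ValueError):
            c.model_acf(np.array([1e-3]), spec, N=-1.0,
                        values={"amp0": 1.0, "tau0": 1e-3, "alpha0": 1.0})
        free_alpha = single_component_spec(alpha=None)
        with pytest.raises(ValueError):
            c.model_acf(np.array([1e-3]), free_alpha, N=10.0,
                        values={"amp0": 1.0, "tau0": 1e-3, "alpha0": 1.5})


class TestFitting:
    @settings(max_examples=12)
    @given(
        n_comp=st.integers(1, 3),
        log_tau0=st.floats(-4.0, -2.5),
        ratio=st.floats(0.6, 1.4),
        frac=st.floats(0.15, 0.85),
        n_mol=st.floats(0.5, 50.0),
    )
    def test_zero_noise_identity(self, n_comp, log_tau0, ratio, frac, n_mol):
        """fit_acf on data generated by model_acf recovers the truth exactly."""
        taus = [10 ** (log_tau0 + i * ratio) for i in range(n_comp)]
        if n_comp == 1:
            amps = [1.0]
        elif n_comp == 2:
            amps = [frac, 1 - frac]
        else:
            amps = [frac / 2, frac / 2, 1 - frac]
        lags = multitau_lag_grid(2e-6, 22, 16)
        spec = c.ACFModelSpec(
            components=tuple(c.ACFComponentSpec(tau_d_init=t * 2) for t in taus),
            kappa=5.0)
        values = {}
        for i, (a, t) in enumerate(zip(amps, taus)):
            values[f"amp{i}"] = a
            values[f"tau{i}"] = t
        g = c.model_acf(lags, spec, N=n_mol, values=values)
        res = c.fit_acf(c.AutocorrelationCurve(lags, g), spec)
        assert res.N == pytest.approx(n_mol, rel=1e-4)
        # components may come out permuted; compare as amplitude-weighted sets
        order = np.argsort(res.tau_ds_s)
        true_order = np.argsort(taus)
        np.testing.assert_allclose(res.tau_ds_s[order],
                                   np.asarray(taus)[true_order], rtol=1e-3)
        np.testing.assert_allclose(res.amplitudes[order],
                                   np.asarray(amps)[true_order], atol=1e-4)

    def test_two_component_recovery_under_noise(self):
        """A 3:1 tau-ratio pair with both times free: precise at low noise,
        unbiased (if dispersed) at higher noise — Monte-Carlo calibrated."""
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(tau_d_init=1e-3),
                        c.ACFComponentSpec(tau_d_init=2e-3)),
            kappa=5.0)
        truth = {"amp0": 0.7, "amp1": 0.3, "tau0": 1e-3, "tau1": 3e-3}
        lags = multitau_lag_grid()
        g_true = c.model_acf(lags, spec, 10.0, truth)
        for noise_frac, sd_limit in ((0.001, 0.05), (0.01, None)):
            errs = []
            for seed in range(30):
                curve = c.analytic_curve_with_noise(
                    spec, N=10.0, noise_sd=noise_frac * g_true / g_true[0],
                    seed=seed, values=truth, lags=lags)
                res = c.fit_acf(curve, spec)
                order = np.argsort(res.tau_ds_s)
                errs.append(res.amplitudes[order] - np.array([0.7, 0.3]))
            errs = np.asarray(errs)
            assert np.all(np.abs(errs.mean(axis=0)) < 0.05)  # unbiased
            if sd_limit is not None:
                assert errs.std(axis=0)[0] < sd_limit

    def test_amplitudes_always_sum_to_one(self):
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(tau_d_init=5e-4),
                        c.ACFComponentSpec(tau_d_init=5e-2)),
            kappa=5.0)
        curve = c.analytic_curve_with_noise(
            spec, N=5.0, noise_sd=0.02, seed=3,
            values={"amp0": 0.8, "amp1": 0.2, "tau0": 1e-3, "tau1": 4e-2})
        res = c.fit_acf(c.AutocorrelationCurve(curve.lags, curve.G), spec)
        assert np.sum(res.amplitudes) == pytest.approx(1.0, abs=1e-9)

    def test_fixed_parameters_pass_through_unchanged(self):
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(tau_d_s=1.7e-3),
                        c.ACFComponentSpec(amplitude=0.25, tau_d_init=5e-2)),
            kappa=5.0)
        curve = c.analytic_curve_with_noise(
            spec, N=8.0, noise_sd=0.01, seed=11,
            values={"amp0": 0.75, "tau1": 6e-2})
        res = c.fit_acf(c.AutocorrelationCurve(curve.lags, curve.G), spec)
        assert res.tau_ds_s[0] == 1.7e-3
        assert res.amplitudes[1] == pytest.approx(0.25, abs=1e-12)

    def test_triplet_time_bounds_are_hard(self):
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(tau_d_init=1e-3),),
            kappa=5.0, triplet=c.TripletSpec())
        truth = {"amp0": 1.0, "tau0": 1.5e-3,
                 "triplet_fraction": 0.15, "triplet_tau": 2e-4}
        for seed in range(5):
            curve = c.analytic_curve_with_noise(spec, N=4.0, noise_sd=0.01,
                                                seed=seed, values=truth)
            res = c.fit_acf(c.AutocorrelationCurve(curve.lags, curve.G), spec)
            assert 1e-4 <= res.triplet_tau_s <= 3e-4
            assert 0.0 <= res.triplet_fraction < 1.0

    def test_short_curve_rejected(self):
        spec = single_component_spec(tau_d_init=1e-3)
        lags = np.geomspace(1e-6, 1e-1, 10)
        g = np.exp(-lags)
        with pytest.raises(ValueError):
            c.fit_acf(c.AutocorrelationCurve(lags, g), spec)

    def test_fixed_tau_outside_lag_range_warns_in_result(self):
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(tau_d_s=1e3),), kappa=5.0)
        lags = multitau_lag_grid(1e-6, 14, 16)
        g = c.model_acf(lags, single_component_spec(amplitude=1.0, tau_d_s=1e-3), 5.0)
        res = c.fit_acf(c.AutocorrelationCurve(lags, g), spec)
        assert any("outside the lag range" in w for w in res.warnings)

    def test_estimator_sklearn_contract(self):
        spec = single_component_spec(tau_d_init=1e-3)
        est = MultiComponentACFModel(spec=spec)
        assert est.get_params()["spec"] is spec
        lags = multitau_lag_grid(2e-6, 18, 16)
        g = c.model_acf(lags, single_component_spec(amplitude=1.0, tau_d_s=1e-3), 7.0)
        est.fit(lags, g)
        assert est.result_.N == pytest.approx(7.0, rel=1e-5)
        np.testing.assert_allclose(est.predict(lags), g, rtol=1e-5)


class TestCalibration:
    def make_dye_curve(self, tau_d, kappa, N=2.0, noise=0.0, seed=0):
        lags = multitau_lag_grid(1e-6, 16, 16)
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(amplitude=1.0, tau_d_s=tau_d),),
            kappa=kappa)
        if noise > 0:
            return c.analytic_curve_with_noise(spec, N, noise, seed, lags=lags)
        return c.AutocorrelationCurve(lags, c.model_acf(lags, spec, N))

    def test_reference_dye_waist(self):
        # tau_D = 25 us with D_ref = 400 um^2/s -> w_xy = 0.2 um
        curve = self.make_dye_curve(2.5e-5, 5.0)
        fv = c.calibrate_focal_volume(curve, D_ref_um2s=400.0)
        assert fv.w_xy_um == pytest.approx(0.2, rel=1e-4)
        assert fv.kappa == pytest.approx(5.0, rel=1e-3)

    def test_effective_volume_formula(self):
        fv = c.FocalVolume(w_xy_um=0.3, kappa=5.0)
        assert fv.V_eff_fL == pytest.approx(np.pi**1.5 * 0.027 * 5.0, rel=1e-12)
        assert fv.V_eff_fL == pytest.approx(0.752, abs=5e-4)

    def test_waist_scales_with_sqrt_of_reference_D(self):
        curve = self.make_dye_curve(2.5e-5, 5.0)
        fv1 = c.calibrate_focal_volume(curve, D_ref_um2s=400.0)
        fv2 = c.calibrate_focal_volume(curve, D_ref_um2s=800.0)
        assert fv2.w_xy_um == pytest.approx(np.sqrt(2) * fv1.w_xy_um, rel=1e-6)

    def test_poor_single_component_fit_rejected(self):
        # strongly two-component data cannot calibrate
        lags = multitau_lag_grid(1e-6, 18, 16)
        spec = c.ACFModelSpec(
            components=(c.ACFComponentSpec(amplitude=0.5, tau_d_s=2e-5),
                        c.ACFComponentSpec(amplitude=0.5, tau_d_s=2e-2)),
            kappa=5.0)
        curve = c.AutocorrelationCurve(lags, c.model_acf(lags, spec, 2.0))
        with pytest.raises(CalibrationError):
            c.calibrate_focal_volume(curve, D_ref_um2s=400.0)

    def test_volume_consistency_enforced(self):
        with pytest.raises(ValueError):
            c.FocalVolume(w_xy_um=0.3, kappa=5.0, V_eff_fL=1.0)


class TestConversions:
    def test_tau_to_diffusion_reference(self, focal_volume):
        assert c.tau_to_diffusion(1.49e-3, focal_volume) == pytest.approx(15.1, abs=0.01)

    def test_tau_diffusion_round_trip(self, focal_volume):
        for d in (0.5, 5.7, 9.1, 15.1, 400.0):
            tau = c.diffusion_to_tau(d, focal_volume)
            assert c.tau_to_diffusion(tau, focal_volume) == pytest.approx(d, rel=1e-12)

    def test_diffusion_vanishes_for_infinite_tau(self, focal_volume):
        assert c.tau_to_diffusion(1e12, focal_volume) < 1e-10
        with pytest.raises(ValueError):
            c.tau_to_diffusion(0.0, focal_volume)

    def test_concentration_avogadro_anchor(self):
        fv = c.FocalVolume(w_xy_um=(1.0 / (np.pi**1.5 * 5.0)) ** (1 / 3), kappa=5.0)
        assert fv.V_eff_fL == pytest.approx(1.0, rel=1e-9)
        assert c.concentration_from_N(6.022, fv) == pytest.approx(10.0, abs=0.01)
        assert c.concentration_from_N(0.0, fv) == 0.0
        assert c.concentration_from_N(12.044, fv) == pytest.approx(20.0, abs=0.02)

    def test_molecular_brightness(self):
        assert c.molecular_brightness(50_000.0, 10.0) == pytest.approx(5_000.0)
        with pytest.raises(ValueError):
            c.molecular_brightness(50_000.0, 0.0)


class TestCurveContainer:
    def test_rejects_bad_lags(self):
        with pytest.raises(ValueError):
            c.AutocorrelationCurve(np.array([1e-3, 1e-3]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            c.AutocorrelationCurve(np.array([0.0, 1e-3]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            c.AutocorrelationCurve(np.array([1e-3]), np.array([1.0, 2.0]))

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            c.AutocorrelationCurve(np.array([1e-3, 2e-3]), np.array([1.0, 0.5]),
                                   weights=np.array([1.0, -1.0]))
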