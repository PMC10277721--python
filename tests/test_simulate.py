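"""Synthetic-data generator: covariates, person effects, panel paths,
missingness mechanisms and determinism."""

import numpy as np
import pytest

import dsempanel as dp
from dsempanel.model import DsemSpec
from dsempanel.simulate import (
    DEFAULT_PREVALENCES,
    GeneratorConfig,
    draw_covariates,
    draw_person_effects,
    inject_missingness,
    simulate_panel,
)


class TestDrawCovariates:
    def test_zero_prevalence_gives_zeros(self):
        cov = draw_covariates(200, {"bd2": 0.0, "female": 0.0, "age55": 0.0, "rapid": 0.0},
                              seed=1)
        assert (cov.to_numpy() == 0).all()

    def test_bd2_prevalence_matches_cohort_fraction(self):
        cov = draw_covariates(10_000, DEFAULT_PREVALENCES, seed=2)
        assert cov["bd2"].mean() == pytest.approx(0.384, abs=0.02)
        assert cov["female"].mean() == pytest.approx(0.68, abs=0.02)

    def test_same_seed_identical(self):
        a = draw_covariates(50, DEFAULT_PREVALENCES, seed=9)
        b = draw_covariates(50, DEFAULT_PREVALENCES, seed=9)
        assert a.equals(b)


class TestDrawPersonEffects:
    def test_degenerate_omega_returns_gamma(self):
        spec = dp.calibrated_spec(("dep",))
        degenerate = DsemSpec(spec.processes, spec.gamma, np.zeros_like(spec.omega))
        eta, n_redraws = draw_person_effects(degenerate, 20, seed=0)
        assert eta == pytest.approx(np.tile(spec.gamma, (20, 1)))
        assert n_redraws == 0

    def test_sample_covariance_approaches_omega(self):
        spec = dp.calibrated_spec(("dep",))
        eta, _ = draw_person_effects(spec, 5000, seed=3)
        emp = np.cov(eta.T)
        sd = np.sqrt(np.diag(spec.omega))
        scale = np.outer(sd, sd) + 1e-12
        assert np.abs((emp - spec.omega) / scale).max() < 0.1

    def test_covariate_coefficient_shifts_group_mean(self):
        spec = dp.calibrated_spec(("dep",))
        B = np.zeros((4, 4))
        B[spec.idx("mu_dep"), 0] = 2.0  # bd2 raises the depression mean
        spec = DsemSpec(spec.processes, spec.gamma, spec.omega, B=B)
        cov = draw_covariates(4000, DEFAULT_PREVALENCES, seed=4)
        eta, _ = draw_person_effects(spec, cov, seed=4)
        mu = eta[:, spec.idx("mu_dep")]
        grp = cov["bd2"].to_numpy()
        assert (mu[grp == 1].mean() - mu[grp == 0].mean()) == pytest.approx(2.0, abs=0.3)

    def test_hopelessly_non_stationary_spec_rejected(self):
        spec = dp.calibrated_spec(("dep",))
        gamma = spec.gamma.copy()
        gamma[spec.idx("phi_dep_dep")] = 0.995
        omega = spec.omega.copy()
        omega[1, 1] = 1.0  # most draws explosive
        with pytest.raises(ValueError, match="rejection rate"):
            draw_person_effects(DsemSpec(spec.processes, gamma, omega), 200, seed=5)


class TestSimulatePanel:
    def test_noiseless_panel_is_constant_at_the_mean(self):
        spec = dp.calibrated_spec(("dep",))
        gamma = spec.gamma.copy()
        gamma[spec.idx("phi_dep_dep")] = 0.0
        gamma[spec.idx("logv_dep")] = -40.0  # innovation variance ~ 0
        gamma[spec.idx("slope_dep")] = 0.0
        spec = DsemSpec(spec.processes, gamma, np.zeros_like(spec.omega))
        panel, _ = simulate_panel(GeneratorConfig(spec=spec, n=5, n_weeks=20, seed=6))
        assert panel.data["dep"].to_numpy() == pytest.approx(7.33, abs=1e-6)

    def test_empirical_variance_matches_stationary_oracle(self):
        spec = dp.calibrated_spec(("dep",))
        spec = DsemSpec(spec.processes, spec.gamma, np.zeros_like(spec.omega))
        panel, truth = simulate_panel(GeneratorConfig(spec=spec, n=2, n_weeks=20_000, seed=7))
        eff = dp.PersonEffects.from_vector(truth["effects"][0], 1)
        target = dp.stationary_covariance(eff.phi, eff.innovation)[0, 0]
        arr = panel.to_arrays(("dep",))[0, :, 0]
        weeks = np.arange(1, len(arr) + 1)
        detrended = arr - eff.mu[0] - eff.slope[0] * (weeks - (len(arr) + 1) / 2)
        assert detrended.var() == pytest.approx(target, rel=0.05)

    def test_grand_mean_tracks_fixed_effect(self):
        spec = dp.calibrated_spec(("dep",))
        panel, _ = simulate_panel(GeneratorConfig(spec=spec, n=1000, n_weeks=91, seed=8))
        se = np.sqrt(21.10 / 1000)
        assert np.nanmean(panel.data["dep"]) == pytest.approx(7.33, abs=4 * se)

    def test_determinism_bit_exact(self):
        cfg = GeneratorConfig(spec=dp.calibrated_spec(("hypo", "ins")), n=20,
                              n_weeks=30, seed=9)
        a, _ = simulate_panel(cfg)
        b, _ = simulate_panel(cfg)
        assert a.data.equals(b.data)
        assert a.covariates.equals(b.covariates)

    def test_discretise_respects_scale_bounds_and_mask(self):
        cfg = GeneratorConfig(spec=dp.calibrated_spec(("dep", "ins")), n=100,
                              n_weeks=60, seed=10, discretise=True,
                              missingness="mcar", missing_rate=0.2)
        panel, _ = simulate_panel(cfg)
        dep = panel.data["dep"].dropna()
        ins = panel.data["ins"].dropna()
        assert dep.between(0, 27).all() and (dep == dep.round()).all()
        assert ins.between(0, 9).all() and (ins == ins.round()).all()


class TestInjectMissingness:
    def _panel(self, seed=11, n=400, T=60):
        cfg = GeneratorConfig(spec=dp.calibrated_spec(("dep",)), n=n, n_weeks=T, seed=seed)
        return simulate_panel(cfg)[0]

    def test_rate_zero_unchanged(self):
        panel = self._panel()
        out = inject_missingness(panel, "mcar", 0.0, seed=1)
        assert out.data.equals(panel.data)

    def test_mcar_rate_matches(self):
        panel = self._panel()
        out = inject_missingness(panel, "mcar", 0.2, seed=2, outcomes=["dep"])
        frac = out.data["dep"].isna().mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_mar_logistic_slope_recovered(self):
        import statsmodels.api as sm

        panel = self._panel(n=600, T=80)
        slope = 0.25
        out = inject_missingness(panel, "mar", 0.25, seed=3, outcomes=["dep"],
                                 mar_slope=slope)
        arr_obs = out.to_arrays(("dep",))[:, :, 0]
        arr_orig = panel.to_arrays(("dep",))[:, :, 0]
        n, T = arr_obs.shape
        # reconstruct the predictor: last observed value before each week
        ys, ms = [], []
        for i in range(n):
            last = arr_obs[i, 0] if not np.isnan(arr_obs[i, 0]) else np.nanmean(arr_obs)
            for t in range(1, T):
                ms.append(np.isnan(arr_obs[i, t]))
                ys.append(last)
                if not np.isnan(arr_obs[i, t]):
                    last = arr_obs[i, t]
        fit = sm.Logit(np.asarray(ms, dtype=float), sm.add_constant(np.asarray(ys))).fit(disp=0)
        assert fit.params[1] == pytest.approx(slope, abs=0.05)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError, match="mechanism"):
            inject_missingness(self._panel(), "nmar", 0.2)


def test_calibration_hits_target_standardised_effect():
    spec = dp.calibrated_spec(("dep", "ins"))
    cal = dp.calibrate_cross_lag(spec, ("ins", "dep"), 0.065, n_mc=40_000, seed=12)
    implied = dp.implied_average_standardised(cal, n_mc=40_000, seed=12)
    assert implied[1, 0] == pytest.approx(0.065, abs=1e-4)


def test_config_validation_errors():
    spec = dp.calibrated_spec(("dep",))
    with pytest.raises(ValueError):
        GeneratorConfig(spec=spec, n=1).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(spec=spec, missing_rate=1.5).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(spec=spec, prevalences={"bd2": 2.0}).validate()
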