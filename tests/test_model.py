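"""Core model mathematics: equations, stationary covariance, and
per-person standardisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dsempanel as dp
from dsempanel.model import (
    DsemSpec,
    NonStationaryError,
    PersonEffects,
    effect_names,
    grid_midpoint,
    model_equations,
    standardise_person,
    stationary_covariance,
    validate_spec,
)


def bivariate_person(phi=None, logv=(0.0, np.log(2.0))):
    return PersonEffects(
        mu=[5.0, 3.0],
        phi=phi if phi is not None else [[0.4, 0.1], [0.2, 0.3]],
        log_innovation=list(logv),
        slope=[0.0, 0.0],
    )


class TestModelEquations:
    def test_degenerate_dynamics_return_the_mean(self):
        eff = PersonEffects(mu=[7.0], phi=[[0.0]], log_innovation=[0.0], slope=[0.0])
        dev, obs = model_equations(eff, [0.0], [0.0], week=10, n_weeks=91)
        assert dev == pytest.approx(0.0)
        assert obs == pytest.approx(7.0)

    def test_univariate_carry_over(self):
        eff = PersonEffects(mu=[7.0], phi=[[0.5]], log_innovation=[0.0], slope=[0.0])
        dev, obs = model_equations(eff, [2.0], [0.0], week=5, n_weeks=9)
        assert dev[0] == pytest.approx(1.0)
        assert obs[0] == pytest.approx(8.0)

    def test_bivariate_hand_multiply(self):
        eff = bivariate_person()
        prev = np.array([1.0, -2.0])
        shock = np.array([0.5, 0.0])
        dev, obs = model_equations(eff, prev, shock, week=3, n_weeks=5)
        # hand 2x2 multiply: [0.4*1 + 0.1*(-2), 0.2*1 + 0.3*(-2)] + shock
        assert dev == pytest.approx([0.4 - 0.2 + 0.5, 0.2 - 0.6])
        assert obs == pytest.approx(np.array([5.0, 3.0]) + dev)

    def test_trend_centred_at_grid_midpoint(self):
        eff = PersonEffects(mu=[7.0], phi=[[0.0]], log_innovation=[0.0], slope=[0.1])
        mid = int(grid_midpoint(91))
        _, obs_mid = model_equations(eff, [0.0], [0.0], week=mid, n_weeks=91)
        _, obs_late = model_equations(eff, [0.0], [0.0], week=mid + 10, n_weeks=91)
        assert obs_mid[0] == pytest.approx(7.0)
        assert obs_late[0] == pytest.approx(8.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            model_equations(bivariate_person(), [1.0], [0.0, 0.0], 2, 5)


class TestStationaryCovariance:
    def test_white_noise(self):
        psi = np.array([1.5, 2.5])
        sigma = stationary_covariance(np.zeros((2, 2)), psi)
        assert sigma == pytest.approx(np.diag(psi))

    def test_univariate_closed_form_to_ten_digits(self):
        sigma = stationary_covariance([[0.5]], [3.0])
        assert sigma[0, 0] == pytest.approx(4.0, rel=1e-10)
        for phi, piv in [(0.9, 0.1), (-0.7, 2.0), (0.36, 1.8)]:
            sigma = stationary_covariance([[phi]], [piv])
            assert sigma[0, 0] == pytest.approx(piv / (1 - phi**2), rel=1e-10)

    def test_bivariate_matches_long_simulation(self):
        phi = np.array([[0.4, 0.1], [0.2, 0.3]])
        psi = np.array([1.0, 2.0])
        sigma = stationary_covariance(phi, psi)
        rng = np.random.default_rng(12)
        n = 400_000
        y = np.zeros(2)
        acc = np.zeros((2, 2))
        draws = rng.standard_normal((n, 2)) * np.sqrt(psi)
        ys = np.empty((n, 2))
        for t in range(n):
            y = phi @ y + draws[t]
            ys[t] = y
        emp = np.cov(ys[1000:].T)
        assert emp == pytest.approx(sigma, rel=0.03, abs=0.03)

    def test_non_stationary_raises(self):
        with pytest.raises(NonStationaryError):
            stationary_covariance([[1.01]], [1.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_lyapunov_residual_at_solver_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            phi = rng.uniform(-0.6, 0.6, size=(2, 2))
            if np.max(np.abs(np.linalg.eigvals(phi))) < 0.95:
                break
        psi = rng.uniform(0.1, 5.0, size=2)
        sigma = stationary_covariance(phi, psi)
        resid = sigma - phi @ sigma @ phi.T - np.diag(psi)
        assert np.abs(resid).max() < 1e-10 * max(1.0, np.abs(sigma).max())
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestStandardisePerson:
    def test_univariate_standardised_inertia_is_raw_inertia(self):
        eff = PersonEffects(mu=[5.0], phi=[[0.47]], log_innovation=[1.0], slope=[0.0])
        assert standardise_person(eff)[0, 0] == 0.47

    def test_equal_scales_leave_cross_lags_unchanged(self):
        # symmetric phi and equal innovations give equal stationary sds
        eff = bivariate_person(phi=[[0.4, 0.15], [0.15, 0.4]], logv=(0.5, 0.5))
        star = standardise_person(eff)
        assert star[0, 1] == pytest.approx(0.15, rel=1e-10)
        assert star[1, 0] == pytest.approx(0.15, rel=1e-10)

    def test_matches_regression_on_standardised_simulated_series(self):
        eff = bivariate_person()
        star = standardise_person(eff)
        rng = np.random.default_rng(5)
        n = 300_000
        sd = np.sqrt(eff.innovation)
        y = np.zeros(2)
        ys = np.empty((n, 2))
        shocks = rng.standard_normal((n, 2)) * sd
        for t in range(n):
            y = eff.phi @ y + shocks[t]
            ys[t] = y
        z = ys / ys.std(axis=0)
        # regress z_dep[t] on both lagged standardised series
        Xl, yv = z[:-1], z[1:]
        for j in range(2):
            beta = np.linalg.lstsq(Xl, yv[:, j], rcond=None)[0]
            assert beta == pytest.approx(star[j], abs=0.01)

    def test_invariant_to_trend_and_mean(self):
        a = bivariate_person()
        b = PersonEffects(mu=[50.0, -3.0], phi=a.phi, log_innovation=a.log_innovation,
                          slope=[0.5, -0.5])
        assert standardise_person(a) == pytest.approx(standardise_person(b))

    def test_non_stationary_person_raises(self):
        eff = bivariate_person(phi=[[0.9, 0.5], [0.5, 0.9]])
        with pytest.raises(NonStationaryError):
            standardise_person(eff)


class TestValidateSpec:
    def test_calibrated_defaults_pass(self):
        validate_spec(dp.calibrated_spec(("dep",)))
        validate_spec(dp.calibrated_spec(("hypo", "ins")))

    def test_negative_eigenvalue_omega_rejected(self):
        spec = dp.calibrated_spec(("dep",))
        omega = spec.omega.copy()
        omega[0, 1] = omega[1, 0] = 10.0  # breaks positive semidefiniteness
        with pytest.raises(ValueError, match="positive semidefinite"):
            validate_spec(DsemSpec(spec.processes, spec.gamma, omega))

    def test_explosive_mean_inertia_rejected(self):
        spec = dp.calibrated_spec(("dep",))
        gamma = spec.gamma.copy()
        gamma[spec.idx("phi_dep_dep")] = 1.2
        with pytest.raises(NonStationaryError):
            validate_spec(DsemSpec(spec.processes, gamma, spec.omega))

    def test_dimension_checks(self):
        spec = dp.calibrated_spec(("dep",))
        with pytest.raises(ValueError, match="gamma"):
            validate_spec(DsemSpec(("dep", "ins"), spec.gamma, np.eye(10)))


def test_effect_names_ordering_and_size():
    names = effect_names(("dep", "ins"))
    assert len(names) == 10
    assert names[:2] == ["mu_dep", "mu_ins"]
    assert names[2:6] == ["phi_dep_dep", "phi_dep_ins", "phi_ins_dep", "phi_ins_ins"]
    assert effect_names(("dep",)) == ["mu_dep", "phi_dep_dep", "logv_dep", "slope_dep"]


def test_spec_yaml_round_trip(tmp_path):
    spec = dp.calibrated_spec(
        ("hypo", "ins"), omega_corr={("phi_hypo_ins", "phi_ins_hypo"): 0.8}
    )
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = DsemSpec.from_yaml(path)
    assert back.processes == spec.processes
    assert back.gamma == pytest.approx(spec.gamma)
    assert back.omega == pytest.approx(spec.omega)


def test_person_effects_vector_round_trip():
    eff = bivariate_person()
    back = PersonEffects.from_vector(eff.to_vector(), 2)
    assert back.phi == pytest.approx(eff.phi)
    assert back.mu == pytest.approx(eff.mu)
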