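"""Synthetic weekly panels with the exact statistical structure the model
assumes.

The generator is the package's ground-truth oracle: person effects are
drawn from the between-person multivariate normal (with rejection of
non-stationary lag matrices), deviations recurse through the within-person
AR(1) equations from a stationary initial condition, a small random linear
trend is added, and missingness can be injected completely at random or as
a logistic function of the previous observed score (missing at random).

The calibrated default specs carry the cohort-level values reported for
the True-Colours-style bipolar panel this emulates: individual-mean levels
(1.98 / 7.33 / 3.29 for (hypo)mania, depression, insomnia), individual-mean
variances (1.96 / 21.10 / 3.71) and inertias (0.40 / 0.47 / 0.36).
Quantities that panel does not pin down (innovation-variance means,
random-effect spreads of the lag coefficients and log variances, trend
size, covariate prevalences for age and rapid cycling) are documented
defaults chosen to satisfy stationarity — see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from ._linalg import batch_spectral_radius, batch_stationary_cov, psd_factor
from .model import DsemSpec, effect_names, grid_midpoint, validate_spec
from .panel import COVARIATES, OUTCOMES, Panel, SCALE_BOUNDS

__all__ = [
    "CALIBRATED_MEANS",
    "CALIBRATED_SDS",
    "DEFAULT_PREVALENCES",
    "GeneratorConfig",
    "calibrated_spec",
    "draw_covariates",
    "draw_person_effects",
    "simulate_panel",
    "inject_missingness",
    "implied_average_standardised",
    "calibrate_cross_lag",
]

#: fixed-effect means of the calibrated generator, keyed by effect name
CALIBRATED_MEANS = {
    "mu_hypo": 1.98,
    "mu_dep": 7.33,
    "mu_ins": 3.29,
    "phi_hypo_hypo": 0.40,
    "phi_dep_dep": 0.47,
    "phi_ins_ins": 0.36,
    # cross-lag means: raw-scale values consistent with the reported
    # average individually standardised effects at the calibrated scales
    "phi_dep_ins": 0.047,
    "phi_ins_dep": 0.031,
    "phi_hypo_ins": 0.008,
    "phi_ins_hypo": 0.011,
    "logv_hypo": 0.4,
    "logv_dep": 2.2,
    "logv_ins": 0.8,
    "slope_hypo": -0.005,
    "slope_dep": -0.005,
    "slope_ins": -0.005,
}

#: random-effect standard deviations of the calibrated generator
CALIBRATED_SDS = {
    "mu_hypo": np.sqrt(1.96),
    "mu_dep": np.sqrt(21.10),
    "mu_ins": np.sqrt(3.71),
    "phi": 0.15,  # all lag-matrix entries
    "logv": 0.5,
    "slope": 0.005,
}

DEFAULT_PREVALENCES = {"bd2": 0.384, "female": 0.68, "age55": 0.40, "rapid": 0.30}


def calibrated_spec(processes=("dep",), omega_corr=None, gamma_overrides=None, B=None) -> DsemSpec:
    """Build the calibrated model spec for 1 or 2 of ``dep, ins, hypo``.

    Parameters
    ----------
    processes
        Process labels, e.g. ``("dep",)`` or ``("hypo", "ins")``.
    omega_corr
        Optional mapping ``{(name_a, name_b): rho}`` of random-effect
        correlations to plant in Omega (zero elsewhere).
    gamma_overrides
        Optional mapping ``{name: value}`` replacing fixed-effect means.
    B
        Optional covariate coefficient matrix (n_effects x 4).
    """
    names = effect_names(processes)
    gamma = np.array([CALIBRATED_MEANS[n] for n in names], dtype=float)
    if gamma_overrides:
        for key, value in gamma_overrides.items():
            gamma[names.index(key)] = float(value)
    sds = np.array(
        [
            CALIBRATED_SDS[n] if n in CALIBRATED_SDS else CALIBRATED_SDS[n.split("_")[0]]
            for n in names
        ],
        dtype=float,
    )
    omega = np.diag(sds**2)
    if omega_corr:
        for (a, b), rho in omega_corr.items():
            i, j = names.index(a), names.index(b)
            omega[i, j] = omega[j, i] = rho * sds[i] * sds[j]
    return validate_spec(DsemSpec(processes=tuple(processes), gamma=gamma, omega=omega, B=B))


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition settings for one simulated panel."""

    spec: DsemSpec
    n: int = 649
    n_weeks: int = 91
    prevalences: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    missingness: str = "none"  # none | mcar | mar
    missing_rate: float = 0.0
    mar_slope: float = 0.3
    discretise: bool = False
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_weeks < 3:
            raise ValueError("n_weeks must be >= 3")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for key, value in self.prevalences.items():
            if key not in COVARIATES:
                raise ValueError(f"unknown covariate {key!r} in prevalences")
            if not 0 <= value <= 1:
                raise ValueError(f"prevalence for {key!r} outside [0, 1]")
        if self.missingness not in ("none", "mcar", "mar"):
            raise ValueError(f"unknown missingness mechanism {self.missingness!r}")
        validate_spec(self.spec)
        return self


def draw_covariates(n: int, prevalences=None, seed=0) -> pd.DataFrame:
    """Independent Bernoulli baseline covariates at the given prevalences."""
    prevalences = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    rng = np.random.default_rng(seed)
    cols = {
        c: (rng.random(n) < prevalences.get(c, 0.0)).astype(int) for c in COVARIATES
    }
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="id"))


def draw_person_effects(spec: DsemSpec, covariates=None, seed=0, max_reject_rate=0.5):
    """Draw eta_i = gamma + B x_i + u_i, u_i ~ N(0, Omega), rejecting
    non-stationary lag matrices.

    Returns ``(eta, n_redraws)`` with ``eta`` of shape (n, n_effects).
    ``covariates`` may be a DataFrame/array of the four binary covariates
    (required when the spec carries B) or, when ``spec.B`` is None, an
    integer participant count.
    """
    validate_spec(spec)
    rng = np.random.default_rng(seed)
    if isinstance(covariates, (int, np.integer)):
        n, x = int(covariates), None
    elif covariates is None:
        raise ValueError("covariates (or a participant count) required")
    else:
        x = (
            covariates[list(COVARIATES)].to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        n = x.shape[0]
    p, q = spec.n_processes, spec.n_effects
    mean = np.broadcast_to(spec.gamma, (n, q)).copy()
    if spec.B is not None:
        if x is None:
            raise ValueError("spec carries covariate coefficients; covariates required")
        mean = mean + x @ spec.B.T
    chol = psd_factor(spec.omega)

    eta = np.empty((n, q))
    pending = np.arange(n)
    n_redraws = 0
    total = 0
    while pending.size:
        draw = mean[pending] + rng.standard_normal((pending.size, q)) @ chol.T
        phi = draw[:, p : p + p * p].reshape(-1, p, p)
        ok = batch_spectral_radius(phi) < 1.0
        eta[pending[ok]] = draw[ok]
        total += pending.size
        n_redraws += int((~ok).sum())
        pending = pending[~ok]
        if total > 200 * n:
            raise ValueError("rejection rate above 50%; revise the spec towards stationarity")
    if n_redraws / max(total, 1) > max_reject_rate:
        raise ValueError(
            f"stationarity rejection rate {n_redraws / total:.0%} above "
            f"{max_reject_rate:.0%}; revise the spec"
        )
    return eta, n_redraws


def simulate_panel(config: GeneratorConfig):
    """Simulate a full panel; returns ``(Panel, truth)``.

    ``truth`` records the spec, covariates, drawn person effects, initial
    deviations and redraw count — everything needed to score recovery.
    """
    config.validate()
    spec = config.spec
    p, q, n, T = spec.n_processes, spec.n_effects, config.n, config.n_weeks
    ss = np.random.SeedSequence(config.seed)
    seed_cov, seed_eff, seed_path, seed_miss = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    covariates = draw_covariates(n, config.prevalences, seed=seed_cov)
    eta, n_redraws = draw_person_effects(spec, covariates, seed=seed_eff)

    mu = eta[:, :p]
    phi = eta[:, p : p + p * p].reshape(n, p, p)
    pi = np.exp(eta[:, p + p * p : p + p * p + p])
    slope = eta[:, p + p * p + p :] if spec.trend else np.zeros((n, p))

    rng = np.random.default_rng(seed_path)
    sigma0 = batch_stationary_cov(phi, pi)
    w0, v0 = np.linalg.eigh((sigma0 + np.swapaxes(sigma0, 1, 2)) / 2)
    chol0 = v0 * np.sqrt(np.clip(w0, 0.0, None))[:, None, :]
    y = np.einsum("npq,nq->np", chol0, rng.standard_normal((n, p)))
    y0 = y.copy()

    tbar = grid_midpoint(T)
    sd = np.sqrt(pi)
    obs = np.empty((n, T, p))
    for t in range(1, T + 1):
        shock = rng.standard_normal((n, p)) * sd
        y = np.einsum("njk,nk->nj", phi, y) + shock
        c = (t - tbar) if spec.trend else 0.0
        obs[:, t - 1, :] = mu + slope * c + y

    if config.discretise:
        for j, name in enumerate(spec.processes):
            obs[:, :, j] = np.clip(np.round(obs[:, :, j]), 0, SCALE_BOUNDS[name])

    ids = covariates.index.to_numpy()
    data = pd.DataFrame(
        {
            "id": np.repeat(ids, T),
            "week": np.tile(np.arange(1, T + 1), n),
        }
    )
    for name in OUTCOMES:
        data[name] = np.nan
    for j, name in enumerate(spec.processes):
        data[name] = obs[:, :, j].ravel()

    panel = Panel(data, covariates).validate()
    if config.missingness != "none":
        panel = inject_missingness(
            panel,
            mechanism=config.missingness,
            rate=config.missing_rate,
            seed=seed_miss,
            outcomes=spec.processes,
            mar_slope=config.mar_slope,
        )
    truth = {
        "spec": spec,
        "covariates": covariates,
        "effects": eta,
        "effect_names": spec.names,
        "y0": y0,
        "n_redraws": n_redraws,
    }
    return panel, truth


def inject_missingness(panel: Panel, mechanism: str, rate: float, seed=0,
                       outcomes=None, mar_slope: float = 0.3) -> Panel:
    """Remove whole weeks from a panel.

    ``mcar`` drops each participant-week independently with probability
    ``rate``.  ``mar`` makes the drop probability a logistic function of
    the participant's most recent *observed* score on the first modelled
    outcome (week 1 always kept), with slope ``mar_slope`` and an intercept
    calibrated so the marginal rate matches ``rate``; this depends only on
    observed values, hence missing at random.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if mechanism not in ("none", "mcar", "mar"):
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    if mechanism == "none" or rate == 0:
        return panel
    if outcomes is None:
        outcomes = [y for y in OUTCOMES if not panel.data[y].isna().all()]
    outcomes = list(outcomes)
    rng = np.random.default_rng(seed)
    data = panel.data.copy()
    T = panel.n_weeks
    arr = panel.to_arrays(outcomes)  # (n, T, p)
    n = arr.shape[0]

    if mechanism == "mcar":
        drop = rng.random((n, T)) < rate
    else:
        anchor = arr[:, :, 0]
        ref = anchor[~np.isnan(anchor)]
        if ref.size == 0:
            raise ValueError("no observed values to anchor MAR missingness")

        def marginal(alpha):
            return float(np.mean(expit(alpha + mar_slope * ref))) - rate

        alpha = optimize.brentq(marginal, -40.0, 40.0)
        drop = np.zeros((n, T), dtype=bool)
        last = np.where(np.isnan(anchor[:, 0]), np.nanmean(ref), anchor[:, 0])
        for t in range(1, T):
            prob = expit(alpha + mar_slope * last)
            drop[:, t] = rng.random(n) < prob
            observed = ~drop[:, t] & ~np.isnan(anchor[:, t])
            last = np.where(observed, anchor[:, t], last)

    flat = drop.ravel()  # row order matches (id-major, week-minor) panel layout
    order = data.sort_values(["id", "week"]).index
    for y in outcomes:
        col = data.loc[order, y].to_numpy()
        col[flat] = np.nan
        data.loc[order, y] = col
    return Panel(data, panel.covariates.copy()).validate()


def _batch_standardised(eta: np.ndarray, p: int):
    """Standardised lag matrices for a stack of effect vectors.

    Returns ``(phi_star (n, p, p), stationary_mask (n,))``; entries of
    non-stationary rows are NaN.
    """
    n = eta.shape[0]
    phi = eta[:, p : p + p * p].reshape(n, p, p)
    pi = np.exp(eta[:, p + p * p : p + p * p + p])
    ok = batch_spectral_radius(phi) < 1.0
    phi_star = np.full((n, p, p), np.nan)
    if ok.any():
        sigma = batch_stationary_cov(phi[ok], pi[ok])
        sd = np.sqrt(np.einsum("njj->nj", sigma))
        phi_star[ok] = phi[ok] * (sd[:, None, :] / sd[:, :, None])
    return phi_star, ok


def implied_average_standardised(spec: DsemSpec, n_mc: int = 50_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo estimate of the generator's implied average individually
    standardised lag matrix (population average of phi* over the
    random-effect distribution, non-stationary draws excluded)."""
    eta, _ = draw_person_effects(spec, int(n_mc), seed=seed)
    phi_star, ok = _batch_standardised(eta, spec.n_processes)
    return np.nanmean(phi_star[ok], axis=0)


def calibrate_cross_lag(
    spec: DsemSpec,
    target_effect: tuple,
    target_value: float,
    n_mc: int = 50_000,
    seed: int = 0,
    bracket=(0.0, 0.4),
) -> DsemSpec:
    """Adjust one raw cross-lag fixed effect so the generator's implied
    average individually standardised value for that ordered pair equals
    ``target_value``.

    ``target_effect`` is ``(target_process, source_process)``; the implied
    average is computed by Monte-Carlo over the random-effect distribution
    with common random numbers, and the raw mean solved by root finding.
    """
    validate_spec(spec)
    names = spec.names
    a, b = target_effect
    gi = names.index(f"phi_{a}_{b}")
    ja, jb = spec.processes.index(a), spec.processes.index(b)
    p, q = spec.n_processes, spec.n_effects
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((int(n_mc), q))
    u = z @ psd_factor(spec.omega).T

    def implied(value):
        gamma = spec.gamma.copy()
        gamma[gi] = value
        eta = gamma[None, :] + u
        phi_star, ok = _batch_standardised(eta, p)
        return float(np.nanmean(phi_star[ok, ja, jb]))

    lo, hi = bracket
    sol = optimize.brentq(lambda v: implied(v) - target_value, lo, hi, xtol=1e-5)
    gamma = spec.gamma.copy()
    gamma[gi] = sol
    return DsemSpec(spec.processes, gamma, spec.omega.copy(),
                    None if spec.B is None else spec.B.copy(), spec.trend)
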