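"""Core mathematics of the multilevel AR(1) symptom model.

Each participant i's weekly score on process j decomposes into a stable
individual mean, a small linear trend, and a dynamic within-person
deviation:

    Y_ijt = mu_ij + s_ij (t - tbar) + y_ijt,
    y_ijt = sum_k phi_jk,i y_ik,t-1 + e_ijt,     e_ijt ~ N(0, pi_ij)

with tbar the grid midpoint so mu keeps its mid-study "individual mean"
interpretation.  phi_jj,i is the person's inertia (carry-over of a
deviation to the next week), phi_jk,i (j != k) the cross-lagged effect of
the other process's deviation, and pi_ij the innovation variance — modelled
on the log scale so that it stays positive as a random effect.  The person
parameter vector

    eta_i = (mu_i, vec phi_i, log pi_i, s_i)

is multivariate normal across people: eta_i ~ N(gamma + B x_i, Omega),
where x_i holds the four binary baseline covariates.

The module defines the parameter containers (:class:`DsemSpec`,
:class:`PersonEffects`), the one-step model equations, the stationary
within-person covariance (discrete Lyapunov solution), and per-person
standardisation of lag coefficients.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml
from scipy import linalg

from .panel import COVARIATES

__all__ = [
    "DsemSpec",
    "PersonEffects",
    "effect_names",
    "grid_midpoint",
    "model_equations",
    "stationary_covariance",
    "standardise_person",
    "validate_spec",
    "NonStationaryError",
]


class NonStationaryError(ValueError):
    """Raised when a lag matrix has spectral radius >= 1."""


def effect_names(processes) -> list[str]:
    """Canonical random-effect ordering: means, lag matrix (row-major),
    log innovation variances, slopes."""
    p = list(processes)
    names = [f"mu_{a}" for a in p]
    names += [f"phi_{a}_{b}" for a in p for b in p]  # effect of b[t-1] on a[t]
    names += [f"logv_{a}" for a in p]
    names += [f"slope_{a}" for a in p]
    return names


def grid_midpoint(n_weeks: int) -> float:
    """Centre of the 1..T week grid; the trend is centred here."""
    return (n_weeks + 1) / 2.0


def _spectral_radius(phi: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.atleast_2d(phi)))))


@dataclasses.dataclass
class PersonEffects:
    """One participant's latent parameter set."""

    mu: np.ndarray  # (p,) individual means, score units
    phi: np.ndarray  # (p, p) lag matrix; phi[j, k] = effect of k[t-1] on j[t]
    log_innovation: np.ndarray  # (p,) log innovation variances
    slope: np.ndarray  # (p,) linear trend, score units per week

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.log_innovation = np.atleast_1d(np.asarray(self.log_innovation, dtype=float))
        self.slope = np.atleast_1d(np.asarray(self.slope, dtype=float))
        p = len(self.mu)
        if self.phi.shape != (p, p) or len(self.log_innovation) != p or len(self.slope) != p:
            raise ValueError("mismatched process dimensions in PersonEffects")

    @property
    def n_processes(self) -> int:
        return len(self.mu)

    @property
    def innovation(self) -> np.ndarray:
        """Innovation variances pi = exp(log pi), one per process."""
        return np.exp(self.log_innovation)

    def is_stationary(self) -> bool:
        return _spectral_radius(self.phi) < 1.0

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.mu, self.phi.ravel(), self.log_innovation, self.slope])

    @classmethod
    def from_vector(cls, eta: np.ndarray, n_processes: int) -> "PersonEffects":
        p = n_processes
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (p * p + 3 * p,):
            raise ValueError(f"effect vector must have length {p * p + 3 * p}")
        return cls(
            mu=eta[:p],
            phi=eta[p : p + p * p].reshape(p, p),
            log_innovation=eta[p + p * p : 2 * p + p * p],
            slope=eta[2 * p + p * p :],
        )


@dataclasses.dataclass
class DsemSpec:
    """Full parameterisation of the generative/estimated model.

    ``gamma`` is the fixed-effect vector in the :func:`effect_names` order,
    ``omega`` the random-effect covariance over the same vector, and ``B``
    (optional) the covariate coefficient matrix with one column per
    baseline covariate in :data:`dsempanel.panel.COVARIATES`.
    """

    processes: tuple
    gamma: np.ndarray
    omega: np.ndarray
    B: np.ndarray | None = None
    trend: bool = True

    def __post_init__(self):
        self.processes = tuple(self.processes)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.B is not None:
            self.B = np.asarray(self.B, dtype=float)

    @property
    def n_processes(self) -> int:
        return len(self.processes)

    @property
    def n_effects(self) -> int:
        p = self.n_processes
        return p * p + 3 * p

    @property
    def names(self) -> list[str]:
        return effect_names(self.processes)

    def idx(self, name: str) -> int:
        return self.names.index(name)

    def mean_effects(self, x=None) -> PersonEffects:
        """Population-level effects gamma + B x (x defaults to zero)."""
        eta = self.gamma.copy()
        if x is not None and self.B is not None:
            eta = eta + self.B @ np.asarray(x, dtype=float)
        return PersonEffects.from_vector(eta, self.n_processes)

    def mean_phi(self) -> np.ndarray:
        p = self.n_processes
        return self.gamma[p : p + p * p].reshape(p, p)

    # -- serialisation: one YAML format shared by generator and fitter -----

    def to_yaml(self, path=None) -> str:
        doc = {
            "processes": list(self.processes),
            "trend": bool(self.trend),
            "gamma": {n: float(v) for n, v in zip(self.names, self.gamma)},
            "omega": [[float(v) for v in row] for row in self.omega],
        }
        if self.B is not None:
            doc["B"] = {
                n: {c: float(v) for c, v in zip(COVARIATES, row)}
                for n, row in zip(self.names, self.B)
            }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DsemSpec":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and not text.strip().startswith("{"):
                with open(text) as fh:
                    doc = yaml.safe_load(fh)
            else:
                doc = yaml.safe_load(text)
        processes = tuple(doc["processes"])
        names = effect_names(processes)
        gamma = np.array([doc["gamma"][n] for n in names], dtype=float)
        omega = np.array(doc["omega"], dtype=float)
        B = None
        if "B" in doc and doc["B"] is not None:
            B = np.array([[doc["B"][n][c] for c in COVARIATES] for n in names], dtype=float)
        return cls(processes=processes, gamma=gamma, omega=omega, B=B, trend=doc.get("trend", True))


def validate_spec(spec: DsemSpec, tol: float = 1e-10) -> DsemSpec:
    """Check all spec invariants; raise with the offending entry otherwise."""
    p = spec.n_processes
    if p not in (1, 2):
        raise ValueError(f"model supports 1 or 2 processes, got {p}")
    q = spec.n_effects
    if spec.gamma.shape != (q,):
        raise ValueError(f"gamma must have length {q}, got {spec.gamma.shape}")
    if spec.omega.shape != (q, q):
        raise ValueError(f"omega must be {q}x{q}, got {spec.omega.shape}")
    if not np.allclose(spec.omega, spec.omega.T, atol=1e-8):
        raise ValueError("omega is not symmetric")
    eig = np.linalg.eigvalsh((spec.omega + spec.omega.T) / 2)
    if eig.min() < -tol * max(1.0, eig.max()):
        raise ValueError(f"omega is not positive semidefinite (min eigenvalue {eig.min():.3g})")
    if spec.B is not None and spec.B.shape != (q, len(COVARIATES)):
        raise ValueError(f"B must be {q}x{len(COVARIATES)}, got {spec.B.shape}")
    rho = _spectral_radius(spec.mean_phi())
    if rho >= 1.0:
        raise NonStationaryError(
            f"mean lag matrix has spectral radius {rho:.3f} >= 1 (non-stationary)"
        )
    return spec


def model_equations(
    effects: PersonEffects,
    prev_deviation: np.ndarray,
    shock: np.ndarray,
    week: int,
    n_weeks: int,
    trend: bool = True,
):
    """One step of the generative equations.

    Returns ``(deviation, observation)`` for the given week:
    ``deviation = phi @ prev_deviation + shock`` and
    ``observation = mu + slope * (week - tbar) + deviation``.
    """
    prev_deviation = np.atleast_1d(np.asarray(prev_deviation, dtype=float))
    shock = np.atleast_1d(np.asarray(shock, dtype=float))
    p = effects.n_processes
    if prev_deviation.shape != (p,) or shock.shape != (p,):
        raise ValueError("mismatched process dimensions in model_equations")
    dev = effects.phi @ prev_deviation + shock
    c = (week - grid_midpoint(n_weeks)) if trend else 0.0
    obs = effects.mu + effects.slope * c + dev
    return dev, obs


def stationary_covariance(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Within-person stationary covariance Sigma solving
    Sigma = phi Sigma phi' + Psi (discrete Lyapunov equation).

    ``psi`` may be a vector of innovation variances or a diagonal matrix.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.asarray(psi, dtype=float)
    if psi.ndim == 1:
        psi = np.diag(psi)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi dimension mismatch")
    if np.any(np.diag(psi) <= 0):
        raise ValueError("innovation variances must be positive")
    rho = _spectral_radius(phi)
    if rho >= 1.0:
        raise NonStationaryError(f"lag matrix spectral radius {rho:.3f} >= 1; no stationary covariance")
    sigma = linalg.solve_discrete_lyapunov(phi, psi)
    return (sigma + sigma.T) / 2


def standardise_person(effects: PersonEffects) -> np.ndarray:
    """Person-level standardised lag matrix.

    phi*_jk = phi_jk * sigma_k / sigma_j with sigma the stationary
    within-person standard deviations of the (trend-free) deviations.  For
    a univariate model this returns the raw inertia unchanged.
    """
    if not effects.is_stationary():
        raise NonStationaryError("person effects are non-stationary; cannot standardise")
    sigma = stationary_covariance(effects.phi, effects.innovation)
    sd = np.sqrt(np.diag(sigma))
    return effects.phi * (sd[None, :] / sd[:, None])
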