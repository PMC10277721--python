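"""Model and results objects for Bayesian estimation of the symptom DSEM.

:class:`DsemModel` wraps a :class:`~dsempanel.panel.Panel` plus the choice
of modelled processes and covariates; :meth:`DsemModel.fit` runs the Gibbs
sampler (two chains by default) and returns a :class:`DsemResults` holding
the posterior draws, convergence diagnostics and summary tables, in the
spirit of a statsmodels fit.

Posterior p-values are one-tailed, min(P(draw > 0), P(draw < 0)), the
usual convention for MCMC mood-dynamics models; intervals are equal-tailed
95% credible intervals.  The potential scale reduction (PSR) diagnostic uses the
between/within-chain variance ratio R-hat = sqrt((W + B/n) / W), which is
exactly 1 for identical chains and grows without bound when chains do not
overlap.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from .model import DsemSpec, effect_names, validate_spec
from .panel import COVARIATES, Panel
from .sampler import ChainConfig, ChainDraws, run_chain

__all__ = [
    "DsemModel",
    "DsemResults",
    "Diagnostics",
    "fit_dsem",
    "one_tailed_p",
    "psr",
    "posterior_summary",
    "random_effect_correlations",
]


# --------------------------------------------------------------------------
# posterior statistics


def one_tailed_p(draws) -> float:
    """One-tailed MCMC p-value: min(P(draw > 0), P(draw < 0)), in [0, 0.5]."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("one_tailed_p requires at least one draw")
    return float(min(np.mean(draws > 0), np.mean(draws < 0)))


def psr(chains) -> float:
    """Potential scale reduction over >= 2 equal-length chains.

    ``chains`` is a (C, S) array or sequence of per-chain draw sequences.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("psr requires >= 2 chains of equal length")
    s = arr.shape[1]
    within = arr.var(axis=1, ddof=1).mean()
    between = s * arr.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0 if between <= 0 else np.inf
    return float(np.sqrt((within + between / s) / within))


def posterior_summary(draws):
    """(mean, median, equal-tailed 95% credible interval) of a draw set."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("posterior_summary requires draws")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(np.median(draws)), (float(lo), float(hi))


# --------------------------------------------------------------------------


@dataclasses.dataclass
class Diagnostics:
    psr: dict
    ess: dict
    threshold: float
    converged: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "psr": self.psr,
                "ess": self.ess,
                "threshold": self.threshold,
                "converged": bool(self.converged),
            },
            indent=2,
        )


class DsemModel:
    """Multilevel AR(1) dynamic structural equation model of 1-2 weekly
    symptom processes with person-specific means, lag coefficients, log
    innovation variances and linear trends.

    Parameters
    ----------
    panel
        An eligibility-filtered :class:`~dsempanel.panel.Panel`.
    processes
        One or two of ``"dep"``, ``"ins"``, ``"hypo"``.
    covariates
        False for an unconditional model; True to regress all random
        effects on the four baseline covariates jointly; or a list of
        covariate names (one-at-a-time mode uses a single-name list).
    spec
        Optional :class:`DsemSpec` template; only its structure (process
        labels) is used, e.g. when fitting the generator's own spec.
    """

    def __init__(self, panel: Panel, processes=("dep", "ins"), covariates=False,
                 spec: DsemSpec | None = None):
        if spec is not None:
            validate_spec(spec)
            processes = spec.processes
        self.processes = tuple(processes)
        if not 1 <= len(self.processes) <= 2:
            raise ValueError("model supports one or two processes")
        self.panel = panel
        if covariates is True:
            self.covariate_names = list(COVARIATES)
        elif covariates:
            unknown = set(covariates) - set(COVARIATES)
            if unknown:
                raise ValueError(f"unknown covariates: {sorted(unknown)}")
            self.covariate_names = list(covariates)
        else:
            self.covariate_names = []

        self.Y = panel.to_arrays(self.processes)
        n = self.Y.shape[0]
        if n < 2:
            raise ValueError("hierarchical model requires at least 2 participants")
        n_obs = (~np.isnan(self.Y)).sum(axis=1)  # (n, p)
        if (n_obs < 3).any():
            bad = [panel.ids[i] for i in np.nonzero((n_obs < 3).any(axis=1))[0]]
            raise ValueError(
                f"participants with fewer than 3 non-missing weeks on a modelled "
                f"outcome: {bad[:5]}; apply eligibility filtering first"
            )
        self.X = (
            panel.covariates[self.covariate_names].to_numpy(dtype=float)
            if self.covariate_names
            else None
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, covariates: pd.DataFrame, **kwargs):
        return cls(Panel(data, covariates).validate(), **kwargs)

    def fit(
        self,
        chains: int = 2,
        iterations: int = 2000,
        burn: int = 2000,
        seed: int = 0,
        psr_threshold: float = 1.1,
        store_person_effects: bool = True,
        progress=None,
    ) -> "DsemResults":
        """Run the Gibbs sampler and return a :class:`DsemResults`.

        Non-convergence (any monitored PSR above ``psr_threshold``) is
        flagged on the result and warned about, never silent.
        """
        if chains < 1:
            raise ValueError("chains must be >= 1")
        child_seeds = [
            int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(chains)
        ]
        draws = []
        for c in range(chains):
            cfg = ChainConfig(
                iterations=iterations,
                burn=burn,
                seed=child_seeds[c],
                store_person_effects=store_person_effects,
            )
            draws.append(run_chain(self.Y, self.X, cfg, progress=progress))
        return DsemResults(self, draws, seed=seed, psr_threshold=psr_threshold)


class DsemResults:
    """Posterior draws, diagnostics and summaries from a fitted model."""

    def __init__(self, model: DsemModel, chain_draws: list[ChainDraws], seed: int,
                 psr_threshold: float = 1.1):
        self.model = model
        self.processes = model.processes
        self.names = effect_names(model.processes)
        self.covariate_names = model.covariate_names
        self.seed = seed
        self.gamma = np.stack([d.gamma for d in chain_draws])  # (C, S, q)
        self.B = (
            np.stack([d.B for d in chain_draws]) if chain_draws[0].B is not None else None
        )
        self.omega = np.stack([d.omega for d in chain_draws])  # (C, S, q, q)
        self.eta = (
            np.stack([d.eta for d in chain_draws]) if chain_draws[0].eta is not None else None
        )
        self.accept_rate = np.mean([d.accept_rate for d in chain_draws], axis=0)
        self.n_phi_rejections = int(sum(d.n_phi_rejections for d in chain_draws))
        self.n_chains, self.n_draws, self.n_effects = self.gamma.shape
        self.diagnostics = self._diagnostics(psr_threshold)
        if not self.diagnostics.converged:
            import warnings

            worst = max(self.diagnostics.psr.values())
            warnings.warn(
                f"MCMC convergence not reached: max PSR {worst:.3f} > "
                f"{psr_threshold}; interpret results with caution",
                stacklevel=2,
            )

    # -- draw access -------------------------------------------------------

    def fixed_effect(self, name: str) -> np.ndarray:
        """Flattened posterior draws of one fixed effect."""
        return self.gamma[:, :, self.names.index(name)].ravel()

    def covariate_effect(self, effect: str, covariate: str) -> np.ndarray:
        if self.B is None:
            raise ValueError("model was fitted without covariates")
        return self.B[:, :, self.names.index(effect), self.covariate_names.index(covariate)].ravel()

    def omega_entry(self, name_a: str, name_b: str) -> np.ndarray:
        i, j = self.names.index(name_a), self.names.index(name_b)
        return self.omega[:, :, i, j].ravel()

    # -- diagnostics ---------------------------------------------------------

    def _monitored(self) -> dict:
        mon = {n: self.gamma[:, :, i] for i, n in enumerate(self.names)}
        for i, n in enumerate(self.names):
            mon[f"var_{n}"] = self.omega[:, :, i, i]
        if self.B is not None:
            for i, n in enumerate(self.names):
                for j, c in enumerate(self.covariate_names):
                    mon[f"{n}@{c}"] = self.B[:, :, i, j]
        return mon

    def _diagnostics(self, threshold: float) -> Diagnostics:
        mon = self._monitored()
        if self.n_chains >= 2:
            psr_values = {n: psr(v) for n, v in mon.items()}
        else:
            psr_values = {n: float("nan") for n in mon}
        ess_values = {n: _ess(v) for n, v in mon.items()}
        finite = [v for v in psr_values.values() if np.isfinite(v)]
        converged = bool(finite) and all(v < threshold for v in finite)
        return Diagnostics(psr=psr_values, ess=ess_values, threshold=threshold,
                           converged=converged)

    # -- summaries -----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """One row per fixed effect (and covariate coefficient): posterior
        mean, sd, median, 95% credible interval, one-tailed p, PSR."""
        rows = []
        mon = self._monitored()
        for name, arr in mon.items():
            flat = arr.ravel()
            mean, median, (lo, hi) = posterior_summary(flat)
            rows.append(
                {
                    "parameter": name,
                    "mean": mean,
                    "sd": float(flat.std(ddof=1)),
                    "median": median,
                    "ci_2.5": lo,
                    "ci_97.5": hi,
                    "p_one_tailed": one_tailed_p(flat),
                    "psr": self.diagnostics.psr.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        head = [
            "Dynamic structural equation model (multilevel AR(1))",
            f"processes: {', '.join(self.processes)}   participants: {self.model.Y.shape[0]}"
            f"   weeks: {self.model.Y.shape[1]}",
            f"chains: {self.n_chains}   draws/chain: {self.n_draws}   seed: {self.seed}",
            f"covariates: {', '.join(self.covariate_names) or 'none'}",
            f"RW acceptance (log innovation): "
            + ", ".join(f"{a:.2f}" for a in np.atleast_1d(self.accept_rate)),
            f"non-stationary lag proposals rejected: {self.n_phi_rejections}",
        ]
        if not self.diagnostics.converged:
            head.append(
                f"WARNING: convergence flag FALSE (max PSR "
                f"{max(self.diagnostics.psr.values()):.3f} >= {self.diagnostics.threshold})"
            )
        frame = self.summary_frame()
        with pd.option_context("display.float_format", lambda v: f"{v:10.4f}"):
            body = frame.to_string()
        return "\n".join(head) + "\n\n" + body + "\n"

    def random_effect_correlations(self, pair=None):
        """Posterior-mean correlation matrix of the random effects (raw,
        unstandardised), derived from the Omega draws; or one entry when
        ``pair`` = (name_a, name_b)."""
        var = np.einsum("csii->csi", self.omega)
        sd = np.sqrt(var)
        corr = self.omega / (sd[:, :, :, None] * sd[:, :, None, :])
        mean_corr = corr.mean(axis=(0, 1))
        mean_corr = (mean_corr + mean_corr.T) / 2
        np.fill_diagonal(mean_corr, 1.0)
        frame = pd.DataFrame(mean_corr, index=self.names, columns=self.names)
        if pair is None:
            return frame
        a, b = pair
        if a not in self.names or b not in self.names:
            raise ValueError(
                f"effect pair ({a}, {b}) not in this model's random effects; "
                "cross-process pairs require a bivariate fit"
            )
        return float(frame.loc[a, b])

    # -- persistence ---------------------------------------------------------

    def save(self, outdir) -> None:
        """Persist population-level draws as CSV (one row per chain x
        iteration) with a JSON sidecar naming parameters, plus
        diagnostics JSON."""
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cols = {}
        for i, n in enumerate(self.names):
            cols[n] = self.gamma[:, :, i].ravel()
        q = self.n_effects
        for i in range(q):
            for j in range(i, q):
                cols[f"omega[{self.names[i]},{self.names[j]}]"] = self.omega[:, :, i, j].ravel()
        if self.B is not None:
            for i, n in enumerate(self.names):
                for j, c in enumerate(self.covariate_names):
                    cols[f"{n}@{c}"] = self.B[:, :, i, j].ravel()
        frame = pd.DataFrame(cols)
        frame.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        frame.insert(1, "iteration", np.tile(np.arange(self.n_draws), self.n_chains))
        frame.to_csv(outdir / "draws.csv", index=False)
        sidecar = {
            "processes": list(self.processes),
            "effect_names": self.names,
            "covariates": self.covariate_names,
            "columns": list(frame.columns),
            "chains": self.n_chains,
            "iterations": self.n_draws,
            "seed": self.seed,
        }
        (outdir / "draws.json").write_text(json.dumps(sidecar, indent=2))
        (outdir / "diagnostics.json").write_text(self.diagnostics.to_json())


def _ess(chains_2d: np.ndarray) -> float:
    """Effective sample size via arviz (bulk ESS)."""
    try:
        import arviz as az

        return float(az.ess(np.asarray(chains_2d)))
    except Exception:
        return float("nan")


def fit_dsem(
    panel: Panel,
    processes=("dep", "ins"),
    covariates=False,
    chains: int = 2,
    iterations: int = 2000,
    burn: int = 2000,
    seed: int = 0,
    **kwargs,
) -> DsemResults:
    """Functional wrapper: build a :class:`DsemModel` and fit it."""
    model = DsemModel(panel, processes=processes, covariates=covariates)
    return model.fit(chains=chains, iterations=iterations, burn=burn, seed=seed, **kwargs)
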