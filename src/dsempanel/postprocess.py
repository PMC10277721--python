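"""Posterior postprocessing: average individually standardised cross-lag
effects and stratified contrasts.

Cross-lagged effects are reported on a per-person standardised scale: for
each posterior draw, each participant's lag matrix is standardised by that
participant's stationary within-person standard deviations (trend-free
deviations), the standardised matrices are averaged across participants,
and the resulting per-draw averages are summarised over draws.  Person-
draws whose lag matrix is non-stationary have no stationary scale and are
excluded from that draw's average, with the exclusion fraction logged.

Stratum contrasts pair independent posterior draws of the averaged
standardised effect from two disjoint-strata fits; the two-tailed p-value
is 2 * min(P(diff > 0), P(diff < 0)).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._linalg import batch_spectral_radius, batch_stationary_cov
from .inference import DsemResults, one_tailed_p, posterior_summary

__all__ = [
    "StandardisedEffects",
    "StrataComparison",
    "average_standardised_effects",
    "stratified_compare",
]

_EXCLUSION_WARN_FRACTION = 0.05


@dataclasses.dataclass
class StandardisedEffects:
    """Average individually standardised lag effects with uncertainty."""

    processes: tuple
    draws: np.ndarray  # (C, S, p, p) per-draw across-person averages
    excluded_fraction: float  # fraction of person-draws non-stationary

    def effect(self, target: str, source: str) -> np.ndarray:
        """Flattened posterior draws of the averaged standardised effect of
        ``source`` at week t-1 on ``target`` at week t."""
        j = self.processes.index(target)
        k = self.processes.index(source)
        return self.draws[:, :, j, k].reshape(-1)

    def estimate(self, target: str, source: str) -> float:
        return float(self.effect(target, source).mean())

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for j, a in enumerate(self.processes):
            for k, b in enumerate(self.processes):
                flat = self.draws[:, :, j, k].reshape(-1)
                mean, median, (lo, hi) = posterior_summary(flat)
                rows.append(
                    {
                        "effect": f"{b} -> {a}" if j != k else f"{a} inertia",
                        "target": a,
                        "source": b,
                        "mean": mean,
                        "median": median,
                        "ci_2.5": lo,
                        "ci_97.5": hi,
                        "p_one_tailed": one_tailed_p(flat),
                    }
                )
        return pd.DataFrame(rows)


def average_standardised_effects(
    fit: DsemResults, chunk: int = 200
) -> StandardisedEffects:
    """Per-draw, per-person standardisation of the lag matrix, averaged
    over participants, summarised over posterior draws."""
    if fit.eta is None:
        raise ValueError("fit was run without stored person effects")
    p = len(fit.processes)
    C, S, n, q = fit.eta.shape
    out = np.empty((C, S, p, p))
    n_excluded = 0
    for c in range(C):
        for s0 in range(0, S, chunk):
            block = fit.eta[c, s0 : s0 + chunk]  # (s, n, q)
            s = block.shape[0]
            phi = block[:, :, p : p + p * p].reshape(s * n, p, p)
            pi = np.exp(block[:, :, p + p * p : p + p * p + p]).reshape(s * n, p)
            ok = batch_spectral_radius(phi) < 1.0
            star = np.full((s * n, p, p), np.nan)
            if ok.any():
                if p == 1:
                    star[ok] = phi[ok]
                else:
                    sigma = batch_stationary_cov(phi[ok], pi[ok])
                    sd = np.sqrt(np.einsum("mjj->mj", sigma))
                    star[ok] = phi[ok] * (sd[:, None, :] / sd[:, :, None])
            n_excluded += int((~ok).sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[c, s0 : s0 + chunk] = np.nanmean(star.reshape(s, n, p, p), axis=1)
    frac = n_excluded / float(C * S * n)
    if frac > _EXCLUSION_WARN_FRACTION:
        warnings.warn(
            f"{frac:.1%} of person-draws were non-stationary and excluded from "
            "standardisation; averaged estimates may be unstable",
            stacklevel=2,
        )
    return StandardisedEffects(processes=tuple(fit.processes), draws=out,
                               excluded_fraction=frac)


@dataclasses.dataclass
class StrataComparison:
    """Contrast of an averaged standardised effect across two strata."""

    effect: tuple  # (target, source)
    labels: tuple
    estimates: tuple  # per-stratum posterior means
    ses: tuple
    cis: tuple
    difference: float
    se: float
    ci: tuple
    p_two_tailed: float
    n_draws: int

    def summary_frame(self) -> pd.DataFrame:
        a, b = self.labels
        t, s = self.effect
        return pd.DataFrame(
            [
                {
                    "effect": f"{s} -> {t}",
                    f"estimate_{a}": self.estimates[0],
                    f"se_{a}": self.ses[0],
                    f"estimate_{b}": self.estimates[1],
                    f"se_{b}": self.ses[1],
                    "difference": self.difference,
                    "se_difference": self.se,
                    "ci_2.5": self.ci[0],
                    "ci_97.5": self.ci[1],
                    "p_two_tailed": self.p_two_tailed,
                }
            ]
        )


def _as_standardised(fit) -> StandardisedEffects:
    if isinstance(fit, StandardisedEffects):
        return fit
    return average_standardised_effects(fit)


def stratified_compare(fitA, fitB, effect, labels=("stratum_0", "stratum_1")) -> StrataComparison:
    """Compare the magnitude of one averaged standardised effect between
    two fits on disjoint strata.

    ``effect`` is ``(target, source)``.  Draws from the two independent
    posteriors are paired (one stratum's order reversed, so the pairing is
    exchangeable even if the same fit is passed twice) and the difference
    stratum A minus stratum B is summarised.
    """
    stdA, stdB = _as_standardised(fitA), _as_standardised(fitB)
    if stdA.processes != stdB.processes:
        raise ValueError(
            f"mismatched model specs: {stdA.processes} vs {stdB.processes}"
        )
    target, source = effect
    a = stdA.effect(target, source)
    b = stdB.effect(target, source)
    m = min(a.size, b.size)
    diff = a[:m] - b[::-1][:m]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    p = 2.0 * min(np.mean(diff > 0), np.mean(diff < 0))
    return StrataComparison(
        effect=(target, source),
        labels=tuple(labels),
        estimates=(float(a.mean()), float(b.mean())),
        ses=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        cis=(
            tuple(float(v) for v in np.percentile(a, [2.5, 97.5])),
            tuple(float(v) for v in np.percentile(b, [2.5, 97.5])),
        ),
        difference=float(a[:m].mean() - b[:m].mean()),
        se=float(diff.std(ddof=1)),
        ci=(float(lo), float(hi)),
        p_two_tailed=float(min(p, 1.0)),
        n_draws=int(m),
    )
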