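"""Metropolis-within-Gibbs sampler for the multilevel AR(1) symptom model.

One sweep updates, in order: latent initial deviations and missing weeks
(data augmentation, odd/even-week passes so neighbouring cells are never
updated simultaneously), each person's (mean, slope) block and lag-matrix
block by conjugate normal draws, each person's log innovation variance by
adaptive random-walk Metropolis, the fixed effects and covariate
coefficients by a conjugate multivariate normal draw, and the
random-effect covariance by an inverse-Wishart draw.  Person-level lag
draws leaving the stationary region are rejected (the previous value is
kept), which implements the prior truncation to spectral radius < 1.

All person-level updates are vectorised across participants; the only
Python-level loop is over sweeps.  Everything is driven by a single
``numpy`` Generator so a (data, seed) pair reproduces draws bit-exactly.

Priors (diffuse, proper): gamma ~ N(0, 1e4) elementwise except the log
innovation-variance means ~ N(0, 10); covariate coefficients ~ N(0, 1e4).
The random-effect covariance uses the Huang-Wand hierarchical
inverse-Wishart: Omega | a ~ IW(nu + q - 1, 2 nu diag(1/a)) with
a_k ~ inverse-gamma(1/2, 1/A^2) and nu = 2, giving half-t(2, A) marginals
on the random-effect standard deviations and marginally uniform
correlations.  A plain inverse-Wishart with a fixed scale matrix is
unusable here: the random-effect variances span six orders of magnitude
(individual means ~20, slopes ~1e-5), and any fixed scale biases the
correlations of components whose variance is far from it towards +/-1 or
0; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import invwishart

from ._linalg import batch_spectral_radius

__all__ = ["ChainConfig", "ChainDraws", "run_chain"]

_GAMMA_PRIOR_VAR = 1.0e4
_LOGV_MEAN_PRIOR_VAR = 10.0
_B_PRIOR_VAR = 1.0e4
_HW_NU = 2.0  # Huang-Wand degrees of freedom (uniform correlation marginals)
_HW_SCALE = 25.0  # half-t scale on random-effect standard deviations
_TARGET_ACCEPT = 0.35
_ADAPT_RATE = 0.05


@dataclasses.dataclass
class ChainConfig:
    iterations: int = 2000
    burn: int = 2000
    seed: int = 0
    store_person_effects: bool = True


@dataclasses.dataclass
class ChainDraws:
    """Post-burn-in draws from one chain."""

    gamma: np.ndarray  # (S, q)
    B: np.ndarray | None  # (S, q, k) or None
    omega: np.ndarray  # (S, q, q)
    eta: np.ndarray | None  # (S, N, q)
    accept_rate: np.ndarray  # (p,) mean RW acceptance per process, post-burn
    n_phi_rejections: int  # non-stationary lag proposals discarded post-burn


def _draw_mvn_prec(prec: np.ndarray, rhs: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 rhs, prec^-1) for a (..., d, d) stack."""
    d = prec.shape[-1]
    cov = np.linalg.inv(prec + 1e-12 * np.eye(d))
    cov = (cov + np.swapaxes(cov, -1, -2)) / 2
    mean = np.einsum("...ij,...j->...i", cov, rhs)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    eps = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ij,...j->...i", chol, eps)


def _missing_groups(miss: np.ndarray):
    """Static index groups for the augmentation passes.

    Returns ``{parity: dict}`` with, per parity, fully-missing interior
    weeks (i, t with 1 <= t < T), fully-missing final weeks, and
    partially-missing cells (i, t, j) split the same way.  ``t`` is the
    1-based week index.
    """
    n, T, p = miss.shape
    full = miss.all(axis=2)
    part = miss.any(axis=2) & ~full
    groups = {}
    for parity in (1, 0):
        sel_t = np.arange(1, T + 1)
        sel_t = sel_t[sel_t % 2 == parity]
        g = {}
        for kind, mask in (("full", full), ("part", part)):
            tt = sel_t[sel_t < T]
            sub = mask[:, tt - 1]
            ii, jj = np.nonzero(sub)
            g[f"{kind}_int_i"], g[f"{kind}_int_t"] = ii, tt[jj]
            if T % 2 == parity:
                (endi,) = np.nonzero(mask[:, T - 1])
                g[f"{kind}_end_i"] = endi
            else:
                g[f"{kind}_end_i"] = np.empty(0, dtype=int)
        groups[parity] = g
    return groups


def run_chain(
    Y: np.ndarray,
    X: np.ndarray | None,
    config: ChainConfig,
    progress=None,
) -> ChainDraws:
    """Run one MCMC chain on a (N, T, p) panel array (NaN = missing).

    ``X`` is the (N, k) binary covariate matrix or None for an
    unconditional model.
    """
    Y = np.asarray(Y, dtype=float)
    n, T, p = Y.shape
    q = p * p + 3 * p
    k = 0 if X is None else X.shape[1]
    rng = np.random.default_rng(config.seed)

    weeks = np.arange(1, T + 1, dtype=float)
    c = weeks - (T + 1) / 2.0
    c1 = c[0]
    ct, ctm1 = c[1:], c[:-1]
    S_ct, S_ctm1 = ct.sum(), ctm1.sum()
    S_ctt, S_cttm1, S_cmm = (ct**2).sum(), (ct * ctm1).sum(), (ctm1**2).sum()

    miss = np.isnan(Y)
    groups = _missing_groups(miss)

    # --- initial state -----------------------------------------------------
    Yimp = Y.copy()
    col_mean = np.nanmean(np.where(miss, np.nan, Y), axis=1)  # (n, p)
    col_mean = np.where(np.isnan(col_mean), np.nanmean(Y, axis=(0, 1)), col_mean)
    for j in range(p):
        m = miss[:, :, j]
        Yimp[:, :, j][m] = np.broadcast_to(col_mean[:, j][:, None], (n, T))[m]

    mu = col_mean + 0.05 * rng.standard_normal((n, p))
    slope = np.zeros((n, p))
    phi = np.tile(0.3 * np.eye(p), (n, 1, 1)) + 0.03 * rng.standard_normal((n, p, p))
    resid_var = np.maximum(np.nanvar(Yimp, axis=1) * 0.7, 0.05)
    logv = np.log(resid_var) + 0.05 * rng.standard_normal((n, p))
    pi = np.exp(logv)
    y0 = np.zeros((n, p))

    def pack_eta():
        return np.concatenate([mu, phi.reshape(n, -1), logv, slope], axis=1)

    eta = pack_eta()
    gamma = eta.mean(axis=0)
    Bmat = np.zeros((q, k)) if k else None
    omega = np.cov(eta.T) + 0.05 * np.eye(q)
    lam = np.linalg.inv(omega)

    W = np.ones((n, 1)) if k == 0 else np.concatenate([np.ones((n, 1)), X], axis=1)
    WtW = W.T @ W
    prior_prec_gamma = np.full(q, 1.0 / _GAMMA_PRIOR_VAR)
    prior_prec_gamma[p + p * p : 2 * p + p * p] = 1.0 / _LOGV_MEAN_PRIOR_VAR
    prior_prec_theta = np.concatenate(
        [prior_prec_gamma] + [np.full(q, 1.0 / _B_PRIOR_VAR)] * k
    )
    hw_a = np.ones(q)  # Huang-Wand auxiliary scales

    idx_mu = np.arange(p)
    idx_phi = np.arange(p, p + p * p)
    idx_logv = np.arange(p + p * p, 2 * p + p * p)
    idx_slope = np.arange(2 * p + p * p, q)
    idx_ms = np.concatenate([idx_mu, idx_slope])
    rest_ms = np.setdiff1d(np.arange(q), idx_ms)
    rest_phi = np.setdiff1d(np.arange(q), idx_phi)

    step = np.full((n, p), 0.3)  # RW step for log innovation variances

    # Fixed pre-sample prior for the initial deviation: zero mean with the
    # pooled within-person variance of each process.  Keeping this prior
    # fixed (rather than the person's own stationary covariance) keeps every
    # full conditional coherent with one joint model; it matches the
    # stationary scale closely and only touches the first week.
    v0 = np.nanmean(np.nanvar(Y, axis=1), axis=0)
    v0 = np.where(np.isfinite(v0) & (v0 > 0), v0, 1.0)
    prec_y0 = np.diag(1.0 / v0)

    total = config.burn + config.iterations
    S = config.iterations
    out_gamma = np.empty((S, q))
    out_B = np.empty((S, q, k)) if k else None
    out_omega = np.empty((S, q, q))
    out_eta = np.empty((S, n, q)) if config.store_person_effects else None
    acc_sum = np.zeros(p)
    acc_count = 0
    phi_rej_post = 0

    def deviations():
        return Yimp - mu[:, None, :] - slope[:, None, :] * c[None, :, None]

    eye_p = np.eye(p)

    for sweep in range(total):
        pinv = 1.0 / pi

        # --- 1. data augmentation: y0 and missing weeks --------------------
        Z = deviations()  # (n, T, p); Z[:, t-1] is week t's deviation
        # y0 given z_1 and its fixed pre-sample prior
        AtPsiA = np.einsum("nkj,nk,nkl->njl", phi, pinv, phi)
        P0 = prec_y0[None] + AtPsiA
        rhs0 = np.einsum("nkj,nk->nj", phi, Z[:, 0, :] * pinv)
        y0 = _draw_mvn_prec(P0, rhs0, rng)

        Zfull = np.concatenate([y0[:, None, :], Z], axis=1)  # (n, T+1, p)
        for parity in (1, 0):
            g = groups[parity]
            ii, tt = g["full_int_i"], g["full_int_t"]
            if ii.size:
                zm1, zp1 = Zfull[ii, tt - 1], Zfull[ii, tt + 1]
                ph, pv = phi[ii], pinv[ii]
                P = np.einsum("mj,jk->mjk", pv, eye_p) + np.einsum(
                    "mkj,mk,mkl->mjl", ph, pv, ph
                )
                rhs = np.einsum("mjk,mk->mj", ph, zm1) * pv + np.einsum(
                    "mkj,mk->mj", ph, zp1 * pv
                )
                Zfull[ii, tt] = _draw_mvn_prec(P, rhs, rng)
            ii = g["full_end_i"]
            if ii.size:
                zm1 = Zfull[ii, T - 1]
                mean = np.einsum("mjk,mk->mj", phi[ii], zm1)
                Zfull[ii, T] = mean + np.sqrt(pi[ii]) * rng.standard_normal(mean.shape)
            for kind, has_fwd in (("part_int", True), ("part_end", False)):
                ii = g[f"{kind}_i"]
                if not ii.size:
                    continue
                tt = g[f"{kind}_t"] if has_fwd else np.full(ii.shape, T)
                sub = miss[ii, tt - 1]  # (m, p) which comps are missing
                for j in range(p):
                    mj = sub[:, j]
                    if not mj.any():
                        continue
                    im, tm = ii[mj], tt[mj]
                    ph, pv = phi[im], pinv[im]
                    zm1 = Zfull[im, tm - 1]
                    prec = pv[:, j].copy()
                    mean_num = np.einsum("mk,mk->m", ph[:, j, :], zm1) * pv[:, j]
                    if has_fwd:
                        zc, zp1 = Zfull[im, tm], Zfull[im, tm + 1]
                        prec = prec + np.einsum("mk,mk->m", ph[:, :, j] ** 2, pv)
                        r = zp1 - np.einsum("mkl,ml->mk", ph, zc) + ph[:, :, j] * zc[:, j : j + 1]
                        mean_num = mean_num + np.einsum("mk,mk->m", ph[:, :, j] * pv, r)
                    draw = mean_num / prec + rng.standard_normal(prec.shape) / np.sqrt(prec)
                    Zfull[im, tm, j] = draw
        y0 = Zfull[:, 0, :]
        # write imputed observations back
        imp = Zfull[:, 1:, :] + mu[:, None, :] + slope[:, None, :] * c[None, :, None]
        Yimp[miss] = imp[miss]

        # --- 2. (mu, slope) conjugate block --------------------------------
        A = eye_p[None] - phi  # (n, p, p)
        PsiA = pinv[:, :, None] * A
        AtPsiA_ = np.einsum("nlj,nlk->njk", A, PsiA)
        AtPsi = np.swapaxes(PsiA, 1, 2)  # (A^T Psi^-1)_{jl}
        AtPsiPhi = np.einsum("nlj,nl,nlk->njk", A, pinv, phi)
        PsiPhi = pinv[:, :, None] * phi
        PhitPsiPhi = np.einsum("nlj,nl,nlk->njk", phi, pinv, phi)
        diag_pinv = pinv[:, :, None] * eye_p[None]

        UL = (T - 1) * AtPsiA_ + diag_pinv
        UR = S_ct * AtPsi - S_ctm1 * AtPsiPhi + c1 * diag_pinv
        LR = (
            S_ctt * diag_pinv
            - S_cttm1 * (PsiPhi + np.swapaxes(PsiPhi, 1, 2))
            + S_cmm * PhitPsiPhi
            + c1 * c1 * diag_pinv
        )
        a1 = Yimp[:, 0, :] - np.einsum("njk,nk->nj", phi, y0)
        a_rest = Yimp[:, 1:, :] - np.einsum("njk,ntk->ntj", phi, Yimp[:, :-1, :])
        Sa = a_rest.sum(axis=1)
        Sca = np.einsum("t,ntj->nj", ct, a_rest)
        Scm1a = np.einsum("t,ntj->nj", ctm1, a_rest)
        b_top = np.einsum("nlj,nl->nj", A, pinv * Sa) + pinv * a1
        b_bot = pinv * Sca - np.einsum("nlj,nl->nj", phi, pinv * Scm1a) + c1 * (pinv * a1)

        lik_prec = np.empty((n, 2 * p, 2 * p))
        lik_prec[:, :p, :p] = UL
        lik_prec[:, :p, p:] = UR
        lik_prec[:, p:, :p] = np.swapaxes(UR, 1, 2)
        lik_prec[:, p:, p:] = LR
        b = np.concatenate([b_top, b_bot], axis=1)

        m_all = gamma[None, :] + (X @ Bmat.T if k else 0.0)
        Qc = lam[np.ix_(idx_ms, idx_ms)]
        cross = lam[np.ix_(idx_ms, rest_ms)]
        d = eta[:, rest_ms] - m_all[:, rest_ms]
        rhs = m_all[:, idx_ms] @ Qc.T - d @ cross.T + b
        theta = _draw_mvn_prec(Qc[None] + lik_prec, rhs, rng)
        mu, slope = theta[:, :p], theta[:, p:]
        eta[:, idx_mu], eta[:, idx_slope] = mu, slope

        # --- 3. lag matrix conjugate block (stationarity by rejection) -----
        Z = deviations()
        Zfull = np.concatenate([y0[:, None, :], Z], axis=1)
        Zl, Zc = Zfull[:, :T, :], Zfull[:, 1:, :]
        Sz = np.einsum("ntj,ntk->njk", Zl, Zl)
        R = np.einsum("ntj,ntk->njk", Zc, Zl)
        lik_prec = np.zeros((n, p * p, p * p))
        for j in range(p):
            lik_prec[:, j * p : (j + 1) * p, j * p : (j + 1) * p] = Sz * pinv[:, j, None, None]
        b = (R * pinv[:, :, None]).reshape(n, p * p)
        Qc = lam[np.ix_(idx_phi, idx_phi)]
        cross = lam[np.ix_(idx_phi, rest_phi)]
        d = eta[:, rest_phi] - m_all[:, rest_phi]
        rhs = m_all[:, idx_phi] @ Qc.T - d @ cross.T + b
        f = _draw_mvn_prec(Qc[None] + lik_prec, rhs, rng)
        cand = f.reshape(n, p, p)
        if p == 1:
            ok = np.abs(cand[:, 0, 0]) < 1.0
        else:
            ok = batch_spectral_radius(cand) < 1.0
        phi = np.where(ok[:, None, None], cand, phi)
        if sweep >= config.burn:
            phi_rej_post += int((~ok).sum())
        eta[:, idx_phi] = phi.reshape(n, -1)

        # --- 4. log innovation variances: adaptive RW Metropolis -----------
        resid = Zc - np.einsum("njk,ntk->ntj", phi, Zl)
        SSE = np.einsum("ntj,ntj->nj", resid, resid)
        acc_this = np.zeros(p)
        for j in range(p):
            iglob = idx_logv[j]
            rest_j = np.setdiff1d(np.arange(q), [iglob])
            lam_jj = lam[iglob, iglob]
            cross_v = lam[iglob, rest_j]
            mc = m_all[:, iglob] - (eta[:, rest_j] - m_all[:, rest_j]) @ cross_v / lam_jj
            cur = logv[:, j]
            prop = cur + step[:, j] * rng.standard_normal(n)

            def logpost(lv):
                return -0.5 * (T * lv + SSE[:, j] * np.exp(-lv)) - 0.5 * lam_jj * (lv - mc) ** 2

            log_alpha = logpost(prop) - logpost(cur)
            accept = np.log(rng.random(n)) < log_alpha
            logv[:, j] = np.where(accept, prop, cur)
            acc_this[j] = accept.mean()
            if sweep < config.burn:
                step[:, j] *= np.exp(_ADAPT_RATE * (accept.astype(float) - _TARGET_ACCEPT))
        pi = np.exp(logv)
        eta[:, idx_logv] = logv
        if sweep >= config.burn:
            acc_sum += acc_this
            acc_count += 1

        # --- 5. fixed effects and covariate coefficients --------------------
        prec = np.kron(WtW, lam) + np.diag(prior_prec_theta)
        rhs = (lam @ (eta.T @ W)).ravel(order="F")
        cho = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        noise = np.linalg.solve(cho.T, rng.standard_normal(mean.shape))
        vec_theta = mean + noise
        Theta = vec_theta.reshape(q, k + 1, order="F")
        gamma = Theta[:, 0]
        if k:
            Bmat = Theta[:, 1:]

        # --- 6. random-effect covariance (Huang-Wand hierarchical IW) -------
        m_all = gamma[None, :] + (X @ Bmat.T if k else 0.0)
        u = eta - m_all
        scale = 2.0 * _HW_NU * np.diag(1.0 / hw_a) + u.T @ u
        scale = (scale + scale.T) / 2
        omega = invwishart.rvs(df=_HW_NU + q - 1 + n, scale=scale, random_state=rng)
        omega = np.atleast_2d(omega)
        omega = (omega + omega.T) / 2
        lam = np.linalg.inv(omega)
        # a_k | Omega ~ inverse-gamma((nu + q)/2, nu (Omega^-1)_kk + 1/A^2)
        rate_a = _HW_NU * np.diag(lam) + 1.0 / _HW_SCALE**2
        hw_a = rate_a / rng.gamma((_HW_NU + q) / 2.0, 1.0, size=q)

        if sweep >= config.burn:
            s = sweep - config.burn
            out_gamma[s] = gamma
            if k:
                out_B[s] = Bmat
            out_omega[s] = omega
            if out_eta is not None:
                out_eta[s] = eta
        if progress is not None and (sweep + 1) % 500 == 0:
            progress(sweep + 1, total)

    return ChainDraws(
        gamma=out_gamma,
        B=out_B,
        omega=out_omega,
        eta=out_eta,
        accept_rate=acc_sum / max(acc_count, 1),
        n_phi_rejections=phi_rej_post,
    )
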