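"""Low-level MCMC chain kernels (numba-compiled when available).

Both kernels are adaptive random-walk Metropolis-within-Gibbs samplers:
one coordinate at a time, Gaussian proposals whose log step sizes are tuned
toward a 0.44 per-coordinate acceptance rate during burn-in and frozen
afterwards.  They are deliberately free of Python objects so that numba can
compile them; the public fitting API lives in :mod:`cshazard.mcmc`.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _softplus(x):
    if x > 30.0:
        return x
    return math.log1p(math.exp(x))


@njit(cache=True)
def logistic_chain(Xt, y, w, L, theta0, eta0, prior_prec,
                   n_iter, burn_in, thin, seed, step0):
    """One chain for Bayesian logistic regression.

    Sampling runs in rotated coordinates ``phi`` with ``theta = theta0 +
    L @ phi`` (L a Cholesky preconditioner), so coordinate-wise proposals
    mix even when design columns are strongly correlated.  The diffuse
    normal prior (precision ``prior_prec``) applies to ``theta``.
    Returns (kept theta draws, kept deviances, final acceptance rates).
    """
    n, p = Xt.shape
    np.random.seed(seed)
    phi = np.zeros(p)
    theta = theta0.copy()
    eta = eta0.copy()
    lstep = np.zeros(p)
    for j in range(p):
        lstep[j] = math.log(step0)
    acc = np.zeros(p)
    n_keep = 0
    it = burn_in
    while it < n_iter:
        n_keep += 1
        it += thin
    thetas = np.empty((n_keep, p))
    devs = np.empty(n_keep)

    ll = 0.0
    for i in range(n):
        ll += w[i] * (y[i] * eta[i] - _softplus(eta[i]))

    keep_idx = 0
    batch = 0
    for it in range(n_iter):
        for j in range(p):
            delta = math.exp(lstep[j]) * np.random.normal()
            dll = 0.0
            for i in range(n):
                step_e = Xt[i, j] * delta
                dll += w[i] * (y[i] * step_e
                               - (_softplus(eta[i] + step_e) - _softplus(eta[i])))
            dlp = 0.0
            for k in range(p):
                t_new = theta[k] + L[k, j] * delta
                dlp += -0.5 * prior_prec * (t_new * t_new - theta[k] * theta[k])
            if math.log(np.random.random()) < dll + dlp:
                for i in range(n):
                    eta[i] += Xt[i, j] * delta
                for k in range(p):
                    theta[k] += L[k, j] * delta
                phi[j] += delta
                ll += dll
                acc[j] += 1.0
        if it < burn_in and (it + 1) % 50 == 0:
            batch += 1
            gain = min(0.25, 2.0 / math.sqrt(batch))
            for j in range(p):
                rate = acc[j] / 50.0
                if rate > 0.44:
                    lstep[j] += gain
                else:
                    lstep[j] -= gain
                acc[j] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0:
            for k in range(p):
                thetas[keep_idx, k] = theta[k]
            devs[keep_idx] = -2.0 * ll
            keep_idx += 1
    rates = acc / max(n_iter - burn_in, 1)
    return thetas, devs, rates


@njit(cache=True)
def _ph_loglik_from_H(Hc, pi, m_case, m_ctrl):
    nb = Hc.shape[0]
    ll = 0.0
    for k in range(nb):
        if m_ctrl[k] > 0.0:
            sp = pi + (1.0 - pi) * math.exp(-Hc[k])
            if sp <= 0.0:
                return -1e18
            ll += m_ctrl[k] * math.log(sp)
        if m_case[k] > 0.0:
            fp = (1.0 - pi) * (-math.expm1(-Hc[k]))
            if fp <= 0.0:
                return -1e18
            ll += m_case[k] * math.log(fp)
    return ll


@njit(cache=True)
def _delta_loglik(Hc, j, delta, pi, m_case, m_ctrl):
    """Change in log-likelihood when bin j's rate shifts H by ``delta``
    for every bin >= j."""
    nb = Hc.shape[0]
    dll = 0.0
    for k in range(j, nb):
        h_old = Hc[k]
        h_new = Hc[k] + delta
        if m_ctrl[k] > 0.0:
            sp_new = pi + (1.0 - pi) * math.exp(-h_new)
            sp_old = pi + (1.0 - pi) * math.exp(-h_old)
            if sp_new <= 0.0:
                return -1e18
            dll += m_ctrl[k] * (math.log(sp_new) - math.log(sp_old))
        if m_case[k] > 0.0:
            fp_new = (1.0 - pi) * (-math.expm1(-h_new))
            fp_old = (1.0 - pi) * (-math.expm1(-h_old))
            if fp_new <= 0.0:
                return -1e18
            dll += m_case[k] * (math.log(fp_new) - math.log(fp_old))
    return dll


@njit(cache=True)
def _rate_prior_sum(lam, loglam, alpha, beta0, first_scale):
    """Log prior of the whole rate chain given (alpha, beta0), including the
    normalizing constants that depend on alpha/beta0 (needed for hyperparameter
    updates), excluding the log-scale Jacobian."""
    nb = lam.shape[0]
    rate0 = (1.0 / beta0) if first_scale else beta0
    lp = (alpha * math.log(rate0) - math.lgamma(alpha)
          + (alpha - 1.0) * loglam[0] - rate0 * lam[0])
    lg = math.lgamma(alpha)
    for t in range(1, nb):
        r = alpha / lam[t - 1]
        lp += alpha * math.log(r) - lg + (alpha - 1.0) * loglam[t] - r * lam[t]
    return lp


@njit(cache=True)
def ph_chain(m_case, m_ctrl, loglam_init, alpha_init, beta0_init, pi_init,
             sample_alpha, sample_beta0, with_cure, first_scale,
             alpha_lo, alpha_hi, beta0_lo, beta0_hi,
             n_iter, burn_in, thin, seed):
    """One chain for the piecewise-constant hazard with the correlated
    gamma (martingale) prior process, optionally with a cure fraction.

    Grouped current-status data enter as weighted case/control counts by
    exposure (``m_case[k]``/``m_ctrl[k]`` = subjects whose observation age
    spans k+1 one-year bins).  Rates are sampled on the log scale; alpha,
    beta0 and pi are random-walk updates rejected outside their uniform
    prior supports.  Returns kept draws ``(lam..., alpha, beta0, pi)``,
    deviances, and acceptance rates.
    """
    nb = m_case.shape[0]
    np.random.seed(seed)
    loglam = loglam_init.copy()
    lam = np.exp(loglam)
    alpha = alpha_init
    beta0 = beta0_init
    pi = pi_init
    Hc = np.cumsum(lam)

    n_coord = nb + 3  # rates + alpha + beta0 + pi
    lstep = np.full(n_coord, math.log(0.5))
    lstep[nb] = math.log(5.0)        # alpha lives on [10, 100]
    lstep[nb + 1] = math.log(0.002)  # beta0 lives on [0.001, 0.01]
    lstep[nb + 2] = math.log(0.05)   # pi lives on [0, 1]
    acc = np.zeros(n_coord)

    cur_ll = _ph_loglik_from_H(Hc, pi, m_case, m_ctrl)

    n_keep = 0
    it = burn_in
    while it < n_iter:
        n_keep += 1
        it += thin
    draws = np.empty((n_keep, nb + 3))
    devs = np.empty(n_keep)

    keep_idx = 0
    batch = 0
    for it in range(n_iter):
        # ---- rate coordinates (log scale) -------------------------------
        for j in range(nb):
            x_old = loglam[j]
            x_new = x_old + math.exp(lstep[j]) * np.random.normal()
            l_old = lam[j]
            l_new = math.exp(x_new)
            delta = l_new - l_old
            dll = _delta_loglik(Hc, j, delta, pi, m_case, m_ctrl)
            # prior terms touching lambda_j: own term plus successor's
            if j == 0:
                r_in = (1.0 / beta0) if first_scale else beta0
            else:
                r_in = alpha / lam[j - 1]
            dlp = (alpha - 1.0) * (x_new - x_old) - r_in * delta
            if j + 1 < nb:
                # successor term: alpha*log(alpha/lam_j) - (alpha/lam_j)*lam_{j+1}
                dlp += -alpha * (x_new - x_old) \
                    - alpha * lam[j + 1] * (1.0 / l_new - 1.0 / l_old)
            djac = x_new - x_old
            if math.log(np.random.random()) < dll + dlp + djac:
                loglam[j] = x_new
                lam[j] = l_new
                for k in range(j, nb):
                    Hc[k] += delta
                cur_ll += dll
                acc[j] += 1.0
        # ---- alpha ------------------------------------------------------
        if sample_alpha:
            a_new = alpha + math.exp(lstep[nb]) * np.random.normal()
            if alpha_lo <= a_new <= alpha_hi:
                dlp = (_rate_prior_sum(lam, loglam, a_new, beta0, first_scale)
                       - _rate_prior_sum(lam, loglam, alpha, beta0, first_scale))
                if math.log(np.random.random()) < dlp:
                    alpha = a_new
                    acc[nb] += 1.0
        # ---- beta0 ------------------------------------------------------
        if sample_beta0:
            b_new = beta0 + math.exp(lstep[nb + 1]) * np.random.normal()
            if beta0_lo <= b_new <= beta0_hi:
                r_old = (1.0 / beta0) if first_scale else beta0
                r_new = (1.0 / b_new) if first_scale else b_new
                dlp = alpha * (math.log(r_new) - math.log(r_old)) \
                    - (r_new - r_old) * lam[0]
                if math.log(np.random.random()) < dlp:
                    beta0 = b_new
                    acc[nb + 1] += 1.0
        # ---- pi ---------------------------------------------------------
        if with_cure:
            p_new = pi + math.exp(lstep[nb + 2]) * np.random.normal()
            if 0.0 <= p_new < 1.0:
                ll_new = _ph_loglik_from_H(Hc, p_new, m_case, m_ctrl)
                if math.log(np.random.random()) < ll_new - cur_ll:
                    pi = p_new
                    cur_ll = ll_new
                    acc[nb + 2] += 1.0
        # ---- adaptation / bookkeeping -----------------------------------
        if it < burn_in and (it + 1) % 50 == 0:
            batch += 1
            gain = min(0.25, 2.0 / math.sqrt(batch))
            for j in range(n_coord):
                rate = acc[j] / 50.0
                if rate > 0.44:
                    lstep[j] += gain
                else:
                    lstep[j] -= gain
                acc[j] = 0.0
        if (it + 1) % 1000 == 0:  # refresh against numerical drift
            Hc = np.cumsum(lam)
            cur_ll = _ph_loglik_from_H(Hc, pi, m_case, m_ctrl)
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(nb):
                draws[keep_idx, j] = lam[j]
            draws[keep_idx, nb] = alpha
            draws[keep_idx, nb + 1] = beta0
            draws[keep_idx, nb + 2] = pi
            devs[keep_idx] = -2.0 * cur_ll
            keep_idx += 1
    rates = acc / max(n_iter - burn_in, 1)
    return draws, devs, rates


@njit(cache=True)
def gamma_process_step_draws(lam_t, alpha, n_draws, seed):
    """Draws of lambda(t+1) | lambda(t) from the correlated gamma prior:
    Gamma(shape=alpha, rate=alpha/lambda_t), so the mean is lambda_t."""
    np.random.seed(seed)
    out = np.empty(n_draws)
    scale = lam_t / alpha
    for i in range(n_draws):
        out[i] = np.random.gamma(alpha, scale)
    return out
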