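"""Numba kernels: Wiener first-passage density, likelihoods, sampler, simulator.

Everything here operates on plain float64 arrays; the public modules wrap
these kernels with validated dataclasses. The diffusion coefficient is fixed
at 1 throughout (the convention under which uniform priors of a few units on
the drift weights are sensible).

Parameter vector layout (always length 6):
    attribute model: [beta_intercept, beta_reward, beta_distance, alpha, zeta, tau]
    option model:    [beta_temperature, log_k, v_lim,             alpha, zeta, tau]
zeta is the *relative* starting point (fraction of alpha).
"""

import numpy as np
from numba import njit

# truncation error bound for the infinite-series density
SERIES_EPS = 1e-8

MODEL_ATTRIBUTE = 0
MODEL_OPTION = 1


@njit(cache=True)
def wiener_logpdf_lower(td, nu, alpha, zeta, eps):
    """Log density of hitting the *lower* boundary at decision time ``td``.

    Small-time / large-time series with adaptive truncation: the number of
    terms is chosen so the truncation error of the scaled density is below
    ``eps``, and the cheaper of the two expansions is used.
    """
    if td <= 0.0:
        return -np.inf
    u = td / (alpha * alpha)  # normalized time

    # terms needed by the small-time expansion
    if 2.0 * np.sqrt(2.0 * np.pi * u) * eps < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * np.sqrt(2.0 * np.pi * u) * eps))
        if ks < np.sqrt(u) + 1.0:
            ks = np.sqrt(u) + 1.0
    else:
        ks = 2.0
    # terms needed by the large-time expansion
    if np.pi * u * eps < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * u * eps) / (np.pi * np.pi * u))
        if kl < 1.0 / (np.pi * np.sqrt(u)):
            kl = 1.0 / (np.pi * np.sqrt(u))
    else:
        kl = 1.0 / (np.pi * np.sqrt(u))

    if ks < kl:  # small-time expansion
        K = int(np.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) - (K - 1) // 2
        s = 0.0
        for k in range(lo, hi + 1):
            z = zeta + 2.0 * k
            s += z * np.exp(-z * z / (2.0 * u))
        f1 = s / np.sqrt(2.0 * np.pi * u * u * u)
    else:  # large-time expansion
        K = int(np.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * zeta)
        f1 = np.pi * s
    if f1 < 1e-300:
        f1 = 1e-300
    return -nu * alpha * zeta - nu * nu * td / 2.0 - 2.0 * np.log(alpha) + np.log(f1)


@njit(cache=True)
def wiener_logpdf(rt, upper, nu, alpha, zeta, tau, eps):
    """Log density of (boundary, rt); upper obtained by reflection nu->-nu, zeta->1-zeta."""
    td = rt - tau
    if td <= 0.0:
        return -np.inf
    if upper:
        return wiener_logpdf_lower(td, -nu, alpha, 1.0 - zeta, eps)
    return wiener_logpdf_lower(td, nu, alpha, zeta, eps)


@njit(cache=True)
def upper_prob(nu, alpha, zeta):
    """Probability of absorption at the upper boundary (closed form)."""
    x = -2.0 * nu * alpha
    if np.abs(x) < 1e-12:
        return zeta
    # expm1 keeps the ratio stable for small |nu|
    return np.expm1(x * zeta) / np.expm1(x)


@njit(cache=True)
def compute_drifts(params, model_id, include_intercept, include_sigmoid,
                   rdiff, ddiff, m_close, d_close, m_distant, d_distant, out):
    n = rdiff.size
    if model_id == MODEL_ATTRIBUTE:
        b0 = params[0] if include_intercept else 0.0
        for i in range(n):
            out[i] = b0 + params[1] * rdiff[i] + params[2] * ddiff[i]
    else:
        b_temp = params[0]
        k = np.exp(params[1])
        v_lim = params[2]
        for i in range(n):
            sv_d = m_distant[i] / (1.0 + k * d_distant[i])
            sv_c = m_close[i] / (1.0 + k * d_close[i])
            vp = b_temp * (sv_d - sv_c)
            if include_sigmoid:
                out[i] = 2.0 * v_lim / (1.0 + np.exp(-vp)) - v_lim
            else:
                out[i] = vp
    return out


@njit(cache=True)
def loglik_pointwise(params, model_id, include_intercept, include_sigmoid, choice_only,
                     rdiff, ddiff, m_close, d_close, m_distant, d_distant,
                     upper, rt, eps, nu_buf, out_ll):
    """Per-trial log likelihood; returns the total. ``upper`` is int8 (1=distant)."""
    n = rt.size
    if choice_only:
        # binary-choice Bernoulli model: logistic of the raw value comparison
        # (no sigmoid transform, no diffusion parameters)
        compute_drifts(params, model_id, include_intercept, False,
                       rdiff, ddiff, m_close, d_close, m_distant, d_distant, nu_buf)
        total = 0.0
        for i in range(n):
            x = nu_buf[i]
            # log sigmoid, stable both directions
            if x >= 0.0:
                lp = -np.log1p(np.exp(-x))
                lq = -x - np.log1p(np.exp(-x))
            else:
                lp = x - np.log1p(np.exp(x))
                lq = -np.log1p(np.exp(x))
            ll = lp if upper[i] == 1 else lq
            out_ll[i] = ll
            total += ll
        return total
    compute_drifts(params, model_id, include_intercept, include_sigmoid,
                   rdiff, ddiff, m_close, d_close, m_distant, d_distant, nu_buf)
    alpha = params[3]
    zeta = params[4]
    tau = params[5]
    total = 0.0
    for i in range(n):
        ll = wiener_logpdf(rt[i], upper[i] == 1, nu_buf[i], alpha, zeta, tau, eps)
        out_ll[i] = ll
        total += ll
    return total


@njit(cache=True)
def _safe_cholesky(A):
    """Lower Cholesky with a success flag (no exceptions under numba)."""
    n = A.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def mh_gibbs_sample(model_id, include_intercept, include_sigmoid, choice_only,
                    rdiff, ddiff, m_close, d_close, m_distant, d_distant,
                    upper, rt, lb, ub, mask, fixed,
                    n_chains, n_keep, n_burn, seed, eps):
    """Adaptive Metropolis-within-Gibbs under uniform box priors.

    Per-parameter Gaussian random-walk proposals, Robbins-Monro tuned toward
    0.44 acceptance during burn-in and frozen afterwards. The second half of
    burn-in additionally estimates the posterior covariance of the sampled
    block, which then drives one joint (blocked) Metropolis proposal per
    sweep -- this speeds mixing along the correlated drift-weight directions.
    Out-of-box proposals are rejected (the uniform prior has zero density
    there).

    Returns (draws[chains, keep, 6], loglik[trials, chains*keep], accept_rate[6]).
    """
    p = 6
    n = rt.size
    draws = np.empty((n_chains, n_keep, p))
    ll_mat = np.empty((n, n_chains * n_keep))
    acc_count = np.zeros(p)
    acc_total = np.zeros(p)
    nu_buf = np.empty(n)
    cur_ll = np.empty(n)
    prop_ll = np.empty(n)

    for c in range(n_chains):
        np.random.seed(seed + 1000003 * c)
        x = np.empty(p)
        cur_total = -np.inf
        # draw a starting point with finite likelihood from the central prior box
        for attempt in range(200):
            for j in range(p):
                if mask[j]:
                    x[j] = lb[j] + (0.25 + 0.5 * np.random.random()) * (ub[j] - lb[j])
                else:
                    x[j] = fixed[j]
            cur_total = loglik_pointwise(
                x, model_id, include_intercept, include_sigmoid, choice_only,
                rdiff, ddiff, m_close, d_close, m_distant, d_distant,
                upper, rt, eps, nu_buf, cur_ll)
            if np.isfinite(cur_total):
                break
        log_step = np.empty(p)
        for j in range(p):
            log_step[j] = np.log(0.1 * (ub[j] - lb[j]) + 1e-12)

        # sampled-dimension index for the blocked proposal
        dims = np.empty(p, dtype=np.int64)
        d = 0
        for j in range(p):
            if mask[j]:
                dims[d] = j
                d += 1
        w_count = 0
        w_mean = np.zeros(d)
        w_m2 = np.zeros((d, d))
        chol = np.zeros((d, d))
        have_chol = False
        joint_scale = 2.38 * 2.38 / max(d, 1)

        total_iter = n_burn + n_keep
        for t in range(total_iter):
            for j in range(p):
                if not mask[j]:
                    continue
                old = x[j]
                prop = old + np.exp(log_step[j]) * np.random.standard_normal()
                accepted = False
                if lb[j] <= prop <= ub[j]:
                    x[j] = prop
                    prop_total = loglik_pointwise(
                        x, model_id, include_intercept, include_sigmoid, choice_only,
                        rdiff, ddiff, m_close, d_close, m_distant, d_distant,
                        upper, rt, eps, nu_buf, prop_ll)
                    if np.log(np.random.random()) < prop_total - cur_total:
                        accepted = True
                        cur_total = prop_total
                        for i in range(n):
                            cur_ll[i] = prop_ll[i]
                    else:
                        x[j] = old
                if t < n_burn:
                    gamma = 2.0 / np.sqrt(t + 1.0)
                    if gamma > 0.25:
                        gamma = 0.25
                    log_step[j] += gamma * ((1.0 if accepted else 0.0) - 0.44)
                    if log_step[j] < -12.0:
                        log_step[j] = -12.0
                    elif log_step[j] > 4.0:
                        log_step[j] = 4.0
                else:
                    acc_total[j] += 1.0
                    if accepted:
                        acc_count[j] += 1.0
            # covariance accumulation over the second half of burn-in
            if n_burn // 2 <= t < n_burn:
                w_count += 1
                for a_i in range(d):
                    da = x[dims[a_i]] - w_mean[a_i]
                    w_mean[a_i] += da / w_count
                    for b_i in range(a_i + 1):
                        w_m2[a_i, b_i] += da * (x[dims[b_i]] - w_mean[b_i])
            if t == n_burn - 1 and w_count > 2 * d:
                cov = np.empty((d, d))
                for a_i in range(d):
                    for b_i in range(a_i + 1):
                        cv = joint_scale * w_m2[a_i, b_i] / (w_count - 1)
                        cov[a_i, b_i] = cv
                        cov[b_i, a_i] = cv
                    cov[a_i, a_i] += 1e-12 + 1e-8 * cov[a_i, a_i]
                chol, have_chol = _safe_cholesky(cov)
            # one joint blocked proposal per sweep once the kernel is frozen
            if have_chol and t >= n_burn:
                ok = True
                xprop = x.copy()
                z = np.empty(d)
                for a_i in range(d):
                    z[a_i] = np.random.standard_normal()
                for a_i in range(d):
                    step = 0.0
                    for b_i in range(a_i + 1):
                        step += chol[a_i, b_i] * z[b_i]
                    j = dims[a_i]
                    xprop[j] = x[j] + step
                    if xprop[j] < lb[j] or xprop[j] > ub[j]:
                        ok = False
                if ok:
                    prop_total = loglik_pointwise(
                        xprop, model_id, include_intercept, include_sigmoid,
                        choice_only, rdiff, ddiff, m_close, d_close, m_distant,
                        d_distant, upper, rt, eps, nu_buf, prop_ll)
                    if np.log(np.random.random()) < prop_total - cur_total:
                        cur_total = prop_total
                        for j in range(p):
                            x[j] = xprop[j]
                        for i in range(n):
                            cur_ll[i] = prop_ll[i]
            if t >= n_burn:
                idx = t - n_burn
                for j in range(p):
                    draws[c, idx, j] = x[j]
                col = c * n_keep + idx
                for i in range(n):
                    ll_mat[i, col] = cur_ll[i]

    acc_rate = np.empty(p)
    for j in range(p):
        acc_rate[j] = acc_count[j] / acc_total[j] if acc_total[j] > 0 else np.nan
    return draws, ll_mat, acc_rate


@njit(cache=True)
def simulate_walks(nu, alpha, zeta, tau, dt, t_max, seed):
    """Euler-Maruyama simulation of one diffusion per entry of ``nu``.

    A Brownian-bridge crossing check between consecutive Euler points removes
    most of the O(sqrt(dt)) boundary-crossing bias of the plain scheme.

    Returns (boundary int8: 1 upper / 0 lower / -1 censored at t_max, rt
    including non-decision time).
    """
    n = nu.size
    boundary = np.empty(n, dtype=np.int8)
    rts = np.empty(n)
    sdt = np.sqrt(dt)
    np.random.seed(seed)
    for i in range(n):
        a = alpha[i]
        x = zeta[i] * a
        v = nu[i]
        t = 0.0
        b = np.int8(-1)
        while t < t_max:
            x_old = x
            x += v * dt + sdt * np.random.standard_normal()
            t += dt
            if x >= a:
                b = np.int8(1)
                break
            if x <= 0.0:
                b = np.int8(0)
                break
            # bridge probability of an unobserved excursion across a boundary
            p_up = np.exp(-2.0 * (a - x_old) * (a - x) / dt)
            p_lo = np.exp(-2.0 * x_old * x / dt)
            u = np.random.random()
            if u < p_up:
                b = np.int8(1)
                break
            if u < p_up + p_lo:
                b = np.int8(0)
                break
        boundary[i] = b
        rts[i] = tau[i] + t
    return boundary, rts
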