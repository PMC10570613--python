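"""Gradient-based MCMC engine.

Two samplers share one algorithm (Hamiltonian Monte Carlo with a
dual-averaging step-size schedule, diagonal mass-matrix adaptation in the
middle warmup window, jittered leapfrog trajectory lengths, and a
1000-unit energy-error divergence threshold):

* :func:`hmc_sample` — generic single-chain driver for any Python callable
  ``potential(x) -> (U, grad)`` where ``U = -log posterior``.  Used for
  small bespoke models (e.g. the bivariate intercept-correlation model) and
  for closed-form validation targets.
* :func:`glmm_chain` — numba-compiled chain for the two crossed
  random-intercept likelihoods (Gaussian reaction times, lapse-rate
  logistic accuracy), with analytic gradients.  Parameter layout on the
  unconstrained scale::

      [fixed effects (k), log sigma_participant, log sigma_item,
       log sigma_resid | logit p_miss, z_participant (n_p), z_item (n_i)]

  Random intercepts are non-centred: the deviation for participant j is
  ``sigma_participant * z_participant[j]``.

Priors baked into the GLMM potential: fixed effects N(0, scale_j^2);
sigmas Gamma(shape, rate) (density ``s^(shape-1) exp(-rate s)``); lapse
rate Beta(a, b).  All include the log-transform Jacobians.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Leapfrog energy error beyond which a trajectory is counted as divergent.
MAX_ENERGY_ERROR = 1000.0

GAUSSIAN_RT = 0
LAPSE_LOGISTIC = 1

# dual-averaging constants (Hoffman & Gelman 2014)
_DA_GAMMA = 0.05
_DA_T0 = 10.0
_DA_KAPPA = 0.75


@njit(cache=True, error_model="numpy")
def glmm_potential(kind, x, y, g, c, pidx, iidx, n_p, n_i, k, fixed_scales, prior, grad):
    """Negative log posterior and its gradient (written into ``grad``).

    ``prior = [sigma_shape, sigma_rate, pmiss_alpha, pmiss_beta]``.
    """
    d = x.shape[0]
    for j in range(d):
        grad[j] = 0.0
    n = y.shape[0]
    log_sp = x[k]
    log_si = x[k + 1]
    extra = x[k + 2]
    sp = np.exp(log_sp)
    si = np.exp(log_si)
    zp_off = k + 3
    zi_off = k + 3 + n_p
    acc_p = np.zeros(n_p)
    acc_i = np.zeros(n_i)
    L = 0.0

    if kind == GAUSSIAN_RT:
        sr = np.exp(extra)
        inv_v = 1.0 / (sr * sr)
        sum_r2 = 0.0
        for t in range(n):
            mu = x[0] + x[1] * g[t]
            if k == 4:
                mu += x[2] * c[t] + x[3] * g[t] * c[t]
            mu += sp * x[zp_off + pidx[t]] + si * x[zi_off + iidx[t]]
            r = y[t] - mu
            sum_r2 += r * r
            w = r * inv_v
            grad[0] += w
            grad[1] += w * g[t]
            if k == 4:
                grad[2] += w * c[t]
                grad[3] += w * g[t] * c[t]
            acc_p[pidx[t]] += w
            acc_i[iidx[t]] += w
        L += -n * extra - 0.5 * sum_r2 * inv_v
        grad[k + 2] = -n + sum_r2 * inv_v + (prior[0] - prior[1] * sr)
        L += prior[0] * extra - prior[1] * sr
    else:
        pm = 1.0 / (1.0 + np.exp(-extra))
        half_minus = 0.5 - pm
        dpm_acc = 0.0
        for t in range(n):
            eta = x[0] + x[1] * g[t]
            if k == 4:
                eta += x[2] * c[t] + x[3] * g[t] * c[t]
            eta += sp * x[zp_off + pidx[t]] + si * x[zi_off + iidx[t]]
            pe = 1.0 / (1.0 + np.exp(-eta))
            P = 0.5 + half_minus * pe
            if P < 1e-12:
                P = 1e-12
            elif P > 1.0 - 1e-12:
                P = 1.0 - 1e-12
            if y[t] > 0.5:
                L += np.log(P)
                w = 1.0 / P
            else:
                L += np.log(1.0 - P)
                w = -1.0 / (1.0 - P)
            deta = w * half_minus * pe * (1.0 - pe)
            grad[0] += deta
            grad[1] += deta * g[t]
            if k == 4:
                grad[2] += deta * c[t]
                grad[3] += deta * g[t] * c[t]
            acc_p[pidx[t]] += deta
            acc_i[iidx[t]] += deta
            dpm_acc += w * (-pe)
        grad[k + 2] = dpm_acc * pm * (1.0 - pm) + (prior[2] - (prior[2] + prior[3]) * pm)
        L += prior[2] * np.log(pm) + prior[3] * np.log(1.0 - pm)

    dot_p = 0.0
    for j in range(n_p):
        zj = x[zp_off + j]
        grad[zp_off + j] = sp * acc_p[j] - zj
        dot_p += zj * acc_p[j]
        L += -0.5 * zj * zj
    dot_i = 0.0
    for j in range(n_i):
        zj = x[zi_off + j]
        grad[zi_off + j] = si * acc_i[j] - zj
        dot_i += zj * acc_i[j]
        L += -0.5 * zj * zj

    grad[k] = sp * dot_p + (prior[0] - prior[1] * sp)
    grad[k + 1] = si * dot_i + (prior[0] - prior[1] * si)
    L += prior[0] * log_sp - prior[1] * sp
    L += prior[0] * log_si - prior[1] * si

    for j in range(k):
        s2 = fixed_scales[j] * fixed_scales[j]
        L += -0.5 * x[j] * x[j] / s2
        grad[j] += -x[j] / s2

    for j in range(d):
        grad[j] = -grad[j]
    return -L


@njit(cache=True, error_model="numpy")
def glmm_chain(
    kind,
    y,
    g,
    c,
    pidx,
    iidx,
    n_p,
    n_i,
    k,
    fixed_scales,
    prior,
    x0,
    n_warmup,
    n_draws,
    target_accept,
    seed,
    integration_time,
    max_leapfrog,
):
    """Run one HMC chain for a GLMM potential; returns (draws, n_divergent).

    ``n_divergent`` counts post-warmup divergences only.  Fully
    deterministic given ``seed``.
    """
    np.random.seed(seed)
    d = x0.shape[0]
    x = x0.copy()
    grad = np.zeros(d)
    grad_new = np.zeros(d)
    U = glmm_potential(kind, x, y, g, c, pidx, iidx, n_p, n_i, k, fixed_scales, prior, grad)

    inv_mass = np.ones(d)
    sqrt_mass = np.ones(d)
    eps = 0.1
    mu_da = np.log(10.0 * eps)
    log_eps_bar = np.log(eps)
    h_bar = 0.0
    m_da = 0

    w1 = n_warmup // 2
    w2 = (9 * n_warmup) // 10
    wf_mean = np.zeros(d)
    wf_m2 = np.zeros(d)
    n_w = 0

    draws = np.zeros((n_draws, d))
    n_div = 0
    total = n_warmup + n_draws

    for it in range(total):
        if it == n_warmup:
            eps = np.exp(log_eps_bar)

        p = np.empty(d)
        K = 0.0
        for j in range(d):
            p[j] = np.random.normal() * sqrt_mass[j]
            K += 0.5 * p[j] * p[j] * inv_mass[j]
        H0 = U + K

        ratio = integration_time / eps
        if ratio > max_leapfrog:
            L_base = max_leapfrog
        elif ratio < 1.0:
            L_base = 1
        else:
            L_base = int(ratio) + 1
        lo = L_base // 2
        if lo < 1:
            lo = 1
        L_steps = lo + np.random.randint(0, L_base - lo + 1)

        xn = x.copy()
        pn = p.copy()
        for j in range(d):
            grad_new[j] = grad[j]
        Un = U
        diverged = False
        for j in range(d):
            pn[j] -= 0.5 * eps * grad_new[j]
        for step in range(L_steps):
            for j in range(d):
                xn[j] += eps * inv_mass[j] * pn[j]
            Un = glmm_potential(
                kind, xn, y, g, c, pidx, iidx, n_p, n_i, k, fixed_scales, prior, grad_new
            )
            if not np.isfinite(Un):
                diverged = True
                break
            if step < L_steps - 1:
                for j in range(d):
                    pn[j] -= eps * grad_new[j]
        dH = np.inf
        if not diverged:
            for j in range(d):
                pn[j] -= 0.5 * eps * grad_new[j]
            Kn = 0.0
            for j in range(d):
                Kn += 0.5 * pn[j] * pn[j] * inv_mass[j]
            dH = (Un + Kn) - H0
            if not np.isfinite(dH) or dH > MAX_ENERGY_ERROR:
                diverged = True

        if diverged:
            accept_prob = 0.0
        elif dH > 0.0:
            accept_prob = np.exp(-dH)
        else:
            accept_prob = 1.0
        if (not diverged) and np.random.random() < accept_prob:
            x = xn.copy()
            U = Un
            for j in range(d):
                grad[j] = grad_new[j]

        if it < n_warmup:
            m_da += 1
            h_bar = (1.0 - 1.0 / (m_da + _DA_T0)) * h_bar + (
                target_accept - accept_prob
            ) / (m_da + _DA_T0)
            log_eps = mu_da - np.sqrt(m_da) / _DA_GAMMA * h_bar
            if log_eps < -18.0:
                log_eps = -18.0
            elif log_eps > 7.0:
                log_eps = 7.0
            eta = m_da ** (-_DA_KAPPA)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if w1 <= it < w2:
                n_w += 1
                for j in range(d):
                    delta = x[j] - wf_mean[j]
                    wf_mean[j] += delta / n_w
                    wf_m2[j] += delta * (x[j] - wf_mean[j])
            if it == w2 - 1 and n_w > 4:
                for j in range(d):
                    var = wf_m2[j] / (n_w - 1)
                    var = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    if var < 1e-8:
                        var = 1e-8
                    inv_mass[j] = var
                    sqrt_mass[j] = 1.0 / np.sqrt(var)
                mu_da = np.log(10.0 * eps)
                log_eps_bar = np.log(eps)
                h_bar = 0.0
                m_da = 0
        else:
            if diverged:
                n_div += 1
            for j in range(d):
                draws[it - n_warmup, j] = x[j]

    return draws, n_div


def hmc_sample(
    potential,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.9,
    integration_time: float = 1.2,
    max_leapfrog: int = 128,
):
    """Generic single-chain HMC for ``potential(x) -> (U, grad_U)``.

    Same adaptation schedule as :func:`glmm_chain`.  Returns
    ``(draws, n_divergent)``.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    U, grad = potential(x)

    inv_mass = np.ones(d)
    sqrt_mass = np.ones(d)
    eps = 0.1
    mu_da = np.log(10.0 * eps)
    log_eps_bar = np.log(eps)
    h_bar = 0.0
    m_da = 0

    w1 = n_warmup // 2
    w2 = (9 * n_warmup) // 10
    window: list[np.ndarray] = []

    draws = np.zeros((n_draws, d))
    n_div = 0
    for it in range(n_warmup + n_draws):
        if it == n_warmup:
            eps = np.exp(log_eps_bar)
        p = rng.standard_normal(d) * sqrt_mass
        H0 = U + 0.5 * np.sum(p * p * inv_mass)

        ratio = integration_time / eps
        L_base = max_leapfrog if ratio > max_leapfrog else (1 if ratio < 1.0 else int(ratio) + 1)
        lo = max(1, L_base // 2)
        L_steps = int(rng.integers(lo, L_base + 1))

        xn = x.copy()
        pn = p - 0.5 * eps * grad
        Un, gn = U, grad
        diverged = False
        for step in range(L_steps):
            xn = xn + eps * inv_mass * pn
            Un, gn = potential(xn)
            if not np.isfinite(Un):
                diverged = True
                break
            if step < L_steps - 1:
                pn = pn - eps * gn
        dH = np.inf
        if not diverged:
            pn = pn - 0.5 * eps * gn
            with np.errstate(all="ignore"):
                dH = (Un + 0.5 * np.sum(pn * pn * inv_mass)) - H0
            if not np.isfinite(dH) or dH > MAX_ENERGY_ERROR:
                diverged = True

        if diverged:
            accept_prob = 0.0
        else:
            accept_prob = float(np.exp(-dH)) if dH > 0 else 1.0
        if (not diverged) and rng.random() < accept_prob:
            x, U, grad = xn, Un, gn

        if it < n_warmup:
            m_da += 1
            h_bar = (1.0 - 1.0 / (m_da + _DA_T0)) * h_bar + (target_accept - accept_prob) / (
                m_da + _DA_T0
            )
            log_eps = mu_da - np.sqrt(m_da) / _DA_GAMMA * h_bar
            eta = m_da ** (-_DA_KAPPA)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if w1 <= it < w2:
                window.append(x.copy())
            if it == w2 - 1 and len(window) > 4:
                arr = np.asarray(window)
                var = arr.var(axis=0, ddof=1)
                n_w = len(window)
                var = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                var = np.maximum(var, 1e-8)
                inv_mass = var
                sqrt_mass = 1.0 / np.sqrt(var)
                mu_da = np.log(10.0 * eps)
                log_eps_bar = np.log(eps)
                h_bar = 0.0
                m_da = 0
        else:
            if diverged:
                n_div += 1
            draws[it - n_warmup] = x
    return draws, n_div
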