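"""Numba kernel for the BayesB Gibbs/Metropolis-Hastings sampler.

Model per record i: y_i = mu + sum_j z_ij a_j + e_i with var(e_i) =
sigma2_e / w_i. Each marker effect a_j has its own variance sigma2_j drawn
from a mixture: zero with prior probability pi, otherwise scaled inverse
chi-squared (nu, s2). sigma2_j is updated by independence
Metropolis-Hastings with the prior as proposal and the marker effect
integrated out of the likelihood, so only the likelihood ratio enters the
acceptance probability; a_j is then drawn from its normal full conditional
whenever sigma2_j > 0.

The "common variance" mode pins every sigma2_j to one fixed value and skips
the mixture update, which reduces the sampler to Bayesian ridge / SNP-BLUP
and provides the equivalence oracle against GBLUP.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chi2_draw(df):
    # chi-squared via gamma(df/2, 2); numba supports np.random.gamma
    return np.random.gamma(df / 2.0, 2.0)


@njit(cache=True)
def bayesb_chain(
    Zt,  # (m, n) centered dosages, C-contiguous by marker
    y,  # (n,)
    w,  # (n,) residual weights, var(e_i) = sigma2_e / w_i
    pi,  # prior P(effect is zero)
    n_iter,
    burn_in,
    thin,
    nu,  # prior df for marker variance
    s2,  # prior scale for marker variance
    common,  # bool: common fixed variance (ridge mode)
    sigma2_common,
    n_mh,  # MH cycles per marker per iteration
    seed,
):
    np.random.seed(seed)
    m, n = Zt.shape

    sw = 0.0
    for i in range(n):
        sw += w[i]

    zwz = np.zeros(m)
    for j in range(m):
        acc = 0.0
        for i in range(n):
            acc += w[i] * Zt[j, i] * Zt[j, i]
        zwz[j] = acc

    a = np.zeros(m)
    sig2 = np.zeros(m)
    if common:
        for j in range(m):
            sig2[j] = sigma2_common

    # init mu at weighted mean, residual variance at weighted MSE
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= sw
    e = np.empty(n)
    var_e = 0.0
    for i in range(n):
        e[i] = y[i] - mu
        var_e += w[i] * e[i] * e[i]
    var_e = var_e / n + 1e-12

    a_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    var_e_sum = 0.0
    n_samples = 0
    n_accept = 0
    n_prop = 0

    for it in range(n_iter):
        # intercept
        r = 0.0
        for i in range(n):
            r += w[i] * e[i]
        mu_new = mu + r / sw + np.random.normal(0.0, 1.0) * np.sqrt(var_e / sw)
        delta_mu = mu_new - mu
        for i in range(n):
            e[i] -= delta_mu
        mu = mu_new

        for j in range(m):
            c = zwz[j]
            if c <= 0.0:
                continue
            aj = a[j]
            rhs = c * aj
            for i in range(n):
                rhs += w[i] * Zt[j, i] * e[i]

            if common:
                s2j = sig2[j]
            else:
                cur = sig2[j]
                # integrated log-likelihood of sigma2 relative to sigma2=0
                if cur > 0.0:
                    ll_cur = -0.5 * np.log(1.0 + cur * c / var_e) + (
                        0.5 * cur * rhs * rhs / (var_e * (var_e + cur * c))
                    )
                else:
                    ll_cur = 0.0
                for _ in range(n_mh):
                    if np.random.random() < pi:
                        prop = 0.0
                    else:
                        prop = nu * s2 / _chi2_draw(nu)
                    if prop > 0.0:
                        ll_prop = -0.5 * np.log(1.0 + prop * c / var_e) + (
                            0.5 * prop * rhs * rhs / (var_e * (var_e + prop * c))
                        )
                    else:
                        ll_prop = 0.0
                    n_prop += 1
                    if np.log(np.random.random() + 1e-300) < ll_prop - ll_cur:
                        cur = prop
                        ll_cur = ll_prop
                        n_accept += 1
                sig2[j] = cur
                s2j = cur

            if s2j <= 0.0:
                if aj != 0.0:
                    for i in range(n):
                        e[i] += Zt[j, i] * aj
                    a[j] = 0.0
            else:
                lhs = c + var_e / s2j
                mean = rhs / lhs
                a_new = mean + np.random.normal(0.0, 1.0) * np.sqrt(var_e / lhs)
                diff = aj - a_new
                if diff != 0.0:
                    for i in range(n):
                        e[i] += Zt[j, i] * diff
                a[j] = a_new

        # residual variance, flat scale prior
        sse = 0.0
        for i in range(n):
            sse += w[i] * e[i] * e[i]
        var_e = sse / _chi2_draw(n - 2.0) + 1e-12

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            mu_sum += mu
            var_e_sum += var_e
            for j in range(m):
                a_sum[j] += a[j]
                if sig2[j] > 0.0:
                    incl_sum[j] += 1.0

    inv = 1.0 / max(n_samples, 1)
    accept_rate = n_accept / max(n_prop, 1)
    return (
        a_sum * inv,
        incl_sum * inv,
        mu_sum * inv,
        var_e_sum * inv,
        accept_rate,
    )
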