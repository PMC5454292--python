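"""Numba kernels for the per-gene model fits.

The nested sampler evaluates the cosine^q / linear mean and the L1
likelihood tens of thousands of times per gene; these kernels keep that
inner loop compiled.  All randomness is drawn outside (numpy Generator)
and passed in as arrays, so results are bit-reproducible and independent
of numba's internal RNG.
"""
from __future__ import annotations

import numpy as np
from numba import njit

MODEL_COS24 = 0
MODEL_COS12 = 1
MODEL_LINEAR = 2

_TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _mu_into(model_id, theta, times, out):
    if model_id == MODEL_LINEAR:
        for i in range(times.size):
            out[i] = theta[0] + theta[1] * times[i]
    else:
        T = 24.0 if model_id == MODEL_COS24 else 12.0
        a = theta[0]
        p = theta[1]
        q = theta[2]
        for i in range(times.size):
            c = 0.5 * (1.0 + np.cos(_TWO_PI * times[i] / T - p))
            out[i] = a * c ** q


@njit(cache=True)
def l1_loglik(model_id, theta, times, xvals, xmed, eps_floor):
    """L1 log-likelihood; xvals is (replicate, time), NaN = missing."""
    m = times.size
    mu = np.empty(m)
    _mu_into(model_id, theta, times, mu)
    total = 0.0
    n_rep = xvals.shape[0]
    for t in range(m):
        s = 0.0
        cnt = 0
        for r in range(n_rep):
            v = xvals[r, t]
            if not np.isnan(v):
                s += abs(v - mu[t])
                cnt += 1
        eps = s / cnt
        if eps < eps_floor:
            eps = eps_floor
        total += -np.log(2.0 * eps) - abs(xmed[t] - mu[t]) / eps
    return total


@njit(cache=True)
def constrained_walk(model_id, times, xvals, xmed, eps_floor,
                     lower, upper, theta0, l_min, steps, normals):
    """Metropolis walk inside the hard-likelihood constraint L > l_min.

    The prior is uniform, so a proposal (reflected back into the bounds) is
    accepted exactly when its likelihood clears the constraint.  Returns the
    final point, its log-likelihood and the number of accepted steps.
    """
    d = theta0.size
    cur = theta0.copy()
    cur_l = l1_loglik(model_id, cur, times, xvals, xmed, eps_floor)
    prop = np.empty(d)
    n_acc = 0
    for s in range(normals.shape[0]):
        for j in range(d):
            x = cur[j] + normals[s, j] * steps[j]
            w = upper[j] - lower[j]
            y = (x - lower[j]) % (2.0 * w)
            if y > w:
                y = 2.0 * w - y
            prop[j] = lower[j] + y
        l = l1_loglik(model_id, prop, times, xvals, xmed, eps_floor)
        if l > l_min:
            for j in range(d):
                cur[j] = prop[j]
            cur_l = l
            n_acc += 1
    return cur, cur_l, n_acc


@njit(cache=True)
def loglik_batch(model_id, thetas, times, xvals, xmed, eps_floor, out):
    for i in range(thetas.shape[0]):
        out[i] = l1_loglik(model_id, thetas[i], times, xvals, xmed, eps_floor)
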