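"""Nested sampling: Bayesian evidence and posterior summaries per fit.

Skilling-style nested sampling over the uniform priors of `models`:
``n_live`` points are drawn from the prior, the worst point is repeatedly
replaced by a constrained-prior draw obtained from a short Metropolis walk
started at a random survivor, and the evidence

    Z = integral of L(theta) * pi(theta) d theta

is accumulated with the standard exponential prior-mass shrinkage
X_i = exp(-i / n_live).  Posterior means and standard deviations come from
the importance weights w_i = L_i * (X_{i-1} - X_i) / Z; the phase of the
rhythmic models is summarised circularly so wrap-around never inflates its
standard deviation.

`nested_sample` accepts any log-likelihood callable (used by the analytic
validation problems); `fit_series` is the compiled fast path for the three
expression models.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _fast
from .expression import ExpressionSeries, ScaledSeries
from .models import (COS12, COS24, EPS_FLOOR, LINEAR, PHASE_ALTERNATIVE,
                     PHASE_PRIMARY, PriorSpec, make_priors, model_mu)

_MODEL_IDS = {COS24: _fast.MODEL_COS24, COS12: _fast.MODEL_COS12,
              LINEAR: _fast.MODEL_LINEAR}

#: Posterior-mean phase closer than this (radians) to a prior-window edge
#: triggers a refit with the alternative window centred on zero.
PHASE_EDGE_RAD = 0.2


@dataclass
class SamplerConfig:
    """Nested-sampling constants.

    n_live ≥ 50 live points; termination when the maximum remaining
    log-evidence contribution drops below ``termination_tol`` nats;
    ``mcmc_steps`` Metropolis steps per replacement, step size adapted
    toward ~50% acceptance.
    """

    n_live: int = 300
    termination_tol: float = 1e-4
    max_iterations: int = 20000
    mcmc_steps: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 50:
            raise ValueError("n_live must be >= 50")
        if self.termination_tol <= 0:
            raise ValueError("termination_tol must be positive")


@dataclass
class NSRun:
    """Raw output of one nested-sampling run."""

    samples: np.ndarray          # (n_samples, ndim), dead points then live
    logl: np.ndarray             # log-likelihood per sample
    logwt: np.ndarray            # unnormalised log posterior weight per sample
    logZ: float
    logZ_sd: float
    H: float                     # information (nats)
    converged: bool
    n_iterations: int
    dead_logl: np.ndarray        # likelihood sequence of discarded points


@dataclass
class FitResult:
    """Evidence and posterior summaries for one (gene, model) pair."""

    gene_id: str
    model: str
    logZ: float
    logZ_sd: float
    param_mean: dict[str, float]
    param_sd: dict[str, float]
    l1_error: float
    converged: bool
    n_iterations: int
    seed: int
    phase_window: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "model": self.model,
            "logZ": self.logZ,
            "logZ_sd": self.logZ_sd,
            "param_mean": dict(self.param_mean),
            "param_sd": dict(self.param_sd),
            "l1_error": self.l1_error,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "phase_window": self.phase_window,
        }


def _logsubexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b."""
    return a + math.log1p(-math.exp(b - a))


def _nested_loop(walk: Callable, theta_live: np.ndarray, logl_live: np.ndarray,
                 cfg: SamplerConfig, rng: np.random.Generator) -> NSRun:
    n = cfg.n_live
    if not np.any(np.isfinite(logl_live)):
        raise ValueError("no live point with finite likelihood")
    dead_theta: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logwt: list[float] = []
    logZ = -np.inf
    H = 0.0
    logx_prev = 0.0
    frac = 0.1  # step size as a fraction of each prior width
    converged = False
    i = 0
    while i < cfg.max_iterations:
        i += 1
        logx = -i / n
        logw = _logsubexp(logx_prev, logx)
        worst = int(np.argmin(logl_live))
        l_worst = float(logl_live[worst])
        logwt = l_worst + logw
        if np.isfinite(logwt):
            logz_new = np.logaddexp(logZ, logwt)
            if np.isfinite(logZ):
                H = (math.exp(logwt - logz_new) * l_worst
                     + math.exp(logZ - logz_new) * (H + logZ) - logz_new)
            else:
                H = math.exp(logwt - logz_new) * l_worst - logz_new
            logZ = float(logz_new)
        dead_theta.append(theta_live[worst].copy())
        dead_logl.append(l_worst)
        dead_logwt.append(logwt)
        logx_prev = logx

        l_max = float(np.max(logl_live))
        if i > n and np.isfinite(logZ):
            remaining = np.logaddexp(logZ, l_max + logx) - logZ
            if remaining < cfg.termination_tol:
                converged = True
                break

        # replace the worst point: walk from a random survivor
        if n > 1:
            j = worst
            while j == worst:
                j = int(rng.integers(n))
        else:
            j = worst
        theta_new, l_new, n_acc = walk(theta_live[j].copy(), l_worst, frac, rng)
        theta_live[worst] = theta_new
        logl_live[worst] = l_new
        rate = n_acc / cfg.mcmc_steps
        if rate > 0.6:
            frac = min(frac * 1.3, 1.0)
        elif rate < 0.3:
            frac = max(frac * 0.7, 1e-4)

    # fold the surviving live points into evidence and posterior
    logw_live = logx_prev - math.log(n)
    live_logwt = np.empty(n)
    for k in range(n):
        lw = float(logl_live[k]) + logw_live
        live_logwt[k] = lw
        if not np.isfinite(lw):
            continue
        logz_new = np.logaddexp(logZ, lw)
        if np.isfinite(logZ):
            H = (math.exp(lw - logz_new) * float(logl_live[k])
                 + math.exp(logZ - logz_new) * (H + logZ) - logz_new)
        else:
            H = math.exp(lw - logz_new) * float(logl_live[k]) - logz_new
        logZ = float(logz_new)

    samples = np.vstack(dead_theta + [theta_live]) if dead_theta else theta_live.copy()
    logl = np.concatenate([np.asarray(dead_logl), logl_live])
    logwt = np.concatenate([np.asarray(dead_logwt), live_logwt])
    logz_sd = math.sqrt(max(H, 0.0) / n)
    return NSRun(samples=samples, logl=logl, logwt=logwt, logZ=logZ,
                 logZ_sd=logz_sd, H=H, converged=converged, n_iterations=i,
                 dead_logl=np.asarray(dead_logl))


def _reflect(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    w = upper - lower
    y = np.mod(x - lower, 2.0 * w)
    return lower + np.where(y > w, 2.0 * w - y, y)


def nested_sample(loglik: Callable[[np.ndarray], float], prior: PriorSpec,
                  cfg: SamplerConfig) -> NSRun:
    """Nested sampling for an arbitrary log-likelihood over uniform priors."""
    rng = np.random.default_rng(cfg.seed)
    d = prior.ndim
    theta_live = rng.uniform(prior.lower, prior.upper, size=(cfg.n_live, d))
    logl_live = np.array([float(loglik(t)) for t in theta_live])

    def walk(theta0, l_min, frac, walk_rng):
        steps = frac * (prior.upper - prior.lower)
        normals = walk_rng.standard_normal((cfg.mcmc_steps, d))
        cur = theta0
        cur_l = float(loglik(cur))
        n_acc = 0
        for s in range(cfg.mcmc_steps):
            prop = _reflect(cur + normals[s] * steps, prior.lower, prior.upper)
            l = float(loglik(prop))
            if l > l_min:
                cur, cur_l = prop, l
                n_acc += 1
        return cur, cur_l, n_acc

    return _nested_loop(walk, theta_live, logl_live, cfg, rng)


def posterior_summaries(samples: np.ndarray, logwt: np.ndarray,
                        circular_index: Optional[int] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted posterior means and SDs; one parameter may be circular.

    Circular parameters (the phase, in radians) are summarised by the
    weighted resultant vector: mean = atan2(S, C) and
    SD = sqrt(-2 * log Rbar).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    logwt = np.asarray(logwt, dtype=float)
    finite = np.isfinite(logwt)
    if not np.any(finite):
        raise ValueError("zero total posterior weight")
    w = np.zeros_like(logwt)
    w[finite] = np.exp(logwt[finite] - np.max(logwt[finite]))
    w /= w.sum()
    means = samples.T @ w
    sq = (samples ** 2).T @ w
    sds = np.sqrt(np.maximum(sq - means ** 2, 0.0))
    if circular_index is not None:
        p = samples[:, circular_index]
        c = float(np.sum(w * np.cos(p)))
        s = float(np.sum(w * np.sin(p)))
        rbar = min(math.hypot(c, s), 1.0)
        means[circular_index] = math.atan2(s, c) % (2.0 * math.pi)
        if rbar <= 1e-12:
            sds[circular_index] = math.sqrt(-2.0 * math.log(1e-12))
        else:
            sds[circular_index] = math.sqrt(-2.0 * math.log(rbar))
    return means, sds


def _series_arrays(scaled: ScaledSeries | ExpressionSeries):
    s = scaled.series if isinstance(scaled, ScaledSeries) else scaled
    times = s.grid.times_array()
    xvals = np.ascontiguousarray(s.values, dtype=float)
    with np.errstate(all="ignore"):
        xmed = np.nanmedian(xvals, axis=0)
    if np.any(~np.isfinite(xmed)):
        raise ValueError(f"{s.gene_id}: time point with no observed replicate")
    return s, times, xvals, xmed


def _fit_one_window(model: str, prior: PriorSpec, times, xvals, xmed,
                    cfg: SamplerConfig, seed: int) -> NSRun:
    mid = _MODEL_IDS[model]
    rng = np.random.default_rng(seed)
    d = prior.ndim
    theta_live = rng.uniform(prior.lower, prior.upper, size=(cfg.n_live, d))
    logl_live = np.empty(cfg.n_live)
    _fast.loglik_batch(mid, theta_live, times, xvals, xmed, EPS_FLOOR, logl_live)

    lower, upper = prior.lower, prior.upper

    def walk(theta0, l_min, frac, walk_rng):
        steps = frac * (upper - lower)
        normals = walk_rng.standard_normal((cfg.mcmc_steps, d))
        return _fast.constrained_walk(mid, times, xvals, xmed, EPS_FLOOR,
                                      lower, upper, theta0, l_min, steps, normals)

    return _nested_loop(walk, theta_live, logl_live, cfg, rng)


def fit_series(scaled: ScaledSeries | ExpressionSeries, model: str,
               cfg: SamplerConfig, seed: Optional[int] = None) -> FitResult:
    """Fit one model to one scaled series; returns evidence + summaries.

    Rhythmic models are first fitted with the phase prior on [0, 2*pi]; if
    the posterior-mean phase lands within 0.2 rad of either edge the fit is
    repeated with the window centred on zero ([-pi, pi]) and the refit kept,
    so the reported phase never sits against a prior boundary.  The L1
    residual error is evaluated at the posterior-mean parameters.
    """
    if seed is None:
        seed = cfg.seed
    s, times, xvals, xmed = _series_arrays(scaled)
    span = s.grid.span_hours

    if model == LINEAR:
        prior = make_priors(LINEAR, grid_span_hours=span)
        run = _fit_one_window(model, prior, times, xvals, xmed, cfg, seed)
        means, sds = posterior_summaries(run.samples, run.logwt)
        window = None
    else:
        prior = make_priors(model, PHASE_PRIMARY, grid_span_hours=span)
        run = _fit_one_window(model, prior, times, xvals, xmed, cfg, seed)
        means, sds = posterior_summaries(run.samples, run.logwt, circular_index=1)
        window = PHASE_PRIMARY
        edge_dist = min(means[1], 2.0 * np.pi - means[1])
        if edge_dist < PHASE_EDGE_RAD:
            prior = make_priors(model, PHASE_ALTERNATIVE, grid_span_hours=span)
            run = _fit_one_window(model, prior, times, xvals, xmed, cfg,
                                  seed + 1)
            means, sds = posterior_summaries(run.samples, run.logwt,
                                             circular_index=1)
            window = PHASE_ALTERNATIVE
        means = means.copy()
        means[1] = means[1] % (2.0 * np.pi)

    mu_hat = model_mu(model, means, times)
    l1_error = float(np.sum(np.abs(xmed - mu_hat)))
    return FitResult(
        gene_id=s.gene_id,
        model=model,
        logZ=run.logZ,
        logZ_sd=run.logZ_sd,
        param_mean={n: float(v) for n, v in zip(prior.names, means)},
        param_sd={n: float(v) for n, v in zip(prior.names, sds)},
        l1_error=l1_error,
        converged=run.converged,
        n_iterations=run.n_iterations,
        seed=seed,
        phase_window=window,
    )
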