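"""Candidate mean-models and the replicate-aware L1 likelihood.

Three models compete per gene: a peaked 24 h cosine, the same form with a
12 h period, and a linear drift.  The rhythmic form is

    f(t) = a * ((1 + cos(2*pi*t/T - p)) / 2) ** q

which varies between 0 and the amplitude ``a``, peaks where the phase angle
``2*pi*t/T`` equals ``p`` (mod 2*pi), and sharpens as the exponent ``q``
grows; ``q = 1`` is the standard raised cosine.

The likelihood is a per-time Laplace density of the replicate median
``x~_t`` with scale ``eps_t`` set to the mean absolute deviation of the
replicates from the model value ``mu_t``:

    log L = sum_t [ -log(2*eps_t) - |x~_t - mu_t| / eps_t ]

Maximising it minimises the sum of absolute residuals, while times at which
replicates disagree more contribute flatter (down-weighted) terms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .expression import ExpressionSeries

COS24 = "cos24"
COS12 = "cos12"
LINEAR = "linear"
MODELS = (COS24, COS12, LINEAR)

#: Floor on the per-time Laplace scale (on the 0-10 scaled axis); prevents an
#: infinite density when replicates coincide with the model.
EPS_FLOOR = 1e-3

#: Prior windows for the phase parameter p (radians).
PHASE_PRIMARY = "primary"      # [0, 2*pi]
PHASE_ALTERNATIVE = "alternative"  # [-pi, pi], used when p fits near 0 or 2*pi


@dataclass(frozen=True)
class CosineQParams:
    """Amplitude a (scaled units), phase p (radians), exponent q, period T (h)."""

    a: float
    p: float
    q: float
    T: float = 24.0

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("exponent q must be non-negative")
        if self.T not in (24.0, 12.0):
            raise ValueError("period T must be 24 or 12 hours")

    @property
    def phase_hours(self) -> float:
        """Peak time in ZT hours, reduced to [0, T)."""
        return (self.p * self.T / (2.0 * np.pi)) % self.T


@dataclass(frozen=True)
class LinearParams:
    """Intercept b0 (scaled units) and slope b1 (scaled units per hour)."""

    b0: float
    b1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.b0) and np.isfinite(self.b1)):
            raise ValueError("linear parameters must be finite")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: parameter names with lower/upper bounds."""

    model: str
    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    phase_window: Optional[str] = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.shape != (len(self.names),):
            raise ValueError("bound shapes do not match parameter names")
        if np.any(lo >= hi):
            raise ValueError("every lower bound must be below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def log_volume(self) -> float:
        return float(np.sum(np.log(self.upper - self.lower)))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "names": list(self.names),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "phase_window": self.phase_window,
        }


def cosineq_eval(params: CosineQParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the peaked cosine model at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    base = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / params.T - params.p))
    out = params.a * base ** params.q
    return float(out) if out.ndim == 0 else out


def linear_eval(params: LinearParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the linear drift model at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    out = params.b0 + params.b1 * t
    return float(out) if out.ndim == 0 else out


def model_mu(model: str, theta: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Model mean at each grid time for a raw parameter vector."""
    theta = np.asarray(theta, dtype=float)
    if model == COS24:
        return cosineq_eval(CosineQParams(theta[0], theta[1], theta[2], 24.0), times)
    if model == COS12:
        return cosineq_eval(CosineQParams(theta[0], theta[1], theta[2], 12.0), times)
    if model == LINEAR:
        return linear_eval(LinearParams(theta[0], theta[1]), times)
    raise ValueError(f"unknown model {model!r}")


def make_priors(model: str,
                phase_window: str = PHASE_PRIMARY,
                grid_span_hours: float = 20.0,
                overrides: Optional[Mapping[str, tuple[float, float]]] = None) -> PriorSpec:
    """Uniform prior bounds for one model.

    Rhythmic models: a in [0, 10] (data are scaled to max median 10, so the
    amplitude cannot exceed 10), p in [0, 2*pi] or the alternative window
    [-pi, pi], q in [1, 8].  Linear model: b0 in [0, 10] and a slope range
    wide enough that any line reachable within the scaled data range over
    the grid span has positive prior mass.
    """
    if model in (COS24, COS12):
        if phase_window == PHASE_PRIMARY:
            p_lo, p_hi = 0.0, 2.0 * np.pi
        elif phase_window == PHASE_ALTERNATIVE:
            p_lo, p_hi = -np.pi, np.pi
        else:
            raise ValueError(f"unknown phase window {phase_window!r}")
        names = ("a", "p", "q")
        lower = [0.0, p_lo, 1.0]
        upper = [10.0, p_hi, 8.0]
        window = phase_window
    elif model == LINEAR:
        if grid_span_hours <= 0:
            raise ValueError("grid span must be positive")
        names = ("b0", "b1")
        slope = 10.0 / grid_span_hours
        lower = [0.0, -slope]
        upper = [10.0, slope]
        window = None
    else:
        raise ValueError(f"unknown model {model!r}")
    if overrides:
        for name, (lo, hi) in overrides.items():
            if name not in names:
                raise ValueError(f"{model}: no parameter {name!r}")
            i = names.index(name)
            lower[i], upper[i] = float(lo), float(hi)
    return PriorSpec(model=model, names=names,
                     lower=np.array(lower), upper=np.array(upper),
                     phase_window=window)


def l1_loglikelihood(s: ExpressionSeries, mu: np.ndarray,
                     eps_floor: float = EPS_FLOOR) -> float:
    """Replicate-aware L1 log-likelihood of a scaled series under mean ``mu``.

    Per time t: eps_t = mean over observed replicates of |x_rt - mu_t|
    (floored), x~_t = replicate median, and the contribution is
    -log(2*eps_t) - |x~_t - mu_t| / eps_t.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (s.grid.n_timepoints,):
        raise ValueError("mu must give one value per grid time")
    total = 0.0
    for t in range(s.grid.n_timepoints):
        col = s.values[:, t]
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            raise ValueError(f"{s.gene_id}: no replicate at time index {t}")
        eps = max(float(np.mean(np.abs(obs - mu[t]))), eps_floor)
        xmed = float(np.median(obs))
        total += -np.log(2.0 * eps) - abs(xmed - mu[t]) / eps
    return total
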