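"""F24 Fourier screen: the initial false-discovery filter.

The two replicates of a 6-point day are concatenated into one 12-point
series spanning ZT0..ZT44 at 4 h spacing (replicate 2 relabelled
ZT24..ZT44).  The F24 statistic is the relative spectral power at the 24 h
period of that 48 h window — |DFT bin 2|^2 over the total power in the
non-zero-frequency bins — so it lies in [0, 1] and ignores the series mean.
Significance comes from permuting the time labels; genes whose (BH
adjusted, by default) p-value exceeds 0.2 are not considered further.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_seed
from .expression import ExpressionMatrix, ExpressionSeries

F24_THRESHOLD = 0.2


@dataclass(frozen=True)
class F24Result:
    gene_id: str
    statistic: float
    p_value: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0 + 1e-12:
            raise ValueError("F24 statistic must lie in [0, 1]")
        if self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot undercut the raw p")


def concatenate_replicates(s: ExpressionSeries) -> np.ndarray:
    """Replicate 1 at ZT0..ZT20 followed by replicate 2 as ZT24..ZT44."""
    if s.grid.n_replicates != 2:
        raise ValueError(
            f"{s.gene_id}: replicate concatenation requires exactly 2 replicates, "
            f"got {s.grid.n_replicates}"
        )
    if s.grid.n_timepoints != 6:
        raise ValueError(f"{s.gene_id}: expected 6 time points, got {s.grid.n_timepoints}")
    out = np.concatenate([s.values[0], s.values[1]])
    if np.any(~np.isfinite(out)):
        raise ValueError(f"{s.gene_id}: missing values cannot be concatenated")
    return out


def concatenated_times(sampling_interval: float = 4.0, n: int = 12) -> np.ndarray:
    return np.arange(n) * sampling_interval


def f24_statistic(x: np.ndarray, sampling_interval: float = 4.0) -> float:
    """Relative spectral power at the 24 h period of the concatenated series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    window = n * sampling_interval
    k24 = window / 24.0
    if abs(k24 - round(k24)) > 1e-9:
        raise ValueError("24 h period does not fall on a DFT bin for this grid")
    k24 = int(round(k24))
    spec = np.fft.rfft(x - x.mean())
    power = np.abs(spec[1:]) ** 2
    total = power.sum()
    if total <= 0.0:
        return 0.0
    return float(power[k24 - 1] / total)


def _f24_statistic_rows(xs: np.ndarray, k24: int) -> np.ndarray:
    """Vectorised statistic for many series (rows)."""
    xs = xs - xs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(xs, axis=1)
    power = np.abs(spec[:, 1:]) ** 2
    total = power.sum(axis=1)
    out = np.zeros(xs.shape[0])
    ok = total > 0
    out[ok] = power[ok, k24 - 1] / total[ok]
    return out


def f24_pvalue(x: np.ndarray, n_perm: int = 999, seed: int = 0,
               sampling_interval: float = 4.0) -> float:
    """Permutation p-value: (1 + #{perm stat >= observed}) / (n_perm + 1)."""
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    x = np.asarray(x, dtype=float)
    obs = f24_statistic(x, sampling_interval)
    k24 = int(round(x.size * sampling_interval / 24.0))
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, x.size)), axis=1)
    stats = _f24_statistic_rows(x[idx], k24)
    return float((1 + np.sum(stats >= obs)) / (n_perm + 1))


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def f24_screen(m: ExpressionMatrix, n_perm: int = 999, seed: int = 0,
               threshold: float = F24_THRESHOLD,
               use_adjusted: bool = True) -> pd.DataFrame:
    """Run the F24 screen over a matrix; per-gene seeds derive from ``seed``.

    Returns a DataFrame indexed by gene_id with columns statistic, p_value,
    p_adjusted and passed.  The threshold (inclusive: p = 0.2 is retained)
    applies to the adjusted p-value by default; set ``use_adjusted=False``
    to filter on the raw permutation p-value.
    """
    rows = {}
    for s in m:
        x = concatenate_replicates(s)
        rows[s.gene_id] = (
            f24_statistic(x),
            f24_pvalue(x, n_perm=n_perm, seed=derive_seed(seed, "f24", s.gene_id)),
        )
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["statistic", "p_value"])
    df.index.name = "gene_id"
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    basis = df["p_adjusted"] if use_adjusted else df["p_value"]
    df["passed"] = basis <= threshold
    return df


def apply_filter(results: pd.DataFrame, threshold: float = F24_THRESHOLD,
                 use_adjusted: bool = True) -> set[str]:
    """Gene ids whose filter p-value is at most ``threshold`` (inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if len(results) == 0:
        return set()
    col = "p_adjusted" if use_adjusted else "p_value"
    return set(results.index[results[col] <= threshold].astype(str))
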