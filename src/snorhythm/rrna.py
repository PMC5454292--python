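"""snoRNA–rRNA coupling: per-gene regression and enrichment scan.

Many snoRNA chemically modify the 18S/28S ribosomal RNAs, and their nuclear
abundance can run in antiphase with the accumulation of their target.  To
quantify that coupling, each gene's 12 samples (two replicates at six time
points, matched by replicate and time) are regressed on the target rRNA
series by ordinary least squares.  A hypergeometric scan then asks, for
each R^2 threshold from 0 to 1, whether modifiers of the target are
over-represented among the negatively (or positively) correlated expressed
genes.  The input matrix must already have rRNA removed and the remaining
TPM rescaled to 10^6 per sample (``expression.renormalize_excluding``) so
that fluctuations of total rRNA cannot masquerade as coupling.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ExpressionSeries, GeneAnnotation

logger = logging.getLogger(__name__)

_FLAT_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class RegressionResult:
    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    direction: str  # negative | positive | flat

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError("R^2 out of range")


@dataclass
class CorrelationScan:
    """Scan results for one target: per-threshold counts and tail p-values."""

    target: str
    table: pd.DataFrame  # columns: target, r2_threshold, direction, k, K, n, N, p
    max_significant_r2: dict[str, float]  # per direction; NaN if never significant
    alpha: float


def regress_vs_target(g: ExpressionSeries, target: ExpressionSeries
                      ) -> RegressionResult:
    """OLS of gene TPM on target TPM over matched (replicate, time) samples."""
    if g.grid != target.grid:
        raise ValueError("gene and target must share the time grid")
    x = target.values.reshape(-1)
    y = g.values.reshape(-1)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"{g.gene_id}: too few matched samples")
    if np.ptp(x) == 0:
        raise ValueError("target series has zero variance")
    if np.ptp(y) == 0:
        return RegressionResult(g.gene_id, 0.0, float(np.mean(y)), 0.0, "flat")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    scale = max(np.std(y) / max(np.std(x), _FLAT_SLOPE_TOL), 1.0)
    if abs(fit.slope) < _FLAT_SLOPE_TOL * scale:
        direction = "flat"
    else:
        direction = "negative" if fit.slope < 0 else "positive"
    return RegressionResult(g.gene_id, float(fit.slope), float(fit.intercept),
                            min(r2, 1.0), direction)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_lower_tail(k: int, K: int, n: int, N: int) -> float:
    """Depletion tail P(X <= k)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.cdf(k, N, K, n))


def regress_all(m: ExpressionMatrix, target_series: ExpressionSeries,
                genes: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Regression of every (or selected) gene on the target series."""
    genes = list(genes) if genes is not None else m.gene_ids
    rows = []
    for gid in genes:
        r = regress_vs_target(m.series(gid), target_series)
        rows.append({"gene_id": r.gene_id, "slope": r.slope,
                     "intercept": r.intercept, "r_squared": r.r_squared,
                     "direction": r.direction})
    return pd.DataFrame(rows).set_index("gene_id")


def correlation_scan(m: ExpressionMatrix,
                     ann: Mapping[str, GeneAnnotation],
                     target_series: ExpressionSeries,
                     target_label: str,
                     expressed: pd.DataFrame,
                     modifier_set: Optional[set[str]] = None,
                     grid_step: float = 0.01,
                     alpha: float = 0.05) -> CorrelationScan:
    """Hypergeometric over-representation of target modifiers across R^2.

    The population is the expressed genes of ``m``; the marked set at each
    threshold r is {expressed genes with the given direction and R^2 >= r}
    (threshold inclusive); the drawn set is the expressed snoRNA annotated
    with ``rrna_target == target_label`` unless ``modifier_set`` overrides
    it (e.g. with the modifiers' host genes).  One-sided enrichment tails
    P(X >= k) are reported per direction.
    """
    rrna_present = [g for g in m.gene_ids
                    if g in ann and ann[g].biotype == "rRNA"]
    if rrna_present:
        raise ValueError(
            "matrix still contains rRNA gene(s) "
            f"{rrna_present}; renormalize_excluding them first")
    expressed_genes = [g for g in m.gene_ids
                       if g in expressed.index and bool(expressed.loc[g, "expressed"])]
    if modifier_set is None:
        modifiers = {g for g in expressed_genes
                     if g in ann and ann[g].biotype == "snoRNA"
                     and ann[g].rrna_target == target_label}
    else:
        modifiers = set(modifier_set) & set(expressed_genes)
    n = len(modifiers)
    N = len(expressed_genes)
    if N == 0:
        raise ValueError("no expressed genes to scan")
    if n == 0:
        logger.warning("empty modifier set for target %s; p = 1 everywhere",
                       target_label)

    reg = regress_all(m, target_series, expressed_genes)
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    rows = []
    max_sig: dict[str, float] = {}
    for direction in ("negative", "positive"):
        in_dir = reg["direction"] == direction
        r2 = reg["r_squared"].to_numpy()
        is_mod = reg.index.isin(modifiers)
        sig_at = []
        for r in thresholds:
            hit = in_dir.to_numpy() & (r2 >= r)
            K = int(hit.sum())
            k = int((hit & is_mod).sum())
            p = hypergeometric_tail(k, K, n, N) if n > 0 else 1.0
            rows.append({"target": target_label, "r2_threshold": float(r),
                         "direction": direction, "k": k, "K": K,
                         "n": n, "N": N, "p": p})
            if p < alpha:
                sig_at.append(float(r))
        max_sig[direction] = max(sig_at) if sig_at else float("nan")
    table = pd.DataFrame(rows)
    return CorrelationScan(target=target_label, table=table,
                           max_significant_r2=max_sig, alpha=alpha)
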