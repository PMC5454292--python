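"""Circadian verdicts: evidence-ratio model selection and radial filtering.

A gene that passed the F24 screen is called *candidate circadian* when the
evidence for the 24 h model is at least ten times that of the better of the
two alternatives (12 h cosine, linear), i.e. logZ_cos24 - max(logZ_cos12,
logZ_linear) >= ln 10.  Candidates whose phase is poorly determined or whose
fit is poor are then removed by the radial score

    score = sqrt((phase_sd / phase_sd_max)^2 + (l1_error / l1_max)^2)

normalised by the candidate cohort's maxima so both axes are commensurate.
In quantile mode the worst ceil(5%) of candidates are excluded (defining an
absolute threshold); in transfer mode a threshold and normalisation derived
from another cohort (the protein-coding genes, in the original analysis)
are applied unchanged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .models import COS12, COS24, LINEAR
from .nested import FitResult

EVIDENCE_FACTOR = 10.0
EXCLUDE_FRACTION = 0.05


@dataclass(frozen=True)
class RadialNorm:
    """Cohort maxima used to normalise the two radial-score axes."""

    phase_sd_max: float
    l1_max: float

    def __post_init__(self) -> None:
        if self.phase_sd_max <= 0 or self.l1_max <= 0:
            raise ValueError("radial normalisation components must be positive")


def compare_models(fits: Mapping[str, FitResult]) -> tuple[str, float]:
    """Winning model and the log evidence ratio of cos24 over the alternatives.

    The ratio baseline is the better of the two alternatives (the stricter
    reading); it is returned in log space, candidate-circadian means
    log_ratio >= ln(10).
    """
    for model in (COS24, COS12, LINEAR):
        if model not in fits:
            raise ValueError(f"missing fit for model {model}")
        if not fits[model].converged:
            raise ValueError(f"fit for model {model} did not converge")
    logz = {m: fits[m].logZ for m in (COS24, COS12, LINEAR)}
    winner = max(logz, key=lambda m: logz[m])
    log_ratio = logz[COS24] - max(logz[COS12], logz[LINEAR])
    return winner, float(log_ratio)


def radial_score(phase_sd: float, l1_error: float, norm: RadialNorm) -> float:
    """Combined phase-uncertainty / fit-error quality score (lower = better)."""
    if phase_sd < 0 or l1_error < 0:
        raise ValueError("score components must be non-negative")
    return math.hypot(phase_sd / norm.phase_sd_max, l1_error / norm.l1_max)


def cohort_norm(phase_sds: np.ndarray, l1_errors: np.ndarray) -> RadialNorm:
    """Normalisation from a candidate cohort; guards degenerate maxima."""
    if len(phase_sds) == 0:
        raise ValueError("empty candidate cohort")
    return RadialNorm(phase_sd_max=max(float(np.max(phase_sds)), 1e-12),
                      l1_max=max(float(np.max(l1_errors)), 1e-12))


def call_circadian(fits_by_gene: Mapping[str, Mapping[str, FitResult]],
                   f24: pd.DataFrame,
                   policy: str = "quantile",
                   threshold: Optional[float] = None,
                   norm: Optional[RadialNorm] = None,
                   evidence_factor: float = EVIDENCE_FACTOR,
                   exclude_fraction: float = EXCLUDE_FRACTION,
                   ) -> tuple[pd.DataFrame, RadialNorm, float]:
    """Per-gene circadian calls from model fits and the F24 screen.

    ``fits_by_gene`` should contain fits only for genes that passed F24.
    Policy ``"quantile"`` derives the radial threshold from this cohort
    (exactly ceil(exclude_fraction * n) worst candidates excluded, ties
    broken by gene_id); policy ``"absolute"`` requires a ``threshold`` and
    ``norm`` transferred from a defining cohort.  Returns the call table,
    the normalisation used, and the absolute threshold (max retained score
    in quantile mode).
    """
    if policy not in ("quantile", "absolute"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "absolute" and (threshold is None or norm is None):
        raise ValueError("absolute policy requires a transferred threshold and norm")

    log_factor = math.log(evidence_factor)
    rows = []
    for gene_id, fits in fits_by_gene.items():
        passed = bool(f24.loc[gene_id, "passed"]) if gene_id in f24.index else False
        converged = all(fits[m].converged for m in (COS24, COS12, LINEAR))
        if converged:
            winner, log_ratio = compare_models(fits)
        else:
            winner, log_ratio = "", float("nan")
        c24 = fits[COS24]
        phase_sd_h = c24.param_sd["p"] * 24.0 / (2.0 * math.pi)
        rows.append({
            "gene_id": gene_id,
            "passed_f24": passed,
            "converged": converged,
            "logZ_cos24": fits[COS24].logZ,
            "logZ_cos12": fits[COS12].logZ,
            "logZ_linear": fits[LINEAR].logZ,
            "winning_model": winner,
            "log_evidence_ratio": log_ratio,
            "evidence_ratio": math.exp(min(log_ratio, 700.0)) if np.isfinite(log_ratio) else float("nan"),
            "phase_hours": (c24.param_mean["p"] * 24.0 / (2.0 * math.pi)) % 24.0,
            "phase_sd_hours": phase_sd_h,
            "l1_error": c24.l1_error,
            "_phase_sd_rad": c24.param_sd["p"],
        })
    df = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["passed_f24", "converged", "logZ_cos24", "logZ_cos12",
                 "logZ_linear", "winning_model", "log_evidence_ratio",
                 "evidence_ratio", "phase_hours", "phase_sd_hours",
                 "l1_error", "_phase_sd_rad"])
    df.index.name = "gene_id"

    candidate = (df["passed_f24"] & df["converged"]
                 & (df["log_evidence_ratio"] >= log_factor))
    df["candidate"] = candidate

    cand = df[candidate]
    if policy == "quantile":
        if len(cand) == 0:
            raise ValueError("no candidate-circadian genes to define the cohort")
        norm = cohort_norm(cand["_phase_sd_rad"].to_numpy(),
                           cand["l1_error"].to_numpy())
    assert norm is not None
    scores = pd.Series(
        [radial_score(r, l, norm) for r, l in
         zip(df["_phase_sd_rad"], df["l1_error"])],
        index=df.index, dtype=float)
    df["radial_score"] = scores

    if policy == "quantile":
        n = len(cand)
        n_excl = math.ceil(exclude_fraction * n)
        order = sorted(cand.index, key=lambda g: (-scores[g], g))
        excluded = set(order[:n_excl])
        circadian = candidate & ~df.index.isin(excluded)
        retained_scores = scores[circadian]
        threshold = float(retained_scores.max()) if len(retained_scores) else 0.0
    else:
        circadian = candidate & (scores <= threshold)

    df["circadian"] = circadian
    df = df.drop(columns=["_phase_sd_rad"])
    # invariant of the verdict
    bad = df[df["circadian"] & ~(df["passed_f24"]
                                 & (df["log_evidence_ratio"] >= log_factor))]
    if len(bad):
        raise AssertionError(f"inconsistent circadian flags: {bad.index.tolist()}")
    return df, norm, float(threshold)


def phase_histogram(calls: pd.DataFrame, bin_hours: float = 4.0) -> pd.DataFrame:
    """Counts of circadian genes per ZT phase bin; bin sum = circadian count."""
    if 24.0 % bin_hours != 0:
        raise ValueError("bin width must divide 24 h")
    edges = np.arange(0.0, 24.0 + bin_hours, bin_hours)
    if len(calls):
        phases = calls.loc[calls["circadian"], "phase_hours"].to_numpy() % 24.0
    else:
        phases = np.empty(0)
    counts, _ = np.histogram(phases, bins=edges)
    return pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_end": edges[1:],
        "count": counts,
    })
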