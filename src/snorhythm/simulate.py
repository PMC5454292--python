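"""Synthetic nuclear RNA-seq time courses with known ground truth.

The generator emulates the structure of a replicated circadian expression
experiment: six Zeitgeber time points at 4 h spacing, two biological
replicates, and gene classes with 24 h peaked-cosine rhythms, 12 h rhythms,
linear drifts or flat noise.  Optional extras plant snoRNA–host pairs with
configurable abundance ratios and an rRNA-like module: one high-abundance
target series plus a population of "modifier" snoRNA in antiphase with it
(and their positively correlated host genes).

Defaults reflect the study conditions the pipeline is validated under:
amplitudes uniform on [6, 10] TPM, peaking exponent q drawn from {1, 2, 4},
additive Laplace noise of scale 0.5 TPM (clamped at zero to stay a valid
TPM), phases uniform on [0, 24) h.  Every gene draws from its own RNG
substream keyed by (master seed, gene id), so adding genes never perturbs
existing ones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .expression import (DEFAULT_GRID, ExpressionMatrix, ExpressionSeries,
                         GeneAnnotation, TimeGrid, write_annotation_table,
                         write_expression_table)
from .models import CosineQParams, LinearParams, cosineq_eval, linear_eval

logger = logging.getLogger(__name__)

CLASSES = ("cyclic24", "cyclic12", "linear", "flat")

TruthParams = Union[CosineQParams, LinearParams, None]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative class, true parameters and RNG seed for one gene."""

    gene_id: str
    klass: str
    params: TruthParams
    seed_used: int

    def __post_init__(self) -> None:
        if self.klass in ("cyclic24", "cyclic12", "rrna_target", "rrna_modifier"):
            if not isinstance(self.params, CosineQParams):
                raise ValueError(f"{self.gene_id}: cyclic class needs cosine parameters")
        if self.klass == "flat" and self.params is not None:
            raise ValueError(f"{self.gene_id}: flat class carries no parameters")


@dataclass(frozen=True)
class RRNAModuleSpec:
    """One rRNA-like target plus antiphase modifier snoRNA and their hosts."""

    target_label: str = "28S"
    target_phase_hours: float = 16.0
    n_modifiers: int = 20
    antiphase: bool = True
    target_abundance: float = 2.0e5
    modifier_amplitude_range: tuple[float, float] = (10.0, 30.0)
    host_amplitude_range: tuple[float, float] = (5.0, 15.0)


@dataclass(frozen=True)
class GeneratorConfig:
    grid: TimeGrid = DEFAULT_GRID
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"cyclic24": 200, "cyclic12": 100,
                                 "linear": 100, "flat": 200})
    amplitude_range: tuple[float, float] = (6.0, 10.0)
    q_range: tuple[float, float] = (1.0, 4.0)
    q_choices: Optional[tuple[float, ...]] = (1.0, 2.0, 4.0)
    noise_model: str = "laplace"
    noise_scale: float = 0.5
    baseline_range: tuple[float, float] = (1.0, 10.0)
    linear_slope_range: tuple[float, float] = (-0.4, 0.4)
    host_pair_ratios: tuple[float, ...] = ()
    rrna_module: Optional[RRNAModuleSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.n_per_class.items():
            if k not in CLASSES:
                raise ValueError(f"unknown gene class {k!r}")
            if v < 0:
                raise ValueError(f"negative count for class {k!r}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.noise_model not in ("laplace", "gaussian"):
            raise ValueError("noise_model must be 'laplace' or 'gaussian'")
        qs = self.q_choices if self.q_choices is not None else self.q_range
        if min(qs) < 1.0 or max(qs) > 8.0:
            raise ValueError("q values must stay within the fitting prior [1, 8]")


def _noise(rng: np.random.Generator, cfg: GeneratorConfig, shape, scale=None):
    scale = cfg.noise_scale if scale is None else scale
    if cfg.noise_model == "laplace":
        return rng.laplace(0.0, scale, size=shape)
    return rng.normal(0.0, scale, size=shape)


def _observe(mean: np.ndarray, rng, cfg: GeneratorConfig, scale=None) -> np.ndarray:
    vals = mean[None, :] + _noise(rng, cfg, (cfg.grid.n_replicates,
                                             cfg.grid.n_timepoints), scale)
    return np.maximum(vals, 0.0)


def _draw_q(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    if cfg.q_choices is not None:
        return float(rng.choice(np.asarray(cfg.q_choices, dtype=float)))
    return float(rng.uniform(*cfg.q_range))


def _cyclic_gene(gene_id: str, period: float, cfg: GeneratorConfig):
    seed = derive_seed(cfg.seed, "gene", gene_id)
    rng = np.random.default_rng(seed)
    a = float(rng.uniform(*cfg.amplitude_range))
    phase_hours = float(rng.uniform(0.0, 24.0))
    q = _draw_q(rng, cfg)
    p = 2.0 * np.pi * (phase_hours % period) / period
    params = CosineQParams(a=a, p=p, q=q, T=period)
    mean = cosineq_eval(params, cfg.grid.times_array())
    values = _observe(mean, rng, cfg)
    return ExpressionSeries(gene_id, cfg.grid, values), params, seed


def generate_dataset(cfg: GeneratorConfig):
    """Generate a full dataset with truth and annotations.

    Returns ``(ExpressionMatrix, {gene_id: SyntheticTruth},
    {gene_id: GeneAnnotation})``.  Reproducible bit-for-bit from the seed.
    """
    series: list[ExpressionSeries] = []
    truths: dict[str, SyntheticTruth] = {}
    anns: dict[str, GeneAnnotation] = {}
    times = cfg.grid.times_array()

    def add(s, truth, ann):
        series.append(s)
        truths[s.gene_id] = truth
        anns[s.gene_id] = ann

    for klass in CLASSES:
        n = cfg.n_per_class.get(klass, 0)
        for i in range(n):
            gene_id = f"{klass}_{i:04d}"
            if klass in ("cyclic24", "cyclic12"):
                period = 24.0 if klass == "cyclic24" else 12.0
                s, params, seed = _cyclic_gene(gene_id, period, cfg)
                truth = SyntheticTruth(gene_id, klass, params, seed)
            else:
                seed = derive_seed(cfg.seed, "gene", gene_id)
                rng = np.random.default_rng(seed)
                if klass == "linear":
                    b0 = float(rng.uniform(*cfg.baseline_range))
                    b1 = float(rng.uniform(*cfg.linear_slope_range))
                    params = LinearParams(b0=b0, b1=b1)
                    mean = np.maximum(linear_eval(params, times), 0.0)
                    truth = SyntheticTruth(gene_id, klass, params, seed)
                else:  # flat
                    level = float(rng.uniform(*cfg.baseline_range))
                    mean = np.full(cfg.grid.n_timepoints, level)
                    truth = SyntheticTruth(gene_id, klass, None, seed)
                s = ExpressionSeries(gene_id, cfg.grid,
                                     _observe(mean, rng, cfg))
            add(s, truth,
                GeneAnnotation(gene_id=gene_id, biotype="protein_coding"))

    for i, ratio in enumerate(cfg.host_pair_ratios):
        host_id, sno_id = f"host_{i:04d}", f"sno_{i:04d}"
        seed_h = derive_seed(cfg.seed, "gene", host_id)
        rng_h = np.random.default_rng(seed_h)
        level = float(rng_h.uniform(*cfg.baseline_range))
        host_mean = np.full(cfg.grid.n_timepoints, level)
        add(ExpressionSeries(host_id, cfg.grid, _observe(host_mean, rng_h, cfg)),
            SyntheticTruth(host_id, "host", None, seed_h),
            GeneAnnotation(gene_id=host_id, biotype="protein_coding"))
        seed_s = derive_seed(cfg.seed, "gene", sno_id)
        rng_s = np.random.default_rng(seed_s)
        sno_mean = float(ratio) * host_mean
        add(ExpressionSeries(sno_id, cfg.grid, _observe(sno_mean, rng_s, cfg)),
            SyntheticTruth(sno_id, "hosted_snoRNA", None, seed_s),
            GeneAnnotation(gene_id=sno_id, biotype="snoRNA",
                           host_gene_id=host_id,
                           host_category="protein_coding",
                           box_class="CD" if i % 2 == 0 else "HACA"))

    if cfg.rrna_module is not None:
        for s, truth, ann in generate_rrna_module(cfg):
            add(s, truth, ann)

    if not series:
        raise ValueError("configuration generates no genes")
    return ExpressionMatrix.from_series(series), truths, anns


def generate_rrna_module(cfg: GeneratorConfig):
    """Genes of the rRNA module: target, antiphase modifiers, their hosts.

    The target is a high-abundance raised cosine (q = 1) peaking at the
    configured phase, riding on a baseline of a quarter of its amplitude so
    it never vanishes; its replicate noise is scaled in proportion to its
    abundance.  Modifier snoRNA use q = 1 with phase shifted by 12 h when
    the antiphase flag is set, so each modifier's mean is an exactly
    decreasing affine function of the target's mean; host genes are in
    phase with the target (positively correlated).
    """
    spec = cfg.rrna_module
    if spec is None:
        raise ValueError("rrna_module spec absent")
    if spec.n_modifiers == 0 and spec.antiphase:
        logger.warning("rRNA module requested with antiphase but 0 modifiers; "
                       "no genes emitted")
        return []
    times = cfg.grid.times_array()
    label = spec.target_label
    out = []

    def cos_series(gene_id, amplitude, phase_hours, baseline, noise_scale, klass,
                   ann):
        seed = derive_seed(cfg.seed, "gene", gene_id)
        rng = np.random.default_rng(seed)
        p = 2.0 * np.pi * (phase_hours % 24.0) / 24.0
        params = CosineQParams(a=amplitude, p=p, q=1.0, T=24.0)
        mean = baseline + cosineq_eval(params, times)
        values = _observe(mean, rng, cfg, scale=noise_scale)
        return (ExpressionSeries(gene_id, cfg.grid, values),
                SyntheticTruth(gene_id, klass, params, seed), ann)

    target_id = f"rRNA_{label}"
    out.append(cos_series(
        target_id, spec.target_abundance, spec.target_phase_hours,
        0.25 * spec.target_abundance,
        cfg.noise_scale * spec.target_abundance / 10.0,
        "rrna_target",
        GeneAnnotation(gene_id=target_id, biotype="rRNA")))

    mod_phase = spec.target_phase_hours + (12.0 if spec.antiphase else 0.0)
    for i in range(spec.n_modifiers):
        mod_id = f"mod{label}_{i:04d}"
        host_id = f"modhost{label}_{i:04d}"
        seed_a = derive_seed(cfg.seed, "amplitude", mod_id)
        rng_a = np.random.default_rng(seed_a)
        amp = float(rng_a.uniform(*spec.modifier_amplitude_range))
        host_amp = float(rng_a.uniform(*spec.host_amplitude_range))
        out.append(cos_series(
            mod_id, amp, mod_phase, 0.1 * amp, cfg.noise_scale,
            "rrna_modifier",
            GeneAnnotation(gene_id=mod_id, biotype="snoRNA",
                           host_gene_id=host_id,
                           host_category="protein_coding",
                           box_class="CD" if i % 2 == 0 else "HACA",
                           rrna_target=label)))
        out.append(cos_series(
            host_id, host_amp, spec.target_phase_hours, 0.1 * host_amp,
            cfg.noise_scale, "host",
            GeneAnnotation(gene_id=host_id, biotype="protein_coding")))
    return out


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

def write_truth_table(truths: dict[str, SyntheticTruth], path: str | Path) -> None:
    rows = []
    for t in truths.values():
        row = {"gene_id": t.gene_id, "klass": t.klass, "a": "", "p_hours": "",
               "q": "", "b0": "", "b1": "", "seed": t.seed_used}
        if isinstance(t.params, CosineQParams):
            row.update(a=t.params.a, p_hours=t.params.phase_hours, q=t.params.q)
        elif isinstance(t.params, LinearParams):
            row.update(b0=t.params.b0, b1=t.params.b1)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def write_dataset(outdir: str | Path, matrix: ExpressionMatrix,
                  truths: dict[str, SyntheticTruth],
                  anns: dict[str, GeneAnnotation]) -> dict[str, Path]:
    """Write expression.tsv, annotation.tsv and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_table(matrix, paths["expression"])
    write_annotation_table(anns, paths["annotation"])
    write_truth_table(truths, paths["truth"])
    return paths
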