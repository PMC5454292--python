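"""End-to-end orchestration of the pipeline stages.

Library entry points behind the command-line interface.  Each stage
consumes/produces the TSV dialects of `expression`, runs every gene
independently with an RNG substream derived from one master seed, and
never drops a gene silently: `rhythm_analysis` assigns each input gene a
terminal status in {degenerate, failed_f24, non_converged, not_circadian,
circadian}.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .calls import RadialNorm, call_circadian, phase_histogram
from .expression import (DEFAULT_GRID, ExpressionMatrix, GeneAnnotation,
                         TimeGrid, call_expressed, host_ratio_population,
                         load_annotation_table, load_counts_table,
                         load_expression_table, log2_maxmin_fold_change,
                         renormalize_excluding, scale_series)
from .f24 import f24_screen
from .models import COS12, COS24, LINEAR, MODELS
from .nested import FitResult, SamplerConfig, fit_series
from .rrna import correlation_scan
from .simulate import GeneratorConfig, RRNAModuleSpec, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

STATUS_ORDER = ("degenerate", "failed_f24", "non_converged",
                "not_circadian", "circadian")

_FLOAT_FORMAT = "%.10g"


@dataclass
class RhythmRunResult:
    calls: pd.DataFrame          # one row per input gene, terminal status
    f24: pd.DataFrame
    fits: dict[str, dict[str, FitResult]]
    norm: Optional[RadialNorm]
    threshold: Optional[float]


def rhythm_analysis(matrix: ExpressionMatrix,
                    master_seed: int,
                    f24_n_perm: int = 999,
                    f24_threshold: float = 0.2,
                    f24_use_adjusted: bool = True,
                    sampler: Optional[SamplerConfig] = None,
                    policy: str = "quantile",
                    radial_threshold: Optional[float] = None,
                    radial_norm: Optional[RadialNorm] = None,
                    evidence_factor: float = 10.0) -> RhythmRunResult:
    """Full chain: scale -> F24 screen -> 3 model fits -> verdicts.

    Genes are processed independently; per-gene RNG substreams make the
    result invariant to gene order and to adding unrelated genes.
    """
    sampler = sampler or SamplerConfig()

    scaled = {}
    degenerate = set()
    for s in matrix:
        if not s.has_complete_times() or np.any(~np.isfinite(s.values)):
            degenerate.add(s.gene_id)
            continue
        sc = scale_series(s)
        if sc.degenerate:
            degenerate.add(s.gene_id)
        else:
            scaled[s.gene_id] = sc

    fit_input = ExpressionMatrix.from_series(
        [matrix.series(g) for g in matrix.gene_ids if g in scaled]
    ) if scaled else None
    if fit_input is None:
        raise ValueError("no non-degenerate genes to analyse")

    f24 = f24_screen(fit_input, n_perm=f24_n_perm,
                     seed=derive_seed(master_seed, "f24"),
                     threshold=f24_threshold, use_adjusted=f24_use_adjusted)
    passers = [g for g in fit_input.gene_ids if bool(f24.loc[g, "passed"])]
    logger.info("F24 screen: %d/%d genes pass at %.2f",
                len(passers), len(fit_input), f24_threshold)

    fits: dict[str, dict[str, FitResult]] = {}
    for gene_id in passers:
        fits[gene_id] = {
            model: fit_series(scaled[gene_id], model,
                              replace(sampler,
                                      seed=derive_seed(master_seed, "fit",
                                                       gene_id, model)))
            for model in MODELS
        }

    converged_fits = {g: f for g, f in fits.items()
                      if all(f[m].converged for m in MODELS)}
    norm = radial_norm
    threshold = radial_threshold
    if converged_fits:
        try:
            call_df, norm, threshold = call_circadian(
                converged_fits, f24, policy=policy,
                threshold=radial_threshold, norm=radial_norm,
                evidence_factor=evidence_factor)
        except ValueError:
            # no candidate-circadian genes: all fitted genes are negative
            call_df = None
    else:
        call_df = None

    rows = []
    for gene_id in matrix.gene_ids:
        row = {"gene_id": gene_id, "status": "", "passed_f24": False,
               "logZ_cos24": np.nan, "logZ_cos12": np.nan,
               "logZ_linear": np.nan, "evidence_ratio": np.nan,
               "phase_hours": np.nan, "phase_sd_hours": np.nan,
               "l1_error": np.nan, "radial_score": np.nan,
               "circadian": False}
        if gene_id in degenerate:
            row["status"] = "degenerate"
        elif gene_id not in fits:
            row["status"] = "failed_f24"
            row["passed_f24"] = False
        else:
            row["passed_f24"] = True
            f = fits[gene_id]
            row.update(logZ_cos24=f[COS24].logZ, logZ_cos12=f[COS12].logZ,
                       logZ_linear=f[LINEAR].logZ,
                       phase_hours=(f[COS24].param_mean["p"] * 24.0
                                    / (2.0 * np.pi)) % 24.0,
                       phase_sd_hours=f[COS24].param_sd["p"] * 24.0
                       / (2.0 * np.pi),
                       l1_error=f[COS24].l1_error)
            if gene_id not in converged_fits:
                row["status"] = "non_converged"
            elif call_df is None:
                row["status"] = "not_circadian"
            else:
                c = call_df.loc[gene_id]
                row.update(evidence_ratio=c["evidence_ratio"],
                           radial_score=c["radial_score"],
                           circadian=bool(c["circadian"]))
                row["status"] = "circadian" if c["circadian"] else "not_circadian"
        rows.append(row)
    calls = pd.DataFrame(rows).set_index("gene_id")
    assert set(calls["status"]) <= set(STATUS_ORDER)
    return RhythmRunResult(calls=calls, f24=f24, fits=fits,
                           norm=norm, threshold=threshold)


def correlate_analysis(matrix: ExpressionMatrix,
                       ann: Mapping[str, GeneAnnotation],
                       targets: Mapping[str, str],
                       grid_step: float = 0.01,
                       alpha: float = 0.05,
                       include_hosts: bool = True) -> pd.DataFrame:
    """rRNA-excluded renormalisation + regression + enrichment scans.

    ``targets`` maps a target label (e.g. "28S") to the gene_id carrying
    that rRNA's series.  Returns the concatenated scan table with a ``set``
    column distinguishing the modifier scan from the modifiers'-hosts scan.
    """
    rrna_ids = {g for g in matrix.gene_ids
                if g in ann and ann[g].biotype == "rRNA"}
    for label, gid in targets.items():
        if gid not in matrix:
            raise ValueError(f"target series {gid!r} for {label} absent from matrix")
    renorm = renormalize_excluding(matrix, rrna_ids) if rrna_ids else matrix
    expressed = call_expressed(renorm)
    tables = []
    for label, gid in targets.items():
        target_series = matrix.series(gid)
        scan = correlation_scan(renorm, ann, target_series, label,
                                expressed, grid_step=grid_step, alpha=alpha)
        t = scan.table.copy()
        t.insert(0, "set", "modifier")
        tables.append(t)
        if include_hosts:
            hosts = {ann[g].host_gene_id for g in ann
                     if ann[g].biotype == "snoRNA"
                     and ann[g].rrna_target == label and ann[g].host_gene_id}
            host_scan = correlation_scan(
                renorm, ann, target_series, label, expressed,
                modifier_set={h for h in hosts if h in renorm},
                grid_step=grid_step, alpha=alpha)
            th = host_scan.table.copy()
            th.insert(0, "set", "host")
            tables.append(th)
    return pd.concat(tables, ignore_index=True)


def filters_analysis(matrix: ExpressionMatrix,
                     ann: Mapping[str, GeneAnnotation],
                     counts: Optional[pd.DataFrame] = None,
                     host_ratio: float = 10.0) -> pd.DataFrame:
    """Descriptive population filters: expressed, identifiable, host ratio, FC."""
    flags = call_expressed(matrix, counts)
    high_ratio = host_ratio_population(matrix, ann, ratio=host_ratio)
    flags["high_host_ratio"] = [g in high_ratio for g in flags.index]
    flags["log2_maxmin_fc"] = [log2_maxmin_fold_change(matrix.series(g))
                               for g in flags.index]
    return flags


# ---------------------------------------------------------------------------
# Config-file front end
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _grid_from_config(cfg: dict) -> TimeGrid:
    g = cfg.get("grid")
    if not g:
        return DEFAULT_GRID
    return TimeGrid(tuple(g.get("timepoints", DEFAULT_GRID.timepoints)),
                    int(g.get("n_replicates", DEFAULT_GRID.n_replicates)))


def build_generator_config(cfg: dict, seed: int) -> GeneratorConfig:
    gen = dict(cfg.get("generator", {}))
    rrna = gen.pop("rrna_module", None)
    kwargs = {}
    for f in dataclasses.fields(GeneratorConfig):
        if f.name in gen:
            v = gen[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    kwargs["grid"] = _grid_from_config(cfg)
    kwargs["seed"] = seed
    if rrna:
        kwargs["rrna_module"] = RRNAModuleSpec(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in rrna.items()})
    return GeneratorConfig(**kwargs)


def _sampler_from_config(cfg: dict) -> SamplerConfig:
    s = cfg.get("sampler", {})
    return SamplerConfig(
        n_live=int(s.get("n_live", 300)),
        termination_tol=float(s.get("termination_tol", 1e-4)),
        max_iterations=int(s.get("max_iterations", 20000)),
        mcmc_steps=int(s.get("mcmc_steps", 25)),
    )


def _write_manifest(outdir: Path, cfg: dict, seed: int) -> None:
    manifest = {"seed": seed, "config_hash": config_hash(cfg),
                "version": __version__}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _prepare_outdir(outdir: str | Path, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use --force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def run_simulate(cfg: dict, outdir: str | Path, seed: int,
                 force: bool = False) -> Path:
    outdir = _prepare_outdir(outdir, force)
    gen_cfg = build_generator_config(cfg, seed)
    matrix, truths, anns = generate_dataset(gen_cfg)
    write_dataset(outdir, matrix, truths, anns)
    _write_manifest(outdir, cfg, seed)
    logger.info("simulated %d genes into %s", len(matrix), outdir)
    return outdir


def run_rhythm(cfg: dict, outdir: str | Path, seed: int,
               force: bool = False) -> Path:
    outdir = _prepare_outdir(outdir, force)
    grid = _grid_from_config(cfg)
    matrix = load_expression_table(cfg["inputs"]["expression"], grid)
    f24cfg = cfg.get("f24", {})
    radial = cfg.get("radial", {})
    norm = None
    if radial.get("policy", "quantile") == "absolute":
        norm = RadialNorm(phase_sd_max=float(radial["phase_sd_max"]),
                          l1_max=float(radial["l1_max"]))
    result = rhythm_analysis(
        matrix, master_seed=seed,
        f24_n_perm=int(f24cfg.get("n_perm", 999)),
        f24_threshold=float(f24cfg.get("threshold", 0.2)),
        f24_use_adjusted=bool(f24cfg.get("use_adjusted", True)),
        sampler=_sampler_from_config(cfg),
        policy=radial.get("policy", "quantile"),
        radial_threshold=radial.get("threshold"),
        radial_norm=norm,
        evidence_factor=float(cfg.get("evidence_factor", 10.0)),
    )
    result.calls.to_csv(outdir / "calls.tsv", sep="\t",
                        float_format=_FLOAT_FORMAT)
    result.f24.to_csv(outdir / "f24.tsv", sep="\t", float_format=_FLOAT_FORMAT)
    phase_histogram(result.calls).to_csv(outdir / "phases.tsv", sep="\t",
                                         index=False, float_format=_FLOAT_FORMAT)
    _write_manifest(outdir, cfg, seed)
    counts = result.calls["status"].value_counts().to_dict()
    logger.info("rhythm run complete: %s", counts)
    return outdir


def run_correlate(cfg: dict, outdir: str | Path, seed: int,
                  force: bool = False) -> Path:
    outdir = _prepare_outdir(outdir, force)
    grid = _grid_from_config(cfg)
    matrix = load_expression_table(cfg["inputs"]["expression"], grid)
    ann = load_annotation_table(cfg["inputs"]["annotation"])
    scan_cfg = cfg.get("scan", {})
    targets = scan_cfg.get("targets")
    if not targets:
        raise ValueError("scan.targets must map target labels to gene ids")
    table = correlate_analysis(matrix, ann, targets,
                               grid_step=float(scan_cfg.get("grid_step", 0.01)),
                               alpha=float(scan_cfg.get("alpha", 0.05)))
    table.to_csv(outdir / "scan.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FORMAT)
    _write_manifest(outdir, cfg, seed)
    return outdir


def run_filters(cfg: dict, outdir: str | Path, seed: int,
                force: bool = False) -> Path:
    outdir = _prepare_outdir(outdir, force)
    grid = _grid_from_config(cfg)
    matrix = load_expression_table(cfg["inputs"]["expression"], grid)
    ann = load_annotation_table(cfg["inputs"]["annotation"])
    counts = None
    if cfg["inputs"].get("counts"):
        counts = load_counts_table(cfg["inputs"]["counts"], grid)
    table = filters_analysis(matrix, ann, counts,
                             host_ratio=float(cfg.get("host_ratio", 10.0)))
    table.to_csv(outdir / "filters.tsv", sep="\t", float_format=_FLOAT_FORMAT)
    _write_manifest(outdir, cfg, seed)
    return outdir
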