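"""Expression-table I/O, scaling and population filters.

The unit of analysis is a gene's replicate × time TPM matrix on a shared
Zeitgeber-time grid (default ZT0..ZT20 at 4 h spacing, two biological
replicates per time point).  This module reads and writes the tab-separated
dialect used throughout the pipeline, rescales series for model fitting
(min median 0, max median 10), renormalises TPM after excluding genes
(e.g. rRNA), and computes the descriptive population filters: expressed /
identifiable calls, snoRNA-over-host abundance ratios, and max/min fold
changes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_ID_COLUMN = "gene_id"

BIOTYPES = frozenset(
    {"snoRNA", "protein_coding", "processed_transcript", "lincRNA", "rRNA", "other"}
)
HOST_CATEGORIES = frozenset(
    {"protein_coding", "processed_transcript", "lincRNA", "antisense", "non_genic"}
)
BOX_CLASSES = frozenset({"CD", "HACA", "unknown"})
RRNA_TARGETS = frozenset({"18S", "28S", "5.8S", "none"})

#: Relative tolerance below which a series' median dynamic range counts as zero.
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class TimeGrid:
    """Sampling design: ZT time points (hours after dawn) × replicate count."""

    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_replicates: int = 2

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        if len(tps) < 1:
            raise ValueError("TimeGrid needs at least one time point")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("time points must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def span_hours(self) -> float:
        return self.timepoints[-1] - self.timepoints[0]

    def sample_labels(self) -> list[str]:
        """Column labels ZT{t}_rep{r}, time-major to match the table dialect."""
        return [
            f"ZT{t:g}_rep{r}"
            for t in self.timepoints
            for r in range(1, self.n_replicates + 1)
        ]

    def times_array(self) -> np.ndarray:
        return np.asarray(self.timepoints, dtype=float)


DEFAULT_GRID = TimeGrid()


@dataclass(frozen=True)
class ExpressionSeries:
    """One gene's TPM observations, shaped (replicate, timepoint).

    Missing cells are NaN; all observed values must be non-negative.
    """

    gene_id: str
    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_replicates, self.grid.n_timepoints)
        if vals.shape != expected:
            raise ValueError(
                f"{self.gene_id}: values shape {vals.shape} != grid shape {expected}"
            )
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"{self.gene_id}: negative TPM values")
        object.__setattr__(self, "values", vals)

    def per_time_medians(self) -> np.ndarray:
        """Median across available replicates at each time point."""
        with np.errstate(all="ignore"):
            return np.nanmedian(self.values, axis=0)

    def has_complete_times(self) -> bool:
        """True if every time point has at least one observed replicate."""
        return bool(np.all(np.any(np.isfinite(self.values), axis=0)))


@dataclass(frozen=True)
class ScaledSeries:
    """A series rescaled so per-time medians span [0, 10], with the inverse map.

    ``scaled = (raw - offset) * gain``.  ``degenerate`` marks zero dynamic
    range (all per-time medians equal): such series are excluded from
    fitting rather than divided by zero.
    """

    series: ExpressionSeries
    offset: float
    gain: float
    degenerate: bool

    def invert(self) -> ExpressionSeries:
        raw = self.series.values / self.gain + self.offset
        return ExpressionSeries(self.series.gene_id, self.series.grid, raw)


class ExpressionMatrix:
    """Gene × sample TPM table on one shared TimeGrid.

    Backed by a pandas DataFrame indexed by gene_id with columns
    ``ZT{t}_rep{r}`` in time-major order.
    """

    def __init__(self, data: pd.DataFrame, grid: TimeGrid):
        labels = grid.sample_labels()
        missing = [c for c in labels if c not in data.columns]
        if missing:
            raise ValueError(f"missing sample columns: {missing}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id entries: {dups}")
        self.data = data.loc[:, labels].astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = GENE_ID_COLUMN
        self.grid = grid

    # -- construction ------------------------------------------------------
    @classmethod
    def from_series(cls, series: Iterable[ExpressionSeries]) -> "ExpressionMatrix":
        series = list(series)
        if not series:
            raise ValueError("no series given")
        grid = series[0].grid
        rows = {}
        for s in series:
            if s.grid != grid:
                raise ValueError("all series must share one TimeGrid")
            # (replicate, time) -> time-major flat vector
            rows[s.gene_id] = s.values.T.reshape(-1)
        df = pd.DataFrame.from_dict(rows, orient="index", columns=grid.sample_labels())
        return cls(df, grid)

    # -- access ------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_labels(self) -> list[str]:
        return self.data.columns.tolist()

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index

    def series(self, gene_id: str) -> ExpressionSeries:
        if gene_id not in self.data.index:
            raise KeyError(gene_id)
        flat = self.data.loc[gene_id].to_numpy(dtype=float)
        vals = flat.reshape(self.grid.n_timepoints, self.grid.n_replicates).T
        return ExpressionSeries(gene_id, self.grid, vals)

    def __iter__(self) -> Iterator[ExpressionSeries]:
        for g in self.gene_ids:
            yield self.series(g)

    def values_3d(self) -> np.ndarray:
        """All values as an array shaped (gene, replicate, timepoint)."""
        arr = self.data.to_numpy(dtype=float)
        return arr.reshape(len(self.data), self.grid.n_timepoints, self.grid.n_replicates)\
            .transpose(0, 2, 1)

    def per_time_medians(self) -> pd.DataFrame:
        """Per-gene median across replicates at each time point."""
        with np.errstate(all="ignore"):
            med = np.nanmedian(self.values_3d(), axis=1)
        return pd.DataFrame(med, index=self.data.index,
                            columns=[f"ZT{t:g}" for t in self.grid.timepoints])


@dataclass(frozen=True)
class GeneAnnotation:
    """Biotype / host / box-class / rRNA-target annotation for one gene.

    ``host_category == "non_genic"`` iff there is no host gene; antisense
    genes carry the overlapped gene as their host.
    """

    gene_id: str
    biotype: str
    host_gene_id: Optional[str] = None
    host_category: str = "non_genic"
    box_class: str = "unknown"
    rrna_target: str = "none"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if self.host_category not in HOST_CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown host_category {self.host_category!r}")
        if self.box_class not in BOX_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown box_class {self.box_class!r}")
        if self.rrna_target not in RRNA_TARGETS:
            raise ValueError(f"{self.gene_id}: unknown rrna_target {self.rrna_target!r}")
        has_host = self.host_gene_id is not None and self.host_gene_id != ""
        if has_host == (self.host_category == "non_genic"):
            raise ValueError(
                f"{self.gene_id}: host_category {self.host_category!r} inconsistent "
                f"with host_gene_id {self.host_gene_id!r}"
            )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def load_expression_table(path: str | Path, grid_spec: TimeGrid = DEFAULT_GRID) -> ExpressionMatrix:
    """Read a tab-separated gene × sample TPM table onto ``grid_spec``.

    The header must name one ``gene_id`` column and one ``ZT{t}_rep{r}``
    column for every (time, replicate) in the grid; duplicated gene ids and
    non-numeric cells are hard errors.  Empty cells become missing values.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if GENE_ID_COLUMN not in raw.columns:
        raise ValueError(f"{path}: no '{GENE_ID_COLUMN}' column")
    labels = grid_spec.sample_labels()
    missing = [c for c in labels if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing sample column(s) {missing}")
    raw = raw.set_index(GENE_ID_COLUMN)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene_id row(s): {dups}")
    numeric = {}
    for col in labels:
        try:
            numeric[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[coerced.isna() & raw[col].notna()].tolist()
            raise ValueError(f"{path}: non-numeric cell(s) in column {col}, rows {bad}")
    return ExpressionMatrix(pd.DataFrame(numeric, index=raw.index), grid_spec)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the TSV dialect `load_expression_table` reads."""
    m.data.to_csv(path, sep="\t", float_format="%.10g")


def load_annotation_table(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read the annotation TSV (gene_id, biotype, host_gene_id, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["gene_id", "biotype", "host_gene_id", "host_category",
                "box_class", "rrna_target"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {missing}")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = GeneAnnotation(
            gene_id=row.gene_id,
            biotype=row.biotype,
            host_gene_id=row.host_gene_id or None,
            host_category=row.host_category or "non_genic",
            box_class=row.box_class or "unknown",
            rrna_target=row.rrna_target or "none",
        )
        if ann.gene_id in out:
            raise ValueError(f"{path}: duplicated annotation for {ann.gene_id}")
        out[ann.gene_id] = ann
    return out


def write_annotation_table(anns: Mapping[str, GeneAnnotation] | Iterable[GeneAnnotation],
                           path: str | Path) -> None:
    if isinstance(anns, Mapping):
        anns = anns.values()
    rows = [
        {
            "gene_id": a.gene_id,
            "biotype": a.biotype,
            "host_gene_id": a.host_gene_id or "",
            "host_category": a.host_category,
            "box_class": a.box_class,
            "rrna_target": a.rrna_target,
        }
        for a in anns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_counts_table(path: str | Path, grid_spec: TimeGrid = DEFAULT_GRID) -> pd.DataFrame:
    """Read a unique-read count table (same sample columns, integer cells)."""
    df = pd.read_csv(path, sep="\t").set_index(GENE_ID_COLUMN)
    labels = grid_spec.sample_labels()
    missing = [c for c in labels if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample column(s) {missing}")
    return df.loc[:, labels]


# ---------------------------------------------------------------------------
# Scaling and renormalisation
# ---------------------------------------------------------------------------

def scale_series(s: ExpressionSeries) -> ScaledSeries:
    """Affinely rescale so the per-time medians span exactly [0, 10].

    A series whose per-time medians are all equal has no dynamic range to
    scale; it is returned unchanged and flagged ``degenerate`` so callers
    exclude it from fitting.
    """
    if s.grid.n_timepoints < 2:
        raise ValueError(f"{s.gene_id}: need >= 2 time points to scale")
    med = s.per_time_medians()
    if np.any(~np.isfinite(med)):
        raise ValueError(f"{s.gene_id}: time point with no observed replicate")
    lo, hi = float(np.min(med)), float(np.max(med))
    if hi - lo <= _DEGENERATE_RTOL * max(1.0, abs(hi)):
        return ScaledSeries(series=s, offset=0.0, gain=1.0, degenerate=True)
    gain = 10.0 / (hi - lo)
    scaled = np.where(np.isfinite(s.values), (s.values - lo) * gain, np.nan)
    # clamp tiny negatives from replicates below the minimum median: allowed,
    # the model range is [0, a] but observations may sit below 0 after shift
    out = ExpressionSeries.__new__(ExpressionSeries)
    object.__setattr__(out, "gene_id", s.gene_id)
    object.__setattr__(out, "grid", s.grid)
    object.__setattr__(out, "values", scaled)
    return ScaledSeries(series=out, offset=lo, gain=gain, degenerate=False)


def renormalize_excluding(m: ExpressionMatrix, excluded: Iterable[str]) -> ExpressionMatrix:
    """Drop ``excluded`` genes and rescale each sample column to sum 10^6.

    This is the step that removes rRNA before correlation analyses, so that
    fluctuations in total rRNA do not drive apparent co-variation in the
    remaining genes.
    """
    excluded = set(excluded)
    unknown = excluded - set(m.gene_ids)
    if unknown:
        raise ValueError(f"excluded genes not in matrix: {sorted(unknown)}")
    keep = [g for g in m.gene_ids if g not in excluded]
    if not keep:
        raise ValueError("cannot exclude every gene")
    data = m.data.loc[keep]
    colsum = data.sum(axis=0, skipna=True)
    if np.any(colsum.to_numpy() <= 0):
        bad = colsum.index[colsum <= 0].tolist()
        raise ValueError(f"sample column(s) with zero total after exclusion: {bad}")
    return ExpressionMatrix(data * (1e6 / colsum), m.grid)


# ---------------------------------------------------------------------------
# Population filters
# ---------------------------------------------------------------------------

def call_expressed(m: ExpressionMatrix,
                   unique_counts: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-gene expressed / identifiable flags.

    A gene is *expressed* if its TPM exceeds the first quartile of the TPM
    distribution of that sample in at least one sample (quartile by the
    linear-interpolation convention).  It is *identifiable* if it has at
    least one uniquely mapping read in any sample; with no count table every
    gene is identifiable by default (logged).
    """
    if len(m) == 0:
        raise ValueError("empty expression matrix")
    arr = m.data.to_numpy(dtype=float)
    q1 = np.nanpercentile(arr, 25, axis=0)  # per sample column
    expressed = np.any(np.where(np.isfinite(arr), arr, -np.inf) > q1, axis=1)
    if unique_counts is None:
        logger.warning("no unique-read count table supplied; "
                       "all genes treated as identifiable")
        identifiable = np.ones(len(m), dtype=bool)
    else:
        missing = set(m.gene_ids) - set(unique_counts.index.astype(str))
        if missing:
            raise ValueError(f"count table missing gene(s): {sorted(missing)}")
        counts = unique_counts.loc[m.gene_ids, m.sample_labels].to_numpy(dtype=float)
        identifiable = np.nansum(counts >= 1, axis=1) > 0
    return pd.DataFrame(
        {"expressed": expressed, "identifiable": identifiable},
        index=pd.Index(m.gene_ids, name=GENE_ID_COLUMN),
    )


def host_ratio_population(m: ExpressionMatrix,
                          ann: Mapping[str, GeneAnnotation],
                          ratio: float = 10.0) -> set[str]:
    """snoRNA at least ``ratio`` times their host at every time point.

    Compared on unscaled per-time medians, boundary inclusive.  snoRNA whose
    host is absent from the matrix are skipped with a warning.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    out: set[str] = set()
    for a in ann.values():
        if a.biotype != "snoRNA" or not a.host_gene_id:
            continue
        if a.gene_id not in m:
            continue
        if a.host_gene_id not in m:
            logger.warning("host %s of snoRNA %s absent from matrix; skipped",
                           a.host_gene_id, a.gene_id)
            continue
        sno = m.series(a.gene_id).per_time_medians()
        host = m.series(a.host_gene_id).per_time_medians()
        if np.any(~np.isfinite(sno)) or np.any(~np.isfinite(host)):
            logger.warning("missing time point for pair %s/%s; skipped",
                           a.gene_id, a.host_gene_id)
            continue
        if np.all(sno >= ratio * host):
            out.add(a.gene_id)
    return out


def log2_maxmin_fold_change(s: ExpressionSeries, pseudocount: float = 0.01) -> float:
    """log2 of (max over min) per-time median TPM over the time course.

    When the minimum median is zero, ``pseudocount`` TPM is added to both
    extremes to keep the ratio finite.
    """
    med = s.per_time_medians()
    med = med[np.isfinite(med)]
    if med.size == 0:
        raise ValueError(f"{s.gene_id}: no observed time points")
    mx, mn = float(np.max(med)), float(np.min(med))
    c = pseudocount if mn <= 0 else 0.0
    return float(np.log2((mx + c) / (mn + c)))
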