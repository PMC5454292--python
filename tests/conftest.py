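import numpy as np
import pytest

from snorhythm.expression import DEFAULT_GRID, ExpressionSeries, TimeGrid


@pytest.fixture
def grid() -> TimeGrid:
    return DEFAULT_GRID


def make_series(values, gene_id="g", grid=DEFAULT_GRID) -> ExpressionSeries:
    """Build a series from a (replicate, time) array-like."""
    return ExpressionSeries(gene_id, grid, np.asarray(values, dtype=float))


def series_from_medians(medians, gene_id="g", grid=DEFAULT_GRID) -> ExpressionSeries:
    """Series whose replicates all equal the given per-time medians."""
    med = np.asarray(medians, dtype=float)
    return ExpressionSeries(gene_id, grid,
                            np.tile(med, (grid.n_replicates, 1)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
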