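import math

import numpy as np
import pandas as pd
import pytest

from snorhythm.expression import (ExpressionMatrix, GeneAnnotation,
                                  call_expressed, renormalize_excluding)
from snorhythm.rrna import (correlation_scan, hypergeometric_lower_tail,
                            hypergeometric_tail, regress_vs_target)
from snorhythm.simulate import (GeneratorConfig, RRNAModuleSpec,
                                generate_dataset)

from conftest import make_series


class TestRegression:
    def _series(self, values, gene_id="g"):
        return make_series(np.asarray(values).reshape(2, 6), gene_id)

    def test_exact_positive_line(self, rng):
        x = rng.uniform(1, 10, 12)
        r = regress_vs_target(self._series(2 * x, "y"), self._series(x, "x"))
        assert r.slope == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.direction == "positive"

    def test_exact_negative_line(self, rng):
        x = rng.uniform(1, 8, 12)
        r = regress_vs_target(self._series(-x + 10, "y"), self._series(x, "x"))
        assert r.slope == pytest.approx(-1.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.direction == "negative"

    def test_matches_textbook_ols(self, rng):
        x = rng.uniform(0, 10, 12)
        y = rng.uniform(0, 10, 12)
        r = regress_vs_target(self._series(y), self._series(x, "t"))
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        assert r.slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert r.intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean(),
                                            abs=1e-10)
        assert r.r_squared == pytest.approx(sxy ** 2 / (sxx * syy), abs=1e-10)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            regress_vs_target(self._series(np.arange(12.0)),
                              self._series(np.ones(12), "t"))

    def test_constant_gene_is_flat(self, rng):
        r = regress_vs_target(self._series(np.full(12, 3.0)),
                              self._series(rng.uniform(1, 5, 12), "t"))
        assert r.direction == "flat" and r.r_squared == 0.0


class TestHypergeometricTail:
    def test_extreme_overlap_closed_form(self):
        assert hypergeometric_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_hits_is_certain(self):
        assert hypergeometric_tail(0, 5, 5, 10) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)) / math.comb(N, n)
            assert hypergeometric_tail(k, K, n, N) == pytest.approx(
                expected, abs=1e-12)

    def test_lower_and_upper_tails_cover(self):
        p_hi = hypergeometric_tail(3, 10, 8, 25)
        p_lo = hypergeometric_lower_tail(2, 10, 8, 25)
        assert p_hi + p_lo == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(6, 5, 5, 10)


MODULE_CFG = GeneratorConfig(
    n_per_class={"cyclic24": 0, "cyclic12": 0, "linear": 0, "flat": 100},
    rrna_module=RRNAModuleSpec(n_modifiers=10), seed=42)


@pytest.fixture(scope="module")
def rrna_dataset():
    m, truths, anns = generate_dataset(MODULE_CFG)
    renorm = renormalize_excluding(m, {"rRNA_28S"})
    expressed = call_expressed(renorm)
    return m, anns, renorm, expressed


class TestCorrelationScan:
    def test_refuses_matrix_with_rrna(self, rrna_dataset):
        m, anns, renorm, expressed = rrna_dataset
        with pytest.raises(ValueError, match="rRNA"):
            correlation_scan(m, anns, m.series("rRNA_28S"), "28S", expressed)

    def test_antiphase_module_significant_negative_only(self, rrna_dataset):
        m, anns, renorm, expressed = rrna_dataset
        scan = correlation_scan(renorm, anns, m.series("rRNA_28S"), "28S",
                                expressed, grid_step=0.05)
        t = scan.table
        at_0 = t[(t.r2_threshold == 0.0) & (t.direction == "negative")]
        assert float(at_0["p"].iloc[0]) < 0.05
        assert scan.max_significant_r2["negative"] > 0.3
        assert not (scan.max_significant_r2["positive"] > 0.0)

    def test_counts_non_increasing_in_threshold(self, rrna_dataset):
        m, anns, renorm, expressed = rrna_dataset
        scan = correlation_scan(renorm, anns, m.series("rRNA_28S"), "28S",
                                expressed, grid_step=0.1)
        for direction in ("negative", "positive"):
            sub = scan.table[scan.table.direction == direction]
            assert np.all(np.diff(sub["k"].to_numpy()) <= 0)
            assert np.all(np.diff(sub["K"].to_numpy()) <= 0)

    def test_nothing_at_r2_one_gives_p_one(self, rrna_dataset):
        m, anns, renorm, expressed = rrna_dataset
        scan = correlation_scan(renorm, anns, m.series("rRNA_28S"), "28S",
                                expressed, grid_step=0.5)
        top = scan.table[scan.table.r2_threshold == 1.0]
        assert (top["p"] == 1.0).all()
        assert (top["k"] == 0).all()

    def test_label_shuffled_modifiers_not_enriched(self, rrna_dataset):
        m, anns, renorm, expressed = rrna_dataset
        rng = np.random.default_rng(7)
        flats = [g for g in renorm.gene_ids if g.startswith("flat_")]
        fake = set(rng.choice(flats, size=10, replace=False))
        scan = correlation_scan(renorm, anns, m.series("rRNA_28S"), "28S",
                                expressed, modifier_set=fake, grid_step=0.05)
        frac_sig = float((scan.table["p"] < 0.05).mean())
        assert frac_sig <= 0.25
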