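import numpy as np
import pandas as pd
import pytest

from snorhythm.expression import (DEFAULT_GRID, ExpressionMatrix, GeneAnnotation,
                                  TimeGrid, call_expressed,
                                  host_ratio_population, load_expression_table,
                                  log2_maxmin_fold_change,
                                  renormalize_excluding, scale_series,
                                  write_expression_table)
from snorhythm.simulate import GeneratorConfig, generate_dataset

from conftest import make_series, series_from_medians


def random_matrix(rng, n_genes=5, grid=DEFAULT_GRID):
    series = [make_series(rng.uniform(0, 100, (grid.n_replicates,
                                               grid.n_timepoints)),
                          gene_id=f"g{i}", grid=grid)
              for i in range(n_genes)]
    return ExpressionMatrix.from_series(series)


class TestTableIO:
    def test_roundtrip_full_precision(self, rng, tmp_path):
        m = random_matrix(rng)
        path = tmp_path / "expr.tsv"
        write_expression_table(m, path)
        back = load_expression_table(path, m.grid)
        assert back.gene_ids == m.gene_ids
        np.testing.assert_allclose(back.data.to_numpy(), m.data.to_numpy(),
                                   rtol=1e-9)

    def test_header_forces_shape(self, rng, tmp_path):
        m = random_matrix(rng, n_genes=3)
        path = tmp_path / "expr.tsv"
        write_expression_table(m, path)
        back = load_expression_table(path, DEFAULT_GRID)
        assert len(back) == 3
        assert back.series("g0").values.shape == (2, 6)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        cols = "\t".join(DEFAULT_GRID.sample_labels())
        row = "\t".join(["1"] * 12)
        path = tmp_path / "dup.tsv"
        path.write_text(f"gene_id\t{cols}\ng1\t{row}\ng1\t{row}\n")
        with pytest.raises(ValueError, match="g1"):
            load_expression_table(path)

    def test_missing_sample_column_named(self, rng, tmp_path):
        m = random_matrix(rng)
        df = m.data.drop(columns=["ZT8_rep2"])
        path = tmp_path / "short.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="ZT8_rep2"):
            load_expression_table(path)

    def test_non_numeric_cell_located(self, rng, tmp_path):
        m = random_matrix(rng)
        df = m.data.astype(object)
        df.loc["g1", "ZT4_rep1"] = "oops"
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="ZT4_rep1"):
            load_expression_table(path)


class TestScaling:
    def test_medians_mapped_to_0_10(self):
        grid = TimeGrid((0.0, 4.0, 8.0), 2)
        s = series_from_medians([2, 4, 6], grid=grid)
        sc = scale_series(s)
        np.testing.assert_allclose(sc.series.per_time_medians(), [0, 5, 10])
        assert not sc.degenerate

    def test_already_scaled_unchanged(self):
        s = series_from_medians([0, 2, 4, 6, 8, 10])
        sc = scale_series(s)
        np.testing.assert_allclose(sc.series.values, s.values)

    def test_constant_series_flagged_degenerate(self):
        s = series_from_medians([5, 5, 5, 5, 5, 5])
        sc = scale_series(s)
        assert sc.degenerate

    def test_inverse_recovers_input(self, rng):
        for _ in range(20):
            s = make_series(rng.uniform(0, 50, (2, 6)))
            sc = scale_series(s)
            if sc.degenerate:
                continue
            np.testing.assert_allclose(sc.invert().values, s.values, rtol=1e-9)


class TestRenormalize:
    ONE_SAMPLE = TimeGrid((0.0,), 1)

    def test_proportional_rescale(self):
        m = ExpressionMatrix.from_series([
            make_series([[500000.0]], "rRNA", self.ONE_SAMPLE),
            make_series([[300000.0]], "A", self.ONE_SAMPLE),
            make_series([[200000.0]], "B", self.ONE_SAMPLE),
        ])
        out = renormalize_excluding(m, {"rRNA"})
        assert out.gene_ids == ["A", "B"]
        np.testing.assert_allclose(out.data.loc["A"], 600000.0)
        np.testing.assert_allclose(out.data.loc["B"], 400000.0)

    def test_identity_when_nothing_excluded(self):
        m = ExpressionMatrix.from_series([
            make_series([[600000.0]], "A", self.ONE_SAMPLE),
            make_series([[400000.0]], "B", self.ONE_SAMPLE),
        ])
        out = renormalize_excluding(m, set())
        np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_column_sums_one_million(self, rng):
        m = random_matrix(rng, n_genes=8)
        out = renormalize_excluding(m, {"g0", "g3"})
        np.testing.assert_allclose(out.data.sum(axis=0), 1e6, rtol=1e-6)

    def test_excluding_everything_fails(self, rng):
        m = random_matrix(rng, n_genes=2)
        with pytest.raises(ValueError):
            renormalize_excluding(m, {"g0", "g1"})


class TestCallExpressed:
    ONE_SAMPLE = TimeGrid((0.0,), 1)

    def test_first_quartile_rule(self):
        m = ExpressionMatrix.from_series([
            make_series([[v]], f"g{v}", self.ONE_SAMPLE)
            for v in [0.0, 1.0, 2.0, 3.0]
        ])
        flags = call_expressed(m)
        # Q1 of {0,1,2,3} = 0.75 under linear interpolation
        assert not flags.loc["g0.0", "expressed"]
        assert flags.loc[["g1.0", "g2.0", "g3.0"], "expressed"].all()

    def test_any_sample_suffices(self, rng):
        vals = np.full((2, 6), 1.0)
        high = vals.copy()
        high[0, 3] = 500.0  # above threshold in exactly one sample
        m = ExpressionMatrix.from_series(
            [make_series(high, "hit")] +
            [make_series(vals * rng.uniform(0.5, 2), f"bg{i}") for i in range(10)])
        assert call_expressed(m).loc["hit", "expressed"]

    def test_reordering_invariance(self, rng):
        m = random_matrix(rng, n_genes=9)
        flags = call_expressed(m)
        shuffled = ExpressionMatrix(m.data.sample(frac=1, random_state=7), m.grid)
        flags2 = call_expressed(shuffled)
        pd.testing.assert_frame_equal(flags, flags2.loc[flags.index])

    def test_identifiable_requires_a_unique_read(self, rng):
        m = random_matrix(rng, n_genes=3)
        counts = pd.DataFrame(1, index=m.gene_ids, columns=m.sample_labels)
        counts.loc["g1"] = 0
        flags = call_expressed(m, counts)
        assert not flags.loc["g1", "identifiable"]
        assert flags.loc[["g0", "g2"], "identifiable"].all()

    def test_count_table_must_cover_genes(self, rng):
        m = random_matrix(rng, n_genes=3)
        counts = pd.DataFrame(1, index=["g0", "g1"], columns=m.sample_labels)
        with pytest.raises(ValueError, match="g2"):
            call_expressed(m, counts)


def _pair_annotation(sno, host):
    return {
        sno: GeneAnnotation(gene_id=sno, biotype="snoRNA", host_gene_id=host,
                            host_category="protein_coding"),
        host: GeneAnnotation(gene_id=host, biotype="protein_coding"),
    }


class TestHostRatio:
    def test_boundary_ratio_included(self):
        sno = series_from_medians([50, 60, 70, 80, 90, 100], "sno")
        host = series_from_medians([5, 6, 7, 8, 9, 10], "host")
        m = ExpressionMatrix.from_series([sno, host])
        assert host_ratio_population(m, _pair_annotation("sno", "host")) == {"sno"}

    def test_single_low_timepoint_excludes(self):
        sno_med = [50, 60, 70, 80, 90, 99]  # last ratio 9.9
        sno = series_from_medians(sno_med, "sno")
        host = series_from_medians([5, 6, 7, 8, 9, 10], "host")
        m = ExpressionMatrix.from_series([sno, host])
        assert host_ratio_population(m, _pair_annotation("sno", "host")) == set()

    def test_planted_pairs_recovered_exactly(self):
        cfg = GeneratorConfig(
            n_per_class={"cyclic24": 0, "cyclic12": 0, "linear": 0, "flat": 5},
            host_pair_ratios=(25.0, 40.0, 2.0, 4.0),
            noise_scale=0.01, seed=3)
        m, truths, anns = generate_dataset(cfg)
        assert host_ratio_population(m, anns) == {"sno_0000", "sno_0001"}

    def test_monotone_in_ratio(self):
        cfg = GeneratorConfig(
            n_per_class={"cyclic24": 0, "cyclic12": 0, "linear": 0, "flat": 0},
            host_pair_ratios=tuple(np.linspace(2, 40, 8)),
            noise_scale=0.05, seed=4)
        m, truths, anns = generate_dataset(cfg)
        previous = None
        for ratio in [2, 5, 10, 20, 50]:
            current = host_ratio_population(m, anns, ratio=ratio)
            if previous is not None:
                assert current <= previous
            previous = current


class TestFoldChange:
    def test_examples(self):
        assert log2_maxmin_fold_change(
            series_from_medians([2, 2, 2, 8, 2, 2])) == pytest.approx(2.0)
        assert log2_maxmin_fold_change(
            series_from_medians([3, 3, 3, 3, 3, 3])) == pytest.approx(0.0)

    def test_matches_direct_recomputation(self, rng):
        for _ in range(25):
            s = make_series(rng.uniform(0.1, 100, (2, 6)))
            med = np.median(s.values, axis=0)
            expected = np.log2(med.max() / med.min())
            assert log2_maxmin_fold_change(s) == pytest.approx(expected, abs=1e-12)

    def test_pseudocount_guards_zero(self):
        s = series_from_medians([0, 1, 2, 3, 4, 5])
        fc = log2_maxmin_fold_change(s)
        assert np.isfinite(fc)
        assert fc == pytest.approx(np.log2(5.01 / 0.01))
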