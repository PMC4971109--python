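import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from conftest import random_cds
from pancub.codon_metrics import compute_metrics, count_codons, rscu
from pancub.errors import DegenerateResultError, UndefinedInputError, ValidationError
from pancub.genetic_code import reverse_complement, standard_code
from pancub.io_formats import ExpressionTable, GeneRecord, TRNATable
from pancub.selection_analysis import (
    axis_factor_correlations,
    coa_rscu,
    enc_plot,
    expected_nc,
    expression_correlation,
    neutrality_plot,
    one_way_anova,
    spearman_rho,
    trna_codon_vector,
    trna_similarity_by_set,
)
from pancub.synthetic_data import (
    SyntheticConfig,
    default_preferred_codons,
    generate_gene_sequence,
    generate_trna_table,
)


def _row(**kwargs):
    """Minimal metric-row stand-in for diagnostics that only touch a few fields."""
    defaults = dict(
        gene_id="g", set_label="core", gc3=0.5, gc12=0.5, nc=50.0, cai=0.5,
    )
    defaults.update(kwargs)
    return type("Row", (), defaults)()


class TestExpectedNc:
    def test_midpoint(self):
        assert expected_nc(0.5) == pytest.approx(60.5)

    def test_endpoints(self):
        assert expected_nc(0.0) == pytest.approx(31.0)
        assert expected_nc(1.0) == pytest.approx(32.0)

    @pytest.mark.parametrize("x", [0.1, 0.25, 0.4])
    def test_symmetry(self, x):
        assert expected_nc(x) - x == pytest.approx(expected_nc(1 - x) - (1 - x))

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            expected_nc(1.5)


class TestEncPlot:
    def test_no_deviation(self):
        m = _row(gene_id="g1", nc=expected_nc(0.5), gc3=0.5)
        result = enc_plot([m])
        assert result.genes["deviation"][0] == pytest.approx(0.0)
        assert not result.genes["deviated"][0]

    def test_hand_deviation(self):
        # expected 60, estimated 45: deviation 0.25, deviated at 0.15
        # (gc3 chosen so the curve gives ~60, then scaled exactly)
        m = _row(gene_id="g1", nc=45.0, gc3=0.5)
        result = enc_plot([m])
        expected = expected_nc(0.5)
        assert result.genes["deviation"][0] == pytest.approx(
            (expected - 45.0) / expected
        )
        assert result.genes["deviated"][0]

    def test_missing_nc_counted(self):
        rows = [_row(gene_id="g1"), _row(gene_id="g2", nc=float("nan"))]
        result = enc_plot(rows)
        assert result.n_missing == 1
        assert len(result.genes) == 1

    def test_sweep_monotone_in_threshold(self, small_metrics):
        result = enc_plot(small_metrics)
        for label, sub in result.sweep.groupby("set_label"):
            ordered = sub.sort_values("threshold")["fraction_deviated"]
            assert (ordered.diff().dropna() <= 1e-12).all()


class TestNeutralityPlot:
    def test_perfectly_collinear(self):
        rows = [
            _row(gene_id=f"g{i}", gc3=x, gc12=x)
            for i, x in enumerate([0.2, 0.4, 0.6, 0.8])
        ]
        table = neutrality_plot(rows).table
        assert table["slope"][0] == pytest.approx(1.0)
        assert table["r"][0] == pytest.approx(1.0)

    def test_flat_gc12(self):
        rows = [
            _row(gene_id=f"g{i}", gc3=x, gc12=0.42)
            for i, x in enumerate([0.2, 0.5, 0.8])
        ]
        table = neutrality_plot(rows).table
        assert table["slope"][0] == pytest.approx(0.0)

    def test_degenerate_x_reports_missing(self):
        rows = [_row(gene_id=f"g{i}", gc3=0.5, gc12=0.1 * i) for i in range(4)]
        table = neutrality_plot(rows).table
        assert math.isnan(table["slope"][0])

    def test_matches_ols_oracle(self, rng):
        x = rng.random(100)
        y = 0.3 * x + 0.1 + rng.normal(0, 0.02, 100)
        rows = [
            _row(gene_id=f"g{i}", gc3=float(a), gc12=float(b))
            for i, (a, b) in enumerate(zip(x, y))
        ]
        table = neutrality_plot(rows).table
        slope, intercept, r = oracles.ols_oracle(list(x), list(y))
        assert table["slope"][0] == pytest.approx(slope, abs=1e-9)
        assert table["intercept"][0] == pytest.approx(intercept, abs=1e-9)
        assert table["r"][0] == pytest.approx(r, abs=1e-9)

    @pytest.mark.parametrize("b", [0.0, 0.3, 1.0])
    def test_slope_recovery(self, b):
        rng = np.random.default_rng(int(b * 10))
        x = rng.uniform(0.3, 0.7, 1000)
        y = 0.2 + b * x + rng.normal(0, 0.01, 1000)
        rows = [
            _row(gene_id=f"g{i}", gc3=float(a), gc12=float(c))
            for i, (a, c) in enumerate(zip(x, y))
        ]
        assert neutrality_plot(rows).table["slope"][0] == pytest.approx(b, abs=0.05)


def _metric_rows_from_seqs(seqs, labels=None):
    records = [
        GeneRecord(f"s1:g{i}", "s1", seq) for i, seq in enumerate(seqs)
    ]
    partition = {
        f"s1:g{i}": (labels[i] if labels else "core") for i in range(len(seqs))
    }
    return compute_metrics(records, partition=partition, min_len=10)


class TestCOA:
    def test_inertia_fractions_sum_to_one(self, small_metrics):
        coa = coa_rscu(small_metrics)
        assert coa.inertia_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_row_permutation_invariance(self, small_metrics):
        coa1 = coa_rscu(small_metrics)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_metrics))
        coa2 = coa_rscu([small_metrics[i] for i in perm])
        lookup = {g: coa2.row_coords[i] for i, g in enumerate(coa2.gene_ids)}
        for i, g in enumerate(coa1.gene_ids):
            assert np.allclose(coa1.row_coords[i], lookup[g], atol=1e-9)

    def test_gc3_separation_on_two_groups(self, rng):
        pref = default_preferred_codons()
        seqs, gc3s = [], []
        for i in range(60):
            gc3 = 0.2 if i < 30 else 0.8
            seqs.append(generate_gene_sequence(300, gc3, 0.0, pref, rng))
            gc3s.append(gc3)
        rows = _metric_rows_from_seqs(seqs)
        coa = coa_rscu(rows)
        axis1 = coa.row_coords[:, 0]
        measured_gc3 = np.array([r.gc3 for r in rows])
        rho, _ = spearman_rho(axis1, measured_gc3)
        assert abs(rho) > 0.9
        assert coa.inertia_fractions[0] > 0.10  # axis 1 is a major trend
        assert 0 in coa.major_axes

    def test_rank_one_structure_dominates(self):
        # two distinct RSCU profiles -> a single contrast carries the inertia
        seqs = ["TTT" * 30 + "GCT" * 30, "TTC" * 30 + "GCC" * 30] * 10
        rows = _metric_rows_from_seqs(seqs)
        coa = coa_rscu(rows)
        assert coa.inertia_fractions[0] > 0.99

    def test_identical_rows_degenerate(self):
        seqs = ["TTTGCTGCA" * 20] * 5
        rows = _metric_rows_from_seqs(seqs)
        with pytest.raises(DegenerateResultError):
            coa_rscu(rows)

    def test_matches_eigendecomposition_oracle(self, small_metrics):
        rows = small_metrics[:40]
        M = np.vstack([np.nan_to_num(m.rscu, nan=0.0) for m in rows])
        M = M[:, M.sum(axis=0) > 0]
        fractions, gram = oracles.ca_oracle(M)
        coa = coa_rscu(rows, n_axes=10)
        k = min(len(fractions), len(coa.inertia_fractions))
        assert np.allclose(coa.inertia_fractions[:k], fractions[:k], atol=1e-9)
        full = coa_rscu(rows, n_axes=len(coa.inertia_fractions))
        gram_impl = full.row_coords @ full.row_coords.T
        assert np.allclose(gram_impl, gram, atol=1e-9)


class TestAxisFactorCorrelations:
    def test_identity_factor(self, small_metrics):
        import dataclasses

        clones = [dataclasses.replace(m) for m in small_metrics]
        coa = coa_rscu(clones)
        # inject the axis-1 coordinate itself as gc3 to get rho == 1
        rows = {m.gene_id: m for m in clones}
        for i, g in enumerate(coa.gene_ids):
            rows[g].gc3 = float(coa.row_coords[i, 0])
        table = axis_factor_correlations(coa, clones, factors=("gc3",))
        assert np.allclose(table["rho"], 1.0)

    def test_null_factor_small_rho(self):
        rng = np.random.default_rng(1)
        seqs = [random_cds(rng, 120) for _ in range(500)]
        rows = _metric_rows_from_seqs(seqs)
        coa = coa_rscu(rows)
        shuffled = rng.permutation([r.cai for r in rows])
        for r, v in zip(rows, shuffled):
            r.cai = float(v)
        table = axis_factor_correlations(coa, rows, factors=("cai",))
        assert abs(table["rho"][0]) < 0.15
        assert table["p_value"][0] > 0.001

    def test_expression_factor_and_skip_warning(self, small_metrics, caplog):
        coa = coa_rscu(small_metrics)
        expr = ExpressionTable(values={})
        table = axis_factor_correlations(
            coa, small_metrics, factors=("expression",), expression=expr
        )
        assert table.empty  # <3 non-missing everywhere: all skipped


class TestExpressionCorrelation:
    def test_monotone_function_gives_one(self, small_metrics):
        expr = ExpressionTable(
            values={m.gene_id: math.exp(3 * m.cai) for m in small_metrics}
        )
        table = expression_correlation(small_metrics, expr)
        assert np.allclose(table["rho"].dropna(), 1.0)

    def test_insufficient_overlap_missing(self, small_metrics):
        expr = ExpressionTable(values={small_metrics[0].gene_id: 1.0})
        table = expression_correlation(small_metrics, expr)
        assert table["rho"].isna().all()

    def test_tied_expression_missing_with_warning(self, small_metrics, caplog):
        expr = ExpressionTable(values={m.gene_id: 7.0 for m in small_metrics})
        table = expression_correlation(small_metrics, expr)
        assert table["rho"].isna().all()
        assert any("degenerate" in m for m in caplog.messages)


class TestTRNASimilarity:
    def test_proportional_vectors_give_one(self):
        pref = default_preferred_codons()
        trna = generate_trna_table(pref, high_copy=10, low_copy=0, jitter=0)
        vec = trna_codon_vector(trna)
        code = standard_code()
        indicator = np.array(
            [1.0 if c in set(pref.values()) else 0.0 for c in code.informative_codons]
        )
        # high-copy anticodons decode exactly the preferred codons; with
        # degeneracy scaling the vector is proportional to family size there
        assert (vec[indicator == 0] == 0).all()
        assert (vec[indicator == 1] > 0).all()

    def test_strong_selection_limit_similarity_one(self, rng):
        pref = default_preferred_codons()
        trna = generate_trna_table(pref, high_copy=10, low_copy=0, jitter=0)
        seqs = [generate_gene_sequence(400, 0.5, 50.0, pref, rng) for _ in range(5)]
        rows = _metric_rows_from_seqs(seqs)
        result = trna_similarity_by_set(rows, trna)
        assert result.table["similarity"][0] == pytest.approx(1.0, abs=1e-6)

    def test_unused_codons_give_low_similarity(self):
        # tRNA copies only on codons the gene set never uses
        code = standard_code()
        seqs = ["TTTGCTCAT" * 40]
        rows = _metric_rows_from_seqs(seqs)
        entries = {reverse_complement("GGG"): 10}
        result = trna_similarity_by_set(rows, TRNATable(entries=entries))
        assert result.table["similarity"][0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_trna_vector_rejected(self, small_metrics):
        with pytest.raises(UndefinedInputError):
            trna_similarity_by_set(small_metrics, TRNATable(entries={}))

    def test_average_mode_runs(self, small_metrics, small_pangenome):
        result = trna_similarity_by_set(
            small_metrics, small_pangenome.trna, average=True
        )
        assert ((result.table["similarity"] >= 0) & (result.table["similarity"] <= 1)).all()

    def test_wobble_adds_coverage(self):
        # a single tRNA with G at position 34 reads both C- and T-ending codons
        code = standard_code()
        entries = {"GAA": 4}  # anticodon GAA: Watson-Crick cognate TTC (Phe)
        strict = trna_codon_vector(TRNATable(entries=entries), wobble=False)
        wobbled = trna_codon_vector(TRNATable(entries=entries), wobble=True)
        idx = {c: i for i, c in enumerate(code.informative_codons)}
        assert strict[idx["TTC"]] == 4 and strict[idx["TTT"]] == 0
        assert wobbled[idx["TTC"]] == 4 and wobbled[idx["TTT"]] == 4


class TestAnova:
    def test_identical_groups(self):
        assert one_way_anova([[1, 2, 3], [1, 2, 3]])[0] == pytest.approx(0.0)

    def test_hand_value(self):
        f_stat, p = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f_stat == pytest.approx(13.5)
        assert 0 < p < 1

    def test_constant_groups_f_zero(self):
        assert one_way_anova([[2, 2], [2, 2]]) == (0.0, 1.0)

    def test_matches_oracle_and_scipy(self, rng):
        groups = [list(rng.normal(i, 1, 20)) for i in range(4)]
        f_stat, p = one_way_anova(groups)
        assert f_stat == pytest.approx(oracles.anova_oracle(groups), abs=1e-9)
        ref = stats.f_oneway(*groups)
        assert f_stat == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_too_few_groups(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1, 2]])


class TestSpearman:
    def test_increasing(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)

    def test_decreasing(self):
        assert spearman_rho([1, 2, 3], [9, 5, 1])[0] == pytest.approx(-1.0)

    def test_ties_match_oracle(self):
        x = [1, 2, 2, 3, 3, 3, 4]
        y = [5, 5, 6, 7, 7, 8, 9]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(oracles.spearman_oracle(x, y), abs=1e-12)

    def test_matches_scipy_on_random(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_ranks_missing(self):
        rho, p = spearman_rho([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)
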