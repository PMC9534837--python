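"""QC, normalization, HVG selection, scaling, annotation and DEG testing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats
from hypothesis import given, settings, strategies as st

import ecosys
from ecosys import CountMatrix, GeneSignature
from ecosys.preprocess import (
    bh_adjust,
    filter_qc,
    find_markers,
    normalize_log,
    rank_sum_test,
    scale_expression,
    select_hvg,
)


def _make_cm(dense, gene_ids=None, cell_ids=None, meta=None):
    dense = np.asarray(dense)
    g = gene_ids or [f"g{i}" for i in range(dense.shape[0])]
    c = cell_ids or [f"c{j}" for j in range(dense.shape[1])]
    meta = meta if meta is not None else pd.DataFrame(index=range(dense.shape[1]))
    return CountMatrix(sp.csr_matrix(dense), np.array(g, dtype=object), np.array(c, dtype=object), meta)


class TestFilterQC:
    def _qc_fixture(self):
        # 300 genes (1 mitochondrial); 4 cells with controlled detection/mito
        n_genes = 300
        X = np.zeros((n_genes, 4), dtype=int)
        X[:150, 0] = 1          # 150 detected -> removed
        X[:200, 1] = 1          # exactly 200 detected -> removed (> rule)
        X[:201, 2] = 1          # 201 detected -> kept
        X[:250, 3] = 1          # kept
        genes = [f"g{i}" for i in range(n_genes - 1)] + ["MT-g"]
        return _make_cm(X, gene_ids=genes)

    def test_gene_count_boundary(self):
        cm = self._qc_fixture()
        out, report = filter_qc(cm, min_gene_prevalence=0.0)
        assert list(out.cell_ids) == ["c2", "c3"]
        assert report["n_cells_removed_low_genes"] == 2

    def test_mito_fraction_boundary(self):
        # 1000 UMI total; cell a: 25% mito (removed), cell b: exactly 20% (kept)
        X = np.zeros((300, 2), dtype=int)
        X[:299, 0] = 3
        X[299, 0] = 299          # mito frac = 299/1196 = 0.25
        X[:299, 1] = 4
        X[299, 1] = 299          # mito frac = 299/1495 = 0.2
        genes = [f"g{i}" for i in range(299)] + ["MT-g"]
        cm = _make_cm(X, gene_ids=genes)
        out, _ = filter_qc(cm, min_genes=200, max_mito_frac=0.20, min_gene_prevalence=0.0)
        assert list(out.cell_ids) == ["c1"]

    def test_rare_gene_removed(self, counts):
        # a gene detected in 1 of ~2000 cells (0.05%) fails the 0.1% prevalence rule
        out, _ = filter_qc(counts)
        sub = counts.counts.tocsr()
        prevalence = np.asarray((sub > 0).sum(axis=1)).ravel() / counts.n_cells
        rare = counts.gene_ids[prevalence <= 0.0005]
        assert not set(rare) & set(out.gene_ids)

    def test_idempotent(self, counts):
        once, _ = filter_qc(counts)
        twice, rep = filter_qc(once)
        assert rep["n_cells_kept"] == once.n_cells
        assert rep["n_genes_kept"] == once.n_genes

    def test_all_cells_removed_raises(self):
        X = np.ones((300, 2), dtype=int)
        X[10:, :] = 0  # 10 detected genes everywhere
        cm = _make_cm(X)
        with pytest.raises(ValueError, match="loosen"):
            filter_qc(cm)


class TestNormalize:
    def test_formula(self):
        # one cell: counts [10, 90]; libsize 100; count = libsize/10 -> ln(1001)
        cm = _make_cm([[10], [90]])
        norm = normalize_log(cm, scale_factor=1e4)
        dense = norm.dense()
        assert dense[0, 0] == pytest.approx(np.log(1 + 10 / 100 * 1e4))
        assert dense[0, 0] == pytest.approx(np.log(1001))

    def test_zero_count_is_zero(self):
        cm = _make_cm([[0], [5]])
        assert normalize_log(cm).dense()[0, 0] == 0.0

    def test_doubling_counts_is_invariant(self):
        a = _make_cm([[3, 1], [7, 2], [0, 5]])
        b = _make_cm([[6, 1], [14, 2], [0, 5]])
        na, nb = normalize_log(a).dense(), normalize_log(b).dense()
        np.testing.assert_allclose(na[:, 0], nb[:, 0], rtol=1e-12)

    def test_expm1_recovers_scaled_counts(self):
        cm = _make_cm([[3, 1], [7, 2]])
        norm = normalize_log(cm)
        lib = cm.library_sizes()
        recovered = np.expm1(norm.dense()) * lib / norm.scale_factor
        np.testing.assert_allclose(recovered, cm.counts.toarray(), atol=1e-6)

    def test_zero_cell_rejected(self):
        cm = _make_cm([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero-count"):
            normalize_log(cm)


class TestHVG:
    def test_constant_gene_never_beats_varying(self):
        from ecosys.containers import NormalizedMatrix

        rng = np.random.default_rng(0)
        X = rng.poisson(5, size=(50, 100)).astype(float)
        X[0, :] = 3.0  # constant gene in the normalized matrix
        nm = NormalizedMatrix(sp.csr_matrix(X),
                              np.array([f"g{i}" for i in range(50)], dtype=object),
                              np.array([f"c{j}" for j in range(100)], dtype=object),
                              pd.DataFrame(index=range(100)))
        top = select_hvg(nm, n_top=49)
        assert "g0" not in top

    def test_n_top_equal_gene_count_returns_all(self, norm):
        top = select_hvg(norm, n_top=norm.n_genes)
        assert len(top) == norm.n_genes

    def test_n_top_too_large_raises(self, norm):
        with pytest.raises(ValueError):
            select_hvg(norm, n_top=norm.n_genes + 1)

    def test_planted_module_recall(self, norm, truth):
        top = set(select_hvg(norm, n_top=2000))
        recall = len(top & set(truth.module_genes)) / len(truth.module_genes)
        assert recall >= 0.9


class TestScale:
    def test_constant_gene_zeroed_and_flagged(self):
        cm = _make_cm([[2, 2, 2], [1, 5, 9]])
        scaled = scale_expression(normalize_log(cm))
        # after library normalization the first gene varies; use raw constant input
        X = np.array([[2.0, 2.0, 2.0], [1.0, 5.0, 9.0]])
        from ecosys.containers import NormalizedMatrix

        nm = NormalizedMatrix(sp.csr_matrix(X), np.array(["a", "b"], dtype=object),
                              np.array(["c1", "c2", "c3"], dtype=object), pd.DataFrame(index=range(3)))
        scaled = scale_expression(nm)
        assert (scaled.values[0] == 0).all()
        assert "a" in scaled.zero_variance_genes

    def test_mean_zero_unit_sd(self, scaled):
        varying = ~np.isin(scaled.gene_ids, scaled.zero_variance_genes)
        Z = scaled.values[varying]
        unclipped = np.abs(Z).max(axis=1) < scaled.clip_max
        np.testing.assert_allclose(Z[unclipped].mean(axis=1), 0, atol=1e-6)
        np.testing.assert_allclose(Z[unclipped].std(axis=1, ddof=1), 1, atol=1e-6)

    def test_clipping(self):
        from ecosys.containers import NormalizedMatrix

        x = np.zeros((1, 201))
        x[0, 0] = 100.0  # extreme outlier, ~14 SD above the mean
        nm = NormalizedMatrix(sp.csr_matrix(x), np.array(["a"], dtype=object),
                              np.array([f"c{i}" for i in range(201)], dtype=object),
                              pd.DataFrame(index=range(201)))
        scaled = scale_expression(nm, clip_max=10)
        assert scaled.values.max() == 10.0


class TestAnnotate:
    def test_recovers_planted_cell_types(self, norm, truth):
        marker_sets = {t: GeneSignature(t, g) for t, g in truth.marker_sets.items()}
        ann = ecosys.annotate_cells(norm, marker_sets, seed=0)
        assert (ann["label"].to_numpy() == truth.cell_type).mean() >= 0.95

    def test_single_marker_set_labels_everything(self, norm, truth):
        sets = {"only": GeneSignature("only", truth.marker_sets["T"])}
        ann = ecosys.annotate_cells(norm, sets, seed=0)
        assert (ann["label"] == "only").all()

    def test_empty_intersection_names_the_set(self, norm):
        sets = {"ghost": GeneSignature("ghost", ["NOPE1", "NOPE2"])}
        with pytest.raises(ValueError, match="ghost"):
            ecosys.annotate_cells(norm, sets, seed=0)

    def test_tie_breaks_lexicographically_and_flags(self):
        from ecosys.containers import NormalizedMatrix

        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(40, 30)).astype(float)
        nm = NormalizedMatrix(sp.csr_matrix(X), np.array([f"g{i}" for i in range(40)], dtype=object),
                              np.array([f"c{i}" for i in range(30)], dtype=object),
                              pd.DataFrame(index=range(30)))
        same = GeneSignature("a", ["g0", "g1"])
        sets = {"b_set": GeneSignature("b_set", ["g0", "g1"]), "a_set": same}
        ann = ecosys.annotate_cells(nm, sets, seed=0)
        assert (ann["label"] == "a_set").all()
        assert ann["tie"].all()


def _oracle_rank_sum_p(x, y):
    """Independent exact two-sided p: enumerate all assignments of pooled values."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), nx)]
    sums = np.array(sums)
    p_lo = (sums <= obs + 1e-9).mean()
    p_hi = (sums >= obs - 1e-9).mean()
    return min(1.0, 2 * min(p_lo, p_hi))


class TestWilcoxon:
    def test_textbook_case(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(3, 9, size=2)
        # integer draws force ties, the hard case
        x = rng.integers(0, 5, size=nx).astype(float)
        y = rng.integers(0, 5, size=ny).astype(float)
        assert rank_sum_test(x, y) == pytest.approx(_oracle_rank_sum_p(x, y), abs=1e-12)

    def test_large_group_approximation_is_close(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 100)
        y = rng.normal(0.5, 1, 120)
        p = rank_sum_test(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFindMarkers:
    def test_planted_type_markers_recovered(self, norm, truth):
        deg = find_markers(norm, truth.cell_type, "T", only_pos=True)
        found = set(deg["gene_id"]) & set(truth.marker_sets["T"])
        assert len(found) >= 20  # of 25 planted markers

    def test_null_groups_yield_no_calls(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3, size=(100, 200))
        cm = _make_cm(X)
        norm = normalize_log(cm)
        labels = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        deg = find_markers(norm, labels, "a")
        assert len(deg) == 0

    def test_unknown_group_rejected(self, norm, truth):
        with pytest.raises(ValueError, match="unknown group"):
            find_markers(norm, truth.cell_type, "Neuron")

    def test_filters_respected(self, norm, truth):
        deg = find_markers(norm, truth.cell_type, "Epithelial", only_pos=True)
        assert (deg["adj_p"] <= 0.01).all()
        assert (deg["log_fc"] >= 0.25).all()
        assert (deg["adj_p"] >= deg["p_value"] - 1e-15).all()
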