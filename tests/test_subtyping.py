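"""Single-sample enrichment scoring, subtype clustering and bulk projection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ecosys
from ecosys import GeneSignature
from ecosys.subtyping import (
    assign_subtypes,
    enrichment_matrix,
    log2_cpm,
    project_bulk,
    ss_enrichment,
    top_signature,
)


def brute_force_running_sum(expr, gene_ids, gene_set, alpha):
    """Literal, loop-based evaluation of the running-sum enrichment definition."""
    expr = list(map(float, expr))
    n = len(expr)
    ranks = []
    for v in expr:  # average ranks, computed from first principles
        smaller = sum(1 for u in expr if u < v)
        equal = sum(1 for u in expr if u == v)
        ranks.append(smaller + (equal + 1) / 2.0)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    in_set = [gene_ids[i] in set(gene_set) for i in order]
    n_hit = sum(in_set)
    if n_hit == n:
        return 0.0
    w_total = sum(ranks[order[i]] ** alpha for i in range(n) if in_set[i])
    score, cum_hit, cum_miss = 0.0, 0.0, 0.0
    for i in range(n):
        if in_set[i]:
            cum_hit += ranks[order[i]] ** alpha / w_total
        else:
            cum_miss += 1.0 / (n - n_hit)
        score += cum_hit - cum_miss
    return score


class TestSSEnrichment:
    def test_single_top_gene_worked_example(self):
        # N=4, set = {top gene}, alpha=0 -> 1 + 2/3 + 1/3 + 0 = 2
        s = ss_enrichment([1.0, 4.0, 2.0, 3.0], list("abcd"), ["b"], alpha=0.0,
                          min_set_genes=1)
        assert s == pytest.approx(2.0)

    def test_whole_universe_set_scores_zero(self):
        assert ss_enrichment([1, 2, 3, 4], list("abcd"), list("abcd")) == 0.0

    def test_monotone_transform_invariance(self):
        expr = [0.3, 2.0, 1.1, 0.7, 5.0]
        a = ss_enrichment(expr, list("abcde"), ["b", "e"], alpha=0.25)
        b = ss_enrichment(np.exp(expr), list("abcde"), ["b", "e"], alpha=0.25)
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_exhaustive_bruteforce_agreement(self, alpha):
        # every gene set of size <= 3 over an 8-gene universe, with ties present
        gene_ids = list("abcdefgh")
        rng = np.random.default_rng(0)
        exprs = [
            rng.normal(size=8),
            np.array([1.0, 2.0, 2.0, 3.0, 0.5, 2.0, 4.0, 1.0]),  # heavy ties
            np.arange(8.0),
        ]
        for expr in exprs:
            for size in (1, 2, 3):
                for genes in combinations(gene_ids, size):
                    got = ss_enrichment(expr, gene_ids, list(genes), alpha=alpha,
                                        min_set_genes=1)
                    want = brute_force_running_sum(expr, gene_ids, genes, alpha)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError, match="need >= 2"):
            ss_enrichment([1, 2, 3], list("abc"), ["a"])


class TestEnrichmentMatrix:
    def test_subtypes_score_highest_on_own_set(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=12,
                                                  purity_range=(0.7, 0.9))
        sets = {k: GeneSignature(k, v) for k, v in truth.subtype_gene_sets.items()}
        mat = enrichment_matrix(log2_cpm(bulk), sets)
        for lab in ("I", "II", "III"):
            own = mat.scores.loc[truth.bulk_subtype == lab, lab].mean()
            other = mat.scores.loc[truth.bulk_subtype != lab, lab].mean()
            assert own > other

    def test_duplicated_set_gives_identical_columns(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(50, 4)),
                            index=[f"g{i}" for i in range(50)])
        sets = {"a": GeneSignature("a", ["g1", "g5", "g9"]),
                "b": GeneSignature("b", ["g1", "g5", "g9"])}
        mat = enrichment_matrix(expr, sets)
        np.testing.assert_allclose(mat.scores["a"], mat.scores["b"])

    def test_single_entity(self):
        expr = pd.DataFrame({"s1": [3.0, 1.0, 2.0, 0.5]}, index=list("abcd"))
        mat = enrichment_matrix(expr, {"x": GeneSignature("x", ["a", "c"]),
                                       "y": GeneSignature("y", ["b", "d"])})
        assert mat.scores.shape == (1, 2)

    def test_bad_set_raises_or_skips(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        sets = {"ok": GeneSignature("ok", ["a", "b"]),
                "bad": GeneSignature("bad", ["zz"])}
        with pytest.raises(ValueError, match="bad"):
            enrichment_matrix(expr, sets)
        with pytest.warns(UserWarning, match="bad"):
            mat = enrichment_matrix(expr, sets, skip_bad_sets=True)
        assert list(mat.scores.columns) == ["ok"]


class TestAssignSubtypes:
    def test_synthetic_cohort_ari(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=60,
                                                  purity_range=(0.6, 0.9))
        sets = {k: GeneSignature(k, v) for k, v in truth.subtype_gene_sets.items()}
        mat = enrichment_matrix(log2_cpm(bulk), sets)
        asn = assign_subtypes(mat, k=3)
        assert adjusted_rand_score(truth.bulk_subtype, asn.labels.to_numpy()) >= 0.9

    def test_label_shuffle_null_ari(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=60,
                                                  purity_range=(0.6, 0.9))
        sets = {k: GeneSignature(k, v) for k, v in truth.subtype_gene_sets.items()}
        mat = enrichment_matrix(log2_cpm(bulk), sets)
        asn = assign_subtypes(mat, k=3)
        rng = np.random.default_rng(0)
        shuffled = truth.bulk_subtype[rng.permutation(60)]
        assert abs(adjusted_rand_score(shuffled, asn.labels.to_numpy())) < 0.1

    def test_k1_single_group(self):
        rng = np.random.default_rng(0)
        mat = enrichment_matrix(
            pd.DataFrame(rng.normal(size=(30, 5)), index=[f"g{i}" for i in range(30)]),
            {"a": GeneSignature("a", ["g0", "g1"]), "b": GeneSignature("b", ["g2", "g3"])},
        )
        asn = assign_subtypes(mat, k=1)
        assert asn.labels.nunique() == 1

    def test_identical_rows_warn_but_deterministic(self):
        scores = pd.DataFrame(np.ones((6, 2)), columns=["a", "b"])
        from ecosys.subtyping import EnrichmentMatrix

        mat = EnrichmentMatrix(scores=scores, alpha=0.25)
        with pytest.warns(UserWarning, match="identical"):
            a = assign_subtypes(mat, k=3)
        with pytest.warns(UserWarning, match="identical"):
            b = assign_subtypes(mat, k=3)
        assert (a.labels == b.labels).all()

    def test_k_exceeding_entities_rejected(self):
        scores = pd.DataFrame(np.eye(2), columns=["a", "b"])
        from ecosys.subtyping import EnrichmentMatrix

        with pytest.raises(ValueError, match="exceeds"):
            assign_subtypes(EnrichmentMatrix(scores=scores, alpha=0.25), k=3)

    def test_newick_export(self):
        rng = np.random.default_rng(0)
        mat = enrichment_matrix(
            pd.DataFrame(rng.normal(size=(30, 5)), index=[f"g{i}" for i in range(30)],
                         columns=list("vwxyz")),
            {"a": GeneSignature("a", ["g0", "g1"]), "b": GeneSignature("b", ["g2", "g3"])},
        )
        asn = assign_subtypes(mat, k=2)
        nwk = asn.to_newick()
        assert nwk.endswith(";") and "v" in nwk


class TestTopSignature:
    def _deg(self, n=20):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "group": "I",
            "log_fc": rng.uniform(0.5, 3, n),
            "p_value": rng.uniform(0, 1e-4, n),
            "adj_p": rng.uniform(0, 1e-3, n),
        })

    def test_returns_top_n(self):
        sig = top_signature(self._deg(20), "I", n=15)
        assert len(sig) == 15

    def test_fewer_rows_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="only"):
            sig = top_signature(self._deg(5), "I", n=15)
        assert len(sig) == 5

    def test_tie_resolved_deterministically(self):
        deg = pd.DataFrame({
            "gene_id": ["gB", "gA", "gC"],
            "group": "I",
            "log_fc": [1.0, 1.0, 2.0],
            "p_value": [0.001] * 3,
            "adj_p": [0.001] * 3,
        })
        sig = top_signature(deg, "I", n=2)
        assert sig.genes == ["gC", "gA"]  # higher log_fc first, then gene_id

    def test_missing_subtype_rejected(self):
        with pytest.raises(ValueError, match="II"):
            top_signature(self._deg(), "II")


class TestProjectBulk:
    def _signatures(self, truth):
        return [GeneSignature(k, v) for k, v in truth.subtype_gene_sets.items()]

    def test_purity_08_accuracy(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=30,
                                                  purity_range=(0.8, 0.8))
        asn, diag = project_bulk(bulk, self._signatures(truth))
        acc = (asn.labels.to_numpy() == truth.bulk_subtype).mean()
        assert acc >= 0.9

    def test_purity_10_noiseless_accuracy_is_one(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=9,
                                                  purity_range=(1.0, 1.0), noise=False)
        asn, _ = project_bulk(bulk, self._signatures(truth))
        assert (asn.labels.to_numpy() == truth.bulk_subtype).all()

    def test_three_singletons(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=3,
                                                  purity_range=(0.9, 0.9))
        asn, _ = project_bulk(bulk, self._signatures(truth))
        assert asn.labels.nunique() == 3

    def test_absent_signature_rejected(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=5)
        sigs = self._signatures(truth)
        sigs[0] = GeneSignature("I", ["NOPE1", "NOPE2"])
        with pytest.raises(ValueError, match="bulk universe"):
            project_bulk(bulk, sigs)

    def test_determinism(self, small_config):
        bulk, truth = ecosys.simulate_bulk_cohort(small_config, n_samples=12)
        a, _ = project_bulk(bulk, self._signatures(truth))
        b, _ = project_bulk(bulk, self._signatures(truth))
        assert (a.labels == b.labels).all()
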