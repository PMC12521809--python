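"""Importance, attribution completeness, hypergeometric and BH oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

import methylpredict as mp
from methylpredict.interpret import bh_fdr
from methylpredict.matrix import AnnotationBundle
from methylpredict.select import FeatureSet


def _hypergeom_tail_enumeration(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(overlap >= k) by exhaustive enumeration over all draws of size n_b."""
    universe = range(n_universe)
    set_a = set(range(n_a))
    hits = total = 0
    for draw in combinations(universe, n_b):
        total += 1
        if len(set_a & set(draw)) >= k:
            hits += 1
    return hits / total


class TestRFImportance:
    def test_single_informative_feature_dominates(self, rng):
        X = rng.normal(size=(120, 5))
        y = (X[:, 2] > 0).astype(int)
        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        imp = mp.rf_importance(model, feature_names=list("abcde"))
        assert imp.values.sum() == pytest.approx(1.0)
        assert imp.values["c"] > 0.8
        assert imp.sd is not None and (imp.sd >= 0).all()

    def test_duplicated_feature_splits_importance(self, rng):
        X = rng.normal(size=(200, 4))
        X[:, 1] = X[:, 0]  # duplicate the informative feature
        y = X[:, 0] * 2 + rng.normal(0, 0.05, size=200)
        model = RandomForestRegressor(n_estimators=100, random_state=0).fit(X, y)
        imp = mp.rf_importance(model).values
        assert imp.iloc[0] + imp.iloc[1] > 0.9  # pair carries the signal jointly

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            mp.rf_importance(RandomForestClassifier())


class TestAttribution:
    def test_linear_model_closed_form(self, rng):
        w = rng.normal(size=6)
        X = rng.normal(size=(40, 6))

        class Linear:
            def input_gradient(self, Z):
                return np.tile(w, (len(Z), 1))

        bg = X[:10]
        attr = mp.integrated_gradients(Linear(), X, bg.mean(axis=0), n_steps=8)
        expected = w * (X - bg.mean(axis=0))
        assert np.allclose(attr, expected, atol=1e-12)

    def test_constant_model_attributes_nothing(self, rng):
        X = rng.normal(size=(20, 3))

        class Const:
            def input_gradient(self, Z):
                return np.zeros_like(Z)

        imp = mp.deep_attribution(Const(), X, n_background=5)
        assert (imp.values == 0).all()

    def test_completeness_on_two_layer_network(self, rng):
        X = rng.normal(size=(50, 8))
        y = np.tanh(X[:, 0]) + X[:, 1] ** 2 * 0.1
        est = mp.FFNNRegressor(hidden_sizes=(16,), lr=0.01, epochs=200, seed=0).fit(X, y)
        bg = X[:10]
        baseline = bg.mean(axis=0)
        attr = mp.integrated_gradients(est, X, baseline, n_steps=256)
        delta = est.predict(X) - est.predict(baseline[None, :])[0]
        resid = np.abs(attr.sum(axis=1) - delta)
        scale = np.abs(delta) + 1e-9
        assert np.median(resid / scale) < 1e-3
        # denser Riemann oracle agrees with the 256-step path integral
        oracle = mp.integrated_gradients(est, X[:5], baseline, n_steps=2048)
        assert np.allclose(attr[:5], oracle, atol=1e-3)

    def test_empty_background_rejected(self, rng):
        est = mp.FFNNRegressor(hidden_sizes=(), lr=0.01, epochs=5, seed=0)
        X = rng.normal(size=(10, 2))
        est.fit(X, X[:, 0])
        with pytest.raises(ValueError, match="background"):
            mp.deep_attribution(est, X, background=X[:0])


class TestTopN:
    def test_identity_and_sort_oracle(self, rng):
        vals = pd.Series(rng.normal(size=30), index=[f"p{i:03d}" for i in range(30)])
        imp = mp.ImportanceVector(vals, method="test")
        assert mp.top_n(imp, 30).probes == sorted(
            vals.index, key=lambda p: (-abs(vals[p]), p)
        )
        top10 = mp.top_n(imp, 10).probes
        bottom = set(vals.abs().nsmallest(20).index)
        assert not (set(top10) & bottom)
        with pytest.raises(ValueError):
            mp.top_n(imp, 31)


class TestSetOverlap:
    def test_identical_sets_probability(self):
        fs = FeatureSet([f"p{i}" for i in range(5)])
        k, p = mp.set_overlap_test(fs, fs, universe=20)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_disjoint_sets_give_p_one(self):
        a = FeatureSet(["x1", "x2"])
        b = FeatureSet(["y1", "y2"])
        k, p = mp.set_overlap_test(a, b, universe=50)
        assert k == 0 and p == 1.0

    @pytest.mark.parametrize("n_universe,n_a,n_b", [(8, 3, 4), (10, 5, 5), (12, 4, 6)])
    def test_matches_exhaustive_enumeration(self, n_universe, n_a, n_b):
        a = FeatureSet([f"e{i}" for i in range(n_a)])
        for k_obs in range(n_b + 1):
            b_members = [f"e{i}" for i in range(min(k_obs, n_a))]
            b_members += [f"z{i}" for i in range(n_b - len(b_members))]
            k, p = mp.set_overlap_test(a, FeatureSet(b_members), universe=n_universe)
            assert p == pytest.approx(
                _hypergeom_tail_enumeration(k, n_universe, n_a, n_b), abs=1e-12
            )

    def test_oversized_sets_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            mp.set_overlap_test(FeatureSet(["a", "b", "c"]), FeatureSet(["a"]), universe=2)


class TestIntersectionCounts:
    def test_disjoint_and_nested(self):
        tbl = mp.intersection_counts({"A": {"x", "y"}, "B": {"z"}})
        patterns = {(r["A"], r["B"]): r["count"] for _, r in tbl.iterrows()}
        assert patterns == {(True, False): 2, (False, True): 1}
        tbl = mp.intersection_counts({"A": {"x", "y", "z"}, "B": {"x"}})
        patterns = {(r["A"], r["B"]): r["count"] for _, r in tbl.iterrows()}
        assert patterns == {(True, True): 1, (True, False): 2}

    def test_counts_sum_to_union_bruteforce(self, rng):
        sets = {
            name: set(rng.choice(50, size=rng.integers(5, 20), replace=False).tolist())
            for name in "ABC"
        }
        tbl = mp.intersection_counts(sets)
        assert tbl["count"].sum() == len(sets["A"] | sets["B"] | sets["C"])
        for _, row in tbl.iterrows():
            members = set.intersection(
                *[sets[n] if row[n] else set(range(50)) - sets[n] for n in "ABC"]
            )
            assert row["count"] == len(members)


def test_bh_step_up_known_example():
    adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
    # monotone non-decreasing in rank order of raw p, capped at 1
    raw = np.array([0.001, 0.5, 0.9, 0.02, 1.0])
    adj = bh_fdr(raw)
    order = np.argsort(raw)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert adj.max() <= 1.0


class TestORA:
    def test_constructed_signal_set_attains_minimal_p(self, small_ann):
        target = "PATHWAY_003"
        genes = small_ann.collections["pathways"][target]
        hit_probes = [
            p for p, g in small_ann.probe_gene.items() if g and g <= genes
        ]
        assert hit_probes, "fixture must contain probes exclusive to the set"
        tbl = mp.ora_genesets(FeatureSet(hit_probes), small_ann, "pathways")
        assert tbl.iloc[0]["term"] == target
        assert tbl.iloc[0]["p"] == tbl["p"].min()
        assert (tbl["fdr"] >= tbl["p"] - 1e-12).all()

    def test_null_draw_at_expectation_not_significant(self):
        # k at its expectation under the null -> upper-tail p >= ~0.5
        from scipy.stats import hypergeom

        p = hypergeom.sf(2 - 1, 20, 10, 4)  # E[k] = 2
        assert p >= 0.5
        assert p == pytest.approx(
            _hypergeom_tail_enumeration(2, 20, 10, 4), abs=1e-12
        )

    def test_invariance_to_probe_order_and_duplicates(self, small_ann):
        probes = [p for p, g in small_ann.probe_gene.items() if g][:50]
        a = mp.ora_genesets(FeatureSet(probes), small_ann, "pathways")
        b = mp.ora_genesets(FeatureSet(probes[::-1]), small_ann, "pathways")
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_null_column(self, small_ann):
        probes = [p for p, g in small_ann.probe_gene.items() if g][:30]
        tbl = mp.ora_genesets(
            FeatureSet(probes), small_ann, "pathways", permutation_null=20, seed=0
        )
        assert "perm_p" in tbl
        assert tbl["perm_p"].between(0, 1).all()


class TestGenomicFeatureEnrichment:
    def test_all_island_top_set_small_n_oracle(self):
        # 10-probe array, 5 Island; top 4 all Island -> exact tail sum
        probes = [f"cg{i}" for i in range(10)]
        ann = AnnotationBundle(
            probe_gene={p: frozenset(["G1"]) for p in probes},
            probe_island={p: ("Island" if i < 5 else "OpenSea") for i, p in enumerate(probes)},
            probe_reggroup={p: "Unclassified" for p in probes},
            collections={"pathways": {"S": frozenset(["G1"])}},
        )
        tbl = mp.genomic_feature_enrichment(FeatureSet(probes[:4]), ann)
        island = tbl[(tbl.family == "island") & (tbl.term == "Island")].iloc[0]
        assert island["p"] == pytest.approx(
            _hypergeom_tail_enumeration(4, 10, 5, 4), abs=1e-12
        )

    def test_entire_array_as_top_gives_p_one(self, small_ann):
        tbl = mp.genomic_feature_enrichment(
            FeatureSet(sorted(small_ann.probe_gene)), small_ann
        )
        assert np.allclose(tbl["p"], 1.0)

    def test_category_absent_from_top_gives_p_near_one(self, small_ann):
        probes = [p for p in sorted(small_ann.probe_gene)
                  if small_ann.probe_island[p] != "Island"][:30]
        tbl = mp.genomic_feature_enrichment(FeatureSet(probes), small_ann)
        row = tbl[(tbl.family == "island") & (tbl.term == "Island")].iloc[0]
        assert row["hits"] == 0
        assert row["p"] == pytest.approx(1.0)
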