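"""Masked-network construction, hard sparsity enforcement and set readouts."""

import numpy as np
import pytest

import methylpredict as mp
from methylpredict.matrix import AnnotationBundle
from methylpredict.select import FeatureSet


def _chain_annotation(n: int = 4) -> AnnotationBundle:
    """One-to-one probe -> gene -> set chain."""
    probes = [f"cg{i}" for i in range(n)]
    genes = [f"G{i}" for i in range(n)]
    return AnnotationBundle(
        probe_gene={p: frozenset([g]) for p, g in zip(probes, genes)},
        probe_island={p: "Island" for p in probes},
        probe_reggroup={p: "Unclassified" for p in probes},
        collections={"pathways": {f"SET{i}": frozenset([g]) for i, g in enumerate(genes)}},
    )


def test_build_masks_drops_unannotated_probes(small_ann):
    probes = sorted(small_ann.probe_gene)[:60]
    fs = FeatureSet(probes)
    masks = mp.build_masks(fs, small_ann, "pathways")
    assert set(masks.retained_cpgs) <= set(probes)
    assert all(small_ann.probe_gene[p] for p in masks.retained_cpgs)
    # every retained probe, gene and set is connected
    assert (masks.cpg_gene.sum(axis=1) >= 1).all()
    assert (masks.cpg_gene.sum(axis=0) >= 1).all()
    assert (masks.gene_set.sum(axis=0) >= 1).all()


def test_one_to_one_chain_gives_permutation_masks():
    ann = _chain_annotation(5)
    masks = mp.build_masks(FeatureSet([f"cg{i}" for i in range(5)]), ann, "pathways")
    for m in (masks.cpg_gene, masks.gene_set):
        assert m.shape == (5, 5)
        assert (m.sum(axis=0) == 1).all() and (m.sum(axis=1) == 1).all()


def test_build_masks_requires_annotated_probes():
    ann = _chain_annotation(3)
    ann.probe_gene["cgX"] = frozenset()
    ann.probe_island["cgX"] = "OpenSea"
    ann.probe_reggroup["cgX"] = "unannotated"
    with pytest.raises(ValueError, match="no probes"):
        mp.build_masks(FeatureSet(["cgX"]), ann, "pathways")
    with pytest.raises(KeyError):
        mp.build_masks(FeatureSet(["cg0"]), ann, "missing")


def test_masks_are_immutable(small_ann):
    masks = mp.build_masks(FeatureSet(sorted(small_ann.probe_gene)[:50]), small_ann, "pathways")
    with pytest.raises(ValueError):
        masks.cpg_gene[0, 0] = 1.0


@pytest.fixture(scope="module")
def planted_setup():
    cfg = mp.SynthConfig(
        n_samples=200, n_cpgs=1500, n_genes=120, n_sets=10, age_cpgs=30,
        smoking_cpgs=40, bmi_cpgs=30, alcohol_cpgs=30, ancestry_cpgs=10,
        set_overlap=0.0, planted_set="PATHWAY_000", seed=1,
    )
    ann = mp.generate_annotation(cfg)
    mat, meta = mp.generate_cohort(cfg, ann)
    m = mp.beta_to_m(mat)
    y = meta["age"].to_numpy()
    fs = mp.select_top_k(mp.cpg_correlations(m, y), 200)
    masks = mp.build_masks(fs, ann, "pathways")
    X = m.subset_probes(list(masks.retained_cpgs)).values
    return masks, X, y


def test_masked_zero_weights_zero_at_every_checkpoint(planted_setup):
    masks, X, y = planted_setup
    zero_cg = masks.cpg_gene == 0
    zero_gs = masks.gene_set == 0
    violations = []

    def check(epoch, net):
        if epoch % 10 == 0:
            violations.append(
                max(np.abs(net.W[0][zero_cg]).max(), np.abs(net.W[1][zero_gs]).max())
            )

    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=60, seed=0)
    est.fit(X, y, callback=check)
    assert violations and max(violations) == 0.0


def test_masked_forward_equals_sparse_reconstruction(planted_setup):
    masks, X, y = planted_setup
    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=30, seed=0).fit(X, y)
    net = est.network_
    Xs = (X - est.x_mean_) / est.x_scale_
    # explicit sparse recomputation of the same forward pass
    a = Xs
    import scipy.sparse as sp

    for li, (w, b) in enumerate(zip(net.W, net.b)):
        w_used = sp.csr_matrix(w) if li < 2 else w
        a = np.asarray(a @ w_used) + b
        if li < 2:
            a = np.maximum(a, 0.0)
    assert np.allclose(a[:, 0] + est.y_mean_, est.predict(X), atol=1e-10)


def test_planted_pathway_ranks_top5(planted_setup):
    masks, X, y = planted_setup
    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=800, seed=1).fit(X, y)
    top5 = est.top_weighted_sets(5)["set_name"].tolist()
    assert "PATHWAY_000" in top5


def test_planted_pathway_activation_tracks_age(planted_setup):
    masks, X, y = planted_setup
    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=300, seed=0).fit(X, y)
    acts = est.pathway_activations(X)
    assert list(acts.columns) == list(masks.set_names)
    r = np.corrcoef(acts["PATHWAY_000"], y)[0, 1]
    assert abs(r) > 0.5


def test_masked_not_more_accurate_than_dense_control(planted_setup):
    masks, X, y = planted_setup
    cfg = mp.TrainConfig(learning_rate=0.01, epochs=300, seed=0)
    masked = mp.train_masked_ffnn(X, y, masks, cfg)
    control = mp.train_control_ffnn(X, y, masks, cfg)
    assert masked.metrics["oof_pearson_r"] <= control.metrics["oof_pearson_r"]
    assert control.provenance["model"] == "DenseControlRegressor"


def test_control_has_same_layer_sizes_more_parameters(planted_setup):
    masks, X, y = planted_setup
    dense = mp.MaskedPathwayRegressor(masks, masked=False, lr=0.01, epochs=1, seed=0).fit(X, y)
    sparse = mp.MaskedPathwayRegressor(masks, masked=True, lr=0.01, epochs=1, seed=0).fit(X, y)
    assert dense.network_.sizes == sparse.network_.sizes == list(masks.layer_sizes)
    assert dense.network_.n_parameters() > sparse.network_.n_parameters(nonzero_only=True)
    with pytest.raises(ValueError, match="dense"):
        dense.top_weighted_sets()
    with pytest.raises(ValueError, match="dense"):
        dense.pathway_activations(X)


def test_control_training_deterministic(planted_setup):
    masks, X, y = planted_setup
    cfg = mp.TrainConfig(learning_rate=0.01, epochs=40, seed=5)
    a = mp.train_control_ffnn(X, y, masks, cfg)
    b = mp.train_control_ffnn(X, y, masks, cfg)
    assert np.allclose(a.oof_pred, b.oof_pred, atol=1e-12)


def test_zero_input_activations_equal_rectified_biases():
    ann = _chain_annotation(4)
    masks = mp.build_masks(FeatureSet([f"cg{i}" for i in range(4)]), ann, "pathways")
    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=5, standardize=False, seed=0)
    est.fit(np.random.default_rng(0).normal(size=(20, 4)), np.arange(20.0))
    net = est.network_
    acts = est.pathway_activations(np.zeros((1, 4)))
    expected = np.maximum(np.maximum(net.b[0], 0.0) @ net.W[1] + net.b[1], 0.0)
    assert np.allclose(acts.to_numpy()[0], expected, atol=1e-12)


def test_activation_locality_under_single_gene_perturbation():
    ann = _chain_annotation(4)
    masks = mp.build_masks(FeatureSet([f"cg{i}" for i in range(4)]), ann, "pathways")
    rng = np.random.default_rng(1)
    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=20, standardize=False, seed=0)
    est.fit(rng.normal(size=(30, 4)), np.arange(30.0))
    x = rng.normal(size=(1, 4))
    x2 = x.copy()
    probe_idx = list(masks.retained_cpgs).index("cg2")
    x2[0, probe_idx] += 5.0  # perturb only the probe of gene G2
    a1 = est.pathway_activations(x).to_numpy()[0]
    a2 = est.pathway_activations(x2).to_numpy()[0]
    changed = {s for s, d in zip(masks.set_names, a1 != a2) if d}
    gene_col = list(masks.gene_names).index("G2")
    allowed = {s for s, m in zip(masks.set_names, masks.gene_set[gene_col]) if m}
    assert changed <= allowed


def test_top_weighted_sets_ranking_contract():
    ann = _chain_annotation(3)
    masks = mp.build_masks(FeatureSet([f"cg{i}" for i in range(3)]), ann, "pathways")
    est = mp.MaskedPathwayRegressor(masks, lr=0.01, epochs=1, standardize=False, seed=0)
    est.fit(np.eye(3), np.arange(3.0))
    w = est.network_.W[-1]
    w[:] = 0.0
    w[1, 0] = -2.5  # only SET1 carries readout weight
    top = est.top_weighted_sets(3)
    assert top.iloc[0]["set_name"] == "SET1"
    assert top.iloc[0]["abs_weight"] == pytest.approx(2.5)
    assert (top["abs_weight"].diff().dropna() <= 1e-12).all()
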