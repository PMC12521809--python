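"""Biology-masked explainable clock: CpG -> gene -> gene set -> age.

The explainable regressor is a feed-forward network whose connectivity is
restricted by annotation: a CpG connects only to the genes it is annotated
to, and a gene connects only to the gene sets (pathways or TF-target sets)
that contain it.  The final layer is a dense linear readout from the set
layer to age, so the absolute readout weight of each set measures how much
that biological process contributes to the age estimate, and the set-layer
activations of a single sample give a per-person pathway profile.

A fully-connected control network with identical layer widths quantifies the
accuracy cost of imposing the biological sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .matrix import AnnotationBundle
from .nn import MLP
from .regress import TrainConfig, regression_metrics
from .results import FitResult
from .select import FeatureSet


@dataclass(frozen=True)
class MaskSpec:
    """Binary connectivity of the explainable network.

    ``cpg_gene[i, j] = 1`` iff retained CpG i is annotated to gene j;
    ``gene_set[j, s] = 1`` iff gene j belongs to set s.  Every retained CpG
    has at least one gene, every gene at least one probe and one set, every
    set at least one gene; the arrays are immutable after construction.
    """

    cpg_gene: np.ndarray
    gene_set: np.ndarray
    retained_cpgs: tuple[str, ...]
    gene_names: tuple[str, ...]
    set_names: tuple[str, ...]

    def __post_init__(self) -> None:
        cg, gs = self.cpg_gene, self.gene_set
        if cg.shape != (len(self.retained_cpgs), len(self.gene_names)):
            raise ValueError("cpg_gene shape mismatch")
        if gs.shape != (len(self.gene_names), len(self.set_names)):
            raise ValueError("gene_set shape mismatch")
        if not (cg.sum(axis=1) >= 1).all():
            raise ValueError("every retained CpG needs >= 1 gene")
        if not ((cg.sum(axis=0) >= 1) & (gs.sum(axis=1) >= 1)).all():
            raise ValueError("every gene needs >= 1 probe and >= 1 set")
        if not (gs.sum(axis=0) >= 1).all():
            raise ValueError("every set needs >= 1 gene")
        cg.setflags(write=False)
        gs.setflags(write=False)

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        return (len(self.retained_cpgs), len(self.gene_names), len(self.set_names), 1)


def build_masks(features: FeatureSet, ann: AnnotationBundle, collection: str) -> MaskSpec:
    """Derive the connectivity masks for a feature set and one collection.

    Unannotated probes are dropped; genes absent from every set of the
    collection (and sets with no retained gene) are pruned, then probes left
    with no surviving gene are dropped as well — a zero row could never
    influence the output.
    """
    if collection not in ann.collections:
        raise KeyError(f"collection {collection!r} not in annotation bundle")
    sets = ann.collections[collection]
    genes_in_sets: set[str] = set().union(*sets.values())

    kept_probes, probe_genes = [], []
    for p in features.probes:
        g = ann.probe_gene.get(p, frozenset()) & genes_in_sets
        if g:
            kept_probes.append(p)
            probe_genes.append(g)
    if not kept_probes:
        raise ValueError("no probes with gene annotations linked to the collection")

    genes = sorted(set().union(*probe_genes))
    gidx = {g: j for j, g in enumerate(genes)}
    kept_sets = sorted(s for s, members in sets.items() if members & set(genes))

    cg = np.zeros((len(kept_probes), len(genes)))
    for i, gs in enumerate(probe_genes):
        for g in gs:
            cg[i, gidx[g]] = 1.0
    gsm = np.zeros((len(genes), len(kept_sets)))
    for sj, s in enumerate(kept_sets):
        for g in sets[s] & set(genes):
            gsm[gidx[g], sj] = 1.0
    return MaskSpec(cg, gsm, tuple(kept_probes), tuple(genes), tuple(kept_sets))


class MaskedPathwayRegressor(BaseEstimator, RegressorMixin):
    """Explainable age regressor with annotation-masked connectivity.

    The network is CpG -> gene -> set -> age with ReLU after the gene and set
    layers; the two inner layers carry hard binary masks, the readout is
    dense.  Setting ``masked=False`` gives the fully-connected control with
    the same layer widths.
    """

    def __init__(
        self,
        masks: MaskSpec,
        masked: bool = True,
        lr: float = 1e-6,
        epochs: int = 2500,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.masks = masks
        self.masked = masked
        self.lr = lr
        self.epochs = epochs
        self.standardize = standardize
        self.seed = seed

    def _prep(self, X, fitting: bool):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.masks.retained_cpgs):
            raise ValueError(
                f"X has {X.shape[1]} columns; masks expect {len(self.masks.retained_cpgs)}"
            )
        if self.standardize:
            if fitting:
                self.x_mean_ = X.mean(axis=0)
                sd = X.std(axis=0)
                self.x_scale_ = np.where(sd > 0, sd, 1.0)
            X = (X - self.x_mean_) / self.x_scale_
        return X

    def fit(self, X, y, callback=None):
        X = self._prep(X, fitting=True)
        y = np.asarray(y, dtype=float)
        self.y_mean_ = float(y.mean())  # residual fit; see FFNNRegressor
        layer_masks = (
            [self.masks.cpg_gene, self.masks.gene_set, None] if self.masked else [None] * 3
        )
        self.network_ = MLP(self.masks.layer_sizes, masks=layer_masks, seed=self.seed)
        self.loss_curve_ = self.network_.fit(
            X, y - self.y_mean_, lr=self.lr, epochs=self.epochs, callback=callback
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        return self.y_mean_ + self.network_.predict(self._prep(X, fitting=False))

    def input_gradient(self, X):
        check_is_fitted(self, "network_")
        g = self.network_.input_gradient(self._prep(X, fitting=False))
        if self.standardize:
            g = g / self.x_scale_
        return g

    def pathway_activations(self, X) -> pd.DataFrame:
        """Post-ReLU values of the set-layer neurons, one row per sample."""
        check_is_fitted(self, "network_")
        if not self.masked:
            raise ValueError("dense control model has no named set layer")
        _, hidden = self.network_.forward(self._prep(X, fitting=False), return_hidden=True)
        return pd.DataFrame(hidden[1], columns=list(self.masks.set_names))

    def top_weighted_sets(self, n: int = 10) -> pd.DataFrame:
        """Gene sets ranked by |weight| in the set -> age readout layer."""
        check_is_fitted(self, "network_")
        if not self.masked:
            raise ValueError("dense control model has no named set layer")
        w = np.abs(self.network_.W[-1][:, 0])
        tbl = pd.DataFrame({"set_name": self.masks.set_names, "abs_weight": w})
        tbl = tbl.sort_values(["abs_weight", "set_name"], ascending=[False, True])
        return tbl.head(n).reset_index(drop=True)


def _cv_fit(X, y, masks: MaskSpec, masked: bool, cfg: TrainConfig) -> FitResult:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    oof = np.empty(len(y))
    fold_id = np.full(len(y), -1, dtype=int)
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    for k, (train, test) in enumerate(kf.split(X)):
        est = MaskedPathwayRegressor(
            masks, masked=masked, lr=cfg.learning_rate, epochs=cfg.epochs,
            standardize=cfg.standardize, seed=cfg.seed,
        )
        est.fit(X[train], y[train])
        oof[test] = est.predict(X[test])
        fold_id[test] = k
    final = MaskedPathwayRegressor(
        masks, masked=masked, lr=cfg.learning_rate, epochs=cfg.epochs,
        standardize=cfg.standardize, seed=cfg.seed,
    )
    final.fit(X, y)
    met = regression_metrics(oof, y)
    return FitResult(
        model=final,
        features=list(masks.retained_cpgs),
        oof_pred=oof,
        fold=fold_id,
        metrics={"oof_pearson_r": met.pearson_r, "oof_mae": met.mae, "oof_rmse": met.rmse},
        provenance={
            "model": "MaskedPathwayRegressor" if masked else "DenseControlRegressor",
            "layer_sizes": list(masks.layer_sizes),
            "learning_rate": cfg.learning_rate,
            "epochs": cfg.epochs,
            "folds": cfg.folds,
            "seed": cfg.seed,
            "reference_protocol": cfg.is_reference_protocol(),
        },
    )


def train_masked_ffnn(X, y, masks: MaskSpec, cfg: TrainConfig | None = None) -> FitResult:
    """Cross-validated fit of the biology-masked explainable regressor."""
    return _cv_fit(X, y, masks, masked=True, cfg=cfg or TrainConfig())


def train_control_ffnn(X, y, masks: MaskSpec, cfg: TrainConfig | None = None) -> FitResult:
    """Fully-connected control with the same layer widths as the masked net."""
    return _cv_fit(X, y, masks, masked=False, cfg=cfg or TrainConfig())


def pathway_activations(model: MaskedPathwayRegressor, X) -> pd.DataFrame:
    return model.pathway_activations(X)


def top_weighted_sets(model: MaskedPathwayRegressor, n: int = 10) -> pd.DataFrame:
    return model.top_weighted_sets(n)
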