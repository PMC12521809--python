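"""Correlation-based CpG feature selection.

Every probe is scored by Pearson correlation with the target (point-biserial
for 0/1 targets — same formula), and the top K probes by |r| become the model
input.  For race/ethnicity, selection is the union of per-class top-K lists
against one-hot class indicators, excluding the catch-all "Other" class.
"Top correlated" is interpreted as largest absolute correlation: both hyper-
and hypomethylation carry signal and downstream models are sign-agnostic.
Ties are broken lexicographically by probe ID for cross-platform
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import MethylMatrix


@dataclass
class CorrelationVector:
    """Per-probe Pearson correlations against one target."""

    r: pd.Series  # probe_id -> r in [-1, 1]
    target_name: str
    n_used: int

    def __post_init__(self) -> None:
        if self.n_used < 3:
            raise ValueError("need >= 3 samples for a correlation")
        if (self.r.abs() > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class FeatureSet:
    """Ordered probe list with selection provenance."""

    probes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probes in feature set")

    def __len__(self) -> int:
        return len(self.probes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.provenance}\n")
            fh.writelines(p + "\n" for p in self.probes)

    @classmethod
    def read(cls, path) -> "FeatureSet":
        probes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    probes.append(line)
        return cls(probes)


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``x`` against ``y``; zero-variance -> 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / denom
    r[denom == 0] = 0.0  # zero-variance probes: keep the vector total-ordered
    return np.clip(r, -1.0, 1.0)


def cpg_correlations(mat: MethylMatrix, target, target_name: str = "target") -> CorrelationVector:
    """Pearson correlation of every probe with a numeric target vector."""
    y = np.asarray(target, dtype=float)
    if y.shape != (mat.n_samples,):
        raise ValueError("target length must equal the number of samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("target must be finite")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; correlation undefined")
    r = _pearson_columns(mat.values, y)
    return CorrelationVector(pd.Series(r, index=mat.probe_ids), target_name, mat.n_samples)


def _rank(r: pd.Series) -> pd.Index:
    """Probe IDs ordered by |r| descending, ties lexicographic by probe ID."""
    order = sorted(r.index, key=lambda p: (-abs(r[p]), p))
    return pd.Index(order)


def select_top_k(corr: CorrelationVector, k: int) -> FeatureSet:
    """The k probes with largest absolute correlation, in rank order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(corr.r):
        raise ValueError(f"k={k} exceeds the {len(corr.r)} available probes")
    probes = list(_rank(corr.r)[:k])
    return FeatureSet(probes, {"targets": [corr.target_name], "k": k, "scheme": "topk"})


def select_union_per_class(
    mat: MethylMatrix,
    labels,
    classes: list[str],
    k_per_class: int = 2500,
) -> FeatureSet:
    """Union of per-class top-K selections against one-hot class indicators.

    Each class in ``classes`` must be present at least twice; classes not
    listed (e.g. "Other") do not contribute a top list but still inform the
    indicator coding.  The union preserves first-seen rank order across the
    classes in the given order.
    """
    lab = np.asarray(labels, dtype=object)
    if lab.shape != (mat.n_samples,):
        raise ValueError("labels length must equal the number of samples")
    for cls in classes:
        count = int((lab == cls).sum())
        if count < 2:
            raise ValueError(f"class {cls!r} has {count} members; need >= 2")
    seen: list[str] = []
    have: set[str] = set()
    for cls in classes:
        corr = cpg_correlations(mat, (lab == cls).astype(float), target_name=str(cls))
        for p in _rank(corr.r)[:k_per_class]:
            if p not in have:
                have.add(p)
                seen.append(p)
    return FeatureSet(
        seen, {"targets": list(classes), "k": k_per_class, "scheme": "union"}
    )


class CorrelationSelector(BaseEstimator, TransformerMixin):
    """scikit-learn transformer selecting the top-k |Pearson r| features.

    Parameters
    ----------
    k : number of features to keep (``scheme="topk"``) or per class
        (``scheme="union"``).
    scheme : "topk" for numeric/binary targets, "union" for categorical
        targets with a per-class one-hot union.
    classes : class labels entering the union (required for ``scheme="union"``).
    """

    def __init__(self, k: int = 10000, scheme: str = "topk", classes: list[str] | None = None):
        self.k = k
        self.scheme = scheme
        self.classes = classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        mat = MethylMatrix(
            X, [f"s{i}" for i in range(X.shape[0])],
            [f"f{j:09d}" for j in range(X.shape[1])], space="M",
        )
        if self.scheme == "topk":
            fs = select_top_k(cpg_correlations(mat, np.asarray(y, dtype=float)), self.k)
        elif self.scheme == "union":
            if not self.classes:
                raise ValueError("scheme='union' requires classes")
            fs = select_union_per_class(mat, y, classes=list(self.classes), k_per_class=self.k)
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        idx = {p: j for j, p in enumerate(mat.probe_ids)}
        self.support_idx_ = np.array([idx[p] for p in fs.probes])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_idx_")
        return np.asarray(X)[:, self.support_idx_]
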