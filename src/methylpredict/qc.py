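"""Batch-effect QC and delta-age association models.

Batch screening: PCA on the (mean-centered) M matrix, then — component by
component — the mean silhouette width of each plate/batch treating the single
component as a 1-D embedding with absolute-difference distance.  A strictly
positive per-batch width on some component indicates that plates separate
along that direction of methylation variation; a clean dataset shows none.
The per-component reading is used because a silhouette "across one of the
principal components" is only meaningful one component at a time; a
joint-space variant is available behind a flag.

Associations: each outcome (delta age, predicted smoking/BMI/alcohol) is
modeled by ordinary least squares on chronological age, the epithelial
fraction E, BMI, nine 0-1 lifestyle scores, sex, smoking, alcohol and
race/ethnicity (indicator contrasts against the largest class), with
two-sided t-tests per coefficient and BH FDR across the covariates of one
model.  Welch's unequal-variance t-test serves the pairwise category
contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .interpret import bh_fdr
from .matrix import MethylMatrix


def pca_scores(mat: MethylMatrix | np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of mean-centered data with a fixed sign convention.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-|loading| element is positive, making scores
    reproducible across platforms.

    Returns (scores, explained_variance), scores shape (n_samples, k).
    """
    X = mat.values if isinstance(mat, MethylMatrix) else np.asarray(mat, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores, pca.explained_variance_


def batch_silhouette(
    scores: np.ndarray,
    batch_labels,
    n_components: int = 1000,
    joint: bool = False,
) -> pd.DataFrame:
    """Per-batch mean silhouette width on each principal component.

    Returns a tidy DataFrame (component, batch, silhouette, positive);
    ``joint=True`` instead evaluates one silhouette in the joint space of the
    first ``n_components`` components.  Batches with a single member get
    width 0 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(batch_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct batches")
    k = min(n_components, scores.shape[1])
    rows = []
    if joint:
        widths = silhouette_samples(scores[:, :k], labels)
        for b in np.unique(labels):
            w = float(widths[labels == b].mean())
            rows.append({"component": -1, "batch": b, "silhouette": w, "positive": w > 0})
    else:
        for j in range(k):
            widths = silhouette_samples(scores[:, j : j + 1], labels)
            for b in np.unique(labels):
                w = float(widths[labels == b].mean())
                rows.append({"component": j, "batch": b, "silhouette": w, "positive": w > 0})
    return pd.DataFrame(rows)


def silhouette_permutation_threshold(
    scores: np.ndarray,
    batch_labels,
    n_components: int = 20,
    n_permutations: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Empirical null threshold for per-batch silhouette widths.

    Permutes batch labels and returns the given quantile of the resulting
    per-component, per-batch widths — widths above it are unlikely under
    "no batch structure".
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(batch_labels).copy()
    null: list[float] = []
    for _ in range(n_permutations):
        rng.shuffle(labels)
        rep = batch_silhouette(scores, labels, n_components=n_components)
        null.extend(rep["silhouette"].tolist())
    return float(np.quantile(null, quantile))


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design: categoricals become indicators vs the largest class."""
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "biufc":
            cols[name] = col.astype(float)
        else:
            ref = col.value_counts().idxmax()  # reference = largest class
            for level in sorted(col.unique()):
                if level != ref:
                    cols[f"{name}[{level}]"] = (col == level).astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def fit_association(outcome, covariates: pd.DataFrame, outcome_name: str = "outcome") -> pd.DataFrame:
    """OLS of an outcome on the covariate table, with BH FDR per covariate.

    Categorical covariates are expanded to indicator contrasts against their
    largest level; an intercept is always included (and excluded from the
    FDR adjustment).  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = _design_matrix(covariates)
    if len(y) != len(X):
        raise ValueError("outcome and covariates length mismatch")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more samples than coefficients")
    design = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = []
        base_cols = ["const"]
        for c in X.columns:  # greedily identify columns that add no rank
            trial = design[base_cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(base_cols):
                collinear.append(c)
            else:
                base_cols.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, design).fit()
    out = pd.DataFrame(
        {
            "coefficient": fit.params,
            "std_error": fit.bse,
            "p": fit.pvalues,
        }
    )
    mask = out.index != "const"
    fdr = pd.Series(np.nan, index=out.index)
    fdr[mask] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["fdr"] = fdr
    out.attrs["outcome"] = outcome_name
    out.attrs["formula"] = f"{outcome_name} ~ " + " + ".join(["1", *X.columns])
    return out


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Returns (t, df, two-sided p).  Two zero-variance groups with equal means
    give (0, df, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
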