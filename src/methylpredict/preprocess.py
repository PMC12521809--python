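"""Beta/M transforms and reference-based cell-fraction estimation.

The M value is the log2 odds of methylation, M = log2(beta / (1 - beta)),
computed after clipping beta into [eps, 1 - eps] (default eps = 1e-5) to
avoid infinities at fully (un)methylated probes.  M values are the working
scale for all modelling because they are variance-stabilized near the
extremes of the beta scale.

Cell fractions (epithelial / neutrophil / other immune) are estimated per
sample by nonnegative least squares against reference beta profiles; the
epithelial fraction feeds the delta-age association model as a covariate but
is never used as a model-training input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .matrix import MethylMatrix


def beta_to_m(mat: MethylMatrix, eps: float = 1e-5) -> MethylMatrix:
    """Transform a beta-space matrix to M space with clipping.

    Each value becomes ``log2(b / (1 - b))`` with ``b`` clipped into
    ``[eps, 1 - eps]``, so outputs are bounded by ``log2((1 - eps) / eps)``
    in absolute value.
    """
    if mat.space != "beta":
        raise ValueError(f"expected beta-space input, got {mat.space!r}")
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps must lie in (0, 0.5), got {eps!r}")
    b = np.clip(mat.values, eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return MethylMatrix(m, mat.sample_ids, mat.probe_ids, space="M")


def m_to_beta(mat: MethylMatrix) -> MethylMatrix:
    """Inverse transform: beta = 2^M / (1 + 2^M) (the logistic in base 2)."""
    if mat.space != "M":
        raise ValueError(f"expected M-space input, got {mat.space!r}")
    e = np.exp2(mat.values)
    return MethylMatrix(e / (1.0 + e), mat.sample_ids, mat.probe_ids, space="beta")


def estimate_cell_fractions(mat: MethylMatrix, reference: pd.DataFrame) -> pd.DataFrame:
    """Estimate per-sample cell-type fractions from reference beta profiles.

    Solves, per sample, ``min_w ||R^T w - b||^2  s.t.  w >= 0`` where ``R`` is
    the cell-type x probe reference matrix restricted to probes present in
    ``mat``, then rescales the solution to sum to at most 1.  Deterministic.

    Parameters
    ----------
    mat : beta-space MethylMatrix
    reference : DataFrame, cell types x probes, beta values

    Returns
    -------
    DataFrame, samples x cell types, fractions in [0, 1] summing to <= 1.
    """
    if mat.space != "beta":
        raise ValueError("cell-fraction estimation expects beta values")
    if reference.shape[0] < 2:
        raise ValueError("need at least 2 reference cell types")
    common = [p for p in reference.columns.astype(str) if p in set(mat.probe_ids)]
    if len(common) < 2:
        raise ValueError(
            f"only {len(common)} reference probes overlap the matrix; need >= 2"
        )
    ref = reference.loc[:, common].to_numpy(dtype=float)
    sub = mat.subset_probes(common).values
    out = np.empty((mat.n_samples, ref.shape[0]))
    for i in range(mat.n_samples):
        w, _ = nnls(ref.T, sub[i])
        total = w.sum()
        if total > 1.0:
            w = w / total
        out[i] = w
    return pd.DataFrame(out, index=mat.sample_ids, columns=list(reference.index))
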