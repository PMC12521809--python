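"""Feature importance, attribution, set overlaps and enrichment analyses.

Forest importance is the mean decrease in impurity accumulated within each
tree (with per-tree standard deviation).  Network importance uses integrated
gradients with the mean of a background panel (by convention the first 100
samples) as baseline; per-sample attributions satisfy the completeness
identity sum_i a_i(x) ~ f(x) - f(baseline) and are averaged across all
samples, then ranked by absolute value.

Both enrichment analyses are upper-tail hypergeometric tests with
Benjamini-Hochberg FDR: over-representation of gene sets among the genes
annotated to the top CpGs (universe = genes annotated anywhere on the
array), and over-representation of genomic feature categories
(CpG-island relation, regulatory group) among the top probes against the
array background.  Significance is called at FDR < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .matrix import AnnotationBundle
from .select import FeatureSet

FDR_THRESHOLD = 0.1


@dataclass
class ImportanceVector:
    """Per-probe importances with provenance of how they were computed."""

    values: pd.Series  # probe_id -> importance
    method: str
    background: str = ""
    sd: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("importances must be finite")


def rf_importance(model, feature_names: list[str] | None = None) -> ImportanceVector:
    """Impurity-decrease importance of a fitted forest, normalized to sum 1."""
    if not hasattr(model, "estimators_"):
        raise ValueError("model is not a fitted forest")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    per_tree = np.array([t.feature_importances_ for t in model.estimators_])
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(len(imp))]
    return ImportanceVector(
        values=pd.Series(imp, index=names),
        method="impurity",
        sd=pd.Series(per_tree.std(axis=0), index=names),
    )


def _gradient_fn(model):
    if hasattr(model, "input_gradient"):
        return model.input_gradient
    raise TypeError("model must expose input_gradient (FFNN-family estimator)")


def integrated_gradients(model, X, baseline: np.ndarray, n_steps: int = 256) -> np.ndarray:
    """Path-integral attribution from ``baseline`` to each row of ``X``.

    Uses the midpoint Riemann approximation of
    ``(x - b) * \\int_0^1 grad f(b + a (x - b)) da``; for piecewise-linear
    (ReLU) networks the integrand is piecewise constant, so the sum converges
    quickly to the exact path integral and the attributions satisfy
    completeness: they sum to ``f(x) - f(b)``.
    """
    X = np.asarray(X, dtype=float)
    baseline = np.asarray(baseline, dtype=float).reshape(1, -1)
    grad = _gradient_fn(model)
    diff = X - baseline
    acc = np.zeros_like(X)
    for s in range(n_steps):
        alpha = (s + 0.5) / n_steps
        acc += grad(baseline + alpha * diff)
    return diff * acc / n_steps


def deep_attribution(
    model,
    X,
    background: np.ndarray | None = None,
    n_background: int = 100,
    n_steps: int = 256,
    feature_names: list[str] | None = None,
) -> ImportanceVector:
    """Average integrated-gradients attribution across all samples.

    The baseline is the mean of the background panel (default: the first
    ``n_background`` rows of ``X``).  The signed mean attribution per feature
    is returned; rank by absolute value for top-feature extraction.
    """
    X = np.asarray(X, dtype=float)
    if background is None:
        background = X[:n_background]
    background = np.asarray(background, dtype=float)
    if background.shape[0] == 0:
        raise ValueError("background must contain at least one sample")
    attr = integrated_gradients(model, X, background.mean(axis=0), n_steps=n_steps)
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(X.shape[1])]
    return ImportanceVector(
        values=pd.Series(attr.mean(axis=0), index=names),
        method="integrated_gradients",
        background=f"mean of {background.shape[0]} background samples",
    )


def top_n(imp: ImportanceVector, n: int = 1000) -> FeatureSet:
    """The n features with largest |importance|; ties lexicographic by ID."""
    if n > len(imp.values):
        raise ValueError(f"n={n} exceeds {len(imp.values)} features")
    order = sorted(imp.values.index, key=lambda p: (-abs(imp.values[p]), p))
    return FeatureSet(list(order[:n]), {"method": imp.method, "n": n, "scheme": "top_importance"})


def set_overlap_test(set_a, set_b, universe: int) -> tuple[int, float]:
    """Upper-tail hypergeometric p of observing >= the seen overlap.

    Models |A ∩ B| for fixed set sizes drawn from a universe of ``universe``
    elements: P(X >= k) with X ~ Hypergeom(N=universe, K=|A|, n=|B|).
    """
    a = set(set_a.probes if isinstance(set_a, FeatureSet) else set_a)
    b = set(set_b.probes if isinstance(set_b, FeatureSet) else set_b)
    if len(a) > universe or len(b) > universe or len(a | b) > universe:
        raise ValueError("sets exceed the stated universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, universe, len(a), len(b)))
    return k, min(p, 1.0)


def intersection_counts(sets: dict[str, FeatureSet | set]) -> pd.DataFrame:
    """Exclusive-intersection counts over every membership pattern.

    Each element of the union is assigned to exactly one pattern (the tuple
    of sets containing it), so pattern counts sum to the union size.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    named = {
        k: set(v.probes if isinstance(v, FeatureSet) else v) for k, v in sets.items()
    }
    names = list(named)
    union = set().union(*named.values())
    counts: dict[tuple[bool, ...], int] = {}
    for el in union:
        pattern = tuple(el in named[n] for n in names)
        counts[pattern] = counts.get(pattern, 0) + 1
    rows = [
        {**{n: m for n, m in zip(names, pattern)}, "count": c}
        for pattern, c in sorted(counts.items(), reverse=True)
    ]
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _enrichment_table(rows: list[dict]) -> pd.DataFrame:
    tbl = pd.DataFrame(rows)
    tbl["fdr"] = bh_fdr(tbl["p"].to_numpy())
    return tbl.sort_values(["p", "term"]).reset_index(drop=True)


def ora_genesets(
    top: FeatureSet,
    ann: AnnotationBundle,
    collection: str,
    permutation_null: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set over-representation of the genes behind the top CpGs.

    Maps the top probes to their annotated genes (deduplicated: a probe
    annotated to several genes contributes each once), then tests every set
    in the collection by upper-tail hypergeometric against the universe of
    genes annotated to any probe.  BH FDR is computed across the collection.

    ``permutation_null > 0`` adds an empirical p-value column obtained by
    redrawing equally many random probes and recomputing each set's hit
    count — a simple guard against probes-per-gene bias (off by default).
    """
    if collection not in ann.collections:
        raise KeyError(f"collection {collection!r} not in annotation bundle")
    universe_genes = ann.all_genes()
    if not universe_genes:
        raise ValueError("annotation maps no probe to any gene")

    def probe_genes(probes) -> set[str]:
        out: set[str] = set()
        for p in probes:
            out |= ann.probe_gene.get(p, frozenset())
        return out & universe_genes

    hit_genes = probe_genes(top.probes)
    if not hit_genes:
        raise ValueError("top probes map to no genes")
    n_univ, n_draw = len(universe_genes), len(hit_genes)
    rows = []
    for term, members in ann.collections[collection].items():
        members = members & universe_genes
        k = len(hit_genes & members)
        rows.append(
            {
                "term": term,
                "hits": k,
                "draw": n_draw,
                "term_size": len(members),
                "universe": n_univ,
                "p": float(hypergeom.sf(k - 1, n_univ, len(members), n_draw)),
            }
        )
    tbl = _enrichment_table(rows)
    if permutation_null > 0:
        rng = np.random.default_rng(seed)
        all_probes = np.array(sorted(ann.probe_gene))
        null_hits = {t: 0 for t in tbl["term"]}
        for _ in range(permutation_null):
            draw = probe_genes(rng.choice(all_probes, size=len(top.probes), replace=False))
            for term, members in ann.collections[collection].items():
                if len(draw & members) >= int(tbl.loc[tbl.term == term, "hits"].iloc[0]):
                    null_hits[term] += 1
        tbl["perm_p"] = [
            (null_hits[t] + 1) / (permutation_null + 1) for t in tbl["term"]
        ]
    tbl.attrs["universe"] = "genes annotated to any probe"
    tbl.attrs["significant"] = f"fdr < {FDR_THRESHOLD}"
    return tbl


def genomic_feature_enrichment(top: FeatureSet, ann: AnnotationBundle) -> pd.DataFrame:
    """Enrichment of island-relation and regulatory-group categories.

    For each category, tests whether the top probes contain more probes of
    that category than expected from the array background, by upper-tail
    hypergeometric; BH FDR is computed within each annotation family.
    """
    missing = [p for p in top.probes if p not in ann.probe_island]
    if missing:
        raise ValueError(f"probes missing feature annotation: {missing[:5]}")
    n_univ = len(ann.probe_gene)
    n_draw = len(top.probes)
    frames = []
    for family, mapping in (("island", ann.probe_island), ("reggroup", ann.probe_reggroup)):
        bg = pd.Series(mapping)
        top_cat = bg.loc[list(top.probes)]
        rows = []
        for cat, big_k in bg.value_counts().items():
            k = int((top_cat == cat).sum())
            rows.append(
                {
                    "term": cat,
                    "hits": k,
                    "draw": n_draw,
                    "term_size": int(big_k),
                    "universe": n_univ,
                    "p": float(hypergeom.sf(k - 1, n_univ, int(big_k), n_draw)),
                }
            )
        fam = _enrichment_table(rows)
        fam.insert(0, "family", family)
        frames.append(fam)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["significant"] = f"fdr < {FDR_THRESHOLD}"
    return out
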