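"""Synthetic cohorts with the statistical structure of a buccal methylome study.

The restricted study cohort (thousands of adults, ages 18-93, EPIC-array beta
values plus lifestyle survey metadata) is not publicly available, so this
module generates cohorts carrying the same kinds of signal the modelling
pipeline assumes:

* a linear chronological-age signal planted in a configurable CpG subset,
* a binary smoking mean-shift, continuous BMI and (latent) alcohol effects,
* per-class ancestry shifts over six imbalanced race/ethnicity groups,
* round-robin plate/batch labels, optionally with a planted batch shift,
* a consistent probe -> gene -> gene-set annotation.

All signal is planted on the M scale (the pipeline's working space) and the
matrix is stored in beta space via the inverse logit-2 transform, so betas are
guaranteed to lie strictly inside (0, 1).  Everything is deterministic for a
given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ISLAND_CATEGORIES, REGULATORY_GROUPS, AnnotationBundle, MethylMatrix

# Race/ethnicity levels with proportions rescaled from a large US buccal cohort
# (Asian/Pacific Islander, Black/African American, Hispanic/Latino,
# Middle Eastern/North African, White/Caucasian, Other).
ETHNICITY_LEVELS = (
    "Asian or Pacific Islander",
    "Black or African American",
    "Hispanic or Latino",
    "Middle Eastern or North African",
    "White or Caucasian",
    "Other",
)
ETHNICITY_PROPS = (960 / 8045, 114 / 8045, 869 / 8045, 204 / 8045, 5378 / 8045, 519 / 8045)

ALCOHOL_LEVELS = ("0 drinks", "1-4 drinks", "4-7 drinks", "8-14 drinks", "15+ drinks")

LIFESTYLE_SCORES = ("hf", "af", "st", "sl", "im", "ed", "so", "di", "ex")

SMOKING_PREVALENCE = 1832 / 8045


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes are on the M scale (log2-odds units); ``noise_sd`` is the
    per-probe Gaussian noise standard deviation, also in M units.  Planted
    probe subsets for the different targets are disjoint.
    """

    n_samples: int = 500
    n_cpgs: int = 5000
    n_genes: int = 400
    n_sets: int = 25  # per collection
    age_range: tuple[float, float] = (18.0, 93.0)
    age_cpgs: int = 300
    smoking_cpgs: int = 150
    bmi_cpgs: int = 100
    alcohol_cpgs: int = 100
    ancestry_cpgs: int = 40  # per class
    age_slope: float = 0.02  # M units per year
    smoking_effect: float = 1.0
    bmi_slope: float = 0.05  # M units per BMI unit
    alcohol_effect: float = 0.8  # M units per unit of the 0-1 latent scale
    ancestry_effect: float = 1.0
    noise_sd: float = 0.1
    n_batches: int = 4
    batch_shift: float = 0.0
    batch_frac: float = 0.1  # fraction of probes shifted when batch_shift != 0
    gene_frac: float = 0.6  # fraction of probes with >= 1 gene annotation
    set_overlap: float = 1.0  # extra cross-set gene assignments, per gene; 0 = partition
    age_shape: str = "linear"  # or "nonlinear": monotone accelerating (quadratic) age signal
    planted_set: str | None = None  # funnel age CpGs into this pathway set
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_samples=self.n_samples,
            n_cpgs=self.n_cpgs,
            n_genes=self.n_genes,
            n_sets=self.n_sets,
            n_batches=self.n_batches,
        )
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        planted = dict(
            age_cpgs=self.age_cpgs,
            smoking_cpgs=self.smoking_cpgs,
            bmi_cpgs=self.bmi_cpgs,
            alcohol_cpgs=self.alcohol_cpgs,
        )
        for name, v in planted.items():
            if v < 0 or v > self.n_cpgs:
                raise ValueError(f"{name} must lie in [0, n_cpgs], got {v!r}")
        total = sum(planted.values()) + self.ancestry_cpgs * len(ETHNICITY_LEVELS)
        if total > self.n_cpgs:
            raise ValueError("planted probe counts exceed n_cpgs")
        for name in ("age_slope", "smoking_effect", "bmi_slope", "alcohol_effect",
                     "ancestry_effect", "noise_sd", "batch_shift"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.age_range
        if not (lo < hi):
            raise ValueError("age_range low must be < high")
        if lo < 18:
            raise ValueError("age_range low must be >= 18 (adult cohort)")
        if self.age_shape not in ("linear", "nonlinear"):
            raise ValueError("age_shape must be 'linear' or 'nonlinear'")
        if self.n_genes < self.n_sets:
            raise ValueError("n_genes must be >= n_sets (gene sets must be non-empty)")


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def generate_annotation(cfg: SynthConfig) -> AnnotationBundle:
    """Generate a probe manifest plus two gene-set collections.

    A fixed fraction (``cfg.gene_frac``) of probes carries one to three gene
    symbols; genes are spread round-robin over ``cfg.n_sets`` sets per
    collection with additional random overlap, so sets are non-empty and
    overlapping like real pathway databases.  Deterministic for a seed.
    """
    rng = np.random.default_rng(cfg.seed)
    probes = _probe_ids(cfg.n_cpgs)
    genes = np.array([f"GENE{i:05d}" for i in range(cfg.n_genes)])

    n_annot = int(round(cfg.gene_frac * cfg.n_cpgs))
    annotated = rng.choice(cfg.n_cpgs, size=n_annot, replace=False)
    probe_gene: dict[str, frozenset[str]] = {p: frozenset() for p in probes}
    for i in annotated:
        k = rng.choice((1, 2, 3), p=(0.7, 0.2, 0.1))  # most probes map to one gene
        probe_gene[probes[i]] = frozenset(rng.choice(genes, size=k, replace=False))

    island = rng.choice(
        len(ISLAND_CATEGORIES), size=cfg.n_cpgs, p=(0.30, 0.05, 0.12, 0.36, 0.05, 0.12)
    )
    regp = np.full(len(REGULATORY_GROUPS), 0.05)
    regp[[0, 2, 4]] = (0.20, 0.15, 0.20)
    regp[-1] = 1.0 - regp[:-1].sum()
    reggroup = rng.choice(len(REGULATORY_GROUPS), size=cfg.n_cpgs, p=regp)

    collections: dict[str, dict[str, frozenset[str]]] = {}
    for cname in ("pathways", "tf_targets"):
        sets: dict[str, set[str]] = {f"{cname[:-1].upper()}_{j:03d}": set() for j in range(cfg.n_sets)}
        names = sorted(sets)
        for gi, g in enumerate(genes):  # round-robin guarantees non-empty sets
            sets[names[gi % cfg.n_sets]].add(str(g))
        n_extra = int(round(cfg.set_overlap * cfg.n_genes))  # random overlap
        extra = rng.integers(0, cfg.n_genes, size=n_extra)
        for j, gi in enumerate(extra):
            sets[names[j % cfg.n_sets]].add(str(genes[gi]))
        collections[cname] = {s: frozenset(g) for s, g in sets.items()}

    return AnnotationBundle(
        probe_gene=probe_gene,
        probe_island={p: ISLAND_CATEGORIES[i] for p, i in zip(probes, island)},
        probe_reggroup={p: REGULATORY_GROUPS[i] for p, i in zip(probes, reggroup)},
        collections=collections,
    )


def _pick_planted(cfg: SynthConfig, ann: AnnotationBundle, rng) -> dict[str, np.ndarray]:
    """Choose disjoint probe-index subsets for each planted signal."""
    probes = _probe_ids(cfg.n_cpgs)
    pos = {p: i for i, p in enumerate(probes)}
    taken: set[int] = set()
    out: dict[str, np.ndarray] = {}

    if cfg.planted_set is not None:
        # funnel: age probes must map only to genes of the planted set, so all
        # age signal reaches the set layer through that one set
        target_genes = ann.collections["pathways"][cfg.planted_set]
        eligible = [
            pos[p]
            for p in probes
            if ann.probe_gene[p] and ann.probe_gene[p] <= target_genes
        ]
        if len(eligible) < cfg.age_cpgs:
            raise ValueError(
                f"only {len(eligible)} probes annotate exclusively to set "
                f"{cfg.planted_set!r}; need {cfg.age_cpgs} age probes"
            )
        out["age"] = rng.choice(eligible, size=cfg.age_cpgs, replace=False)
    else:
        out["age"] = rng.choice(cfg.n_cpgs, size=cfg.age_cpgs, replace=False)
    taken |= set(out["age"].tolist())

    def draw(n: int) -> np.ndarray:
        free = np.setdiff1d(np.arange(cfg.n_cpgs), np.fromiter(taken, dtype=int, count=len(taken)))
        chosen = rng.choice(free, size=n, replace=False)
        taken.update(chosen.tolist())
        return chosen

    out["smoking"] = draw(cfg.smoking_cpgs)
    out["bmi"] = draw(cfg.bmi_cpgs)
    out["alcohol"] = draw(cfg.alcohol_cpgs)
    for level in ETHNICITY_LEVELS:
        out[f"ancestry:{level}"] = draw(cfg.ancestry_cpgs)
    return out


def generate_cohort(cfg: SynthConfig, ann: AnnotationBundle) -> tuple[MethylMatrix, pd.DataFrame]:
    """Generate a beta matrix and a metadata table for one synthetic cohort.

    Returns
    -------
    mat : MethylMatrix in beta space, samples x probes
    meta : DataFrame indexed by sample ID with columns ``age``, ``sex``,
        ``smoking``, ``alcohol`` (5-level category), ``alcohol_latent``,
        ``bmi``, ``ethnicity``, ``batch`` and nine 0-1 lifestyle scores.
    """
    if len(ann.probe_gene) != cfg.n_cpgs:
        raise ValueError("annotation does not match cfg.n_cpgs")
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from annotation
    n = cfg.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    probes = _probe_ids(cfg.n_cpgs)

    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    smoking = rng.random(n) < SMOKING_PREVALENCE
    eth_p = np.asarray(ETHNICITY_PROPS) / np.sum(ETHNICITY_PROPS)
    ethnicity = rng.choice(len(ETHNICITY_LEVELS), size=n, p=eth_p)
    bmi = np.clip(rng.normal(27.0, 5.0, size=n), 16.0, 50.0)
    # latent weekly consumption on a healthiest=1 ... heaviest=0 scale, binned
    alcohol_latent = np.clip(rng.beta(3.0, 1.2, size=n), 0.0, 1.0)
    alcohol_cat = pd.cut(
        1.0 - alcohol_latent,
        bins=[-0.001, 0.2, 0.4, 0.6, 0.8, 1.001],
        labels=list(ALCOHOL_LEVELS),
    ).astype(str)
    batch = np.arange(n) % cfg.n_batches

    planted = _pick_planted(cfg, ann, rng)

    baseline = rng.uniform(-2.5, 2.5, size=cfg.n_cpgs)
    m = np.tile(baseline, (n, 1))

    mid_age = float(np.mean(cfg.age_range))
    if cfg.age_shape == "linear":
        age_sig = cfg.age_slope * (age - mid_age)
    else:
        # monotone accelerating signal: same amplitude as the linear case but
        # quadratic in age, so it stays informative across the whole range
        # while a purely linear readout is systematically biased
        lo, hi = cfg.age_range
        u = (age - lo) / (hi - lo)
        age_sig = cfg.age_slope * (hi - lo) * (u**2 - np.mean(u**2))
    m[:, planted["age"]] += age_sig[:, None]
    m[:, planted["smoking"]] += cfg.smoking_effect * smoking[:, None]
    m[:, planted["bmi"]] += cfg.bmi_slope * (bmi - 27.0)[:, None]
    m[:, planted["alcohol"]] += cfg.alcohol_effect * (alcohol_latent - alcohol_latent.mean())[:, None]
    for ci, level in enumerate(ETHNICITY_LEVELS):
        idx = planted[f"ancestry:{level}"]
        m[np.ix_(ethnicity == ci, idx)] += cfg.ancestry_effect

    if cfg.noise_sd > 0:
        m += rng.normal(0.0, cfg.noise_sd, size=m.shape)

    if cfg.batch_shift != 0.0:
        n_shift = max(1, int(round(cfg.batch_frac * cfg.n_cpgs)))
        shifted = rng.choice(cfg.n_cpgs, size=n_shift, replace=False)
        offsets = cfg.batch_shift * (batch - (cfg.n_batches - 1) / 2.0)
        m[:, shifted] += offsets[:, None]

    beta = np.exp2(m) / (1.0 + np.exp2(m))
    mat = MethylMatrix(beta, sample_ids, probes, space="beta")

    meta = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking": np.where(smoking, "smoker", "non-smoker"),
            "alcohol": alcohol_cat,
            "alcohol_latent": alcohol_latent,
            "bmi": bmi,
            "ethnicity": [ETHNICITY_LEVELS[i] for i in ethnicity],
            "batch": [f"plate{b:02d}" for b in batch],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for score in LIFESTYLE_SCORES:
        meta[score] = rng.random(n)
    meta.attrs["planted"] = {k: np.asarray(probes)[v].tolist() for k, v in planted.items()}
    return mat, meta


def generate_cell_reference(
    n_probes: int = 200, cell_types: tuple[str, ...] = ("epithelial", "neutrophil", "otherImmune"),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic reference beta profiles (cell type x probe) for deconvolution.

    Profiles are drawn to be well separated (each cell type hyper-methylated
    on its own probe block), which is what makes reference-based
    deconvolution identifiable.  Synthetic stand-in for published reference
    matrices, which are not distributed with this package.
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    base = rng.uniform(0.2, 0.8, size=(1, n_probes))
    ref = np.clip(base + rng.normal(0, 0.05, size=(k, n_probes)), 0.02, 0.98)
    block = n_probes // k
    for i in range(k):  # give each type a discriminating block
        sl = slice(i * block, (i + 1) * block)
        ref[i, sl] = np.clip(ref[i, sl] + 0.35, 0.02, 0.98)
    return pd.DataFrame(ref, index=list(cell_types), columns=_probe_ids(n_probes))


def write_cohort(
    outdir, mat: MethylMatrix, meta: pd.DataFrame, ann: AnnotationBundle
) -> dict[str, Path]:
    """Write a cohort to disk in the package's plain-text dialects.

    Beta matrix: probes x samples TSV; metadata: CSV; annotation: probe
    manifest TSV plus one GMT file per collection.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": outdir / "betas.tsv",
        "metadata": outdir / "metadata.csv",
        "manifest": outdir / "manifest.tsv",
    }
    mat.write_tsv(paths["betas"])
    meta.to_csv(paths["metadata"])
    ann.write_manifest(paths["manifest"])
    for cname in ann.collections:
        p = outdir / f"{cname}.gmt"
        ann.write_gmt(cname, p)
        paths[f"gmt:{cname}"] = p
    return paths
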