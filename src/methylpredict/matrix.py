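"""Core containers: methylation matrices and annotation bundles.

A :class:`MethylMatrix` holds a sample x probe array of methylation values
in either *beta* space (methylated fraction, values in [0, 1]) or *M* space
(log2 odds of methylation, any finite real).  The space tag is explicit so
downstream code can refuse the wrong scale instead of silently mis-modelling.

An :class:`AnnotationBundle` is the single source of truth relating probes to
gene symbols, CpG-island categories and regulatory-feature groups, plus named
gene-set collections (e.g. pathway and transcription-factor-target sets); it
drives both mask construction for the explainable network and the universes
used by the enrichment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

ISLAND_CATEGORIES = ("Island", "N_Shelf", "N_Shore", "OpenSea", "S_Shelf", "S_Shore")

REGULATORY_GROUPS = (
    "Gene_associated",
    "Gene_Associated_Cell_type_specific",
    "NonGene_Associated",
    "NonGene_Associated_Cell_type_specific",
    "Promoter_associated",
    "Promoter_associated_Cell_type_specific",
    "Unclassified",
    "Unclassified_cell_type_specific",
    "unannotated",
)


@dataclass
class MethylMatrix:
    """Sample x probe methylation matrix with an explicit value-space tag.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_probes)
    sample_ids, probe_ids : sequences of unique identifiers
    space : {"beta", "M"}
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    space: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample x probe array")
        ns, npr = self.values.shape
        if ns != len(self.sample_ids) or npr != len(self.probe_ids):
            raise ValueError("shape of values does not match id lists")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample IDs")
        if len(set(self.probe_ids)) != npr:
            raise ValueError("duplicate probe IDs")
        if self.space not in ("beta", "M"):
            raise ValueError(f"unknown space {self.space!r}; expected 'beta' or 'M'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.space == "beta" and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return a samples x probes DataFrame view."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, space: str) -> "MethylMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=list(frame.index.astype(str)),
            probe_ids=list(frame.columns.astype(str)),
            space=space,
        )

    def subset_probes(self, probes: list[str]) -> "MethylMatrix":
        """Return a new matrix restricted to ``probes`` in the given order."""
        pos = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in pos]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        idx = [pos[p] for p in probes]
        return MethylMatrix(self.values[:, idx], self.sample_ids, list(probes), self.space)

    def write_tsv(self, path) -> None:
        """Write as probes x samples TSV, probe IDs in the first column."""
        self.to_frame().T.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, space: str) -> "MethylMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame.T, space=space)


@dataclass
class AnnotationBundle:
    """Probe-level annotation plus named gene-set collections.

    ``probe_gene`` maps every probe to a (possibly empty) set of gene symbols;
    ``probe_island`` / ``probe_reggroup`` give each probe exactly one category;
    ``collections`` maps a collection name (e.g. ``"pathways"``) to a mapping
    of set name -> gene set.
    """

    probe_gene: dict[str, frozenset[str]]
    probe_island: dict[str, str]
    probe_reggroup: dict[str, str]
    collections: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probes = set(self.probe_gene)
        if set(self.probe_island) != probes or set(self.probe_reggroup) != probes:
            raise ValueError("probe_gene, probe_island, probe_reggroup must cover the same probes")
        bad = {c for c in self.probe_island.values()} - set(ISLAND_CATEGORIES)
        if bad:
            raise ValueError(f"unknown island categories: {sorted(bad)}")
        bad = {c for c in self.probe_reggroup.values()} - set(REGULATORY_GROUPS)
        if bad:
            raise ValueError(f"unknown regulatory groups: {sorted(bad)}")
        for cname, sets in self.collections.items():
            for sname, genes in sets.items():
                if not genes:
                    raise ValueError(f"empty gene set {sname!r} in collection {cname!r}")

    @property
    def probes(self) -> list[str]:
        return sorted(self.probe_gene)

    def all_genes(self) -> frozenset[str]:
        """Union of genes annotated to any probe (the ORA universe)."""
        out: set[str] = set()
        for genes in self.probe_gene.values():
            out |= genes
        return frozenset(out)

    def write_manifest(self, path) -> None:
        rows = [
            (p, ";".join(sorted(self.probe_gene[p])), self.probe_island[p], self.probe_reggroup[p])
            for p in self.probes
        ]
        pd.DataFrame(rows, columns=["probe_id", "genes", "island", "reggroup"]).to_csv(
            path, sep="\t", index=False
        )

    def write_gmt(self, collection: str, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.collections[collection]):
                genes = sorted(self.collections[collection][name])
                fh.write("\t".join([name, collection] + genes) + "\n")

    @classmethod
    def read(cls, manifest_path, gmt_paths: Mapping[str, str]) -> "AnnotationBundle":
        """Load from a probe manifest TSV and one GMT file per collection."""
        from gseapy.parser import read_gmt  # deferred: heavy import

        man = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
        probe_gene = {
            r.probe_id: frozenset(g for g in r.genes.split(";") if g) for r in man.itertuples()
        }
        collections = {
            cname: {s: frozenset(g) for s, g in read_gmt(str(path)).items()}
            for cname, path in gmt_paths.items()
        }
        return cls(
            probe_gene=probe_gene,
            probe_island=dict(zip(man.probe_id, man.island)),
            probe_reggroup=dict(zip(man.probe_id, man.reggroup)),
            collections=collections,
        )
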