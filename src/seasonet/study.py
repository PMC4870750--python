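"""Core data container for two-site, two-season expression studies.

An :class:`ExpressionStudy` bundles the three tables every downstream stage
consumes: a gene x sample abundance matrix on the linear FPKM scale, a sample
metadata table (site, season, sex, body length) and a gene annotation table
(immune / core-immune / hub flags plus an orthologue symbol used for gene-set
work).  All tables are plain :class:`pandas.DataFrame` objects and round-trip
through tab-separated text files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEASONS = ("winter", "summer")

#: canonical sample-metadata columns
SAMPLE_COLUMNS = ("site", "season", "sex", "length_mm")
#: canonical gene-annotation columns
GENE_COLUMNS = ("immune_flag", "core_flag", "hub_flag", "orthologue")


@dataclass
class ExpressionStudy:
    """Expression matrix plus sample metadata and gene annotation.

    Parameters
    ----------
    matrix:
        genes x samples abundances (FPKM scale, non-negative).  The column
        index must equal the index of ``samples``.
    samples:
        per-sample metadata with columns ``site``, ``season`` (one of
        ``winter`` / ``summer``), ``sex`` (``M`` / ``F``) and ``length_mm``.
    genes:
        per-gene annotation with boolean ``immune_flag``, ``core_flag``,
        ``hub_flag`` and a string ``orthologue`` symbol.  Indexed like
        ``matrix``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.columns.equals(self.samples.index):
            raise ValueError("matrix columns must match sample metadata index")
        if not self.matrix.index.equals(self.genes.index):
            raise ValueError("matrix rows must match gene annotation index")
        if self.matrix.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("expression abundances must be non-negative")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        bad = set(self.samples["season"]) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")

    # -- basic properties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def sites(self) -> list[str]:
        return sorted(self.samples["site"].unique())

    # -- transforms and subsetting ----------------------------------------
    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(FPKM + pseudocount) matrix, the scale used by all models."""
        return np.log2(self.matrix + pseudocount)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionStudy":
        ids = pd.Index(gene_ids)
        unknown = ids.difference(self.matrix.index)
        if len(unknown):
            raise KeyError(f"unknown genes: {list(unknown[:5])} ...")
        return ExpressionStudy(
            self.matrix.loc[ids], self.samples, self.genes.loc[ids]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        ids = pd.Index(sample_ids)
        return ExpressionStudy(
            self.matrix[ids], self.samples.loc[ids], self.genes
        )

    def site_study(self, site: str) -> "ExpressionStudy":
        """Restrict to the samples from one collection site."""
        if site not in set(self.samples["site"]):
            raise KeyError(f"site {site!r} not present")
        keep = self.samples.index[self.samples["site"] == site]
        return self.subset_samples(list(keep))

    # -- text IO -----------------------------------------------------------
    def write_tsv(self, outdir: str, prefix: str = "study") -> dict[str, str]:
        """Write matrix/metadata/annotation as TSV; returns the paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "matrix": os.path.join(outdir, f"{prefix}_matrix.tsv"),
            "samples": os.path.join(outdir, f"{prefix}_samples.tsv"),
            "genes": os.path.join(outdir, f"{prefix}_genes.tsv"),
        }
        self.matrix.to_csv(paths["matrix"], sep="\t", index_label="gene")
        self.samples.to_csv(paths["samples"], sep="\t", index_label="sample")
        self.genes.to_csv(paths["genes"], sep="\t", index_label="gene")
        return paths

    @classmethod
    def read_tsv(
        cls, matrix_path: str, samples_path: str, genes_path: str
    ) -> "ExpressionStudy":
        matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        genes = pd.read_csv(genes_path, sep="\t", index_col="gene")
        for col in ("immune_flag", "core_flag", "hub_flag"):
            if col in genes.columns:
                genes[col] = genes[col].astype(bool)
        return cls(matrix, samples, genes)


def default_gene_annotation(gene_ids: Sequence[str]) -> pd.DataFrame:
    """All-false annotation for matrices that arrive without one."""
    idx = pd.Index(gene_ids, name="gene")
    return pd.DataFrame(
        {
            "immune_flag": False,
            "core_flag": False,
            "hub_flag": False,
            "orthologue": [g.upper() for g in idx],
        },
        index=idx,
    )
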