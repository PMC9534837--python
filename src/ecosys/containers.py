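"""In-memory containers shared across the pipeline.

The central object is :class:`CountMatrix`, a sparse genes × cells UMI count
matrix with aligned per-cell metadata.  Matrices are always genes × cells in
memory regardless of on-disk orientation.  Normalized and scaled expression
wrap the same gene/cell index so downstream stages never re-align identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

TISSUES = ("CC", "PT", "MT")  # chronic cholecystitis, primary tumor, metastasis


@dataclass
class CountMatrix:
    """Sparse genes × cells UMI count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique identifiers; order matches matrix rows/columns.
    cell_meta
        One row per cell (aligned with ``cell_ids``); must include
        ``sample_id`` and ``tissue`` columns, may carry labels.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(self.cell_meta) != len(self.cell_ids):
            raise ValueError("cell_meta rows must align 1:1 with cell_ids")
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMI per cell (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_indexer(self, genes: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return np.array([lut[g] for g in genes], dtype=int)

    def subset(
        self,
        gene_mask: Optional[np.ndarray] = None,
        cell_mask: Optional[np.ndarray] = None,
    ) -> "CountMatrix":
        gm = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        cm = np.arange(self.n_cells) if cell_mask is None else np.asarray(cell_mask)
        if gm.dtype == bool:
            gm = np.flatnonzero(gm)
        if cm.dtype == bool:
            cm = np.flatnonzero(cm)
        return CountMatrix(
            counts=self.counts[gm][:, cm],
            gene_ids=self.gene_ids[gm],
            cell_ids=self.cell_ids[cm],
            cell_meta=self.cell_meta.iloc[cm],
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells × genes, AnnData convention)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``ln(1 + count / libsize * scale_factor)``."""

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    scale_factor: float = 1e4
    parent: Optional[CountMatrix] = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_indexer(self, genes: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return np.array([lut[g] for g in genes], dtype=int)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class ScaledMatrix:
    """Per-gene z-scored expression clipped at ``±clip_max``; dense genes × cells."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    clip_max: float = 10.0
    zero_variance_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def gene_indexer(self, genes: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return np.array([lut[g] for g in genes], dtype=int)


@dataclass
class GeneSignature:
    """A named, ordered gene list with optional weights and derivation provenance.

    ``provenance`` is either ``"curated"`` or a dict recording how the list was
    derived (reference gene, top_n, cell subset size, correlation values).
    """

    name: str
    genes: list
    weights: Optional[np.ndarray] = None
    provenance: object = "curated"

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)
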