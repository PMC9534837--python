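"""Readers and writers for the on-disk formats the pipeline touches.

10x-style MatrixMarket directories, BED-like gene position tables,
ligand–receptor pair TSVs, GMT gene-set collections, MAF-lite mutation tables
and clinical CSVs.  All coordinates are 0-based half-open (BED dialect)
internally.  Matrices are genes × cells in memory regardless of on-disk
orientation.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneSignature

_NONSYN_DEFAULT = ("missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site")
VARIANT_CLASSES = _NONSYN_DEFAULT + ("synonymous", "noncoding")


def _find(directory: Path, names: Sequence[str]) -> Optional[Path]:
    for name in names:
        for cand in (directory / name, directory / f"{name}.gz"):
            if cand.exists():
                return cand
    return None


def _read_tsv_column(path: Path, n_cols_min: int = 1) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if df.shape[1] < n_cols_min:
        raise ValueError(f"{path}: expected >= {n_cols_min} columns, found {df.shape[1]}")
    return df


def read_10x_mtx(directory: os.PathLike) -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx + features/genes.tsv + barcodes.tsv).

    Gzipped variants are accepted.  If a ``metadata.csv`` with a ``cell_id``
    column is present it is attached as per-cell metadata; otherwise an empty
    metadata table is created.
    """
    directory = Path(directory)
    mtx_path = _find(directory, ["matrix.mtx"])
    feat_path = _find(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find(directory, ["barcodes.tsv"])
    for p, what in ((mtx_path, "matrix.mtx"), (feat_path, "features.tsv/genes.tsv"), (bc_path, "barcodes.tsv")):
        if p is None:
            raise FileNotFoundError(f"{directory}: missing {what}(.gz)")

    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # truncated or malformed MatrixMarket payload
        raise ValueError(f"{mtx_path}: cannot parse MatrixMarket file ({exc})") from exc
    mat = sp.csr_matrix(mat)
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError(f"{mtx_path}: empty matrix ({mat.shape[0]} x {mat.shape[1]})")

    features = _read_tsv_column(feat_path, 1)
    barcodes = _read_tsv_column(bc_path, 1)
    gene_ids = features.iloc[:, 0].to_numpy(dtype=object)
    cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
    if len(gene_ids) != mat.shape[0]:
        raise ValueError(
            f"{feat_path}: {len(gene_ids)} features but matrix header declares {mat.shape[0]} rows"
        )
    if len(cell_ids) != mat.shape[1]:
        raise ValueError(
            f"{bc_path}: {len(cell_ids)} barcodes but matrix header declares {mat.shape[1]} columns"
        )
    dup = pd.Index(cell_ids).duplicated()
    if dup.any():
        offenders = pd.Index(cell_ids)[dup].unique().tolist()[:5]
        raise ValueError(f"{bc_path}: duplicate barcodes {offenders}")

    meta_path = directory / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        if "cell_id" not in meta.columns:
            raise ValueError(f"{meta_path}: metadata must carry a cell_id column")
        meta = meta.set_index("cell_id").reindex(cell_ids).reset_index(drop=True)
    else:
        meta = pd.DataFrame(index=range(len(cell_ids)))
    return CountMatrix(counts=mat, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)


def write_10x_mtx(cm: CountMatrix, directory: os.PathLike) -> None:
    """Write ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and ``metadata.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    feats = pd.DataFrame({"id": cm.gene_ids, "symbol": cm.gene_ids, "type": "Gene Expression"})
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": cm.cell_ids}).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta = cm.cell_meta.reset_index()
    meta.to_csv(directory / "metadata.csv", index=False)


_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)}
_CHROM_ORDER.update({"chrX": 23, "chrY": 24, "chrM": 25, "chrMT": 25})


def chromosome_sort_key(chrom: str) -> Tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, 100), chrom)


def read_gene_positions(path: os.PathLike, gene_universe: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a BED-like gene position table (chrom, start, end, gene_id; 0-based half-open).

    Output is sorted by (chromosome order, start).  If ``gene_universe`` is
    given, a boolean ``known`` column flags genes present in it; unknown genes
    are retained.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED-like input needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["chromosome", "start", "end", "gene_id"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:5]
        raise ValueError(f"{path}: start >= end on line(s) {rows}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene_id(s) {sorted(df.loc[dup, 'gene_id'].unique())[:10]}")
    df["_key"] = df["chromosome"].map(lambda c: chromosome_sort_key(c)[0])
    df = df.sort_values(["_key", "chromosome", "start"], kind="mergesort").drop(columns="_key")
    df = df[["gene_id", "chromosome", "start", "end"]].reset_index(drop=True)
    if gene_universe is not None:
        known = set(gene_universe)
        df["known"] = df["gene_id"].isin(known)
    return df


def write_gene_positions(positions: pd.DataFrame, path: os.PathLike) -> None:
    """Write a gene position table in BED column order (chrom, start, end, gene_id)."""
    positions[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_lr_pairs(path: os.PathLike) -> List[Tuple[str, str]]:
    """Read a two-column ligand/receptor TSV (header optional); de-duplicated, order kept."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ligand-receptor table needs 2 columns")
    first = [str(x).lower() for x in df.iloc[0, :2]]
    if first == ["ligand", "receptor"]:
        df = df.iloc[1:]
    pairs, seen = [], set()
    for lig, rec in df.iloc[:, :2].itertuples(index=False):
        if pd.isna(lig) or pd.isna(rec):
            raise ValueError(f"{path}: missing ligand or receptor entry")
        key = (lig, rec)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


def write_lr_pairs(pairs: Sequence[Tuple[str, str]], path: os.PathLike) -> None:
    pd.DataFrame(pairs, columns=["ligand", "receptor"]).to_csv(path, sep="\t", index=False)


def read_gmt(path: os.PathLike) -> Dict[str, GeneSignature]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets: Dict[str, GeneSignature] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSignature(name=name, genes=genes)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(signatures: Sequence[GeneSignature], path: os.PathLike) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")


def read_mutations(path: os.PathLike) -> pd.DataFrame:
    """Read a MAF-lite TSV (sample_id, gene_id, variant_class) with a closed vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "gene_id", "variant_class"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: MAF-lite needs columns {sorted(needed)}")
    unknown = sorted(set(df["variant_class"]) - set(VARIANT_CLASSES))
    if unknown:
        raise ValueError(f"{path}: unknown variant_class value(s) {unknown}")
    return df


def write_mutations(mutations: pd.DataFrame, path: os.PathLike) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def read_clinical(path: os.PathLike) -> pd.DataFrame:
    """Read a clinical CSV (sample_id, time, event, density_score, intensity_score)."""
    df = pd.read_csv(path)
    needed = {"sample_id", "time", "event"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(needed)}")
    if (df["time"] < 0).any() or not np.isfinite(df["time"]).all():
        raise ValueError(f"{path}: survival times must be finite and >= 0")
    for col in ("density_score", "intensity_score"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 1) | (vals > 4)).any():
                raise ValueError(f"{path}: {col} must lie in 1..4")
    df["event"] = df["event"].astype(bool)
    return df


def write_clinical(clinical: pd.DataFrame, path: os.PathLike) -> None:
    clinical.to_csv(path, index=False)
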