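"""Gene-signature scoring and correlation-based signature derivation.

Module scores follow the bin-matched control-gene scheme: genes are binned by
average expression, each signature gene contributes the difference between its
expression and a pool of expression-matched control genes, so the score is
centered at zero for an uninformative gene set.  Signatures can be derived by
ranking genome-wide Pearson correlation against an anchor gene (e.g. GZMK for
cytotoxicity, HAVCR2 for exhaustion, IL2RA for Treg programs) on scaled
expression over a cell subset.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GeneSignature, NormalizedMatrix, ScaledMatrix
from .preprocess import bh_adjust, rank_sum_test


def module_score(
    norm: NormalizedMatrix,
    signature: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched control module score per cell.

    Genes are cut into ``n_bins`` equal-frequency bins by mean expression over
    the scored cells; for every signature gene, ``n_ctrl`` control genes are
    drawn from its bin (with replacement when the bin is smaller than
    ``n_ctrl``); the score is the mean expression of signature genes minus the
    mean over the pooled control draws.  Deterministic given ``seed``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_ctrl < 1:
        raise ValueError("n_ctrl must be >= 1")
    universe = {g: i for i, g in enumerate(map(str, norm.gene_ids))}
    sig_idx = np.array([universe[g] for g in signature.genes if g in universe], dtype=int)
    if sig_idx.size == 0:
        raise ValueError(f"signature {signature.name!r} has no genes in the matrix")

    gene_mean = np.asarray(norm.values.mean(axis=1)).ravel()
    order = np.lexsort((np.asarray(norm.gene_ids, dtype=object), gene_mean))
    bins = np.empty(norm.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b

    rng = np.random.default_rng(seed)
    weights = np.zeros(norm.n_genes)
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        replace = len(pool) < n_ctrl
        draw = rng.choice(pool, size=n_ctrl, replace=replace)
        np.add.at(weights, draw, 1.0)

    sig_mean = np.asarray(norm.values[sig_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(norm.values.T @ weights).ravel() / weights.sum()
    return sig_mean - ctrl_mean


def derive_signature(
    scaled: ScaledMatrix,
    reference_gene: str,
    cell_subset: Optional[Sequence[str]] = None,
    top_n: int = 30,
    name: Optional[str] = None,
    include_reference: bool = False,
) -> GeneSignature:
    """Anchor-gene signature: the ``top_n`` genes most correlated with the anchor.

    Pearson correlation between ``reference_gene`` and every other gene over
    ``cell_subset`` of the scaled matrix, sorted descending (ties by gene_id).
    The anchor itself is excluded unless ``include_reference`` is set.
    """
    gene_ids = np.asarray(scaled.gene_ids, dtype=object)
    lut = {g: i for i, g in enumerate(map(str, gene_ids))}
    if reference_gene not in lut:
        raise KeyError(f"reference gene {reference_gene!r} absent from matrix")
    if cell_subset is None:
        cols = np.arange(scaled.values.shape[1])
    else:
        clut = {c: i for i, c in enumerate(map(str, scaled.cell_ids))}
        cols = np.array([clut[c] for c in cell_subset], dtype=int)
    if len(cols) < 10:
        raise ValueError("cell_subset must contain >= 10 cells")

    X = scaled.values[:, cols]
    ref = X[lut[reference_gene]]
    if ref.std() == 0:
        raise ValueError(f"reference gene {reference_gene!r} is constant in the subset")

    Xc = X - X.mean(axis=1, keepdims=True)
    refc = ref - ref.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (refc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ refc) / denom
    r[~np.isfinite(r)] = -np.inf  # constant genes sort last

    candidates = np.arange(len(gene_ids))
    if not include_reference:
        candidates = candidates[candidates != lut[reference_gene]]
    order = sorted(candidates, key=lambda i: (-r[i], str(gene_ids[i])))
    top = order[:top_n]
    return GeneSignature(
        name=name or f"{reference_gene}_top{top_n}",
        genes=[str(gene_ids[i]) for i in top],
        weights=np.array([r[i] for i in top]),
        provenance={
            "derived": True,
            "reference_gene": reference_gene,
            "top_n": top_n,
            "n_cells": int(len(cols)),
        },
    )


def score_groups(
    scores: np.ndarray,
    grouping: Sequence[str],
    min_cells: int = 3,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group score summaries and pairwise Wilcoxon rank-sum comparisons.

    Groups with fewer than ``min_cells`` cells are excluded with a warning;
    p-values are BH-adjusted across the pairwise comparisons.
    """
    scores = np.asarray(scores, dtype=float)
    grouping = np.asarray(grouping, dtype=object)
    if len(scores) != len(grouping):
        raise ValueError("scores and grouping must align per cell")
    groups: Dict[str, np.ndarray] = {}
    for g in pd.unique(grouping):
        vals = scores[grouping == g]
        if len(vals) < min_cells:
            warnings.warn(f"group {g!r} has < {min_cells} cells; excluded")
            continue
        groups[str(g)] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with enough cells")

    summary = pd.DataFrame(
        {
            "group": list(groups),
            "n": [len(v) for v in groups.values()],
            "median": [float(np.median(v)) for v in groups.values()],
            "iqr_low": [float(np.percentile(v, 25)) for v in groups.values()],
            "iqr_high": [float(np.percentile(v, 75)) for v in groups.values()],
        }
    )
    names = sorted(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = rank_sum_test(groups[names[i]], groups[names[j]])
            rows.append((names[i], names[j], p))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value"])
    pairwise["adj_p"] = bh_adjust(pairwise["p_value"].to_numpy())
    return summary, pairwise
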