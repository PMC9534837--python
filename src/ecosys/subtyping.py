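"""Single-sample gene-set enrichment, subtype discovery, and bulk projection.

Malignant-epithelial subtypes are discovered by scoring entities (cells,
pseudobulk clusters, or bulk samples) against a gene-set collection with a
rank-weighted running-sum single-sample enrichment statistic, hierarchically
clustering the (per-set z-scored) enrichment matrix with Ward linkage, and
cutting at k=3.  Characteristic top-N DEG signatures of each subtype project
the classification onto external bulk cohorts via log2(CPM+1) expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.optimize import linear_sum_assignment

from .containers import GeneSignature

SUBTYPE_LABELS = ("I", "II", "III")


@dataclass
class EnrichmentMatrix:
    """Entities × gene-sets enrichment scores (``zscored`` marks per-set scaling)."""

    scores: pd.DataFrame
    alpha: float
    method: str = "rank_weighted_running_sum"
    zscored: bool = False

    def zscore(self) -> "EnrichmentMatrix":
        """Per-set z-scoring across entities (constant sets left at 0)."""
        Z = self.scores.copy()
        sd = Z.std(axis=0, ddof=1).replace(0, np.nan)
        Z = (Z - Z.mean(axis=0)) / sd
        Z = Z.fillna(0.0)
        return EnrichmentMatrix(scores=Z, alpha=self.alpha, method=self.method, zscored=True)


@dataclass
class SubtypeAssignment:
    """Entity → subtype label with the linkage used and dendrogram heights."""

    labels: pd.Series
    linkage_method: str
    heights: np.ndarray
    k: int
    linkage_matrix: Optional[np.ndarray] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("subtype").rename_axis("entity").reset_index()

    def to_newick(self) -> str:
        """Dendrogram in Newick format (leaf names are entity ids)."""
        if self.linkage_matrix is None:
            raise ValueError("no linkage matrix recorded")
        tree = sch.to_tree(self.linkage_matrix)
        names = list(self.labels.index)

        def rec(node):
            if node.is_leaf():
                return str(names[node.id])
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def ss_enrichment(
    expression: Sequence[float],
    gene_ids: Sequence[str],
    gene_set: Sequence[str],
    alpha: float = 0.25,
    normalize: bool = False,
    min_set_genes: int = 2,
) -> float:
    """Rank-weighted running-sum enrichment of ``gene_set`` in one expression vector.

    Genes are ranked by expression (ascending ranks, ties averaged; the top
    gene has rank N) and walked in decreasing-rank order.  At each step the
    score accumulates ``P_hit - P_miss`` where P_hit is the cumulative
    ``rank^alpha``-weighted fraction of set genes encountered and P_miss the
    cumulative fraction of non-set genes.  ``normalize`` divides by
    ``N - |set|``.  A set covering the whole universe scores 0 by convention.
    """
    expr = np.asarray(expression, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    if len(expr) != len(gene_ids):
        raise ValueError("expression and gene_ids must align")
    in_set = np.isin(gene_ids, np.asarray(list(gene_set), dtype=object))
    n_hit = int(in_set.sum())
    if n_hit < min_set_genes:
        raise ValueError(
            f"gene set has {n_hit} gene(s) in the universe; need >= {min_set_genes}"
        )
    if n_hit == 0:
        raise ValueError("gene set has no genes in the universe")
    N = len(expr)
    if n_hit == N:
        return 0.0

    ranks = scipy.stats.rankdata(expr)  # ties -> average rank
    order = np.lexsort((np.arange(N), -ranks))  # walk from top rank down, ties by index
    hit = in_set[order]
    w = np.where(hit, ranks[order] ** alpha, 0.0)
    p_hit = np.cumsum(w) / w.sum()
    p_miss = np.cumsum(~hit) / (N - n_hit)
    score = float(np.sum(p_hit - p_miss))
    if normalize:
        score /= N - n_hit
    return score


def enrichment_matrix(
    expression: pd.DataFrame,
    collection: Dict[str, GeneSignature],
    alpha: float = 0.25,
    skip_bad_sets: bool = False,
) -> EnrichmentMatrix:
    """ss_enrichment for every entity (column) × gene set.

    ``expression`` is genes × entities with gene ids as index.  Per-set errors
    propagate unless ``skip_bad_sets`` drops the offending set with a warning.
    """
    if len(collection) < 2 and not skip_bad_sets:
        if len(collection) == 0:
            raise ValueError("empty gene-set collection")
    gene_ids = expression.index.to_numpy(dtype=object)
    usable: Dict[str, np.ndarray] = {}
    for name, sig in collection.items():
        mask = np.isin(gene_ids, np.asarray(sig.genes, dtype=object))
        if mask.sum() < 2:
            if skip_bad_sets:
                warnings.warn(f"gene set {name!r} has < 2 genes in the universe; skipped")
                continue
            raise ValueError(f"gene set {name!r} has < 2 genes in the universe")
        usable[name] = mask
    if not usable:
        raise ValueError("no usable gene sets")

    N = len(gene_ids)
    entities = expression.columns
    out = np.empty((len(entities), len(usable)))
    X = expression.to_numpy(dtype=float)
    for j, ent in enumerate(entities):
        ranks = scipy.stats.rankdata(X[:, j])
        order = np.lexsort((np.arange(N), -ranks))
        ranked = ranks[order]
        for s, (name, mask) in enumerate(usable.items()):
            hit = mask[order]
            n_hit = int(mask.sum())
            if n_hit == N:
                out[j, s] = 0.0
                continue
            w = np.where(hit, ranked**alpha, 0.0)
            p_hit = np.cumsum(w) / w.sum()
            p_miss = np.cumsum(~hit) / (N - n_hit)
            out[j, s] = np.sum(p_hit - p_miss)
    scores = pd.DataFrame(out, index=entities, columns=list(usable))
    return EnrichmentMatrix(scores=scores, alpha=alpha)


def assign_subtypes(
    matrix: EnrichmentMatrix,
    k: int = 3,
    linkage: str = "ward",
) -> SubtypeAssignment:
    """Hierarchical clustering of enrichment rows cut at ``k`` groups.

    Rows are per-set z-scored unless already scaled; Euclidean Ward linkage by
    default.  Group labels I, II, III, ... are assigned by descending group
    size, ties by first entity id.
    """
    n = matrix.scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} entities")
    Z = matrix if matrix.zscored else matrix.zscore()
    X = Z.scores.to_numpy(dtype=float)
    if n > 1 and np.allclose(X, X[0][None, :]):
        warnings.warn("identical enrichment rows; split is arbitrary but deterministic")
    if k == 1:
        groups = np.ones(n, dtype=int)
        link = sch.linkage(X, method=linkage) if n > 1 else None
    else:
        link = sch.linkage(X, method=linkage)
        groups = sch.fcluster(link, t=k, criterion="maxclust")

    entities = list(matrix.scores.index)
    sizes = pd.Series(groups).value_counts()
    first_pos = {g: int(np.argmax(groups == g)) for g in sizes.index}
    ordered = sorted(sizes.index, key=lambda g: (-sizes[g], first_pos[g]))
    name_of = {
        g: (SUBTYPE_LABELS[i] if i < len(SUBTYPE_LABELS) else f"G{i + 1}")
        for i, g in enumerate(ordered)
    }
    labels = pd.Series([name_of[g] for g in groups], index=entities, name="subtype")
    heights = link[:, 2] if link is not None else np.array([])
    return SubtypeAssignment(
        labels=labels, linkage_method=linkage, heights=heights, k=int(len(ordered)),
        linkage_matrix=link,
    )


def top_signature(deg: pd.DataFrame, subtype_label: str, n: int = 15) -> GeneSignature:
    """Characteristic signature: top ``n`` DEGs of a subtype.

    Ranking key: ascending adjusted P, then descending log fold change, then
    gene_id.  Returns all rows with a warning if fewer than ``n`` exist.
    """
    rows = deg[deg["group"] == subtype_label]
    if rows.empty:
        raise ValueError(f"DEG table has no rows for subtype {subtype_label!r}")
    rows = rows.sort_values(
        ["adj_p", "log_fc", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    if len(rows) < n:
        warnings.warn(f"subtype {subtype_label!r} has only {len(rows)} DEGs (< {n})")
    top = rows.head(n)
    return GeneSignature(
        name=f"subtype_{subtype_label}_top{n}",
        genes=top["gene_id"].tolist(),
        weights=top["log_fc"].to_numpy(),
        provenance={"derived": True, "subtype": subtype_label, "top_n": n},
    )


def log2_cpm(bulk_counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) transform of a genes × samples count table."""
    lib = bulk_counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("bulk sample(s) with zero total counts")
    return np.log2(bulk_counts / lib * 1e6 + 1.0)


def project_bulk(
    bulk_counts: pd.DataFrame,
    signatures: Sequence[GeneSignature],
    alpha: float = 0.25,
    k: int = 3,
) -> Tuple[SubtypeAssignment, pd.DataFrame]:
    """Project subtype signatures onto a bulk cohort.

    log2(CPM+1) transform, per-signature running-sum enrichment, hierarchical
    clustering at ``k``; each cluster is then named after the signature with
    the highest mean z-scored enrichment (one-to-one, Hungarian matching).
    Also returns a per-sample diagnostic table with the argmax winning
    signature.
    """
    if bulk_counts.shape[1] < 3:
        raise ValueError("need >= 3 bulk samples")
    universe = set(map(str, bulk_counts.index))
    for sig in signatures:
        present = [g for g in sig.genes if g in universe]
        if len(present) < 2:
            raise ValueError(f"signature {sig.name!r} has < 2 genes in the bulk universe")
    expr = log2_cpm(bulk_counts)
    mat = enrichment_matrix(expr, {s.name: s for s in signatures}, alpha=alpha)
    Z = mat.zscore()
    assignment = assign_subtypes(Z, k=k)

    # rename hierarchical groups by their dominant signature (one-to-one)
    groups = assignment.labels
    uniq = list(pd.unique(groups))
    sets = list(Z.scores.columns)
    gain = np.array(
        [[Z.scores.loc[groups == g, s].mean() for s in sets] for g in uniq]
    )
    gi, si = linear_sum_assignment(-gain)
    mapping = {uniq[a]: sets[b] for a, b in zip(gi, si)}
    named = groups.map(lambda g: mapping.get(g, g))
    assignment = SubtypeAssignment(
        labels=named,
        linkage_method=assignment.linkage_method,
        heights=assignment.heights,
        k=assignment.k,
        linkage_matrix=assignment.linkage_matrix,
    )
    diagnostics = pd.DataFrame(
        {
            "winning_signature": Z.scores.idxmax(axis=1),
            "assigned": named,
        }
    )
    return assignment, diagnostics
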