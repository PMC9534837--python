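"""Expression-inferred CNV profiles and malignant-cell classification.

Large-scale chromosomal dosage changes are inferred from log-normalized
expression by the moving-average scheme: per-gene centering against a diploid
reference (endothelial cells), clipping, a 101-gene window average within each
chromosome, per-cell median centering, and subtraction of the smoothed
reference-average profile.  Malignancy is then called by K-means clustering of
the profiles with endothelial spike-ins: clusters that co-cluster with the
spike-ins *and* lack CNV (low burden) are non-malignant epithelium; everything
else interrogated is malignant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import euclidean_distances

from .containers import NormalizedMatrix
from .io import chromosome_sort_key


@dataclass
class CNVProfile:
    """Cells × ordered-gene-window matrix of smoothed relative-expression scores."""

    scores: np.ndarray
    cell_ids: np.ndarray
    gene_order: pd.DataFrame  # gene_id, chromosome, start (positions used, in order)
    window_size: int
    reference_cells: Set[str]
    spikein_cells: Set[str]
    clip_bound: float

    def cell_index(self, ids: Iterable[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lut[c] for c in ids], dtype=int)

    @property
    def interrogated_mask(self) -> np.ndarray:
        return np.array([c not in self.reference_cells for c in self.cell_ids])


@dataclass
class MalignancyCall:
    """Per-cell malignancy labels with cluster ids and CNV burden."""

    labels: pd.Series  # cell_id -> {malignant, non_malignant, reference_spikein}
    cluster_id: pd.Series
    burden: pd.Series
    k_used: int
    burden_threshold: float
    nonmalignant_clusters: Set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "cluster_id": self.cluster_id, "burden": self.burden}
        )


def _moving_average_by_chrom(values: np.ndarray, chrom_codes: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the gene axis, restarting at each chromosome.

    The window shrinks symmetrically near chromosome edges, so a constant row
    is preserved exactly.  ``values`` is cells × genes.
    """
    if window == 1:
        return values.copy()
    half = (window - 1) // 2
    out = np.empty_like(values)
    for code in np.unique(chrom_codes):
        cols = np.flatnonzero(chrom_codes == code)
        block = values[:, cols]
        L = len(cols)
        cum = np.cumsum(block, axis=1)
        cum = np.concatenate([np.zeros((block.shape[0], 1)), cum], axis=1)
        idx = np.arange(L)
        h = np.minimum(half, np.minimum(idx, L - 1 - idx))
        lo, hi = idx - h, idx + h + 1
        out[:, cols] = (cum[:, hi] - cum[:, lo]) / (hi - lo)
    return out


def build_cnv_profile(
    norm: NormalizedMatrix,
    positions: pd.DataFrame,
    reference_cells: Sequence[str],
    interrogated_cells: Sequence[str],
    spikein_cells: Sequence[str] = (),
    window: int = 101,
    clip: float = 3.0,
    min_genes_per_chrom: int = 3,
) -> CNVProfile:
    """Infer smoothed relative-expression CNV scores for reference + interrogated cells.

    Pipeline per cell: restrict to positioned genes, order by (chromosome,
    start), subtract the per-gene reference mean, clip to ``[-clip, clip]``,
    window-average within each chromosome, subtract the per-cell median, and
    subtract the smoothed reference-average profile (so the reference mean
    profile is exactly zero).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive count")
    reference_cells = list(reference_cells)
    interrogated_cells = list(interrogated_cells)
    if not reference_cells:
        raise ValueError("empty reference cell set")
    spike = set(spikein_cells)
    overlap = set(reference_cells) & set(interrogated_cells)
    if overlap - spike:
        raise ValueError(
            "reference and interrogated sets overlap beyond declared spike-ins: "
            f"{sorted(overlap - spike)[:5]}"
        )

    pos = positions.copy()
    pos = pos[pos["gene_id"].isin(set(map(str, norm.gene_ids)))]
    chrom_counts = pos.groupby("chromosome")["gene_id"].count()
    small = chrom_counts[chrom_counts < min_genes_per_chrom].index.tolist()
    if small:
        warnings.warn(f"excluding chromosome(s) with < {min_genes_per_chrom} genes: {small}")
        pos = pos[~pos["chromosome"].isin(small)]
    if len(pos) < window and len(pos) < 1:
        raise ValueError("no positioned genes shared with the matrix")
    pos = pos.assign(_key=pos["chromosome"].map(lambda c: chromosome_sort_key(c)[0]))
    pos = pos.sort_values(["_key", "chromosome", "start"], kind="mergesort").drop(columns="_key")
    if not any(c >= window for c in chrom_counts):
        warnings.warn("no chromosome holds a full smoothing window; windows shrink everywhere")

    all_cells = list(dict.fromkeys(list(interrogated_cells) + reference_cells))
    cell_lut = {c: i for i, c in enumerate(norm.cell_ids)}
    missing = [c for c in all_cells if c not in cell_lut]
    if missing:
        raise KeyError(f"cells absent from matrix: {missing[:5]}")
    cell_idx = np.array([cell_lut[c] for c in all_cells])
    gene_idx = norm.gene_indexer(pos["gene_id"].tolist())

    X = np.asarray(norm.values[gene_idx][:, cell_idx].todense(), dtype=float).T  # cells x genes
    ref_rows = np.array([i for i, c in enumerate(all_cells) if c in set(reference_cells)])

    X -= X[ref_rows].mean(axis=0, keepdims=True)
    np.clip(X, -clip, clip, out=X)
    chrom_codes = pd.factorize(pos["chromosome"])[0]
    X = _moving_average_by_chrom(X, chrom_codes, window)
    X -= np.median(X, axis=1, keepdims=True)
    X -= X[ref_rows].mean(axis=0, keepdims=True)

    return CNVProfile(
        scores=X,
        cell_ids=np.array(all_cells, dtype=object),
        gene_order=pos[["gene_id", "chromosome", "start"]].reset_index(drop=True),
        window_size=window,
        reference_cells=set(reference_cells),
        spikein_cells=spike,
        clip_bound=clip,
    )


def cnv_burden(profile: CNVProfile) -> pd.Series:
    """Per-cell CNV burden: mean of squared scores across gene windows."""
    return pd.Series(
        (profile.scores**2).mean(axis=1),
        index=pd.Index(profile.cell_ids, name="cell_id"),
        name="burden",
    )


def cluster_cnv(
    profile: CNVProfile,
    k_candidates: Sequence[int] = tuple(range(2, 11)),
    seed: int = 0,
    n_init: int = 10,
) -> Tuple[pd.Series, int]:
    """K-means over interrogated cells' CNV profiles; k by max mean silhouette.

    Ties in silhouette break to the smallest k.  Degenerate all-identical
    profiles collapse to a single cluster with a warning.
    """
    mask = profile.interrogated_mask
    X = profile.scores[mask]
    cells = profile.cell_ids[mask]
    if len(X) < max(k_candidates):
        raise ValueError(f"need >= {max(k_candidates)} interrogated cells, have {len(X)}")
    if np.allclose(X, X[0][None, :]):
        warnings.warn("all CNV profiles identical; returning a single cluster")
        return pd.Series(0, index=pd.Index(cells, name="cell_id"), name="cluster_id"), 1

    D = euclidean_distances(X)
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in sorted(k_candidates):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        sil = silhouette_score(D, lab, metric="precomputed")
        if sil > best_sil + 1e-12:
            best_k, best_sil, best_labels = k, sil, lab
    if best_labels is None:
        warnings.warn("silhouette selection failed; returning a single cluster")
        return pd.Series(0, index=pd.Index(cells, name="cell_id"), name="cluster_id"), 1
    return (
        pd.Series(best_labels, index=pd.Index(cells, name="cell_id"), name="cluster_id"),
        int(best_k),
    )


def classify_malignancy(
    clusters: pd.Series,
    profile: CNVProfile,
    burden_quantile: float = 0.99,
    spikein_major_frac: float = 0.5,
    cells_per_spikein: int = 50,
) -> MalignancyCall:
    """Call malignant vs non-malignant cells from CNV clusters and spike-ins.

    The burden threshold is the ``burden_quantile`` quantile of reference-cell
    burdens.  A cluster is non-malignant iff it holds a substantial share of
    the spike-ins (>= ``spikein_major_frac`` of all spike-ins, or at least one
    spike-in per ``cells_per_spikein`` member cells) *and* its median burden
    is at or below the threshold.  All other interrogated cells are malignant.
    Spike-in cells themselves are labeled ``reference_spikein``.
    """
    if not profile.spikein_cells:
        raise ValueError("no spike-in cells declared; the reference design requires them")
    burdens = cnv_burden(profile)
    ref_ids = [c for c in profile.cell_ids if c in profile.reference_cells]
    threshold = float(burdens.loc[ref_ids].quantile(burden_quantile))

    spike_in_clusters = clusters.index.isin(profile.spikein_cells)
    if not spike_in_clusters.any():
        raise ValueError("spike-in cells were not assigned to any cluster")
    n_spike_total = int(spike_in_clusters.sum())

    nonmalig: Set[int] = set()
    for cid, members in clusters.groupby(clusters).groups.items():
        n_spike = sum(1 for c in members if c in profile.spikein_cells)
        big_share = n_spike / n_spike_total >= spikein_major_frac
        dense_enough = n_spike >= max(1, len(members) // cells_per_spikein) and n_spike > 0
        low_burden = float(burdens.loc[list(members)].median()) <= threshold
        if (big_share or dense_enough) and low_burden:
            nonmalig.add(cid)

    labels = {}
    for cell, cid in clusters.items():
        if cell in profile.spikein_cells:
            labels[cell] = "reference_spikein"
        elif cid in nonmalig:
            labels[cell] = "non_malignant"
        else:
            labels[cell] = "malignant"
    lab = pd.Series(labels, name="label").reindex(clusters.index)
    lab.index.name = "cell_id"
    return MalignancyCall(
        labels=lab,
        cluster_id=clusters,
        burden=burdens.loc[clusters.index],
        k_used=int(clusters.nunique()),
        burden_threshold=threshold,
        nonmalignant_clusters=nonmalig,
    )


def select_reference_spikeins(
    cell_ids: Sequence[str],
    cell_types: Sequence[str],
    sample_ids: Sequence[str],
    reference_type: str = "Endothelial",
    n_reference_per_sample: int = 100,
    n_spikein_per_sample: int = 10,
    seed: int = 0,
) -> Tuple[list, list]:
    """Sample per-sample endothelial reference and spike-in cells.

    Emulates the reference design: a handful of known-diploid cells from every
    sample join the interrogated set as spike-ins, while up to
    ``n_reference_per_sample`` others per sample form the control.
    """
    rng = np.random.default_rng(seed)
    cell_ids = np.asarray(cell_ids, dtype=object)
    cell_types = np.asarray(cell_types, dtype=object)
    sample_ids = np.asarray(sample_ids, dtype=object)
    reference, spikeins = [], []
    for s in pd.unique(sample_ids):
        pool = cell_ids[(sample_ids == s) & (cell_types == reference_type)]
        if len(pool) == 0:
            warnings.warn(f"sample {s!r} has no {reference_type!r} cells for the reference")
            continue
        pool = pool[rng.permutation(len(pool))]
        n_spike = min(n_spikein_per_sample, max(0, len(pool) - 1))
        spikeins.extend(pool[:n_spike])
        reference.extend(pool[n_spike:n_spike + n_reference_per_sample])
    if not reference:
        raise ValueError("no reference cells could be selected")
    return reference, spikeins


def call_malignancy_pipeline(
    norm: NormalizedMatrix,
    positions: pd.DataFrame,
    cell_types: Sequence[str],
    epithelial_label: str = "Epithelial",
    reference_type: str = "Endothelial",
    window: int = 101,
    clip: float = 3.0,
    k_candidates: Sequence[int] = tuple(range(2, 11)),
    burden_quantile: float = 0.99,
    seed: int = 0,
) -> Tuple[MalignancyCall, CNVProfile]:
    """End-to-end malignancy calling: reference design, profile, K-means, rule."""
    cell_types = np.asarray(cell_types, dtype=object)
    sample_ids = norm.cell_meta["sample_id"].to_numpy()
    reference, spikeins = select_reference_spikeins(
        norm.cell_ids, cell_types, sample_ids, reference_type=reference_type, seed=seed
    )
    epithelial = [c for c, t in zip(norm.cell_ids, cell_types) if t == epithelial_label]
    interrogated = epithelial + list(spikeins)
    profile = build_cnv_profile(
        norm,
        positions,
        reference_cells=reference,
        interrogated_cells=interrogated,
        spikein_cells=spikeins,
        window=window,
        clip=clip,
    )
    clusters, _ = cluster_cnv(profile, k_candidates=k_candidates, seed=seed)
    call = classify_malignancy(clusters, profile, burden_quantile=burden_quantile)
    return call, profile
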