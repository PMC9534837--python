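"""QC filtering, normalization, HVG selection, scaling, annotation, DEG testing.

Thresholds default to the conventional single-cell values this pipeline is
calibrated around: cells kept when > 200 genes are detected and the
mitochondrial UMI fraction is <= 20%; genes kept when detected in > 0.1% of
cells; markers filtered at log fold change >= 0.25 and BH-adjusted P <= 0.01.

Boundary conventions: a cell with exactly 200 detected genes is removed (keep
requires strictly more); a mitochondrial fraction of exactly 0.20 is retained
(removal requires strictly more).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, GeneSignature, NormalizedMatrix, ScaledMatrix

MITO_PREFIX = "MT-"


def filter_qc(
    counts: CountMatrix,
    min_genes: int = 200,
    max_mito_frac: float = 0.20,
    min_gene_prevalence: float = 0.001,
    mito_prefix: str = MITO_PREFIX,
) -> Tuple[CountMatrix, Dict[str, int]]:
    """Remove low-quality cells and near-absent genes.

    Cells are kept iff (detected genes > ``min_genes``) and (mitochondrial UMI
    fraction <= ``max_mito_frac``).  Genes are kept iff detected in strictly
    more than ``min_gene_prevalence`` of the retained cells.  Returns the
    filtered matrix and a filter report.
    """
    mat = counts.counts.tocsc()
    detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    lib = np.asarray(mat.sum(axis=0)).ravel()
    is_mito = np.array([str(g).startswith(mito_prefix) for g in counts.gene_ids])
    mito_umi = np.asarray(mat[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(lib, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, mito_umi / np.maximum(lib, 1), 0.0)

    cell_keep = (detected > min_genes) & (mito_frac <= max_mito_frac)
    if not cell_keep.any():
        raise ValueError(
            "QC removed every cell; loosen min_genes/max_mito_frac "
            f"(min detected={detected.min()}, max mito fraction={mito_frac.max():.3f})"
        )

    sub = counts.counts[:, np.flatnonzero(cell_keep)]
    gene_prev = np.asarray((sub > 0).sum(axis=1)).ravel() / sub.shape[1]
    gene_keep = gene_prev > min_gene_prevalence

    out = counts.subset(gene_mask=gene_keep, cell_mask=cell_keep)
    report = {
        "n_cells_in": counts.n_cells,
        "n_cells_kept": int(cell_keep.sum()),
        "n_cells_removed_low_genes": int((detected <= min_genes).sum()),
        "n_cells_removed_high_mito": int(((mito_frac > max_mito_frac) & (detected > min_genes)).sum()),
        "n_genes_in": counts.n_genes,
        "n_genes_kept": int(gene_keep.sum()),
    }
    return out, report


def normalize_log(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Library-size normalization: ``value = ln(1 + count / libsize * scale_factor)``."""
    lib = counts.library_sizes().astype(float)
    if (lib == 0).any():
        bad = counts.cell_ids[lib == 0][:5]
        raise ValueError(f"zero-count cell(s) {list(bad)}; run filter_qc first")
    mat = counts.counts.tocsc().astype(float)
    mat = mat @ sp.diags(scale_factor / lib)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        values=mat.tocsr(),
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
        cell_meta=counts.cell_meta,
        scale_factor=scale_factor,
        parent=counts,
    )


def select_hvg(norm: NormalizedMatrix, n_top: int = 2000) -> list:
    """Rank genes by mean–variance-trend residual and return the top ``n_top``.

    The per-gene log variance of log-normalized expression is regressed on log
    mean with lowess; genes are ordered by descending residual (standardized
    variance), ties broken by gene_id.  Constant genes rank last.
    """
    if n_top > norm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {norm.n_genes}")
    X = norm.values
    n = norm.n_cells
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * n / max(n - 1, 1)

    expressed = var > 1e-10  # numerically constant genes never enter the trend fit
    resid = np.full(norm.n_genes, -np.inf)
    if expressed.sum() >= 2:
        lx = np.log10(mean[expressed] + 1e-12)
        ly = np.log10(var[expressed])
        fit = lowess(ly, lx, frac=0.3, return_sorted=False)
        resid[expressed] = ly - fit
    order = sorted(
        range(norm.n_genes), key=lambda i: (-resid[i], str(norm.gene_ids[i]))
    )
    return [str(norm.gene_ids[i]) for i in order[:n_top]]


def scale_expression(norm: NormalizedMatrix, clip_max: float = 10.0) -> ScaledMatrix:
    """Per-gene z-score clipped at ``±clip_max``; zero-variance genes set to 0 and flagged."""
    X = np.asarray(norm.values.todense(), dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero_var = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd[zero_var.reshape(-1, 1)] = 1.0
    Z = (X - mean) / sd
    Z[zero_var, :] = 0.0
    np.clip(Z, -clip_max, clip_max, out=Z)
    return ScaledMatrix(
        values=Z,
        gene_ids=norm.gene_ids,
        cell_ids=norm.cell_ids,
        clip_max=clip_max,
        zero_variance_genes=norm.gene_ids[zero_var],
    )


def annotate_cells(
    norm: NormalizedMatrix,
    marker_sets: Dict[str, GeneSignature],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Label each cell by the argmax of marker-set module scores.

    Returns a DataFrame indexed by cell_id with ``label``, ``score``,
    ``runner_up``, ``margin`` and a ``tie`` flag.  Score ties break to the
    lexicographically smallest label.
    """
    from .signatures import module_score  # local import avoids a cycle

    if not marker_sets:
        raise ValueError("no marker sets supplied")
    universe = set(map(str, norm.gene_ids))
    names = sorted(marker_sets)
    scores = np.empty((len(names), norm.n_cells))
    for i, name in enumerate(names):
        sig = marker_sets[name]
        present = [g for g in sig.genes if g in universe]
        if not present:
            raise ValueError(f"marker set {name!r} has no genes in the matrix")
        scores[i] = module_score(norm, sig, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)

    best = np.argmax(scores, axis=0)  # argmax takes the first (lexicographic) on ties
    order = np.argsort(-scores, axis=0, kind="stable")
    second = order[1] if len(names) > 1 else order[0]
    second = np.where(second == best, order[0], second)
    top = scores[best, np.arange(norm.n_cells)]
    run = scores[second, np.arange(norm.n_cells)] if len(names) > 1 else top
    return pd.DataFrame(
        {
            "label": [names[i] for i in best],
            "score": top,
            "runner_up": [names[i] for i in second],
            "margin": top - run if len(names) > 1 else np.zeros(norm.n_cells),
            "tie": (top == run) & (len(names) > 1),
        },
        index=pd.Index(norm.cell_ids, name="cell_id"),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of all rank splits when both groups have at most
    ``exact_max_n`` observations (correct under ties); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    if nx <= exact_max_n and ny <= exact_max_n:
        ranks = scipy.stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:nx].sum()
        stats = np.array([sum(c) for c in combinations(ranks, nx)])
        p_lo = np.mean(stats <= w_obs + 1e-9)
        p_hi = np.mean(stats >= w_obs - 1e-9)
        return float(min(1.0, 2.0 * min(p_lo, p_hi)))
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def find_markers(
    norm: NormalizedMatrix,
    labels: Sequence[str],
    group: str,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    adj_p_max: float = 0.01,
    only_pos: bool = False,
    base: float = np.e,
    return_all: bool = False,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon DEG test with BH correction and the standard filters.

    Genes with expressed fraction >= ``min_pct`` in at least one side are
    tested; BH runs across tested genes; surviving rows satisfy
    ``|log_fc| >= logfc_min`` (``log_fc >= logfc_min`` with ``only_pos``) and
    ``adj_p <= adj_p_max``.  log fold change is
    ``log(mean(expm1(x_in)) + eps) - log(mean(expm1(x_out)) + eps)``.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != norm.n_cells:
        raise ValueError("labels length must equal cell count")
    in_mask = labels == group
    if not in_mask.any():
        raise ValueError(f"unknown group label {group!r}")
    out_mask = ~in_mask
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise ValueError("group and complement must each have >= 3 cells")

    X = np.asarray(norm.values.todense(), dtype=float)
    Xin, Xout = X[:, in_mask], X[:, out_mask]
    pct_in = (Xin > 0).mean(axis=1)
    pct_out = (Xout > 0).mean(axis=1)
    eps = 1e-9
    lfc = np.log(np.expm1(Xin).mean(axis=1) + eps) - np.log(np.expm1(Xout).mean(axis=1) + eps)
    if base != np.e:
        lfc = lfc / np.log(base)

    tested = np.flatnonzero((pct_in >= min_pct) | (pct_out >= min_pct))
    pvals = np.ones(len(tested))
    for j, gi in enumerate(tested):
        pvals[j] = rank_sum_test(Xin[gi], Xout[gi])
    adj = bh_adjust(pvals)

    table = pd.DataFrame(
        {
            "gene_id": norm.gene_ids[tested],
            "group": group,
            "log_fc": lfc[tested],
            "p_value": pvals,
            "adj_p": adj,
            "pct_in_group": pct_in[tested],
            "pct_out": pct_out[tested],
        }
    )
    if return_all:
        return table.reset_index(drop=True)
    eff = table["log_fc"] >= logfc_min if only_pos else table["log_fc"].abs() >= logfc_min
    keep = eff & (table["adj_p"] <= adj_p_max)
    return (
        table[keep]
        .sort_values(["adj_p", "p_value", "gene_id"])
        .reset_index(drop=True)
    )
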