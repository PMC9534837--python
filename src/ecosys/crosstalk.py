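"""Permutation test for ligand–receptor interaction strength between cell groups.

For each (ligand, receptor) pair and ordered (source, target) group pair the
interaction score is the arithmetic mean of the ligand's mean expression in
the source group and the receptor's mean expression in the target group.  The
null is built by shuffling cell → group labels; the permutation p-value uses
the add-one correction, so it is never zero and never below 1/(n_perm+1).
Pairs with expression fraction below ``min_frac`` on either side are reported
but flagged non-testable; the retained set is p <= 0.05.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix


def lr_interaction_test(
    norm: NormalizedMatrix,
    labels: Sequence[str],
    pairs: Sequence[Tuple[str, str]],
    n_perm: int = 1000,
    min_frac: float = 0.1,
    seed: int = 0,
    p_retain: float = 0.05,
    min_cells: int = 3,
    stratify_by: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Score and permutation-test every LR pair across all ordered group pairs.

    ``stratify_by`` (e.g. per-cell sample ids) restricts the label shuffling to
    within strata.  Groups with fewer than ``min_cells`` cells are excluded.
    Missing genes yield rows flagged ``missing_gene`` with NaN score/p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (no null otherwise)")
    if not pairs:
        raise ValueError("no ligand-receptor pairs supplied")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != norm.n_cells:
        raise ValueError("labels must align with cells")

    counts = pd.Series(labels).value_counts()
    groups = sorted(g for g in counts.index if counts[g] >= min_cells)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with enough cells")
    keep = np.isin(labels, groups)
    lab = labels[keep]

    lut = {g: i for i, g in enumerate(map(str, norm.gene_ids))}
    genes_needed = sorted({g for p in pairs for g in p if g in lut})
    gidx = np.array([lut[g] for g in genes_needed], dtype=int)
    gene_row = {g: i for i, g in enumerate(genes_needed)}
    X = np.asarray(norm.values[gidx][:, np.flatnonzero(keep)].todense(), dtype=float)

    grp_idx = {g: np.flatnonzero(lab == g) for g in groups}
    n_cells = X.shape[1]
    M = np.zeros((n_cells, len(groups)))
    for j, g in enumerate(groups):
        M[grp_idx[g], j] = 1.0 / len(grp_idx[g])
    obs_means = X @ M  # genes_needed x groups
    frac = np.zeros((len(genes_needed), len(groups)))
    for j, g in enumerate(groups):
        frac[:, j] = (X[:, grp_idx[g]] > 0).mean(axis=1)

    rng = np.random.default_rng(seed)
    if stratify_by is not None:
        strata = np.asarray(stratify_by, dtype=object)[keep]
        strat_idx = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
    null_means = np.empty((n_perm, len(genes_needed), len(groups)))
    for b in range(n_perm):
        if stratify_by is None:
            perm = rng.permutation(n_cells)
        else:
            perm = np.arange(n_cells)
            for si in strat_idx:
                perm[si] = si[rng.permutation(len(si))]
        null_means[b] = X[:, perm] @ M

    rows = []
    gcol = {g: j for j, g in enumerate(groups)}
    for lig, rec in pairs:
        missing = lig not in lut or rec not in lut
        for a in groups:
            for b in groups:
                if missing:
                    rows.append(
                        (lig, rec, a, b, np.nan, np.nan, np.nan, np.nan, n_perm, False, False, "missing_gene")
                    )
                    continue
                li, ri = gene_row[lig], gene_row[rec]
                ja, jb = gcol[a], gcol[b]
                score = 0.5 * (obs_means[li, ja] + obs_means[ri, jb])
                null = 0.5 * (null_means[:, li, ja] + null_means[:, ri, jb])
                p = (1.0 + np.sum(null >= score - 1e-12)) / (n_perm + 1.0)
                fa, fb = frac[li, ja], frac[ri, jb]
                testable = (fa >= min_frac) and (fb >= min_frac)
                retained = bool(testable and p <= p_retain)
                rows.append((lig, rec, a, b, score, p, fa, fb, n_perm, testable, retained, "ok"))
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "source_group", "target_group", "score", "p_value",
            "expressed_frac_source", "expressed_frac_target", "n_perm", "testable",
            "retained", "flag",
        ],
    )


def dotplot_table(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate LR results into a dot-plot-ready long table (retained pairs only)."""
    kept = results[results["retained"]].copy()
    kept["interaction"] = kept["ligand"] + "_" + kept["receptor"]
    kept["group_pair"] = kept["source_group"] + "|" + kept["target_group"]
    return kept[["interaction", "group_pair", "score", "p_value"]].reset_index(drop=True)
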