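"""Tissue-preference quantification via observed/expected cell ratios (Ro/e).

For a clusters × tissues contingency table, the expected count of each cell is
the chi-square expectation ``row_total × col_total / grand_total``; the ratio
Ro/e = observed / expected measures tissue preference, with Ro/e > 1 read as
enrichment of a cluster in a tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class RoeTable:
    """Observed, expected and Ro/e matrices plus the Pearson chi-square test."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    roe: pd.DataFrame
    chi2_stat: float
    dof: int
    p_value: float

    @property
    def enriched(self) -> pd.DataFrame:
        """Boolean mask, True where Ro/e > 1 (undefined entries are False)."""
        return self.roe.gt(1.0).fillna(False)

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format (cluster, tissue, observed, expected, roe)."""
        long = self.roe.stack(future_stack=True).rename("roe").reset_index()
        long.columns = ["cluster", "tissue", "roe"]
        long["observed"] = self.observed.stack(future_stack=True).to_numpy()
        long["expected"] = self.expected.stack(future_stack=True).to_numpy()
        return long


def roe_table(
    labels: Sequence[str],
    tissues: Sequence[str],
) -> RoeTable:
    """Compute the Ro/e table for per-cell cluster labels and tissue classes.

    Tissues with zero cells are excluded with a warning.  Entries with expected
    count 0 get a missing Ro/e (never infinity).  Requires >= 2 clusters and
    >= 2 tissues with nonzero totals.
    """
    labels = np.asarray(labels, dtype=object)
    tissues = np.asarray(tissues, dtype=object)
    if len(labels) != len(tissues):
        raise ValueError("labels and tissues must align per cell")
    observed = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(tissues, name="tissue"))

    empty_cols = observed.columns[(observed.sum(axis=0) == 0)]
    if len(empty_cols):
        warnings.warn(f"excluding tissue(s) with zero cells: {list(empty_cols)}")
        observed = observed.drop(columns=empty_cols)
    empty_rows = observed.index[(observed.sum(axis=1) == 0)]
    if len(empty_rows):
        observed = observed.drop(index=empty_rows)

    if observed.shape[0] < 2:
        raise ValueError("need >= 2 clusters with cells")
    if observed.shape[1] < 2:
        raise ValueError("need >= 2 tissues with cells")

    row = observed.sum(axis=1).to_numpy(dtype=float)
    col = observed.sum(axis=0).to_numpy(dtype=float)
    grand = row.sum()
    expected = pd.DataFrame(
        np.outer(row, col) / grand, index=observed.index, columns=observed.columns
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        roe = observed / expected
    roe = roe.where(expected > 0)

    chi2, p, dof, _ = scipy.stats.chi2_contingency(observed.to_numpy(), correction=False)
    return RoeTable(
        observed=observed,
        expected=expected,
        roe=roe,
        chi2_stat=float(chi2),
        dof=int(dof),
        p_value=float(p),
    )
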