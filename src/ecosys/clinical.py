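"""Tumor mutational burden, IHC composite scoring, and survival stratification.

TMB is the count of nonsynonymous mutations divided by the assayed exon length
in megabases.  The IHC composite is the density score (1..4) multiplied by the
intensity score (1..4), ranging 1 to 16.  Marker-based stratification splits
samples at the median (strictly greater is "high") and compares groups with
Kaplan–Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

NONSYN_CLASSES = ("missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site")
KNOWN_CLASSES = NONSYN_CLASSES + ("synonymous", "noncoding")


@dataclass
class IHCScore:
    density: int
    intensity: int
    composite: int


def compute_tmb(
    mutations: pd.DataFrame,
    exon_length_mb: float,
    nonsyn_classes: Sequence[str] = NONSYN_CLASSES,
) -> pd.DataFrame:
    """Per-sample TMB: nonsynonymous mutation count / exon length (mut/Mb).

    ``mutations`` is MAF-lite (sample_id, gene_id, variant_class).  Unknown
    variant classes raise; samples present in the table but carrying only
    synonymous variants report TMB 0.
    """
    if exon_length_mb <= 0:
        raise ValueError("exon_length_mb must be > 0")
    unknown = sorted(set(mutations["variant_class"]) - set(KNOWN_CLASSES))
    if unknown:
        raise ValueError(f"unknown variant class value(s): {unknown}")
    bad = sorted(set(nonsyn_classes) - set(KNOWN_CLASSES))
    if bad:
        raise ValueError(f"nonsyn_classes outside the vocabulary: {bad}")
    is_ns = mutations["variant_class"].isin(set(nonsyn_classes))
    counts = (
        mutations.assign(_ns=is_ns)
        .groupby("sample_id", sort=True)["_ns"]
        .sum()
        .astype(int)
    )
    out = counts.rename("n_nonsynonymous").reset_index()
    out["exon_length_mb"] = float(exon_length_mb)
    out["tmb"] = out["n_nonsynonymous"] / exon_length_mb
    return out


def ihc_composite(density: int, intensity: int) -> IHCScore:
    """Composite IHC score: density × intensity, both graded 1..4 (range 1..16)."""
    density, intensity = int(density), int(intensity)
    for name, v in (("density", density), ("intensity", intensity)):
        if not 1 <= v <= 4:
            raise ValueError(f"{name} score {v} outside 1..4")
    return IHCScore(density=density, intensity=intensity, composite=density * intensity)


def median_split(
    values: Sequence[float],
    high_includes_median: bool = False,
) -> np.ndarray:
    """Label each sample "high" or "low" by the median of ``values``.

    By default high means strictly greater than the median (ties go low);
    ``high_includes_median`` flips the convention.  All-identical values raise.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 samples to split")
    med = np.median(vals)
    if np.all(vals == vals[0]):
        raise ValueError("all values identical; no median split exists")
    if high_includes_median:
        high = vals >= med
    else:
        high = vals > med
    return np.where(high, "high", "low").astype(object)


@dataclass
class KMResult:
    """Kaplan–Meier curves per group plus the two-group log-rank test."""

    curves: Dict[str, pd.DataFrame]
    statistic: float
    p_value: float
    n_events: Dict[str, int]


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str],
) -> KMResult:
    """Product-limit survival per group and the two-group log-rank chi-square (1 dof)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=object)
    names = sorted(pd.unique(groups))
    if len(names) != 2:
        raise ValueError(f"log-rank stratification needs exactly 2 groups, found {len(names)}")
    if events.sum() == 0:
        raise ValueError("no events observed; the log-rank statistic is undefined")

    curves, n_events = {}, {}
    for g in names:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=str(g))
        curves[str(g)] = kmf.survival_function_.rename(columns={str(g): "survival"}).reset_index(
            names="time"
        )
        n_events[str(g)] = int(events[m].sum())

    m0 = groups == names[0]
    res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_events=n_events,
    )
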