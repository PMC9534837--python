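"""Synthetic single-cell / bulk / clinical data with planted ground truth.

Emulates an inflammation-to-cancer gallbladder ecosystem study design: UMI
counts over eight cell types sampled from chronic-cholecystitis (CC), primary
tumor (PT) and metastasis (MT) tissues, with

* negative-binomial (gamma–Poisson) counts and lognormal library sizes,
* per-type marker programs (scattered genes, multiplicative fold change),
* chromosome-block dosage changes in malignant epithelium (the CNV signal),
* endothelial cells in every sample (CNV reference / spike-in design),
* a latent-factor co-expression module around a reference gene,
* three disjoint subtype programs activated in malignant cells,
* ligand–receptor effects between source and target cell types,
* purity-mixed bulk cohorts and marker-linked exponential survival.

Everything is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, TISSUES

CELL_TYPES = (
    "Epithelial",
    "T",
    "NK",
    "B",
    "Myeloid",
    "Fibroblast",
    "Endothelial",
    "Mast",
)

# Approximate relative protein-coding gene content of the 22 autosomes,
# so contiguous dosage blocks of a few hundred genes fit on one chromosome.
_CHROM_WEIGHTS = np.array(
    [
        0.103, 0.062, 0.053, 0.038, 0.044, 0.051, 0.046, 0.034, 0.039, 0.038,
        0.064, 0.051, 0.016, 0.031, 0.030, 0.042, 0.058, 0.014, 0.071, 0.027,
        0.012, 0.023,
    ]
)
_CHROM_WEIGHTS = _CHROM_WEIGHTS / _CHROM_WEIGHTS.sum()
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))

_DEFAULT_PROPS = {
    "CC": {
        "Epithelial": 0.30, "T": 0.22, "NK": 0.05, "B": 0.07,
        "Myeloid": 0.12, "Fibroblast": 0.07, "Endothelial": 0.15, "Mast": 0.02,
    },
    "PT": {
        "Epithelial": 0.42, "T": 0.14, "NK": 0.03, "B": 0.05,
        "Myeloid": 0.14, "Fibroblast": 0.09, "Endothelial": 0.12, "Mast": 0.01,
    },
    "MT": {
        "Epithelial": 0.50, "T": 0.10, "NK": 0.03, "B": 0.04,
        "Myeloid": 0.13, "Fibroblast": 0.08, "Endothelial": 0.11, "Mast": 0.01,
    },
}

SUBTYPE_LABELS = ("I", "II", "III")


@dataclass
class SimConfig:
    """Parameters of the synthetic ecosystem.

    Defaults describe the study conditions the package is exercised under: six
    samples spanning CC/PT/MT, ~2,000 cells, 6,000 genes on 22 chromosomes,
    one 300-gene 1.5x amplification in malignant epithelium, a 40-gene
    co-expression module, three 40-gene subtype programs.
    """

    n_genes: int = 6000
    n_cells_per_sample: int = 333
    samples: Tuple[Tuple[str, str], ...] = (
        ("CC1", "CC"), ("CC2", "CC"),
        ("GBC1", "PT"), ("GBC2", "PT"), ("GBC3", "PT"),
        ("MT1", "MT"),
    )
    cell_type_props: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {t: dict(p) for t, p in _DEFAULT_PROPS.items()}
    )
    nb_dispersion: float = 0.1
    libsize_lognormal: Tuple[float, float] = (np.log(8000.0), 0.35)
    marker_effect: float = 8.0
    n_markers_per_type: int = 25
    # (chromosome, start index within chromosome, length in genes, dosage factor)
    cnv_blocks: Tuple[Tuple[str, int, int, float], ...] = (("chr1", 150, 300, 1.5),)
    # (reference gene or None for auto, module size excl. reference, latent SD)
    coexpr_module: Tuple[Optional[str], int, float] = (None, 40, 1.0)
    subtype_set_size: int = 40
    subtype_effect: float = 3.0
    subtype_gene_sets: Optional[Dict[str, Sequence[str]]] = None
    # (ligand, receptor, source_type, target_type, fold-change effect);
    # gene names None -> auto-picked
    lr_pairs: Tuple[Tuple[Optional[str], Optional[str], str, str, float], ...] = (
        (None, None, "Epithelial", "T", 4.0),
        (None, None, "Fibroblast", "Myeloid", 4.0),
        (None, None, "Epithelial", "Endothelial", 4.0),
    )
    n_mito_genes: int = 10
    mito_fraction: float = 0.05
    min_endothelial: int = 12
    seed: int = 0

    def validate(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("sample list is empty")
        if self.n_genes < 100:
            raise ValueError("n_genes too small for a genome layout")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for tissue, props in self.cell_type_props.items():
            if tissue not in TISSUES:
                raise ValueError(f"unknown tissue class {tissue!r}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cell_type_props[{tissue!r}] sums to {total}, not 1")
        for _, tissue in self.samples:
            if tissue not in self.cell_type_props:
                raise ValueError(f"no cell_type_props for tissue {tissue!r}")
        chrom_sizes = dict(zip(CHROMOSOMES, chromosome_gene_counts(self.n_genes)))
        for chrom, start, length, dosage in self.cnv_blocks:
            if dosage <= 0:
                raise ValueError("dosage_factor must be > 0")
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if start < 0 or start + length > chrom_sizes[chrom]:
                raise ValueError(
                    f"cnv_block {chrom}:{start}+{length} exceeds gene range "
                    f"({chrom_sizes[chrom]} genes on {chrom})"
                )
        if self.subtype_gene_sets is not None:
            sets = [set(v) for v in self.subtype_gene_sets.values()]
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    if sets[i] & sets[j]:
                        raise ValueError("subtype gene sets must be pairwise disjoint")


@dataclass
class GroundTruth:
    """Planted truth for a simulated ecosystem (per-cell labels and gene programs)."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_type: np.ndarray
    malignant: np.ndarray
    subtype: np.ndarray  # object array; None for non-malignant cells
    marker_sets: Dict[str, List[str]]
    module_reference: str
    module_genes: List[str]
    module_activity: np.ndarray
    subtype_gene_sets: Dict[str, List[str]]
    lr_pairs: List[Tuple[str, str, str, str, float]]
    mito_genes: List[str]
    gene_positions: pd.DataFrame
    cnv_blocks: List[Tuple[str, int, int, float]]  # chrom, global start idx, length, dosage
    bulk_subtype: Optional[np.ndarray] = None

    @property
    def module_active(self) -> np.ndarray:
        """Cells on the high side of the co-expression latent factor."""
        return self.module_activity > 0

    def cnv_state(self) -> np.ndarray:
        """Dense cells × genes dosage matrix (1 everywhere for non-malignant cells)."""
        state = np.ones((len(self.cell_ids), len(self.gene_ids)))
        for _, start, length, dosage in self.cnv_blocks:
            state[np.ix_(self.malignant, np.arange(start, start + length))] = dosage
        return state

    def block_gene_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.gene_ids), dtype=bool)
        for _, start, length, _ in self.cnv_blocks:
            mask[start:start + length] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "cell_type": self.cell_type,
                "malignant": self.malignant,
                "subtype": [s if s is not None else "" for s in self.subtype],
                "module_activity": self.module_activity,
            }
        )


def chromosome_gene_counts(n_genes: int) -> np.ndarray:
    """Split ``n_genes`` across the 22 synthetic autosomes (index order)."""
    raw = _CHROM_WEIGHTS * n_genes
    counts = np.floor(raw).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = n_genes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def gene_position_table(gene_ids: Sequence[str]) -> pd.DataFrame:
    """BED-like table assigning genes to chromosomes in index order (0-based half-open)."""
    n = len(gene_ids)
    counts = chromosome_gene_counts(n)
    chroms = np.repeat(np.array(CHROMOSOMES, dtype=object), counts)
    within = np.concatenate([np.arange(c) for c in counts])
    return pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object),
            "chromosome": chroms,
            "start": within * 10000,
            "end": within * 10000 + 5000,
        }
    )


def _resolve_layout(config: SimConfig, rng: np.random.Generator):
    """Pick marker / module / subtype / LR / mito genes, mutually disjoint."""
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    positions = gene_position_table(gene_ids)
    chrom_of = positions["chromosome"].to_numpy()
    chrom_offsets = {}
    for i, chrom in enumerate(CHROMOSOMES):
        idx = np.flatnonzero(chrom_of == chrom)
        chrom_offsets[chrom] = int(idx[0]) if len(idx) else None

    blocks_global = []
    block_idx: set = set()
    for chrom, start, length, dosage in config.cnv_blocks:
        g0 = chrom_offsets[chrom] + start
        blocks_global.append((chrom, g0, length, dosage))
        block_idx.update(range(g0, g0 + length))

    # scatter the special programs over non-block genes so that, after 101-gene
    # window smoothing, only the contiguous dosage blocks look like CNV
    free = np.array(sorted(set(range(n)) - block_idx))
    perm = free[rng.permutation(len(free))]
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > len(perm):
            raise ValueError("not enough genes for the requested programs")
        out = perm[cursor:cursor + k]
        cursor += k
        return np.sort(out)

    marker_sets = {t: take(config.n_markers_per_type) for t in CELL_TYPES}
    ref_name, module_size, latent_sd = config.coexpr_module
    module_idx = take(module_size)
    ref_idx = int(take(1)[0]) if ref_name is None else int(np.flatnonzero(gene_ids == ref_name)[0])

    if config.subtype_gene_sets is None:
        subtype_sets = {lab: take(config.subtype_set_size) for lab in SUBTYPE_LABELS}
    else:
        subtype_sets = {
            lab: np.array([int(np.flatnonzero(gene_ids == g)[0]) for g in genes])
            for lab, genes in config.subtype_gene_sets.items()
        }

    lr_resolved = []
    for lig, rec, src, tgt, eff in config.lr_pairs:
        li = int(take(1)[0]) if lig is None else int(np.flatnonzero(gene_ids == lig)[0])
        ri = int(take(1)[0]) if rec is None else int(np.flatnonzero(gene_ids == rec)[0])
        lr_resolved.append((li, ri, src, tgt, eff))

    mito_idx = take(config.n_mito_genes)
    for j, gi in enumerate(mito_idx):
        gene_ids[gi] = f"MT-G{j:02d}"
    positions["gene_id"] = gene_ids

    return {
        "gene_ids": gene_ids,
        "positions": positions,
        "blocks_global": blocks_global,
        "marker_sets": marker_sets,
        "module_idx": module_idx,
        "module_ref_idx": ref_idx,
        "module_latent_sd": latent_sd,
        "subtype_sets": subtype_sets,
        "lr_resolved": lr_resolved,
        "mito_idx": mito_idx,
    }


def _sample_cells(config: SimConfig, rng: np.random.Generator):
    """Draw per-sample cell-type compositions; endothelium guaranteed everywhere."""
    sample_ids, tissues, types = [], [], []
    type_arr = np.array(CELL_TYPES, dtype=object)
    endo = list(CELL_TYPES).index("Endothelial")
    for sid, tissue in config.samples:
        props = np.array([config.cell_type_props[tissue][t] for t in CELL_TYPES])
        counts = rng.multinomial(config.n_cells_per_sample, props)
        if counts[endo] < config.min_endothelial:  # CNV reference design needs them
            donor = int(np.argmax(counts))
            deficit = config.min_endothelial - counts[endo]
            counts[donor] -= deficit
            counts[endo] += deficit
        labels = np.repeat(type_arr, counts)
        rng.shuffle(labels)
        sample_ids.extend([sid] * len(labels))
        tissues.extend([tissue] * len(labels))
        types.extend(labels)
    return (
        np.array(sample_ids, dtype=object),
        np.array(tissues, dtype=object),
        np.array(types, dtype=object),
    )


def simulate_ecosystem(config: Optional[SimConfig] = None) -> Tuple[CountMatrix, GroundTruth]:
    """Generate a synthetic single-cell ecosystem with planted ground truth.

    Returns the sparse genes × cells :class:`CountMatrix` and the
    :class:`GroundTruth` describing every planted program.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    layout = _resolve_layout(config, rng)
    gene_ids = layout["gene_ids"]
    n_genes = config.n_genes

    sample_ids, tissues, cell_types = _sample_cells(config, rng)
    n_cells = len(cell_types)
    cell_ids = np.array(
        [f"{s}_c{i:04d}" for i, s in enumerate(sample_ids)], dtype=object
    )

    malignant = (cell_types == "Epithelial") & np.isin(tissues, ("PT", "MT"))

    # one subtype per tumor sample, cycling I/II/III across tumor samples
    tumor_samples = [s for s, t in config.samples if t in ("PT", "MT")]
    sample_subtype = {
        s: SUBTYPE_LABELS[i % len(SUBTYPE_LABELS)] for i, s in enumerate(tumor_samples)
    }
    subtype = np.array(
        [sample_subtype[s] if m else None for s, m in zip(sample_ids, malignant)],
        dtype=object,
    )

    # baseline relative abundances; mitochondrial genes pinned to a realistic share
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mito_idx = layout["mito_idx"]
    non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
    f = config.mito_fraction
    base[mito_idx] *= (f / (1 - f)) * base[non_mito].sum() / base[mito_idx].sum()

    logmod = np.zeros((n_genes, n_cells))  # log-scale multiplicative modifiers

    for t, idx in layout["marker_sets"].items():
        cells = cell_types == t
        if cells.any():
            logmod[np.ix_(idx, cells)] += np.log(config.marker_effect)

    for chrom, g0, length, dosage in layout["blocks_global"]:
        if malignant.any():
            logmod[np.ix_(np.arange(g0, g0 + length), malignant)] += np.log(dosage)

    for lab, idx in layout["subtype_sets"].items():
        cells = np.array([s == lab for s in subtype])
        if cells.any():
            logmod[np.ix_(idx, cells)] += np.log(config.subtype_effect)

    lr_named = []
    for li, ri, src, tgt, eff in layout["lr_resolved"]:
        logmod[li, cell_types == src] += np.log(eff)
        logmod[ri, cell_types == tgt] += np.log(eff)
        lr_named.append((str(gene_ids[li]), str(gene_ids[ri]), src, tgt, eff))

    # shared latent factor: reference gene + module genes co-fluctuate
    latent = rng.normal(0.0, layout["module_latent_sd"], size=n_cells)
    module_rows = np.concatenate([[layout["module_ref_idx"]], layout["module_idx"]])
    loadings = rng.uniform(0.7, 1.3, size=len(module_rows))
    logmod[module_rows, :] += np.outer(loadings, latent)

    mean = base[:, None] * np.exp(logmod)
    mean /= mean.sum(axis=0, keepdims=True)
    mu, sigma = config.libsize_lognormal
    libsize = rng.lognormal(mean=mu, sigma=sigma, size=n_cells)
    mean *= libsize[None, :]

    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mean * config.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=pd.DataFrame({"sample_id": sample_ids, "tissue": tissues}),
    )
    truth = GroundTruth(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_type=cell_types,
        malignant=malignant,
        subtype=subtype,
        marker_sets={t: [str(gene_ids[i]) for i in idx] for t, idx in layout["marker_sets"].items()},
        module_reference=str(gene_ids[layout["module_ref_idx"]]),
        module_genes=[str(gene_ids[i]) for i in layout["module_idx"]],
        module_activity=latent,
        subtype_gene_sets={lab: [str(gene_ids[i]) for i in idx] for lab, idx in layout["subtype_sets"].items()},
        lr_pairs=lr_named,
        mito_genes=[str(gene_ids[i]) for i in mito_idx],
        gene_positions=layout["positions"],
        cnv_blocks=layout["blocks_global"],
    )
    return cm, truth


def _expected_type_profiles(config: SimConfig, layout, rng: np.random.Generator):
    """Generative mean relative-expression profiles per cell type and per subtype."""
    n_genes = config.n_genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mito_idx = layout["mito_idx"]
    non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
    f = config.mito_fraction
    base[mito_idx] *= (f / (1 - f)) * base[non_mito].sum() / base[mito_idx].sum()

    profiles = {}
    for t in CELL_TYPES:
        p = base.copy()
        p[layout["marker_sets"][t]] *= config.marker_effect
        profiles[t] = p

    subtype_profiles = {}
    for lab in layout["subtype_sets"]:
        p = profiles["Epithelial"].copy()
        for chrom, g0, length, dosage in layout["blocks_global"]:
            p[g0:g0 + length] *= dosage
        p[layout["subtype_sets"][lab]] *= config.subtype_effect
        subtype_profiles[lab] = p / p.sum()

    stroma_types = [t for t in CELL_TYPES if t != "Epithelial"]
    stroma = np.zeros(n_genes)
    for t in stroma_types:
        stroma += profiles[t] / profiles[t].sum()
    stroma /= len(stroma_types)
    return subtype_profiles, stroma


def simulate_bulk_cohort(
    config: Optional[SimConfig] = None,
    n_samples: int = 30,
    purity_range: Tuple[float, float] = (0.6, 0.9),
    depth: int = 500_000,
    noise: bool = True,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Bulk RNA-seq cohort: purity-weighted subtype + stroma mixtures, Poisson-resampled.

    Returns a genes × samples count DataFrame and a :class:`GroundTruth` whose
    ``bulk_subtype`` records each sample's planted subtype (labels cycle
    I/II/III so the cohort is balanced).  ``noise=False`` returns the exact
    expected profile scaled to ``depth`` (no resampling).
    """
    config = config or SimConfig()
    config.validate()
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    lo, hi = purity_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("purity_range must lie in (0, 1]")

    rng = np.random.default_rng(config.seed)
    layout = _resolve_layout(config, rng)
    subtype_profiles, stroma = _expected_type_profiles(config, layout, rng)

    labels = np.array(
        [SUBTYPE_LABELS[i % len(SUBTYPE_LABELS)] for i in range(n_samples)], dtype=object
    )
    purities = rng.uniform(lo, hi, size=n_samples)
    cols = {}
    sample_names = [f"BULK{j:03d}" for j in range(n_samples)]
    for j, (name, lab) in enumerate(zip(sample_names, labels)):
        mix = purities[j] * subtype_profiles[lab] + (1 - purities[j]) * stroma
        mix = mix / mix.sum()
        expected = mix * depth
        cols[name] = rng.poisson(expected) if noise else expected
    bulk = pd.DataFrame(cols, index=pd.Index(layout["gene_ids"], name="gene_id"))

    truth = GroundTruth(
        cell_ids=np.array(sample_names, dtype=object),
        gene_ids=layout["gene_ids"],
        cell_type=np.array(["bulk"] * n_samples, dtype=object),
        malignant=np.ones(n_samples, dtype=bool),
        subtype=labels,
        marker_sets={t: [str(layout["gene_ids"][i]) for i in idx] for t, idx in layout["marker_sets"].items()},
        module_reference=str(layout["gene_ids"][layout["module_ref_idx"]]),
        module_genes=[str(layout["gene_ids"][i]) for i in layout["module_idx"]],
        module_activity=np.zeros(n_samples),
        subtype_gene_sets={lab: [str(layout["gene_ids"][i]) for i in idx] for lab, idx in layout["subtype_sets"].items()},
        lr_pairs=[],
        mito_genes=[str(layout["gene_ids"][i]) for i in layout["mito_idx"]],
        gene_positions=layout["positions"],
        cnv_blocks=layout["blocks_global"],
        bulk_subtype=labels,
    )
    return bulk, truth


def simulate_clinical(
    config: Optional[SimConfig] = None,
    n_patients: int = 100,
    hazard_ratio: float = 4.0,
    base_rate: float = 1.0 / 24.0,
    censoring_rate: float = 0.01,
    mean_nonsynonymous: float = 60.0,
    mean_synonymous: float = 30.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical table + MAF-lite mutation table linked to a marker score.

    Survival is exponential with rate ``base_rate`` (per month), multiplied by
    ``hazard_ratio`` for marker-high patients (the top half of a standard-normal
    marker score).  Censoring is an independent exponential clock
    (``censoring_rate=0`` observes every event).  IHC density/intensity are
    1..4 integers positively linked to the marker.  Mutation counts per sample
    are Poisson with the stated means.
    """
    config = config or SimConfig()
    if n_patients < 4:
        raise ValueError("n_patients must be >= 4")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = np.random.default_rng(config.seed)

    patients = np.array([f"P{i:03d}" for i in range(n_patients)], dtype=object)
    marker = rng.normal(size=n_patients)
    high = marker > np.median(marker)

    rate = np.where(high, base_rate * hazard_ratio, base_rate)
    event_time = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        censor_time = rng.exponential(1.0 / censoring_rate, size=n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    def to_score(x: np.ndarray) -> np.ndarray:
        return np.clip(np.round(2.5 + x + rng.normal(0, 0.5, size=len(x))), 1, 4).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": patients,
            "time": time,
            "event": event,
            "density_score": to_score(marker),
            "intensity_score": to_score(marker),
            "marker_score": marker,
            "truth_high": high,
        }
    )

    classes_nonsyn = ["missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site"]
    rows = []
    gene_pool = [f"G{i:05d}" for i in range(config.n_genes)]
    for pid in patients:
        n_ns = rng.poisson(mean_nonsynonymous)
        n_s = rng.poisson(mean_synonymous)
        genes = rng.choice(gene_pool, size=n_ns + n_s, replace=True)
        cls = list(rng.choice(classes_nonsyn, size=n_ns)) + ["synonymous"] * n_s
        for g, c in zip(genes, cls):
            rows.append((pid, g, c))
    mutations = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class"])
    return clinical, mutations
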