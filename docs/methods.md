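# Methods

This note documents the models, parameter choices and numerical conventions
behind `ecosys`, and what the synthetic benchmark does and does not
demonstrate about real data.

## Synthetic ecosystem model

Counts are gamma–Poisson (negative binomial): gene *g* in cell *c* has mean
`libsize_c × p_gc`, where `p_gc` is a per-cell-normalized relative-abundance
vector and counts are drawn as `Poisson(Gamma(1/φ, mean·φ))` with dispersion
φ = 0.1. Library sizes are lognormal (median 8,000 UMI, σ = 0.35). This is the
standard noise model for droplet scRNA-seq and is sufficient for every
downstream statistic the package tests.

Relative abundances start from a lognormal baseline and are modified
multiplicatively:

* **Cell types** — eight populations (epithelial, T, NK, B, myeloid,
  fibroblast, endothelial, mast) with 25 scattered marker genes each,
  up-modulated 8× in their own type. Tissue-specific composition vectors shift
  epithelium up and immune populations down along CC → PT → MT, and
  endothelium (≥ 12 cells) is guaranteed in every sample because the CNV
  reference design requires it.
* **CNV** — genes live on 22 synthetic chromosomes whose sizes follow
  approximate real autosome gene content, so a contiguous 300-gene block fits
  on the largest chromosome. Dosage acts multiplicatively on the NB mean for
  malignant cells (default: one 1.5× block of 300 genes on chr1), matching the
  dosage logic that expression-CNV inference assumes. Malignant = epithelial
  in PT/MT; benign-tissue epithelium is diploid.
* **Co-expression module** — a reference gene plus 40 module genes load
  (0.7–1.3×) on a shared N(0, 1) latent factor; "module-active" cells are
  those on the positive side of the factor.
* **Subtype programs** — three disjoint 40-gene sets activated 3× in the
  malignant cells of their subtype; each tumor sample carries one subtype
  (cycling I/II/III across samples), as real tumors do.
* **Ligand–receptor effects** — chosen gene pairs up-modulated 4× in their
  source/target cell types.
* **Mitochondrial genes** — ten genes carry the `MT-` prefix and are pinned to
  ~5% of expression so the QC filter is exercisable.

Marker, module, subtype and LR genes are *scattered* across the genome
(seeded, disjoint) rather than contiguous: after 101-gene window smoothing
only the planted contiguous dosage blocks look like CNV, which is exactly the
discrimination the real method relies on.

Bulk cohorts mix one subtype's expected malignant profile with a shared stroma
profile at a sampled purity and Poisson-resample at 500k depth. Clinical
tables use exponential survival (baseline rate 1/24 per month) with the rate
multiplied by the hazard ratio for marker-high patients, independent
exponential censoring, IHC grades (1–4) noisily tracking the marker, and
Poisson mutation counts (means 60 nonsynonymous / 30 synonymous).

**What the generator does not emulate:** doublets, ambient RNA, batch effects
beyond sample identity, subclonal CNV heterogeneity, cell-cycle structure, and
realistic gene–gene correlation beyond the planted programs. Passing the
recovery tests therefore shows the *algorithms* are correct and calibrated
under their stated noise model, not that the thresholds are optimal for any
particular real dataset.

## Preprocessing conventions

QC keeps cells with **> 200** detected genes (a cell with exactly 200 is
removed — the keep rule is strict) and mitochondrial fraction **≤ 20%**
(exactly 20% is retained — the removal rule is strict); genes must be detected
in > 0.1% of retained cells. The two thresholds are deliberately asymmetric at
their boundaries because the conventional phrasing of the two rules is
("> 200 genes" to keep, "> 20%" to remove); both are configurable.

Normalization is `ln(1 + count/libsize × 10⁴)`. HVGs are ranked by the
residual of log variance from a lowess mean–variance trend (frac 0.3), ties
broken by gene id; genes with numerically zero variance (≤ 1e-10) never enter
the fit. Scaling is a per-gene z-score clipped at ±10; zero-variance genes are
set to 0 and flagged.

DEG testing is one-vs-rest Wilcoxon rank-sum: exact enumeration of all rank
splits when both groups have ≤ 10 observations (correct under ties, two-sided
p = 2·min(tail probabilities) capped at 1), otherwise the normal approximation
with tie and continuity corrections. Genes expressed in ≥ 10% of either side
are tested; BH runs across tested genes; survivors need |log FC| ≥ 0.25
(natural log of expm1-mean ratios, ε = 1e-9) and adjusted P ≤ 0.01. Cell
annotation is the argmax of marker-set module scores with lexicographic tie
break; a hook accepts externally computed cluster labels anywhere a label
vector is consumed, so graph-based clustering can be substituted without code
changes.

## CNV inference and malignancy calling

Order of operations: restrict to positioned genes → sort by (chromosome,
start) → subtract per-gene reference mean → clip to ±3 → centered moving
average of 101 genes within each chromosome (the window shrinks symmetrically
at chromosome edges, so constants are preserved) → subtract the per-cell
median → subtract the smoothed reference-average profile. This is the standard
moving-average expression-CNV scheme; the reference design samples up to 100
endothelial cells per sample as control and mixes 10 per sample into the
interrogated set as spike-ins.

K-means (10 restarts, fixed seed) runs over k = 2..10 and k is chosen by
maximum mean silhouette, smallest k on ties — the cluster count is otherwise
arbitrary, and silhouette selection is reproducible and defensible. "Lack of
CNVs" is operationalized as burden (mean squared profile) at or below the 99th
percentile of reference-cell burdens; a cluster is non-malignant iff it holds
≥ 50% of all spike-ins or at least one spike-in per 50 member cells, *and* its
median burden is below that threshold. All thresholds are exposed as
configuration. Clustering is joint across samples by default (a per-sample
run is a matter of subsetting the matrix first).

## Ro/e

Expected counts come from the chi-square marginal product; entries with
expected 0 give a *missing* ratio, never infinity (legitimately empty strata
should not crash a pipeline). The chi-square statistic and p-value are
reported alongside but do not gate the Ro/e > 1 enrichment mask — the ratio
itself is the readout. Computation pools cells per tissue class; per-sample
tables are obtained by grouping the label vector per sample.

## Signature scoring and derivation

Module scores use 24 equal-frequency expression bins and 100 control genes per
signature gene (drawn with replacement when a bin is smaller), the common
defaults of the bin-matched control scheme; bins are computed on the scored
cells. Derivation correlates the anchor gene against all genes on the
*clipped* scaled matrix (the convention of computing on "scaled expression");
an unclipped path is available by scaling with a large `clip_max`. The anchor
is excluded from its own signature by default — it is the anchor, not a
member — with `include_reference=True` to flip.

## Single-sample enrichment and subtyping

The enrichment statistic is the rank-weighted running sum
Σᵢ [P_hit(i) − P_miss(i)] with hit weights rankᵅ (α = 0.25), average ranks for
ties, and walking order by decreasing rank with index tie-break. It is
rank-based, hence invariant to monotone transforms of expression; a set
covering the whole universe scores 0 by convention; optional normalization
divides by N − |set|. The kernel-smoothed variant used by some GSVA-style
tools is deliberately replaced by this single well-defined statistic, which an
exhaustive brute-force oracle can check exactly.

The enrichment matrix is z-scored per set before Ward/Euclidean hierarchical
clustering (flagged on the object); the tree is cut at k = 3 and group labels
I/II/III follow descending group size with first-entity tie-break. "Top genes"
of a subtype are ranked by ascending adjusted P, then descending log FC, then
gene id. Bulk projection replaces variance-stabilizing transforms with
log2(CPM+1) — downstream scoring is rank-based, which makes the choice nearly
inert — scores the three top-15 signatures, clusters at k = 3, and names each
cluster by its dominant signature via one-to-one Hungarian matching (an argmax
winning-signature diagnostic is reported per sample as well).

## Crosstalk

The interaction statistic is the arithmetic mean of the two group means, the
convention of permutation LR tools; multi-subunit receptor complexes are out
of scope (pairs are binary). Label shuffling is global by default with a
per-sample stratified mode. The expression-fraction gate (10% on both sides)
flags rows as non-testable without hiding them; retention is p ≤ 0.05 with the
add-one correction, so p is never 0 and never below 1/(n_perm+1).

## Clinical scoring

The nonsynonymous vocabulary defaults to {missense, nonsense,
frameshift_indel, inframe_indel, splice_site} and is configurable; the exon
length denominator is an explicit input (it is capture-kit specific). Median
splits send ties to "low" ("high" means strictly above the median), with a
flag to flip. Kaplan–Meier estimation and the two-group log-rank test are
delegated to lifelines; identical groups give statistic 0 and p = 1, and a
no-event input is an error rather than a NaN.

## Problem sizes and determinism

The default simulated conditions — six samples across CC/PT/MT, ~2,000 cells,
6,000 genes, one 300-gene 1.5× block, 40-gene module, three 40-gene subtype
programs, 60-sample pseudobulk and 30-sample projection cohorts — were chosen
as the smallest sizes at which every recovery statistic is comfortably
estimable; all generators and stochastic operations (control-gene draws,
K-means, permutation tests) are driven by explicit integer seeds and are
byte-reproducible.

## Known limitations

* Marker-based annotation replaces graph clustering; cluster-level analyses
  accept external labels but the package does not compute embeddings.
* The CNV caller detects large contiguous dosage blocks; focal events smaller
  than roughly half the smoothing window are attenuated by design.
* The burden threshold assumes the reference population is genuinely diploid;
  contaminated references inflate the threshold and cost sensitivity.
* Bulk projection assumes subtype programs survive purity dilution; below
  ~50% purity the enrichment ranks degrade and accuracy falls off.
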