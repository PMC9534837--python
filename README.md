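# ecosys

Tools for dissecting an inflammation-to-cancer ecosystem from single-cell RNA
sequencing: malignant-cell identification from expression-inferred copy-number
profiles, tissue-preference quantification, gene-signature derivation and
scoring, malignant-epithelial subtype discovery with projection onto bulk
cohorts, permutation ligand–receptor crosstalk testing, and clinical scoring
(tumor mutational burden, IHC composites, survival stratification).

The package targets the setting where benign inflamed tissue (chronic
cholecystitis, **CC**), primary tumors (**PT**) and metastases (**MT**) from
the same organ system are profiled together and the question is how cell
states shift along the inflammation → cancer axis. Because such patient data
are controlled-access, a fully specified synthetic-data generator with planted
ground truth is part of the package: every analysis stage is tested end-to-end
against what was planted.

## Methods at a glance

**Expression-inferred CNV and malignancy.** For each cell, log-normalized
expression is centered against a diploid reference (endothelial cells),
clipped to ±3, and averaged in a 101-gene moving window along each chromosome;
the per-cell median and the smoothed reference profile are then subtracted.
Malignancy is called by K-means over these profiles with endothelial
*spike-ins* mixed into the interrogated cells: clusters that co-cluster with
the spike-ins **and** lack CNV (burden = mean squared profile at or below the
99th percentile of reference burdens) are non-malignant epithelium (nEPC);
everything else is malignant (mEPC).

**Ro/e.** For a clusters × tissues contingency table with entries *nᵢⱼ*,
Ro/e*ᵢⱼ* = *nᵢⱼ* / *Eᵢⱼ* with *Eᵢⱼ* = *nᵢ·n·ⱼ*/*n* (the chi-square
expectation); Ro/e > 1 is read as tissue enrichment.

**Signatures.** Module scores use the bin-matched control scheme: genes are
cut into 24 expression bins; each signature gene contributes its expression
minus the mean of 100 control genes drawn from its bin. Signatures are derived
by ranking genome-wide Pearson correlation against an anchor gene (GZMK-style
cytotoxicity, HAVCR2-style exhaustion, IL2RA-style Treg programs) on scaled
expression and keeping the top 30 genes.

**Subtyping.** Entities are scored against gene sets with a rank-weighted
running-sum single-sample enrichment statistic
(score = Σᵢ [P_hit(i) − P_miss(i)], hit weights |rank|^α, α = 0.25), the
enrichment matrix is z-scored per set and Ward-clustered, and the tree is cut
at k = 3. Top-15 DEG signatures of each subtype project the classification
onto bulk cohorts via log2(CPM+1).

**Crosstalk.** For ligand L, receptor R, source group A and target group B the
score is ½(mean L in A + mean R in B); the null shuffles cell labels, and
p = (1 + #{null ≥ observed}) / (n_perm + 1). Pairs with p ≤ 0.05 are retained.

**Clinical.** TMB = nonsynonymous mutations / exon megabases. IHC composite =
density (1–4) × intensity (1–4), range 1–16. Samples split at the median
marker score are compared with Kaplan–Meier curves and the log-rank test.

## Worked example

```python
import ecosys

cfg = ecosys.SimConfig(seed=0)              # ~2,000 cells, 6,000 genes,
counts, truth = ecosys.simulate_ecosystem(cfg)  # one 300-gene 1.5x amplification
filtered, report = ecosys.filter_qc(counts)
norm = ecosys.normalize_log(filtered)

call, profile = ecosys.call_malignancy_pipeline(
    norm, truth.gene_positions, truth.cell_type, seed=0)
print(call.labels.value_counts().to_dict())

roe = ecosys.roe_table(truth.cell_type, counts.cell_meta["tissue"])
print(roe.roe.round(2).loc[["Epithelial", "T", "Endothelial"]])

scaled = ecosys.scale_expression(norm)
sig = ecosys.derive_signature(scaled, truth.module_reference, top_n=30)
print(len(set(sig.genes) & set(truth.module_genes)), "of 30 module genes recovered")
```

prints

```
{'malignant': 602, 'non_malignant': 204, 'reference_spikein': 60}
tissue         CC    MT    PT
cluster
Epithelial   0.76  1.24  1.08
T            1.33  0.83  0.84
Endothelial  1.22  0.79  0.92
30 of 30 module genes recovered
```

All 602 planted malignant epithelial cells are recovered (the 204
non-malignant calls are the benign-tissue epithelium; the 60 spike-ins are the
per-sample endothelial cells deliberately mixed into the interrogated set).
The Ro/e table shows epithelium enriched in tumor tissues and immune/stromal
populations relatively enriched in the inflamed benign tissue, and the
anchor-gene correlation recovers the entire planted co-expression module.

A command-line interface mirrors the library:

```bash
ecosys --seed 0 --outdir out simulate
ecosys --outdir out/qc qc --indir out/counts
ecosys --outdir out/roe roe --labels labels.csv
```

Every subcommand writes a `provenance.json` with inputs, parameters, seed and
version.

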