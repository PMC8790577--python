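# emtime

Pan-cancer EMT scoring and tumor immune microenvironment (TIME) profiling.

Epithelial–mesenchymal transition (EMT) reshapes the immune milieu of solid
tumors: mesenchymal-leaning tumors tend to accumulate macrophages,
overexpress immune checkpoint molecules and suppressive cytokines, and show
inflamed/exhausted T-cell signatures. `emtime` is a library (plus a thin
CLI) for quantifying that association in cohort-scale bulk expression data,
for bioinformaticians working with TCGA-style z-scored matrices and
xCell-style immune enrichment tables.

## The model

For each tumor sample *s* in a cohort, the EMT score is

```
S(s) = mean_{g ∈ M} z_g(s) − mean_{g ∈ E} z_g(s)
```

over a 16-gene canonical panel: epithelial markers **E** = {CDH1, DSP,
TJP1} and mesenchymal markers **M** = {VIM, CDH2, FOXC2, SNAI1, SNAI2,
TWIST1, GSC, FN1, ITGB6, MMP2, MMP3, MMP9, SOX10}, where `z_g` is the
per-gene z-score across the cohort. Each cohort is cut at its score
quartiles into EMT-high ("mesenchymal", top 25%), EMT-intermediate
(middle 50%) and EMT-low ("epithelial", bottom 25%) groups.

Downstream, every TIME marker — 17 immune-cell enrichment scores, 17
checkpoint genes, 17 cytokine genes, and mean-z gene-signature scores — is
contrasted across groups: the median-difference landscape
Δ = median(high) − median(low), two-sample Kolmogorov–Smirnov tests (high
vs low), one-way ANOVA (three groups), and Spearman correlation with the
continuous score. Cohort-level profiles feed PCA (with per-marker
contribution shares), conditional probabilities of high marker expression
given EMT group, and K-means classification of cancer types on delta
profiles with silhouette-selected K. Survival (OS / PFI) is compared
between groups with Kaplan–Meier curves and the log-rank test.

A synthetic-cohort generator plants a latent EMT axis with configurable
marker couplings, enrichment tables and group-linked hazards, so the whole
pipeline is testable end-to-end with known ground truth.

## Worked example

```sh
python examples/01_emt_scoring.py
```

```
cohort DEMO: 200 samples, 3 epithelial + 13 mesenchymal panel genes
group sizes: {'high': 50, 'intermediate': 100, 'low': 50}
score median +0.021, IQR 1.833 (quartiles -0.893 / +0.940)
rank correlation with the planted EMT axis: 0.935
```

The quartile rule assigns exactly 50/100/50 samples; the 16-marker score
ranks samples almost identically to the latent axis the generator planted
(Spearman ρ = 0.935 at noise SD 1). `examples/02_time_landscape.py`
contrasts all 59 default markers — planted positive couplings
(Macrophages, TGFB1, SIGLEC7, IL10, activated stroma) surface with the
largest delta medians and `***` KS bands while null cytokines (IL4, IL5,
IFNA1) stay flat; `examples/03_classify_cancers.py` recovers a planted
two-archetype cancer classification (K = 2, 100% membership agreement);
`examples/04_survival_by_emt_group.py` shows EMT-high survival falling
below EMT-low under a planted hazard ratio of 2 (log-rank p ≈ 2e-6 at
n = 400).

Run the whole pipeline from one config:

```sh
emtime run-all -c config.yaml    # stages: simulate → score → contrast → cluster → survive
```

where `config.yaml` sets `output_dir`, `seed`, and either simulation
parameters or per-cohort `expression` / `enrichment` / `clinical` TSV
paths. Each stage writes TSV outputs plus a `manifest.json` with per-file
checksums; the same config and seed reproduce every file byte-for-byte.

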