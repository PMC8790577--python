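# Methods

## EMT score and stratification

The score is the difference of two means of per-gene z-scores:
`S = mean(z over mesenchymal panel genes) − mean(z over epithelial panel
genes)`, with the canonical 16-gene panel (3 epithelial, 13 mesenchymal)
as default and any disjoint pair of gene lists accepted. Input matrices
are assumed already z-scored per gene, as Firehose-style distributions
are; `ExpressionMatrix.standardize()` re-scales raw inputs. Panel genes
absent from a matrix are dropped from the relevant mean (logged); a
sample with no usable gene on one side receives a missing score and is
excluded from stratification with a warning. A cohort is eligible for
analysis only when it has more than 100 samples (`min_samples`,
configurable) and carries all required panel genes — by default the three
epithelial markers, since a cohort lacking CDH1 outright cannot be scored
comparably.

Stratification sorts samples by `(score, input index)` (a stable sort, so
ties keep file order) and cuts at ranks `⌊n/4⌋` and `⌈3n/4⌉`: the bottom
block is EMT-low, the block above the upper cut EMT-high, the rest
intermediate. With distinct scores and `n` divisible by 4 this is exactly
n/4 / n/2 / n/4 and coincides with thresholding at the 25th/75th
percentiles; for other `n` the rank rule is the definition, chosen because
a percentile threshold is ambiguous under boundary ties while a rank cut
is bit-reproducible. Reported quartiles and IQR use linear-interpolation
("type 7") quantiles, numpy's default.

## Signature scores and the TIME marker table

A signature score is the unweighted mean z-score of the member genes
present — the minimal aggregation consistent with the EMT score itself
(each side of the EMT panel is exactly such a signature, and a one-gene
signature reduces to that gene's row). GSVA/ssGSEA-style rank enrichment
is deliberately out of scope. The packaged
`data/signatures_synthetic.gmt` is a synthetic stand-in: representative
published gene memberships for the eight named signatures (6-gene IFNG,
13-gene inflammatory, 9- and 3-gene exhausted CD8, activated stroma,
hypoxia, cytolytic activity, TAM), not an authoritative curation; any GMT
file can replace it.

The unified marker table inner-joins, on sample IDs, the immune-cell
enrichment table (consumed as produced by xCell-style tools, never
recomputed), checkpoint- and cytokine-gene z-score rows, and signature
scores — 17 + 17 + 17 + 8 = 59 markers by default. Checkpoint/cytokine
names common in the literature are resolved to official symbols through
an editable alias table (PD1→PDCD1, PD-L1→CD274, PD-L2→PDCD1LG2,
TIM3→HAVCR2, GITR→TNFRSF18, TNFA→TNF, KIR→KIR3DL1, VISTA→VSIR,
NOX2→CYBB). Markers keep their native scales; no re-standardization is
applied before testing.

## Group contrasts

Per marker: delta median = median(high) − median(low); two-sample KS of
high vs low (D = sup |ECDF difference|; exact p when n·m ≤ 10,000, else
the asymptotic Kolmogorov distribution — scipy's two branches); one-way
fixed-effects ANOVA across the three groups (zero pooled within-group
variance is an error, not an F of 0/0); Spearman rank correlation with
the continuous score (robust to the heavy right tails of enrichment
scores; Pearson behind a flag). Missing values are excluded pairwise. A
marker whose data cannot support a test carries NaN plus a note in its
result row — nothing is silently dropped. P-values are reported raw, to
match the `*`/`**`/`***` banding convention (p < 0.05 / 0.01 / 0.001);
Benjamini–Hochberg across a landscape is available as an option.

## PCA, conditional probabilities, K-means

Two profile matrices are analyzed: per-(cohort, EMT group) marker medians
(3 rows per cohort) and per-cohort delta profiles (high-minus-low
medians). Columns are standardized before PCA by default because markers
live on incommensurate scales; raw-covariance PCA is a flag. Components
come from a full SVD of the centered matrix, so explained-variance
percentages sum to 100 and per-component marker contributions
(100·loading²/Σloading²) sum to 100. Top contributors are ranked by PC1
contribution with alphabetical tie-breaks.

"High expression" for conditional probabilities means value ≥ the pooled
median across the cohort's assigned samples (any quantile is
configurable); `P(high | group)` is a plain count ratio and therefore
satisfies the law of total probability exactly.

K-means on delta profiles uses Euclidean Lloyd iterations (tolerance
1e-8), 50 restarts, default seed 17, over K = 2…8 (capped at n−1 rows);
the mean silhouette width selects K, with ties resolved toward the
smaller K. Given the seed, assignments are deterministic, and the induced
partition is invariant to row order.

## Survival

Kaplan–Meier curves come from lifelines' product-limit estimator. The
k-sample log-rank statistic is computed in-package in the standard
Mantel–Haenszel form — hypergeometric variance with ties, chi-square from
the first k−1 groups against the pseudo-inverted covariance — because the
result type exposes per-group observed and expected event counts; the
tests cross-check it against lifelines' implementation to 1e-9. OS and
PFI records with a missing time or event are dropped per-endpoint, not
per-subject; "PFS"/"PFI" are treated as one progression endpoint.

## Synthetic cohorts

The generator is linear-Gaussian in a latent per-sample EMT axis
`a ~ N(0, 1)`: mesenchymal panel genes are `+a + noise`, epithelial
`−a + noise`, each TIME marker gene `baseline + β·a + noise` (noise SD 1
by default), after which genes are re-standardized per cohort so the
files look like distributed z-score matrices. Enrichment scores are
`softplus(baseline + β·a + noise)`, keeping them non-negative like real
deconvolution output. Default couplings mirror the association pattern
the pipeline is designed to detect — macrophages, Th1 cells, most
checkpoints, TGFB1 and IL10 positive; IL3/IL4/IL5/IFNA1 and PD-L1 null;
Tregs and CD8+ T cells mildly negative — with 400 samples per cohort.

Survival times are exponential with hazard
`h0 · HR^e`, where `e` is 1 / 0.5 / 0 for the high / intermediate / low
group (groups taken from the pipeline's own stratification of the
generated expression), so hazards are monotone across groups and the
high-vs-low ratio equals the configured HR (default 2). `h0` is 1/1000
per day and 30% of subjects are censored uniformly before their event
time — a realistic fraction for cohort survival tables. At these
defaults the high-vs-low log-rank at n = 300 rejects at p < 0.01 in
roughly 84% of cohorts; the planted effect is unambiguous (a 5× hazard is
detected at p < 0.001 essentially always), but detection of a 2× ratio
at this censoring level is not near-certain, which the acceptance report
measures rather than hides.

Multicohort bundles draw each cohort from one of ≥ 2 archetypes that
scale the whole coupling vector (default scales 1.0 and 0.0, i.e. one
cluster of cohorts with a strongly shifted EMT-high microenvironment and
one with decoupled markers), plus per-cohort jitter of SD 0.05 —
the two-cluster structure the delta-profile K-means is expected to
recover. All randomness flows from a single integer seed; the same seed
reproduces a bundle bit-identically.

What the generator does **not** emulate: gene–gene correlation beyond the
shared axis, cohort-specific library or batch effects, non-linear or
saturating marker responses, informative censoring, and any relation
between enrichment scores and the very genes that would drive them in a
real deconvolution. Passing tests therefore demonstrate that the
statistics recover planted monotone, linear-in-the-axis structure at
realistic noise — not that the biological claims hold in real cohorts.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale: single
cohorts of 120–400 samples, ~160 genes (panel + marker + signature + 50
background genes), multicohort bundles of up to 22 cohorts, 200–1000
Monte-Carlo replicates — a full run of both completes in well under a
minute on one CPU. Pipeline outputs are TSV with `%.10g` floats and
sorted manifests, making seeded runs byte-deterministic (verified by
checksum comparison in both the tests and the acceptance script).

## Known limitations

Gene symbols are matched case-sensitively with no alias resolution beyond
the shipped checkpoint/cytokine table; signature membership defaults are
stand-ins (see above); no multiple-testing correction is applied by
default; Cox models, covariate adjustment and figure rendering are out of
scope. For n not divisible by 4, the rank-cut stratification can differ
by one sample from a percentile-threshold rule — the rank rule is the
contract.
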