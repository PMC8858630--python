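# Methods

This note records the models, parameter choices and numerical conventions
behind `psnpipe`, and what the synthetic-cohort tests do and do not establish
about real data.

## Quality control and normalization

Genes detected (nonzero) in fewer than 5 cells are removed first, at load,
then the cell filters are applied — this is the order the upstream toolchain
imposes (gene filtering happens at object creation). Cell retention bounds are
inclusive: the removal rules are phrased as strict inequalities ("fewer than
200 genes", "more than 15%", "more than 60,000 UMIs"), so cells sitting
exactly on a bound are kept. Mitochondrial genes are identified by the
case-insensitive symbol prefix `MT-`, the community convention. Both filters
are idempotent, and the suite documents that swapping the gene/cell order can
only change results through the detected-gene counts that the `min.cells`
rule alters.

Normalization is `ln(count / cell_total × 10⁴ + 1)`, computed on sparse data
so zero counts stay exactly zero; for every cell with positive total,
`Σ_genes (e^value − 1) = 10⁴` to floating-point precision (a tested
invariant). Cells with zero total are normalized to all-zero with a warning.

Variable genes are ranked by a vst-style standardized variance: per-gene
mean/variance of the raw counts, a mean-variance trend fitted on the log10
scale, per-entry z-scores using the trend-predicted sd clipped at √n_cells,
and the gene statistic is the variance of the clipped z. The trend is a
degree-2 polynomial with a tiny ridge (10⁻⁸) on the non-intercept terms
instead of a LOESS — deterministic, dependency-free, and a declared
approximation of the reference method. With fewer than 3 distinct gene means
the ranking falls back to raw variance (logged).

Doublets are flagged by marker co-expression: a marker set counts as
expressed in a cell when strictly more than half of its genes are nonzero
after normalization, and cells expressing two or more sets are flagged. The
50% floor is this package's choice; the source procedure gives no
quantitative rule.

## CNV signal and malignant calling

The copy-number proxy is intentionally minimal: per gene, subtract the
reference-cell mean (reference = normal epithelial, T, endothelial and
fibroblast cells), clip residuals to ±3, smooth along genome order within
each chromosome with a centred moving average of 101 genes (shrinking at
chromosome edges and on short chromosomes), recentre each cell by its median,
and subtract the reference-cell mean of the smoothed signal. It reproduces
the qualitative block structure a correlation classifier needs; it is not an
HMM segmentation and infers no discrete copy states.

The per-cell CNV score is the mean square of the re-standardized signal.
Cells are ranked by that score (a sum over genes ranks identically at fixed
gene count), and the ⌈5%⌉ top-scoring cells — minimum one — define the
reference vector as the gene-wise mean of their **signed** signals. Averaging
signed signals rather than squared scores preserves the
amplification/deletion sign that the correlation needs; the squared variant
is available behind the same interface. A cell is malignant when the Pearson
correlation between its signal and the reference vector strictly exceeds 0.3,
computed over the full gene vector; zero-variance cells have undefined r and
are non-malignant, flagged. Calls are made per patient on the pooled GG +
solid samples, and only epithelial-compartment cells are eligible for a
malignant call.

Chromosome order is natural (1..22, X, Y, then others), ties broken by start
position then gene id.

## NMF programs and meta-programs

Per sample, malignant-cell expression is z-scored per gene (zero-variance
genes dropped), negatives set to zero, and factorized with NMF (NNDSVD
zero-fill initialization, coordinate descent, tolerance 10⁻⁴, ≤ 500
iterations — deterministic) at each rank in 6..9 (tests and the acceptance
study use the scaled range 4..6). Samples with fewer than 20 malignant cells
are skipped with a log entry. A program is a factor's top 50 genes by
loading, ties broken by gene id; it is robust when it shares at least 35
genes with a program at a different rank.

Robust programs are pooled per clinical group (GG and solid separately) and
clustered hierarchically with distance = 50 − overlap and average linkage.
"Manual inspection" of the dendrogram is replaced by a deterministic cut at
height 15 (= 50 − 35), keeping the meta-program criterion commensurate with
the robustness criterion; clusters spanning ≥ 2 samples become meta-programs.
A core gene must appear in at least ⌈25% × members⌉ member programs spanning
at least two samples — one concrete reading of an ambiguous prose rule; both
the fraction and the cross-sample requirement are switchable arguments. GG
and solid meta-programs are matched afterwards by core-gene Jaccard for
reporting only. Functional annotation is a user-supplied label; ontology
enrichment is out of scope.

## Signature scores

For a gene set, every cell's score is the mean normalized expression of the
set genes minus the mean of a pooled background: for each set gene, 100 genes
drawn from its expression bin (25 equal-count bins on the gene means over all
cells), excluding set members (preventing self-matching bias; drawn with
replacement only when the bin is too small). Missing genes are dropped with a
warning; a fully absent set is an error. Per-set random streams are derived
from (seed, SHA-256 of the set name), so adding or reordering sets never
perturbs the others. Scoring is done on the pooled cohort so the bins — and
hence the matched background — are shared across samples; per-sample binning
would absorb exactly the group-level shifts the mixed model tests.
A constant added to all genes of one cell cancels between foreground and
background (tested), and the all-genes set is its own background population.

## Group statistics

Composition tables are per-sample fractions over a stated denominator
(immune cell types by default). Group comparisons use the two-sided Wilcoxon
rank-sum test (paired by patient for GG vs solid), BH-adjusted per panel
(one family per comparison across cell types). The exact/asymptotic switch —
unstated in the source, which delegated to its stats environment — is: exact
enumeration for the unpaired test when n₁+n₂ ≤ 12 with no ties, and for the
paired test when n ≤ 15 with no zero or tied differences; otherwise the
normal approximation with tie and continuity corrections. All-zero paired
differences give p = 1, flagged. Note the standard BH step-up adjustment is
not idempotent on its own output; the suite verifies it against a brute-force
step-up implementation instead.

The mixed model `score ~ group + (1 | patient)` is estimated by REML using
per-patient sufficient statistics: for a single random intercept the
covariance inverse and determinant have closed forms per patient, so the
profiled REML criterion is optimized over the variance ratio by bounded 1-D
search (tolerance 10⁻⁸) with an explicit boundary check at zero patient
variance. Fixed effects use treatment coding with nLung (else GG, else first
sorted level) as reference. Satterthwaite degrees of freedom are
2φ²/Var(φ) with φ the contrast variance, its gradient over the variance
components taken by central differences and Var(θ̂) from the inverse Hessian
of the REML criterion. When the patient variance is estimated at the
boundary the model reduces to OLS and the residual degrees of freedom are
reported with a flag. The implementation reproduces lmerTest to ≥ 5 decimals
on a frozen dataset, matches the two-sample t-test exactly in the
zero-patient-variance case, and is calibrated in simulation (uniform null
p-values; 95% CI coverage ≈ 0.94). Group comparisons are separate two-group
fits per panel, matching per-panel significance stars; a joint multi-level
fit is available through the same function.

## Ligand–receptor communication

The external package's mass-action model is deliberately replaced by a
declared simplified score: L (R) is the sender (receiver) group mean of the
per-cell geometric mean over ligand (receptor) subunits of normalized
expression, and the communication probability is the Hill function
`L·R/(0.5 + L·R)`. Zero ligand or receptor expression gives probability
exactly 0. Groups below 10 cells are skipped. Significance is a one-sided
permutation test: cell labels shuffled globally, all probabilities
recomputed, `p = (1 + #{perm ≥ obs}) / (1 + n_perm)` with n_perm = 999 by
default (type-I error ≈ 0.05 in simulation); observed probability 0 gives
p = 1 by convention. One shared permutation stream serves all pairs; BH is
applied within each sender–receiver family.

## The synthetic cohort

`simdata.default_config` mirrors a 12-patient cohort with paired GG/solid
samples and nLung tissue for 5 patients, at 300 cells per sample over 1000
genes on 10 chromosomes plus an MT contig — sizes chosen so the full pipeline
runs in seconds while leaving every planted effect detectable; the acceptance
studies state their own sizes (e.g. 6 patients × 300 cells for malignant
calling, 3 patients × 600 cells for meta-program recovery, reflecting that
program discovery needs on the order of 10² malignant cells per sample).

Counts are gamma-Poisson (negative binomial, dispersion 0.3) around
`libsize × softmax(log baseline + CNV log-fold + Σ activity × loading +
group shifts)`, with lognormal library sizes and a fixed 5% of each library
allocated to `MT-` genes. Eight cell types with 5 dedicated marker genes each
follow group-specific abundance weights (myeloid/NK decline and T/B rise
from nLung to solid; the malignant type only exists in tumour samples). The
malignant type shares the epithelial baseline and carries fold-2
amplifications on chromosomes 1–2 and a fold-0.5 deletion on chromosome 3 —
contiguous, as real CNVs are. Three 50-gene expression programs switch on in
~35% of malignant cells (two-component off/on activity mixture); their genes
are deliberately interleaved across chromosomes 4–9 and floored to expressed
baselines, because real co-expression programs consist of expressed genes
scattered over the genome — were they contiguous they would masquerade as
copy-number segments. A "stress" signature (30 scattered genes) is shifted
+0.7 log-units in the solid group. QC-violating cells are planted in exact
per-class counts by direct count surgery (subsampling detected genes,
inflating mitochondrial or total counts), and unplanted cells are nudged back
into compliance if sampling noise trips a rule, so the planted class labels
are exactly consistent with the counts; planting `high_genes` cells requires
a gene universe larger than 6000.

All randomness flows from one integer seed through a `SeedSequence` tree
(one child per sample, one for global model parameters); identical
config + seed reproduces byte-identical fixtures.

What passing tests show — and do not. The simulator exercises the pipeline's
discriminative machinery under a controlled truth; it does not model ambient
RNA, batch effects, doublets (beyond synthetic marker-sum constructions),
transcriptome-wide co-expression, or realistic gene-length/GC structure.
Recovery rates measured here (e.g. malignant-call sensitivity/specificity
≈ 0.99 at fold-2 CNVs) are upper bounds for data with weaker or subclonal
CNV signal, and the plumbing k-means label fallback is no substitute for
curated cell-type annotation.

## Degenerate inputs and tie-breaks

Empty samples write and read as valid zero-entry matrices. Zero-total cells
normalize to zero with a warning. Constant genes are never selected as
variable and are dropped before NMF. Gene ties in program extraction and
expression binning break lexicographically by gene id; cell ties in the
top-5% CNV ranking break by cell order (stable sort). Chromosomes shorter
than the smoothing window shrink the window to the chromosome. Correlation
against the CNV reference is undefined for zero-variance cells: they are
non-malignant and flagged rather than guessed.
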