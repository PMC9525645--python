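# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
desk-scale problem sizes used by the test suite and the acceptance script.

## Data model and preprocessing

`CellMatrix` holds sparse genes × cells counts with per-cell metadata
(sample, condition ∈ {tumor, normal}, cell type, optional 2-D embedding and
doublet score). QC keeps cells with total UMI ≥ 700 and doublet score ≤ 0.4
— the inequalities are applied literally ("fewer than 700" removes 699 and
keeps 700; "above 0.4" keeps exactly 0.4) and the filter is idempotent.

Normalization scales each cell to a common depth (default 10,000 counts)
and maps entries through `log(1 + x/pseudocount)` (natural log, pseudocount
1 by default). This is the dominant single-cell convention; the scale
factor, pseudocount and log base are configurable because every downstream
statistic is rank- or mean-based and none depends on the specific choice.
An all-zero cell stays all-zero, and proportional cells map to identical
columns.

Gene symbols are case-sensitive strings; duplicate symbols are rejected at
read time (first occurrence wins under a permissive flag, logged). Cells
without a cell-type label are excluded from per-type statistics, logged.

## Rank-sum policy

All two-group comparisons (signature scores, proportions) use the two-sided
Wilcoxon rank-sum test with one shared policy: exact null distribution when
there are no ties and total n ≤ 20; exact enumeration over all label
assignments when there are ties and total n ≤ 14 (so identical score
multisets give p = 1 exactly); otherwise the normal approximation with tie
and continuity correction. Degenerate inputs (all values equal) return
p = 1. Signed Z values are defined as the normal quantile of p/2, so |Z|
and p are always mutually consistent.

## Differential cell density

Each sample gets a Gaussian KDE (Scott-type plug-in bandwidth, full 2-D
covariance) on a shared grid over the joint embedding bounding box (5 %
margin); densities are renormalized so density × bin area sums to 1, which
confines the kernel mass to the analysis window. The default grid is
400 × 400; the test suite runs at 100 (and some unit tests smaller) purely
for speed — the statistics are per-bin and do not change character with
resolution. Per-sample density vectors are quantile-normalized (ties map to
the mean of their tied reference quantiles, so the transform is
rank-preserving within sample). The tumor-vs-normal comparison is a per-bin
Welch (unequal-variance) *t*, reported as a signed Z via the p ↔ Z mapping
above; bins with fewer than 1 cell across all samples are masked, and bins
with zero variance in both groups and equal means get Z = 0. The Z map is
antisymmetric under swapping condition labels.

## Compositional analysis

Cell-type fractions are closed after replacing zero counts by half a cell —
the standard multiplicative replacement, since log-ratios are undefined at
zero. ILR coordinates use an orthonormal Helmert-type contrast basis; the
two-group canonical discriminant axis is w = S_w⁺(m₁ − m₀) with pooled
within-class scatter (pseudo-inverse for robustness at small n), oriented
so the tumor mean projects positive, and mapped back through the basis to
CLR space. CLR coefficients sum to zero and are invariant to the basis and
to cell-type order (both tested). The bootstrap resamples samples with
replacement within each condition, then draws a fixed cell budget per
condition (default 1000) allocated across the drawn samples proportionally
to their cell counts, as multivariate-hypergeometric draws of type counts
within each sample — "resampling of samples and cells" with an explicit,
reproducible scheme.

## Expression distance

Pseudobulk profiles sum counts per (sample, cell type); profiles under 10
cells are excluded. The pair distance is 1 − Pearson correlation of
CPM-scaled, log1p-transformed profiles over the genes expressed in at least
one profile of the pair (avoiding zero-variance degeneracies). The
per-type normalized distance divides the median between-condition pair
distance by the median within-condition distance, after averaging pair
distances over rounds (default 100) in which every contributing profile is
subsampled without replacement to the minimum cell count among them —
equalizing cell numbers so coverage differences do not masquerade as
biology. Significance comes from permuting condition labels at the sample
level with the add-one estimator p = (1 + #{perm ≥ obs})/(1 + n_perm);
with fewer than 20 distinct label splits the test switches to exhaustive
enumeration. The overall sample distance is the proportion-weighted average
of per-type distances with weight min(proportion in s, proportion in t) —
a type absent from either sample contributes nothing — and pairs sharing no
type get the matrix maximum imputed (logged). 2-D projection is classical
(Torgerson) MDS via double centering.

## Markers, DE, and signature selection

Markers are one-vs-rest rank-sum tests per gene per cluster, computed
vectorized on shared ranks with tie correction; for tiny problems
(total n ≤ 20) the exact per-gene p is used, so the reported Z matches
brute-force enumeration. A gene is a marker at Z > 3. On exchangeable null
data the flag rate stays below 1 % (two-sided normal tail at 3 ≈ 0.27 %
plus estimation noise).

Pseudobulk DE is a per-gene negative-binomial GLM (mean/dispersion
parameterization, variance μ + μ²/θ) with a condition factor and a log
total-count offset: Wald p on the condition coefficient, log2FC = β/ln 2
reported tumor-vs-normal, BH adjustment. Dispersion is estimated per gene
by maximum likelihood with a Poisson GLM fallback on solver failure. This
is a deliberately plain NB contract rather than a DESeq2 replication:
downstream use is rank- and sign-based (top-N lists, log2FC > 0 filters),
so shrinkage and outlier refinements would not change the pipeline's logic.

The metastatic-signature procedure runs two rounds. Round 1 ranks genes by
one-vs-rest Z of the target tumor subclone against the other subclones
(positive Z only, top N, ties broken by |log2FC| then symbol). Round 2
enforces specificity: a gene must have positive rank-sum Z of the target
against *every* non-tumor population pairwise, ranked by its minimum
pairwise Z. One-vs-rest would let a gene shared with one minority
population slip through, because that population dilutes into "the rest";
the pairwise minimum is the operational reading of "specifically
expressed". The final signature is the intersection ordered by round-1
rank; an empty intersection is a valid, warned outcome. The choice of N
should be commensurate with the gene-pool size (the benchmarks use top-12
of 120 genes, mirroring a top-100-of-20k regime).

## Ligand–receptor inference

Candidates are (pair, sender, receiver) triples whose ligand is detected in
strictly more than 10 % of sender cells and receptor in more than 10 % of
receiver cells. The score is the product of mean normalized expression of
the ligand over sender cells and the receptor over receiver cells. The
null shuffles cell-type labels globally (type sizes preserved) and rescores
every triple per permutation; p is the add-one estimator compared per
triple, BH-adjusted across all triples. Two filters follow: specificity
(marker Z of the ligand in its sender and the receptor in its receiver both
≥ 3) and tumor upregulation (pseudobulk log2FC strictly > 0 for ligand and
receptor in their respective types; an "either" mode exists because the
requirement can be read either way — "both" is the stricter default).
Multi-subunit complexes are not modeled; the pair table is gene-to-gene.

## Survival

Samples are scored by the mean log-scale expression of the signature genes
present (≥ 2 required), stratified into the top ⌊0.25 n⌋ ("high") and
bottom ⌊0.25 n⌋ ("low") by empirical order statistics — exact floor-sized
groups, ties broken by stable sample order, middle 50 % excluded — and
compared with the two-sided log-rank test (lifelines). The reproducibility
power p resamples the signature genes with replacement at original size for
100 rounds, repeats score → stratify → test, and reports the 0.95 quantile
of the p-values; it is monotone in the quantile and conservative under the
null by construction. Zero observed events give statistic 0, p = 1, with a
warning. Expression is assumed log-scale; a log1p flag serves raw-count
cohorts.

## Synthetic cohorts

`simulate_cohort` draws, per sample: a cell count (NB around a mean), a
cell-type composition from a Dirichlet with concentration 50 around the
condition's target proportions (tumor targets are the baseline multiplied
by the planted compositional effects, re-closed), and per-cell NB counts
with mean μ = baseline gene mean × cell-type marker fold × condition DE
fold × a log-uniform per-cell depth factor in [0.5, 2], variance μ + μ²/θ
(θ = 10). Baseline gene means are log-normal (σ = 1). Each type gets a
Gaussian blob in the 2-D embedding (centers on a circle) and 10 marker
genes at 8-fold by default. Ligand–receptor plants multiply the ligand's
mean in the sender type and the receptor's in the receiver type (both
conditions — they model type-specific, not condition-specific, elevation).
Doublet scores are Beta(1.5, 15) with a planted Beta(8, 2) fraction equal
to the doublet rate. One global seed drives named `SeedSequence` child
streams (composition, counts, embedding, doublets, depth, sizes), so output
is bit-reproducible.

`simulate_bulk_survival` draws standard-Gaussian log expression, event
times exponential with rate ∝ exp(log HR × standardized signature mean),
and independent exponential censoring tuned to the requested censoring
fraction under the null.

What the generator does **not** emulate: ambient RNA, batch and patient
effects, realistic manifold geometry beyond Gaussian blobs, gene–gene
correlation beyond the planted structure, or zero inflation beyond the NB.
Passing tests therefore demonstrate calibration and recoverability under a
clean multi-sample NB world — necessary conditions, not guarantees about
any particular real data set.

## Desk-scale problem sizes

The Monte-Carlo properties are evaluated at sizes chosen once for
single-CPU desk runs (thresholds are never adjusted to them):

- proportion-test null: 200 cohorts, 10+10 samples × ~60 cells;
- distance-permutation null: 200 single-type cohorts, 4+4 samples,
  150 genes, 2 subsampling rounds, 199 permutations;
- ligand–receptor null: 200 cohorts, 3 types, 10 random pairs,
  199 permutations;
- density null: 100 cohorts, 5+5 samples, grid 100 × 100;
- planted recovery: 100 runs (composition, expression distance),
  50 runs (ligand–receptor), CoDA bootstrap 400 × 1000 cells;
- survival: 50 powered runs (log HR 0.7, n = 300, 10 genes, 100 bootstrap
  rounds) and 100 null runs.

A borderline note: a confound planted *exactly* equal in a second cell
type sits on the specificity test's decision boundary (the pairwise Z's
sign becomes a coin flip), so the signature benchmark plants the shared
gene slightly higher in the confounding type; the property then holds
across seeds.

## Known limitations

- The density Z map treats bins independently (no spatial smoothing of the
  test statistic) and its calibration is assessed marginally over bins.
- NB dispersion is a single global θ in the generator and a per-gene MLE in
  the DE model; neither models gene-wise dispersion trends.
- The LR permutation null preserves type sizes but not within-sample
  structure (labels shuffle across the aggregated matrix, matching the
  stated procedure); sample-level pseudoreplication is therefore not
  addressed by the p-value, only by the downstream DE filter.
- The reproducibility-power quantile is an empirical quantile of 100
  bootstrap p-values; its own Monte-Carlo error is of order a few
  percentiles.
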