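# scduet

Comparison statistics for **matched tumor / adjacent-normal single-cell
cohorts**, with a ground-truth synthetic generator so every stage can be
exercised and calibrated without any data download.

When the same patient contributes a tumor sample and an adjacent normal
sample, the interesting questions are *differences*: which cell types shift
in abundance, which transcriptional states move, which ligand–receptor
circuits light up, and whether a tumor-derived gene signature predicts
survival in bulk cohorts. `scduet` implements a coherent set of the
non-standard statistics used for exactly this design in kidney-cancer
single-cell studies:

| stage | statistic |
|---|---|
| QC / normalization | UMI ≥ 700 and doublet-score ≤ 0.4 filters; per-cell depth normalization + log1p |
| signature scoring | per-cell mean over a gene module; per-sample means; two-sided Wilcoxon rank-sum comparisons |
| differential density | per-sample Gaussian KDE on a shared 2-D embedding, quantile normalization, per-bin Welch *t* as a signed Z map |
| composition | per-type proportion rank-sum tests (BH-adjusted) and CoDA: ILR transform → two-group canonical discriminant axis → per-type separating coefficients in CLR space, with a samples-and-cells bootstrap |
| expression distance | per-(sample, cell type) pseudobulk; d = 1 − Pearson(log profiles); normalized distance = median(between-condition) / median(within-condition) over cell-subsampling rounds; sample-label permutation p; proportion-weighted overall sample distance + classical MDS |
| markers / DE | one-vs-rest Wilcoxon Z per gene (marker at Z > 3); pseudobulk NB-GLM tumor-vs-normal DE (Wald, BH) |
| metastatic signature | two-round top-N selection: target subclone vs other subclones, then specificity against every non-tumor population; final = intersection |
| interactions | LR score = mean(ligand in sender) × mean(receptor in receiver); >10 %-expressed screen; 1000-permutation null (shuffled cell identities), BH; specificity (marker Z ≥ 3) and tumor-upregulation (log2FC > 0) filters |
| survival | top/bottom-quartile stratification, two-sided log-rank; **reproducibility power p** = 0.95 quantile of log-rank p over 100 gene-bootstrap rounds |

The notation in brief: a normalized distance ≈ 1 means no condition effect;
a CoDA coefficient > 0 means enriched in tumor; an LR permutation p is
`(1 + #{permuted score ≥ observed}) / (1 + n_perm)`; power_p < 0.05 means at
least 95 % of gene-resampled signatures still stratify survival.

## Worked example

`examples/` holds one short script per capability. For instance, expression
distance on a cohort with planted tumor-cell DE
(`python examples/04_expression_distance.py`) prints:

```
             normalized_distance  permutation_p
endothelial                1.001          0.537
fibroblast                 0.989          0.752
macrophage                 0.937          0.856
tcell                      1.024          0.375
tumor                      1.617          0.008
```

Unaffected cell types sit at ≈ 1 (between-condition pairs no farther apart
than within-condition pairs); the tumor cells, which carry the planted
condition-specific expression change, stand out at 1.62 with permutation
p = 0.008. Similarly, the survival example
(`python examples/07_survival.py`) prints

```
log-rank chi2=55.4, p=9.85e-14
reproducibility power p (0.95 quantile over 100 gene bootstraps): 1.93e-05
```

for a 300-sample cohort whose hazard is log-linear (log HR 0.7 per SD) in a
10-gene signature score.

A config-driven runner is also available (`scduet run-all --profile test
--seed 1 --outdir out/`), writing every stage's tables plus a manifest; see
`scduet --help`.

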