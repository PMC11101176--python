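# sexbias

Analysis pipeline for **sex-biased gene expression in male/female stem-cell
differentiation RNA-seq timecourses**: given gene-level counts from XX and
XY cell lines sampled over a differentiation course (e.g. hESC lines
differentiated to neurons at D0/D4/D9/D37, three lines per sex, triplicate
differentiations), it identifies genes with robust sex-biased expression,
estimates X-chromosome-inactivation (XCI) erosion and X:A dosage in the
female lines, quantifies X/Y gametolog dosage compensation, classifies
expression trajectories, scores preranked gene-set enrichment and selects
candidate genes. A synthetic-data generator reproduces the full statistical
structure of such a study with planted ground truth, so every estimator in
the package is validated by parameter recovery.

Intended users: computational biologists analysing sex differences in bulk
RNA-seq cell-line panels, and anyone needing a tested, self-contained
implementation of the stringent sex-bias filter or the XX:XY ratio
machinery.

## The statistics at the core

**Normalization.** Median-of-ratios size factors
`s_j = median_g ( K_gj / (prod_j' K_gj')^(1/m) )` over genes expressed in
every sample, rescaled to geometric mean 1; CPM and TPM
(`tpm_g = 1e6 * (K_g / L_g) / sum_g' (K_g' / L_g')`) for dosage analyses.

**Differential testing.** Per-gene two-group negative-binomial contrast
(`Var = mu + alpha*mu^2`, method-of-moments `alpha`): Wald statistic
`z = log(mu_A/mu_B) / SE` with delta-method SE, two-sided Student-t
p-values, Benjamini–Hochberg adjustment.

**The stringent sex-bias filter.** A gene is sex-biased at a timepoint only
if *all* of: a cell line averages ≥ 50 normalized counts (≈ 2 CPM);
|log2FC| ≥ 0.5; adjusted p ≤ 0.05; coefficient of variation of per-line
means ≤ 0.5 within *both* sexes; and every one of the 9 cross-sex line
pairs differs by ≥ 20% (relative to the larger) in the direction of the
group difference — no line of one sex expresses the gene as high as any
line of the other.

**XCI erosion.** The fraction of X-linked genes (known escapees removed)
with pooled XX:XY TPM ratio > 1.1 estimates the eroded/biallelic share;
the same exceedance over baseline autosomes (chr5, chr16) is subtracted to
remove the noise floor. X:A dosage is the line's mean X-linked TPM over
each autosome's mean TPM.

**Gametologs.** For an X/Y homolog pair, `dose_XX = mean X expression in
XX`, `dose_XY = mean (X + Y) in XY`, `y_share = Y / dose_XY`. Pairs with
substantial Y contribution (mean y_share ≥ 0.2) form the
dosage-compensated group D; otherwise significant end-vs-start change
assigns A (down), B (up) or C (flat). Per-timepoint sex differences in
combined dosage are tested on per-line values with Šidák correction
`p_adj = 1 − (1 − p)^m`.

**Trajectories.** Each expressed gene is classed by the timepoint of its
maximal mean expression (peak_D4/peak_D9/peak_D37, `decreasing` when the
maximum is at D0) or `stable` when max/min ≤ 1.5.

**Enrichment and candidates.** Preranked GSEA on the DE `stat`: weighted
Kolmogorov–Smirnov running sum (hits step `|s|^w / Σ|s|^w`, misses
`−1/(N − n)`), gene-label permutation null, NES, pooled-null FDR q, and
leading-edge (core-enriched) extraction. Candidates are final-timepoint
sex-biased genes with ≥ 1 neuro-implication flag and expression above the
70th percentile (nearest-rank) of the flagged set.

## Worked example

Simulate a study-design dataset (3+3 lines × 4 timepoints × 3 replicates,
2,300 genes with 23 Y-linked and 300 X-linked, 20 planted sex-biased
genes) and run the whole pipeline:

```bash
sexbias simulate --seed 7 --n-planted 20 --outdir demo
cat > demo/config.yaml <<EOF
counts: demo/counts.tsv
samples: demo/samples.tsv
annotation: demo/annotation.tsv
outdir: demo/out
n_perm: 200
seed: 7
EOF
sexbias all --config demo/config.yaml
```

`demo/out/table2_summary.tsv` then reads:

```
timepoint  direction  chrY  chrX  chrX_escapee  autosomal  total
D0         female_up     0     0             0         10     10
D0         male_up      23     0             0         10     33
D4         female_up     0     0             0         10     10
D4         male_up      23     0             0          9     32
D9         female_up     0     4             4         11     15
D9         male_up      23     0             0          9     32
D37        female_up     0     1             1         10     11
D37        male_up      23     0             0         10     33
```

All 23 expressed Y-linked genes are male-biased at every timepoint (they
are silent in XX lines), the occasional female-biased X genes are XCI
escapees whose 1.29× dosage sporadically clears the 1.41-fold cut, and the
planted autosomal effects (10 male-up, 10 female-up) are recovered — at
D37 the filter finds 20 of 20 planted genes with no false autosomal call.
`xci_line_summary.tsv` shows per-line fractions of X genes above the 1.1
ratio threshold (~0.17 here) matched by the chr5/16 baseline, so the
erosion-attributable fraction is 0 — this simulation planted no erosion.
With default Y:X dosage ratio 1, all 12 gametolog pairs land in group D
(`gametolog_groups.tsv`, mean y_share ≈ 0.5): the Y homolog fully
compensates the pair dosage.

Every stage is also available separately (`sexbias de`, `filter`, `xci`,
`gametologs`, `timecourse`, `enrich`) and as library functions.

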