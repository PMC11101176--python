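# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `sexbias` package, in the order the pipeline runs.

## Study design and data model

The pipeline assumes a sex-balanced cell-line panel: `L` cell lines per
sex (default 3), each differentiated in `R` replicate experiments (default
3) and sampled at ordered timepoints (default D0 < D4 < D9 < D37; the
ordering is declared on the sample sheet, never parsed from labels, so
designs with extra timepoints such as D17/D27 extend without code
changes). Counts are gene-level integers; gene metadata supplies
chromosome, length, a user-supplied XCI-escapee flag and an X↔Y gametolog
partner link. All analyses treat the **cell line** as the biological unit:
replicates are averaged into line-level values wherever between-sex
comparisons are made, because replicate differentiations of the same
clonal line are not independent draws from the sex.

## Synthetic data generator

The generator is first-class, tested code: it is how every estimator in
the package is validated, since the real quantities (erosion fractions,
sex effects) have no ground truth in experimental data.

Counts are negative binomial, `K ~ NB(mean = s_j · mu_g,l,t, Var = mu +
alpha·mu²)`, drawn as gamma–Poisson. The condition mean factorises into

* a lognormal baseline per gene (location `log 200`, scale 1.0 — a
  typical bulk RNA-seq abundance spread that puts most genes above the
  50-count floor while retaining a low-expression tail);
* a trajectory multiplier (default mixture: 29% stable, 5% peak-D4, 6%
  peak-D9, 34% peak-D37, 26% decreasing; peak fold 3.0) mirroring the
  proportions such differentiation timecourses report;
* a per-(gene, line) lognormal jitter (sigma 0.1 on the log2 scale) so
  within-sex line-to-line variation is nonzero — without it the CV and
  pairwise filter rules would be vacuous;
* sex factors: Y genes are exactly zero in XX samples by default (an
  optional Poisson leak models mismapping); escapee X genes get a 1.29×
  XX dosage (the average biallelic excess reported for XCI escapees);
  eroded (gene, line) combinations get a 2× boost; planted sex-biased
  genes shift by ±log2FC/2 per sex at their designated timepoints.

**Dispersion default.** `alpha = 0.02` models
*replicate-level* noise of clonal cell lines (per-sample CV ≈ 15% at high
counts), the regime in which triplicate differentiations of the same line
actually operate; between-line biological variation enters separately
through the jitter term. With a between-individual-style `alpha = 0.1`
the per-replicate CV is ~32% and the all-9-pairwise 20% rule would reject
a quarter of genuinely two-fold genes at 3 replicates — a noise regime in
which the published filter could not have produced stable gene lists.

**Erosion is nested across lines.** Each non-escapee X gene receives a
rank in a single erosion-propensity order; a line with erosion fraction
*f* reactivates the top-*f* slice. Culture-induced reactivation recurs at
the same loci across lines, and the nesting makes planted truth analytic:
a gene eroded in *k* of *n* XX lines has expected pooled XX:XY ratio
`(k·boost + (n−k))/n` (`truth_expected_ratio` returns these values, the
oracle used by the recovery tests).

**Planted effects are detectable by construction**: sex-biased genes are
drawn among autosomal genes with baseline mean ≥ 100, so "recall" measures
the filter, not the lottery of planting an effect on a silent gene.

Seeding: one master seed spawns per-stage child streams
(`numpy.random.SeedSequence`), so identical configs reproduce bit-identical
matrices and stages can be varied independently.

What the generator does **not** emulate: batch effects beyond per-line
jitter, gene–gene correlation, length-dependent biases, isoform structure,
and mismapping between X/Y homologs. Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under the
stated model, not robustness to artefacts absent from it.

## Normalization

Median-of-ratios size factors use only genes with nonzero counts in every
sample; if none exists the function refuses and points to a pseudo-
reference fallback rather than silently degrading. Factors are rescaled
to geometric mean exactly 1 — the estimator is scale-free, and pinning the
geometric mean makes normalized counts comparable across runs and satisfies a strict
invariant instead of an approximate one. The median is taken in linear
space (median of `K/geomean`), which matters for even gene counts.

TPM divides by gene length in kb and renormalises each sample to 1e6; it
is used for the dosage analyses (XX:XY ratios, X:A), where length
normalisation puts chromosomes with different gene-length spectra on one
scale. TPM is compositional: planting strong erosion deflates all other
ratios in XX samples by the added X expression (~6% at a 20% erosion
fraction with 600/1800 X genes). The baseline subtraction inherits this
shift, which is why the erosion estimate stays accurate.

## Differential testing

`nb_wald` fits the two-group NB contrast per gene: the group log-mean
difference (pseudo-count 1 normalized count, so all-zero groups stay
finite), delta-method SE `sqrt((1/mu_A + alpha)/n_A + (1/mu_B + alpha)/n_B)`
with a pooled per-gene method-of-moments dispersion floored at 1e-8 — no
empirical-Bayes shrinkage, deliberately: shrinkage is engine-specific
machinery, and the stringent post-hoc filter (not the DE engine) drives
the final gene lists. An externally produced DE table in the same schema
can be supplied instead (`de_table` in the pipeline config).

The p-value uses a **Student-t reference with `n_A + n_B − 2` df**, not a
normal one. With 9 + 9 samples and an estimated SE, the normal reference
is measurably anticonservative (empirical type-I 0.060–0.080 at nominal
0.05 across seeds); the t reference restores 0.046–0.059. This is the
standard small-sample correction when no dispersion shrinkage stabilises
the SE. The signed `stat` column (which feeds GSEA) is unaffected.

Calibration is defined — and tested — under an *exchangeable* null (no
planted effects, no per-line jitter). A line-level random effect is a
real group-structure effect: with it present, within-group samples are
correlated and no two-group test on samples is calibrated (measured
type-I ≈ 0.12 regardless of reference distribution). The pipeline's
defence against line structure is the CV and all-pairwise rules, which
operate on line means; this is why the stringent filter's null false-call
rate stays ≈ 0 even with jitter on.

`welch_log` (Welch t on log2(x+1)) is available as a distribution-free
alternative. BH step-up is the default multiple-testing adjustment
(Bonferroni available); it is re-implemented and cross-checked against an
independent reference implementation in the tests.

## Stringent sex-bias filter

The five criteria and their defaults are listed in the README. Numerical
choices worth recording:

* the CV uses the population (n) standard deviation over line means
  (configurable `cv_ddof`); with three lines the n vs n−1 choice shifts
  the CV by 22%, so it must be pinned;
* all line means zero in one sex gives CV **0**, not ∞ — uniform silence
  is perfectly consistent expression. Without this rule every Y-linked
  gene (silent in XX) would be discarded by the very filter whose main
  output includes them;
* the pairwise rule's denominator is the larger of the two values — the
  symmetric and stricter choice — and a direction-consistency condition
  is included: all 9 pairs must deviate in the sign of the group-mean
  difference (a gene whose lines interleave is not sex-biased no matter
  how large the differences);
* a zero/zero pair contributes difference 0 (fails), keeping the rule
  total;
* filtering runs per timepoint independently; no cross-timepoint
  consistency is imposed.

The filter is monotone in every threshold (tested), and the vectorised
implementation is verified gene-for-gene against a naive nested-loop
implementation on random fixtures.

## XCI erosion and dosage

Ratios use pooled means (all XX samples over all XY samples) or per-line
mode (each XX line over the pooled XY mean — the construction implied by
per-line erosion percentages). Genes below 1 TPM in the XY denominator
group are excluded (a denominator guard; the floor is configurable). The
threshold is strict (`> 1.1`): a gene at exactly 1.1 is not called.

The erosion-attributable fraction is `max(0, frac_above − baseline_frac)`
with the baseline computed as the *fraction* of chr5/16 genes above the
same threshold — not their mean ratio — because only a fraction can be
subtracted from a fraction to give a gene count. A mean-shift reading of
the baseline is dimensionally incompatible with reporting "N of M genes
affected". The absolute count is `round(frac · n_tested)`.

X:A ratios are per line: mean TPM of expressed X genes over mean TPM of
expressed genes per autosome (floor 1 TPM), plus the unweighted mean over
autosomes. The between-line variance comparison reports the sample (n−1)
variance of per-line average X expression within each sex, their XY/XX
ratio, and a one-way ANOVA across lines on per-gene line averages.

## Gametologs

Group D (substantial Y contribution) takes precedence and is defined as
mean y_share ≥ 0.2 across timepoints — the threshold is a config knob and
y_share is reported per pair so users can re-cut. A/B/C are decided by a
two-group test (Welch on log2) of combined pair expression, last timepoint
vs first, at padj ≤ 0.05 and |log2FC| ≥ 0.5 (the same effect-size bar as
the DEG analysis).

Sex-biased dosage calls use per-line dosage values (line = unit) with a
two-sample t-test per timepoint and Šidák familywise correction over the
timepoints; a line-paired two-way OLS ANOVA (sex × timepoint with the
line factor absorbing stable offsets) is attached for reporting. This
approximates a repeated-measures design — the line factor captures the
repeated structure without fitting a full mixed model, which three lines
per sex cannot support.

## Timecourse classification

Timepoint means (pseudo-count 1) are compared by argmax with ties broken
toward the earlier timepoint; `stable` means max/min ≤ 1.5 — some cutoff
must separate "stable" from "peaked", 1.5 is conservative and the knob
(`stable_max_fold`) owns the decreasing-vs-stable boundary. Pooled sexes
by default; Y-linked genes should be classified with `sex="XY"`.

## Enrichment and candidates

The ES is the classic weighted running sum (weight exponent 1). The
degenerate whole-universe set has no miss step; the walk then compares the
weighted hit distribution against the uniform position expectation, which
keeps the ES near zero instead of trivially 1. The permutation null
reassigns membership uniformly at random (gene-label permutation — the
null matching preranked mode), p uses the add-one estimator with floor
`1/(n_perm+1)`, NES divides by the mean same-sign null magnitude, and the
FDR q is the pooled-null tail-fraction ratio capped at 1.

Candidate selection takes the final-timepoint sex-biased genes, flags them
by four neuro-implication sources (user-supplied GO slim and literature
flags; trajectory upregulation and GSEA core-enrichment computed by the
pipeline), and cuts at the nearest-rank 70th percentile of the *flagged*
genes' expression (strictly above) — the flagged subset is the reference
population, and both the subset and the convention are configurable.

## Problem sizes in the validation suite

The acceptance tests run: 50 brute-force filter comparisons at 200 genes;
planted recovery at 2,000 genes / 50 effects; erosion recovery at 600 X +
1,200 baseline genes over four erosion levels; calibration at 2,000 null
genes; 100 compensation runs of a 52-gene design; trajectory recovery at
2,500 genes; 200 permutation-calibration repetitions at 500 genes. These
sizes give sub-minute runtimes per test while keeping Monte-Carlo
standard errors well inside the asserted tolerances.

## Known limitations

* The DE model is a per-timepoint two-group contrast, not a joint
  sex × time GLM; genes whose sex effect is only visible against a shared
  time trend across all timepoints may be less powered.
* The XX:XY ratio approach assumes equal baseline X expression between
  sexes; a gene whose XX expression is physiologically low and doubled by
  erosion to a ratio ≤ 1.1 is invisible to it.
* The erosion estimate subtracts the baseline fraction linearly; it is
  accurate to first order in the false-exceed rate (a few percent at the
  study's noise level) and degrades if the threshold sits inside the bulk
  of the null ratio distribution.
* Group D's 0.2 y_share threshold is a convention, not an estimate.
* The permutation FDR uses the pooled-null convention; with very few gene
  sets the q-values are coarse.
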