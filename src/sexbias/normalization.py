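"""Count normalization and per-gene two-group differential expression.

Normalization follows the median-of-ratios estimator familiar from bulk
RNA-seq: each sample's size factor is the median, over genes expressed in
every sample, of that sample's count divided by the gene's geometric mean
across samples.  Factors are rescaled to geometric mean 1 so normalized
counts live on a common, reproducible scale.  CPM and TPM are provided for
the dosage analyses (X:A ratios use TPM).

The differential test is a self-contained two-group comparison rather than
a joint multi-factor GLM: ``nb_wald`` fits a per-gene negative-binomial
group contrast with method-of-moments dispersion and reports a signed Wald
statistic with a two-sided normal p-value; ``welch_log`` is a Welch t-test
on log2(normalized count + 1).  Multiple testing uses Benjamini-Hochberg
step-up (Bonferroni available).  No empirical-Bayes dispersion shrinkage or
fold-change shrinkage is applied; see docs/methods.md for the rationale and
the escape hatch for externally produced DE tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, GeneAnnotation, SampleSheet

DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# size factors / CPM / TPM
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with a nonzero count in every sample enter the reference
    (their cross-sample geometric mean is positive).  Raises if no such gene
    exists; in that case a pseudo-reference on a filtered gene set is the
    standard fallback and should be applied upstream.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "needs at least one — filter samples or use a pseudo-reference"
        )
    ref = arr[all_pos]
    geomean = np.exp(np.log(ref).mean(axis=1))
    s = np.median(ref / geomean[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean exactly 1
    return pd.Series(s, index=df.columns, name="size_factor")


def cpm(counts: pd.DataFrame | CountMatrix) -> pd.DataFrame:
    """Counts per million, per sample."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0)
    return df / totals * 1e6


def tpm(counts: pd.DataFrame | CountMatrix,
        lengths_bp: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts per million: length-rate normalized to 1e6 per sample."""
    if isinstance(counts, CountMatrix):
        df = counts.counts
        if lengths_bp is None:
            lengths_bp = counts.genes.lengths()
    else:
        df = counts
    if lengths_bp is None:
        raise ValueError("gene lengths required for TPM")
    lengths_bp = lengths_bp.reindex(df.index)
    if (lengths_bp <= 0).any() or lengths_bp.isna().any():
        bad = lengths_bp.index[(lengths_bp <= 0) | lengths_bp.isna()].tolist()
        raise ValueError(f"zero/missing gene length for: {bad[:5]}")
    rate = df.div(lengths_bp / 1e3, axis=0)
    return rate / rate.sum(axis=0) * 1e6


@dataclass
class NormalizedExpression:
    """Counts plus size factors and derived normalized matrices."""

    counts: pd.DataFrame
    size_factor: pd.Series
    norm: pd.DataFrame
    samples: SampleSheet
    genes: GeneAnnotation

    def cpm(self) -> pd.DataFrame:
        return cpm(self.counts)

    def tpm(self) -> pd.DataFrame:
        return tpm(self.counts, self.genes.lengths())


def normalize(cm: CountMatrix) -> NormalizedExpression:
    s = size_factors(cm.counts)
    return NormalizedExpression(
        counts=cm.counts,
        size_factor=s,
        norm=cm.counts / s,
        samples=cm.samples,
        genes=cm.genes,
    )


# ---------------------------------------------------------------------------
# expression floor
# ---------------------------------------------------------------------------


def expression_floor(
    norm: NormalizedExpression | pd.DataFrame,
    samples: SampleSheet | None = None,
    min_count: float = 50.0,
    timepoint: str | None = None,
) -> pd.Series:
    """Gene passes when at least one single cell line averages >= ``min_count``
    normalized counts (over that line's replicate samples, optionally at one
    timepoint).  The 50-count default corresponds to roughly 2 CPM at the
    emulated sequencing depth and separates the unexpressed from the
    expressed mode of the count histogram.
    """
    if isinstance(norm, NormalizedExpression):
        mat, samples = norm.norm, norm.samples
    else:
        mat = norm
        if samples is None:
            raise ValueError("sample sheet required when passing a bare matrix")
    sdf = samples.frame
    if timepoint is not None:
        sdf = sdf[sdf["timepoint"].astype(str) == timepoint]
    best = pd.Series(-np.inf, index=mat.index)
    for _, sub in sdf.groupby("cell_line", observed=True):
        line_mean = mat[sub["sample_id"].tolist()].mean(axis=1)
        best = np.maximum(best, line_mean)
    return best >= min_count


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up, mapped back to input order."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def bonferroni_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(arr * arr.size, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


# ---------------------------------------------------------------------------
# two-group differential test
# ---------------------------------------------------------------------------


def de_test(
    norm: NormalizedExpression | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = "nb_wald",
    genes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    contrast: str = "A_vs_B",
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-gene two-group test on normalized counts.

    Returns a table with columns ``gene_id, contrast, baseMean, mean_A,
    mean_B, log2fc, stat, p, padj``; ``log2fc`` is group A over group B with
    a pseudo-count, so swapping the groups flips the signs of ``log2fc`` and
    ``stat`` and preserves ``p`` exactly.
    """
    mat = norm.norm if isinstance(norm, NormalizedExpression) else norm
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if genes is not None:
        mat = mat.loc[list(genes)]
    a = mat[group_a].to_numpy(dtype=float)
    b = mat[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    if method == "nb_wald":
        stat, p = _nb_wald(a, b, pseudocount)
    elif method == "welch_log":
        res = stats.ttest_ind(
            np.log2(a + 1.0), np.log2(b + 1.0), axis=1, equal_var=False
        )
        stat, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        flat = np.isnan(stat)  # zero variance in both groups
        stat = np.where(flat, 0.0, stat)
        p = np.where(flat, 1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")

    if adjust == "bh":
        padj = bh_adjust(p)
    elif adjust == "bonferroni":
        padj = bonferroni_adjust(p)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "gene_id": mat.index,
            "contrast": contrast,
            "baseMean": np.concatenate([a, b], axis=1).mean(axis=1),
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": log2fc,
            "stat": stat,
            "p": p,
            "padj": padj,
        }
    ).set_index("gene_id", drop=False).rename_axis(None)


def _nb_wald(a: np.ndarray, b: np.ndarray, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    """Wald statistic for the NB log-mean difference between two groups.

    Dispersion is a per-gene pooled method-of-moments estimate
    ``alpha = (s2 - mu) / mu^2`` floored at 1e-8; the delta-method variance
    of the log group-mean difference is ``(1/mu_A + alpha)/n_A +
    (1/mu_B + alpha)/n_B``.  Group means are guarded with the pseudo-count
    so all-zero groups still yield a finite statistic.

    The two-sided p-value uses a Student-t reference with
    ``n_A + n_B - 2`` degrees of freedom rather than a normal one: the SE
    is estimated from the same handful of replicates, and with ~18 samples
    a normal reference is measurably anticonservative (empirical type-I
    ~0.07 at nominal 0.05) while the t reference restores calibration.
    """
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    # pooled excess-variance dispersion, weighted by group df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mean_a) / np.square(mean_a)
        alpha_b = (var_b - mean_b) / np.square(mean_b)
    alpha_a = np.where(np.isfinite(alpha_a), alpha_a, 0.0)
    alpha_b = np.where(np.isfinite(alpha_b), alpha_b, 0.0)
    w_a, w_b = n_a - 1, n_b - 1
    alpha = np.maximum((w_a * alpha_a + w_b * alpha_b) / (w_a + w_b), DISPERSION_FLOOR)
    mu_a = mean_a + pseudocount
    mu_b = mean_b + pseudocount
    beta = np.log(mu_a) - np.log(mu_b)
    se = np.sqrt((1.0 / mu_a + alpha) / n_a + (1.0 / mu_b + alpha) / n_b)
    stat = beta / se
    p = 2.0 * stats.t.sf(np.abs(stat), df=n_a + n_b - 2)
    return stat, np.minimum(p, 1.0)


def sex_contrast(
    norm: NormalizedExpression,
    timepoint: str,
    method: str = "nb_wald",
    min_count: float = 50.0,
    **kwargs,
) -> pd.DataFrame:
    """XX-vs-XY DE table at one timepoint (A = XX, so log2fc > 0 is
    female-biased); genes are floored before testing so the BH adjustment
    runs over tested genes only."""
    xx = norm.samples.select(sex="XX", timepoint=timepoint)
    xy = norm.samples.select(sex="XY", timepoint=timepoint)
    if not xx or not xy:
        raise ValueError(f"need both sexes at timepoint {timepoint}")
    keep = expression_floor(norm, min_count=min_count, timepoint=timepoint)
    return de_test(
        norm, xx, xy, method=method, genes=norm.norm.index[keep],
        contrast=f"sex_{timepoint}", **kwargs,
    )


def time_contrast(
    norm: NormalizedExpression,
    timepoint: str,
    reference: str = "D0",
    method: str = "nb_wald",
    min_count: float = 50.0,
    **kwargs,
) -> pd.DataFrame:
    """Timepoint-vs-reference DE table with sexes pooled (A = later
    timepoint, so log2fc > 0 means upregulated during differentiation)."""
    later = norm.samples.select(timepoint=timepoint)
    ref = norm.samples.select(timepoint=reference)
    keep = expression_floor(norm, min_count=min_count)
    return de_test(
        norm, later, ref, method=method, genes=norm.norm.index[keep],
        contrast=f"time_{timepoint}_vs_{reference}", **kwargs,
    )
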