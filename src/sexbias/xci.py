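"""XCI-erosion estimation from XX:XY expression ratios, X:A dosage, and
between-line variance of X-linked expression.

The erosion readout is indirect: reactivation of silenced X-linked genes in
a female line inflates its expression relative to male lines, so the
fraction of X-linked genes with an XX:XY TPM ratio above a threshold
(default > 1.1, strict) estimates how much of the X is in the eroded or
biallelic range.  Because measurement noise alone pushes some genes over
the threshold, the same exceedance fraction over autosomal baseline
chromosomes (default 5 and 16, chosen for their similar protein-coding
gene counts to X) is subtracted; the clamped difference is the
erosion-attributable fraction.  Known XCI escapees are biallelic by
definition and are removed before the erosion estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneAnnotation, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class XCIConfig:
    ratio_threshold: float = 1.1
    baseline_chromosomes: tuple[str, ...] = ("5", "16")
    min_expression_tpm: float = 1.0
    exclude_escapees: bool = True
    #: "fraction": subtract the baseline chromosomes' threshold-exceedance
    #: fraction (dimensionally consistent with reporting "N of M genes").
    #: "mean_shift": divide X ratios by the mean baseline ratio first and
    #: count exceedances of the recentred ratios, with no subtraction.
    baseline_mode: str = "fraction"

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 1.0:
            raise ValueError("ratio_threshold must exceed 1")


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------


def xx_xy_ratio(
    tpm: pd.DataFrame,
    samples: SampleSheet,
    gene_subset: Sequence[str] | None = None,
    mode: str = "pooled",
    min_expression_tpm: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Per-gene XX:XY expression ratio(s).

    ``pooled``: mean TPM over all XX samples / mean over all XY samples,
    one ``ratio`` column.  ``per_line``: one column per XX line, each that
    line's mean divided by the pooled XY mean.  Genes whose pooled XY mean
    falls below ``min_expression_tpm`` are excluded (the denominator guard);
    the number excluded is returned alongside.
    """
    if mode not in ("pooled", "per_line"):
        raise ValueError(f"unknown mode {mode!r}")
    mat = tpm if gene_subset is None else tpm.loc[list(gene_subset)]
    xx_all = samples.select(sex="XX")
    xy_all = samples.select(sex="XY")
    if not xx_all or not xy_all:
        raise ValueError("need samples of both sexes")
    xy_mean = mat[xy_all].mean(axis=1)
    keep = xy_mean >= min_expression_tpm
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("xx_xy_ratio: %d genes below %.3g TPM in XY excluded",
                    n_excluded, min_expression_tpm)
    mat, xy_mean = mat[keep], xy_mean[keep]
    if mode == "pooled":
        out = pd.DataFrame({"ratio": mat[xx_all].mean(axis=1) / xy_mean})
    else:
        cols = {}
        for line in samples.lines_of_sex("XX"):
            sids = samples.select(cell_line=line)
            cols[line] = mat[sids].mean(axis=1) / xy_mean
        out = pd.DataFrame(cols)
    return out, n_excluded


def erosion_fraction(
    ratios_x: pd.Series,
    ratios_baseline: pd.Series,
    config: XCIConfig | None = None,
) -> dict:
    """Erosion-attributable fraction of X-linked genes.

    ``frac_above`` is the share of X genes with ratio strictly above the
    threshold; ``baseline_frac`` the same statistic over baseline-chromosome
    genes; their clamped difference, times the number of X genes tested,
    gives the estimated count of erosion-affected genes.
    """
    config = config or XCIConfig()
    if len(ratios_baseline) == 0:
        raise ValueError("baseline chromosome gene set is empty")
    if len(ratios_x) == 0:
        raise ValueError("no X-linked ratios supplied")
    thr = config.ratio_threshold
    frac_above = float((ratios_x > thr).mean())
    baseline_frac = float((ratios_baseline > thr).mean())
    if config.baseline_mode == "fraction":
        attributable = max(0.0, frac_above - baseline_frac)
    elif config.baseline_mode == "mean_shift":
        recentred = ratios_x / float(ratios_baseline.mean())
        attributable = float((recentred > thr).mean())
    else:
        raise ValueError(f"unknown baseline_mode {config.baseline_mode!r}")
    n = int(len(ratios_x))
    return {
        "n_x_genes_tested": n,
        "frac_above_threshold": frac_above,
        "baseline_frac": baseline_frac,
        "erosion_attributable_frac": attributable,
        "n_attributable": int(round(attributable * n)),
    }


# ---------------------------------------------------------------------------
# X:A dosage
# ---------------------------------------------------------------------------


def x_to_a_ratio(
    tpm: pd.DataFrame,
    samples: SampleSheet,
    annotation: GeneAnnotation,
    line: str,
    min_expression_tpm: float = 1.0,
) -> tuple[pd.Series, float]:
    """X:A dosage for one cell line from TPM.

    Expressed genes (mean TPM >= floor in the line) only; for each autosome
    the ratio of the line's mean X-linked TPM to its mean TPM on that
    autosome, plus the unweighted mean over autosomes.
    """
    sids = samples.select(cell_line=line)
    if not sids:
        raise ValueError(f"no samples for cell line {line!r}")
    mean_tpm = tpm[sids].mean(axis=1)
    expressed = mean_tpm[mean_tpm >= min_expression_tpm]
    chrom = annotation.chromosome_of().reindex(expressed.index)
    x_mean = expressed[chrom == "X"].mean()
    if np.isnan(x_mean):
        raise ValueError(f"no expressed X-linked genes in line {line!r}")
    out = {}
    autosomes = sorted(
        {c for c in chrom.unique() if c not in ("X", "Y")},
        key=lambda c: (len(c), c),
    )
    for c in autosomes:
        vals = expressed[chrom == c]
        if len(vals) == 0:
            logger.warning("autosome %s has no expressed genes in %s; omitted", c, line)
            continue
        out[c] = float(x_mean / vals.mean())
    ratios = pd.Series(out, name=line)
    return ratios, float(ratios.mean())


# ---------------------------------------------------------------------------
# between-line variance
# ---------------------------------------------------------------------------


def line_variance_ratio(
    expr: pd.DataFrame,
    samples: SampleSheet,
    annotation: GeneAnnotation,
) -> dict:
    """Variance of per-line average X-linked expression, by sex.

    Each line is summarised by the mean expression over X-linked genes
    (averaged over its samples); the sample (n-1) variance across lines is
    reported per sex together with the XY/XX ratio and a one-way ANOVA
    across all lines on per-gene line averages.
    """
    x_genes = annotation.genes_on("X")
    x_expr = expr.loc[[g for g in x_genes if g in expr.index]]
    line_avg = {}
    per_gene_line = {}
    for line in sorted(samples.frame["cell_line"].unique()):
        sids = samples.select(cell_line=line)
        per_gene = x_expr[sids].mean(axis=1)
        per_gene_line[line] = per_gene
        line_avg[line] = float(per_gene.mean())
    sex_of = samples.sex_of_line()
    by_sex = {"XX": [], "XY": []}
    for line, v in line_avg.items():
        by_sex[sex_of[line]].append(v)
    if min(len(v) for v in by_sex.values()) < 2:
        raise ValueError("need at least 2 lines per sex")
    var_xx = float(np.var(by_sex["XX"], ddof=1))
    var_xy = float(np.var(by_sex["XY"], ddof=1))
    f_stat, f_p = stats.f_oneway(*[v.to_numpy() for v in per_gene_line.values()])
    return {
        "line_average": line_avg,
        "var_xx": var_xx,
        "var_xy": var_xy,
        "variance_ratio_xy_over_xx": var_xy / var_xx if var_xx > 0 else np.inf,
        "anova_F": float(f_stat),
        "anova_p": float(f_p),
    }


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------


@dataclass
class XCIReport:
    gene_ratios: pd.DataFrame       # pooled + per-line ratios, flags
    line_summary: pd.DataFrame      # per XX line and pooled erosion stats
    x_to_a: pd.DataFrame            # lines x autosomes (+ mean column)
    variance: dict


def xci_report(
    tpm: pd.DataFrame,
    samples: SampleSheet,
    annotation: GeneAnnotation,
    config: XCIConfig | None = None,
) -> XCIReport:
    """Full XCI analysis: ratios, per-line and pooled erosion fractions,
    X:A dosage per line and the between-line variance comparison.

    Gametolog X members with a pooled ratio above the threshold that are
    not escapees are flagged in ``gene_ratios`` as possibly affected by
    erosion.
    """
    config = config or XCIConfig()
    x_genes = annotation.genes_on("X")
    base_genes = annotation.genes_on(config.baseline_chromosomes)
    if not base_genes:
        raise ValueError(
            f"no genes on baseline chromosomes {config.baseline_chromosomes}"
        )
    escapees = set(annotation.escapees())

    pooled, _ = xx_xy_ratio(tpm, samples, x_genes, "pooled", config.min_expression_tpm)
    per_line, _ = xx_xy_ratio(tpm, samples, x_genes, "per_line", config.min_expression_tpm)
    base_pooled, _ = xx_xy_ratio(
        tpm, samples, base_genes, "pooled", config.min_expression_tpm
    )
    base_per_line, _ = xx_xy_ratio(
        tpm, samples, base_genes, "per_line", config.min_expression_tpm
    )

    gametolog_x = {x for x, _ in annotation.gametolog_pairs()}
    gene_ratios = pooled.join(per_line)
    gene_ratios["escapee"] = [g in escapees for g in gene_ratios.index]
    gene_ratios["gametolog"] = [g in gametolog_x for g in gene_ratios.index]
    gene_ratios["possibly_eroded"] = (
        (gene_ratios["ratio"] > config.ratio_threshold) & ~gene_ratios["escapee"]
    )
    gene_ratios.index.name = "gene_id"

    def _strip_escapees(frame: pd.DataFrame) -> pd.DataFrame:
        if not config.exclude_escapees:
            return frame
        return frame.loc[[g for g in frame.index if g not in escapees]]

    rows = []
    x_strip = _strip_escapees(pooled)
    for line in samples.lines_of_sex("XX"):
        res = erosion_fraction(
            _strip_escapees(per_line)[line], base_per_line[line], config
        )
        rows.append({"line": line, **res})
    rows.append(
        {"line": "pooled", **erosion_fraction(x_strip["ratio"], base_pooled["ratio"], config)}
    )
    line_summary = pd.DataFrame(rows)

    xa_rows = {}
    for line in sorted(samples.frame["cell_line"].unique()):
        ratios, mean_ratio = x_to_a_ratio(
            tpm, samples, annotation, line, config.min_expression_tpm
        )
        xa_rows[line] = pd.concat([ratios, pd.Series({"mean": mean_ratio})])
    x_to_a = pd.DataFrame(xa_rows).T
    x_to_a.index.name = "cell_line"

    variance = line_variance_ratio(tpm, samples, annotation)
    return XCIReport(gene_ratios, line_summary, x_to_a, variance)
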