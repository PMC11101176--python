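"""Stringent post-hoc sex-bias filter and chromosome-class accounting.

A gene is called sex-biased at a timepoint only when all five criteria hold
simultaneously:

1. expression floor — some single cell line averages >= 50 normalized
   counts at the timepoint;
2. effect size — |log2 fold change| >= 0.5 (about 1.41-fold);
3. significance — BH-adjusted p <= 0.05;
4. consistency within sex — the coefficient of variation of the per-line
   mean expression is <= 0.5 in *both* sexes;
5. separation between sexes — every cross-sex line pair differs by at
   least 20% (relative to the larger of the two), all in the direction of
   the group-mean difference, i.e. no line of one sex expresses the gene
   as high as any line of the other sex.

The CV uses the population (n) standard deviation over the line means; the
pairwise rule's denominator is the larger of the pair.  Both choices are
configurable.  Filtering runs per timepoint independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, SampleSheet
from .normalization import NormalizedExpression, expression_floor

CHROM_CLASSES = ("Y", "X_escapee", "X_other", "autosomal")


@dataclass
class FilterConfig:
    min_count: float = 50.0
    min_abs_log2fc: float = 0.5
    max_padj: float = 0.05
    max_cv: float = 0.5
    min_pairwise_diff: float = 0.20
    #: population (n) vs sample (n-1) standard deviation in the CV
    cv_ddof: int = 0
    #: denominator of the pairwise relative difference: the larger value of
    #: the pair ("pair_max", default) or the larger group mean ("group_max")
    pairwise_denominator: str = "pair_max"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_pairwise_diff < 1.0:
            raise ValueError("min_pairwise_diff must lie in (0, 1)")
        for name in ("min_count", "min_abs_log2fc", "max_padj", "max_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def line_means(
    norm: NormalizedExpression | pd.DataFrame,
    samples: SampleSheet | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-gene, per-cell-line mean normalized counts (over replicates)."""
    if isinstance(norm, NormalizedExpression):
        mat, samples = norm.norm, norm.samples
    else:
        mat = norm
        if samples is None:
            raise ValueError("sample sheet required")
    sdf = samples.frame
    if timepoint is not None:
        sdf = sdf[sdf["timepoint"].astype(str) == timepoint]
    cols = {}
    for line, sub in sdf.groupby("cell_line", observed=True):
        cols[line] = mat[sub["sample_id"].tolist()].mean(axis=1)
    return pd.DataFrame(cols)


def within_sex_cv(lm: pd.DataFrame, ddof: int = 0) -> pd.Series:
    """Coefficient of variation across the line-mean columns of one sex.

    All line means zero is perfectly *consistent* (non-)expression and gets
    CV 0 — otherwise every Y-linked gene would be discarded for being
    uniformly silent in XX lines, the very genes the filter must retain.  A
    zero mean with any nonzero value (impossible for non-negative counts,
    kept as a guard) yields +inf.
    """
    if lm.shape[1] < 2:
        raise ValueError("need at least 2 cell lines to compute a CV")
    mean = lm.mean(axis=1)
    sd = lm.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    all_zero = (lm == 0).all(axis=1)
    out = np.where(mean > 0, cv, np.inf)
    out = np.where(all_zero, 0.0, out)
    return pd.Series(out, index=lm.index)


def all_pairwise_rule(
    xx_means: pd.DataFrame,
    xy_means: pd.DataFrame,
    min_diff: float = 0.20,
    denominator: str = "pair_max",
) -> tuple[pd.Series, pd.Series]:
    """Cross-sex separation rule over all line pairs.

    For every (XX line a, XY line b) pair the relative difference is
    ``|a - b| / max(a, b)`` (0 when both are 0).  A gene passes when every
    pair reaches ``min_diff`` *and* every pair's sign(a - b) matches the
    group-mean direction.  Returns (pass, minimum observed difference).
    ``denominator="group_max"`` divides by the larger group mean instead of
    the larger pair value.
    """
    if denominator not in ("pair_max", "group_max"):
        raise ValueError(f"unknown pairwise denominator {denominator!r}")
    xx = xx_means.to_numpy(dtype=float)
    xy = xy_means.to_numpy(dtype=float)
    n_genes = xx.shape[0]
    # pairwise diffs: genes x (n_xx * n_xy)
    a = xx[:, :, None]
    b = xy[:, None, :]
    if denominator == "pair_max":
        denom = np.maximum(a, b)
    else:
        denom = np.broadcast_to(
            np.maximum(xx.mean(axis=1), xy.mean(axis=1))[:, None, None], np.broadcast_shapes(a.shape, b.shape)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(a - b) / denom
    d = np.where(denom > 0, d, 0.0).reshape(n_genes, -1)
    sign = np.sign(a - b).reshape(n_genes, -1)
    group_dir = np.sign(xx.mean(axis=1) - xy.mean(axis=1))
    consistent = (sign == group_dir[:, None]).all(axis=1) & (group_dir != 0)
    min_obs = d.min(axis=1)
    ok = consistent & (min_obs >= min_diff)
    idx = xx_means.index
    return pd.Series(ok, index=idx), pd.Series(min_obs, index=idx)


# ---------------------------------------------------------------------------
# the filter
# ---------------------------------------------------------------------------


def stringent_filter(
    de: pd.DataFrame,
    norm: NormalizedExpression,
    annotation: GeneAnnotation,
    timepoint: str,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Apply all five criteria to an XX-vs-XY DE table at one timepoint.

    ``de`` must come from the sex contrast at ``timepoint`` (log2fc of XX
    over XY).  Returns one row per retained gene with the evidence columns
    of a SexBiasRecord, sorted by adjusted p.
    """
    config = config or FilterConfig()
    contrast = de["contrast"].iloc[0] if len(de) else f"sex_{timepoint}"
    if len(de) and not str(contrast).startswith("sex_"):
        raise ValueError(f"stringent_filter needs an XX-vs-XY contrast, got {contrast!r}")
    samples = norm.samples
    xx_lines = samples.lines_of_sex("XX")
    xy_lines = samples.lines_of_sex("XY")
    if not xx_lines or not xy_lines:
        raise ValueError("need cell lines of both sexes")

    lm = line_means(norm, timepoint=timepoint)
    genes = de["gene_id"]
    lm = lm.loc[genes]
    xx_lm, xy_lm = lm[xx_lines], lm[xy_lines]

    floor_ok = expression_floor(
        norm, min_count=config.min_count, timepoint=timepoint
    ).loc[genes]
    fc_ok = de["log2fc"].abs().to_numpy() >= config.min_abs_log2fc
    p_ok = de["padj"].to_numpy() <= config.max_padj
    cv_xx = within_sex_cv(xx_lm, ddof=config.cv_ddof)
    cv_xy = within_sex_cv(xy_lm, ddof=config.cv_ddof)
    cv_ok = (cv_xx <= config.max_cv) & (cv_xy <= config.max_cv)
    pair_ok, min_obs = all_pairwise_rule(
        xx_lm, xy_lm, config.min_pairwise_diff, config.pairwise_denominator
    )

    keep = floor_ok.to_numpy() & fc_ok & p_ok & cv_ok.to_numpy() & pair_ok.to_numpy()

    chrom_class = annotation.chrom_class().reindex(genes)
    out = pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "timepoint": timepoint,
            "direction": np.where(de["log2fc"] > 0, "female_up", "male_up"),
            "log2fc": de["log2fc"].to_numpy(),
            "padj": de["padj"].to_numpy(),
            "cv_xx": cv_xx.to_numpy(),
            "cv_xy": cv_xy.to_numpy(),
            "min_pairwise_diff_observed": min_obs.to_numpy(),
            "chrom_class": chrom_class.to_numpy(),
        }
    )[keep]
    return out.sort_values("padj", kind="mergesort").reset_index(drop=True)


def brute_force_filter(
    de: pd.DataFrame,
    norm: NormalizedExpression,
    annotation: GeneAnnotation,
    timepoint: str,
    config: FilterConfig | None = None,
) -> list[str]:
    """Naive per-gene loop over all criteria; reference oracle for tests."""
    config = config or FilterConfig()
    samples = norm.samples
    xx_lines = samples.lines_of_sex("XX")
    xy_lines = samples.lines_of_sex("XY")
    kept = []
    for row in de.itertuples(index=False):
        g = row.gene_id
        means = {}
        for line in xx_lines + xy_lines:
            sids = samples.select(cell_line=line, timepoint=timepoint)
            means[line] = float(np.mean([norm.norm.at[g, s] for s in sids]))
        if max(means.values()) < config.min_count:
            continue
        if abs(row.log2fc) < config.min_abs_log2fc:
            continue
        if row.padj > config.max_padj:
            continue
        ok_cv = True
        for lines in (xx_lines, xy_lines):
            vals = [means[l] for l in lines]
            m = float(np.mean(vals))
            sd = float(np.std(vals, ddof=config.cv_ddof))
            if all(v == 0 for v in vals):
                cv = 0.0
            else:
                cv = sd / m if m > 0 else float("inf")
            if cv > config.max_cv:
                ok_cv = False
        if not ok_cv:
            continue
        direction = np.sign(
            np.mean([means[l] for l in xx_lines]) - np.mean([means[l] for l in xy_lines])
        )
        if direction == 0:
            continue
        ok_pairs = True
        for la, lb in product(xx_lines, xy_lines):
            a, b = means[la], means[lb]
            top = max(a, b)
            d = abs(a - b) / top if top > 0 else 0.0
            if d < config.min_pairwise_diff or np.sign(a - b) != direction:
                ok_pairs = False
                break
        if not ok_pairs:
            continue
        kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


def table2_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate retained genes by timepoint x direction x chromosome
    class, with totals and the X-escapee subcount broken out (mirrors the
    per-timepoint male/female accounting of sex-biased DEG)."""
    cols = ["timepoint", "direction", "chrY", "chrX", "chrX_escapee",
            "autosomal", "total"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    # keep the declared timecourse order (the records arrive timepoint by
    # timepoint); directions sort alphabetically within a timepoint
    for (tp, direction), sub in records.groupby(["timepoint", "direction"], sort=False):
        counts = sub["chrom_class"].value_counts()
        n_y = int(counts.get("Y", 0))
        n_esc = int(counts.get("X_escapee", 0))
        n_x = int(counts.get("X_other", 0)) + n_esc
        n_auto = int(counts.get("autosomal", 0))
        rows.append(
            {
                "timepoint": tp,
                "direction": direction,
                "chrY": n_y,
                "chrX": n_x,
                "chrX_escapee": n_esc,
                "autosomal": n_auto,
                "total": n_y + n_x + n_auto,
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    tp_order = {tp: i for i, tp in enumerate(dict.fromkeys(records["timepoint"]))}
    out["_tp"] = out["timepoint"].map(tp_order)
    out = out.sort_values(["_tp", "direction"], kind="mergesort").drop(columns="_tp")
    return out.reset_index(drop=True)
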