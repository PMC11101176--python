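"""Expression-trajectory classification over the differentiation course.

Each expressed gene is summarised by its mean normalized expression per
timepoint and classified by where that profile peaks: ``peak_D4`` /
``peak_D9`` / ``peak_D37`` for an interior or final maximum, ``decreasing``
when the maximum sits at the start (D0), and ``stable`` when the profile's
max/min fold range stays within a cutoff (default 1.5).  Genes failing the
expression floor at every timepoint are ``not_expressed``.  The per-class
counts stratified by chromosome (autosomal / X / Y) reproduce the pie-chart
style accounting of which genome compartments contribute at which stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, SampleSheet
from .normalization import NormalizedExpression, expression_floor

CLASSES = ("peak_D4", "peak_D9", "peak_D37", "decreasing", "stable", "not_expressed")


def classify_trajectory(
    norm: NormalizedExpression,
    gene_subset=None,
    stable_max_fold: float = 1.5,
    pseudocount: float = 1.0,
    sex: str | None = None,
    min_count: float = 50.0,
) -> pd.DataFrame:
    """Per-gene trajectory class from timepoint means.

    Means are taken over all samples at each timepoint (optionally one sex:
    Y-linked genes are classified on XY samples only).  ``fold_range`` is
    max/min of the pseudo-counted timepoint means; ties in the argmax break
    toward the earlier timepoint.
    """
    samples = norm.samples
    tps = samples.timepoints
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    mat = norm.norm
    if gene_subset is not None:
        missing = set(gene_subset) - set(mat.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        mat = mat.loc[list(gene_subset)]

    mu = pd.DataFrame(
        {tp: mat[samples.select(sex=sex, timepoint=tp)].mean(axis=1) for tp in tps}
    )
    mu_pc = mu + pseudocount
    fold_range = mu_pc.max(axis=1) / mu_pc.min(axis=1)
    # argmax with ties toward the earlier timepoint (columns are in order)
    arg = mu_pc.to_numpy().argmax(axis=1)
    peak_tp = np.array(tps, dtype=object)[arg]

    expressed = pd.Series(False, index=mat.index)
    for tp in tps:
        floor = expression_floor(
            mat if sex is None else mat,
            samples,
            min_count=min_count,
            timepoint=tp,
        )
        expressed |= floor

    cls = np.where(
        ~expressed,
        "not_expressed",
        np.where(
            fold_range <= stable_max_fold,
            "stable",
            np.where(peak_tp == tps[0], "decreasing",
                     np.char.add("peak_", peak_tp.astype(str))),
        ),
    )
    out = mu.copy()
    out.columns = [f"mean_{tp}" for tp in tps]
    out["fold_range"] = fold_range
    out["trajectory_class"] = cls
    out.index.name = "gene_id"
    return out


def trajectory_summary(
    classes: pd.DataFrame,
    annotation: GeneAnnotation,
    top_k: int = 4,
) -> pd.DataFrame:
    """Class counts and proportions per chromosome stratum.

    Strata are autosomal / X / Y; proportions are over expressed genes in
    the stratum and sum to 1 there.  The ``top_genes`` column lists up to
    ``top_k`` genes per class by peak expression (the figure labels).
    """
    chrom = annotation.chromosome_of().reindex(classes.index)
    stratum = pd.Series(
        np.where(chrom == "X", "X", np.where(chrom == "Y", "Y", "autosomal")),
        index=classes.index,
    )
    mean_cols = [c for c in classes.columns if c.startswith("mean_")]
    peak_expr = classes[mean_cols].max(axis=1)
    rows = []
    for strat in ("autosomal", "X", "Y"):
        sub = classes[stratum == strat]
        expressed = sub[sub["trajectory_class"] != "not_expressed"]
        n_expr = len(expressed)
        for cls in CLASSES:
            members = sub[sub["trajectory_class"] == cls]
            if cls == "not_expressed":
                prop = np.nan
            else:
                prop = len(members) / n_expr if n_expr else np.nan
            top = (
                peak_expr.loc[members.index]
                .sort_values(ascending=False)
                .head(top_k)
                .index.tolist()
            )
            rows.append(
                {
                    "stratum": strat,
                    "trajectory_class": cls,
                    "n": len(members),
                    "proportion": prop,
                    "top_genes": ",".join(top),
                }
            )
    return pd.DataFrame(rows)
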