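"""X/Y gametolog dosage: compensation, grouping, and sex-bias calls.

Gametologs are X/Y homologous gene pairs in non-recombining regions.  In
XX cells only the X member is expressed; in XY cells the combined dosage is
the X member plus its Y homolog.  When the Y homolog restores the dosage an
XX-biased X member (often an XCI escapee) produces no net sex difference —
the compensation this module quantifies.

Pairs are classified into four groups over the differentiation course:

* **D** — substantial Y-homolog contribution (mean Y share of the combined
  XY dosage >= a threshold, default 0.2); takes precedence.
* **A** — combined pair expression significantly *down* at the final
  timepoint versus the start.
* **B** — significantly *up*.
* **C** — no significant change.

Sex-biased combined dosage is called per timepoint from per-line dosage
values (line = biological unit) with a two-sample t-test and Šidák
familywise correction across timepoints; a line-paired two-way OLS ANOVA
(sex x timepoint, line nested in sex) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneAnnotation, SampleSheet
from .normalization import NormalizedExpression, de_test


@dataclass
class GametologConfig:
    #: minimum mean Y share of combined XY dosage for Group D
    y_share_min: float = 0.2
    max_padj: float = 0.05
    min_abs_log2fc: float = 0.5
    alpha_sexbias: float = 0.05


@dataclass(frozen=True)
class GametologPair:
    x_gene: str
    y_gene: str
    escapee_x: bool = False


def pairs_from_annotation(annotation: GeneAnnotation) -> list[GametologPair]:
    esc = set(annotation.escapees())
    return [
        GametologPair(x, y, x in esc) for x, y in annotation.gametolog_pairs()
    ]


# ---------------------------------------------------------------------------
# dosage
# ---------------------------------------------------------------------------


def combined_dosage(
    norm: NormalizedExpression | pd.DataFrame,
    samples: SampleSheet | None,
    pair: GametologPair,
    timepoint: str,
) -> tuple[float, float, float]:
    """(dose_xx, dose_xy, y_share) at one timepoint.

    dose_xx = mean normalized X-member expression over XX samples;
    dose_xy = mean of (X + Y member) over XY samples; y_share = the Y
    member's fraction of dose_xy (0 when dose_xy is 0).
    """
    if isinstance(norm, NormalizedExpression):
        mat, samples = norm.norm, norm.samples
    else:
        mat = norm
        if samples is None:
            raise ValueError("sample sheet required")
    xx = samples.select(sex="XX", timepoint=timepoint)
    xy = samples.select(sex="XY", timepoint=timepoint)
    dose_xx = float(mat.loc[pair.x_gene, xx].mean()) if xx else np.nan
    x_in_xy = float(mat.loc[pair.x_gene, xy].mean())
    y_in_xy = float(mat.loc[pair.y_gene, xy].mean())
    dose_xy = x_in_xy + y_in_xy
    y_share = y_in_xy / dose_xy if dose_xy > 0 else 0.0
    return dose_xx, dose_xy, y_share


def _per_line_dosage(
    norm: NormalizedExpression, pair: GametologPair, timepoint: str
) -> tuple[pd.Series, pd.Series]:
    """Per-line combined dosage at one timepoint: X in XX lines, X+Y in XY."""
    samples = norm.samples
    xx_vals, xy_vals = {}, {}
    for line in samples.lines_of_sex("XX"):
        sids = samples.select(cell_line=line, timepoint=timepoint)
        xx_vals[line] = float(norm.norm.loc[pair.x_gene, sids].mean())
    for line in samples.lines_of_sex("XY"):
        sids = samples.select(cell_line=line, timepoint=timepoint)
        xy_vals[line] = float(
            norm.norm.loc[pair.x_gene, sids].mean()
            + norm.norm.loc[pair.y_gene, sids].mean()
        )
    return pd.Series(xx_vals), pd.Series(xy_vals)


# ---------------------------------------------------------------------------
# multiple-comparison correction
# ---------------------------------------------------------------------------


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Šidák familywise adjustment ``1 - (1 - p)^m`` for m comparisons."""
    return 1.0 - np.power(1.0 - np.asarray(p, dtype=float), m)


# ---------------------------------------------------------------------------
# sex-bias calls
# ---------------------------------------------------------------------------


def dosage_sexbias(
    norm: NormalizedExpression,
    pair: GametologPair,
    config: GametologConfig | None = None,
) -> pd.DataFrame:
    """Per-timepoint sex-bias calls on combined dosage, Šidák-corrected.

    Per-line dosage values (mean over replicates) are compared between the
    sexes at every timepoint with a two-sample t-test; the familywise
    Šidák correction runs over the number of timepoints.  A two-way OLS
    ANOVA (sex, timepoint, interaction) on the same line-level values is
    attached as frame metadata under ``attrs['anova']``.
    """
    config = config or GametologConfig()
    tps = norm.samples.timepoints
    m = len(tps)
    rows = []
    long = []
    for tp in tps:
        xx, xy = _per_line_dosage(norm, pair, tp)
        if len(xx) < 2 or len(xy) < 2:
            raise ValueError("need at least 2 lines per sex")
        t, p = stats.ttest_ind(xx.to_numpy(), xy.to_numpy(), equal_var=True)
        p_adj = float(sidak_adjust(p, m))
        direction = "female_up" if xx.mean() > xy.mean() else "male_up"
        rows.append(
            {
                "timepoint": tp,
                "dose_xx_mean": float(xx.mean()),
                "dose_xy_mean": float(xy.mean()),
                "t": float(t),
                "p": float(p),
                "p_sidak": p_adj,
                "biased": bool(p_adj < config.alpha_sexbias),
                "direction": direction if p_adj < config.alpha_sexbias else "none",
            }
        )
        for line, v in xx.items():
            long.append({"line": line, "sex": "XX", "timepoint": tp, "dose": v})
        for line, v in xy.items():
            long.append({"line": line, "sex": "XY", "timepoint": tp, "dose": v})
    out = pd.DataFrame(rows)
    out.attrs["anova"] = _two_way_anova(pd.DataFrame(long))
    return out


def _two_way_anova(long: pd.DataFrame) -> pd.DataFrame:
    """Line-paired two-way ANOVA table (sex, timepoint, sex:timepoint).

    Lines are the repeated units: the line factor (nested in sex) absorbs
    stable between-line offsets, approximating a repeated-measures design.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("dose ~ C(sex) * C(timepoint) + C(line)", data=long).fit()
    return sm.stats.anova_lm(model, typ=2)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def classify_group(
    norm: NormalizedExpression,
    pair: GametologPair,
    config: GametologConfig | None = None,
) -> str:
    """Assign one of the groups A-D to a pair (D takes precedence)."""
    config = config or GametologConfig()
    samples = norm.samples
    tps = samples.timepoints
    if len(tps) < 2:
        raise ValueError("need at least first and last timepoints")
    first, last = tps[0], tps[-1]
    shares = [combined_dosage(norm, samples, pair, tp)[2] for tp in tps]
    if float(np.mean(shares)) >= config.y_share_min:
        return "D"
    # combined pair expression per sample (Y member is 0 in XX samples)
    total = (norm.norm.loc[pair.x_gene] + norm.norm.loc[pair.y_gene]).to_frame().T
    total.index = [f"{pair.x_gene}+{pair.y_gene}"]
    res = de_test(
        total,
        samples.select(timepoint=last),
        samples.select(timepoint=first),
        method="welch_log",
        contrast=f"{last}_vs_{first}",
    ).iloc[0]
    if res["padj"] <= config.max_padj and abs(res["log2fc"]) >= config.min_abs_log2fc:
        return "A" if res["log2fc"] < 0 else "B"
    return "C"


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------


def gametolog_report(
    norm: NormalizedExpression,
    annotation: GeneAnnotation,
    config: GametologConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-pair per-timepoint dosage table, per-pair grouping table)."""
    config = config or GametologConfig()
    pairs = pairs_from_annotation(annotation)
    dosage_rows, group_rows = [], []
    for pair in pairs:
        calls = dosage_sexbias(norm, pair, config)
        for row in calls.itertuples(index=False):
            dxx, dxy, share = combined_dosage(norm, norm.samples, pair, row.timepoint)
            dosage_rows.append(
                {
                    "x_gene": pair.x_gene,
                    "y_gene": pair.y_gene,
                    "timepoint": row.timepoint,
                    "dose_xx": dxx,
                    "dose_xy": dxy,
                    "y_share": share,
                    "p_sidak": row.p_sidak,
                    "sexbias": row.direction,
                }
            )
        biased_at = ",".join(
            r.timepoint for r in calls.itertuples(index=False) if r.biased
        )
        group_rows.append(
            {
                "x_gene": pair.x_gene,
                "y_gene": pair.y_gene,
                "escapee_x": pair.escapee_x,
                "group": classify_group(norm, pair, config),
                "mean_y_share": float(
                    np.mean(
                        [combined_dosage(norm, norm.samples, pair, tp)[2]
                         for tp in norm.samples.timepoints]
                    )
                ),
                "sexbias_timepoints": biased_at,
            }
        )
    return pd.DataFrame(dosage_rows), pd.DataFrame(group_rows)
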