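"""Preranked gene-set enrichment (weighted running-sum statistic) and the
final candidate-gene selection.

The enrichment score walks the gene list ranked by the DE test statistic:
set members ("hits") increment the running sum by their weighted score
share ``|score|^w / sum_hits |score|^w`` (w = 1 by default), non-members
decrement by ``1/(N - n_set)``; the ES is the running sum's signed maximum
deviation and the leading edge (core-enriched genes) are the members at or
before the extremum (after it, for negative ES).  Significance comes from a
gene-label permutation null (random same-size sets), NES divides the ES by
the mean same-sign null magnitude, and the FDR q follows the usual
pooled-null tail-ratio convention.

Candidate selection combines the sex-biased calls at the final timepoint
with neuro-implication flags (gene-ontology slim, core-enrichment
membership, trajectory, literature — the latter two user-supplied) and an
expression cut at a percentile (default 70th, nearest-rank) of the flagged
set's expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _ranked(scores: pd.Series) -> pd.Series:
    """Sort scores descending; ties broken by gene id for determinism."""
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    df = scores.rename("score").rename_axis("gene_id").reset_index()
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    return df.set_index("gene_id")["score"]


def enrichment_score(
    scores: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """(ES, running sum, leading-edge members) for one gene set.

    ``scores`` maps gene id -> ranking score (any order; ranked internally).
    Raises when no set member is present in the ranking.
    """
    ranked = _ranked(scores)
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set has no members in the ranked list")
    is_hit = ranked.index.isin(members)
    running = _running_sum(ranked.to_numpy(dtype=float), is_hit, weight_exponent)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    ids = ranked.index.to_numpy()
    if es >= 0:
        leading = [g for g in ids[: i_ext + 1] if g in members]
    else:
        leading = [g for g in ids[i_ext:] if g in members]
    return es, running, leading


def _running_sum(scores: np.ndarray, is_hit: np.ndarray, w: float) -> np.ndarray:
    n = scores.size
    n_set = int(is_hit.sum())
    if n_set == n:
        # degenerate: every gene is a member, so there is no miss step to
        # walk against; compare the weighted hit distribution with the
        # uniform position expectation instead (ES stays near zero)
        weights = np.abs(scores) ** w
        total = weights.sum()
        if total == 0:
            weights = np.ones(n)
            total = float(n)
        return np.cumsum(weights / total - 1.0 / n)
    weights = np.where(is_hit, np.abs(scores) ** w, 0.0)
    total = weights.sum()
    if total == 0:  # all-zero member scores: fall back to equal hit steps
        weights = is_hit.astype(float)
        total = float(n_set)
    steps = weights / total - (~is_hit) / (n - n_set)
    return np.cumsum(steps)


def _es_only(scores: np.ndarray, hit_mask: np.ndarray, w: float) -> float:
    running = _running_sum(scores, hit_mask, w)
    return float(running[np.argmax(np.abs(running))])


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


@dataclass
class GeneSetResult:
    name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    core_enriched: list[str]


def significance(
    scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    fdr_max: float | None = None,
) -> pd.DataFrame:
    """Permutation p, NES and FDR q for a collection of gene sets.

    The null reassigns set membership uniformly at random (same size) —
    the gene-label permutation matching the preranked mode.  p_perm uses
    the add-one estimator ``(1 + #{|ES_null| >= |ES|}) / (1 + n_perm)``,
    so its floor is 1/(n_perm + 1).  NES = ES / mean(|same-sign null ES|).
    FDR q compares pooled null and observed NES tail fractions, capped at
    1.  With ``fdr_max`` set, rows above the cutoff are dropped (the
    enrichment-map filter, conventionally q < 0.1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ranked = _ranked(scores)
    arr = ranked.to_numpy(dtype=float)
    ids = ranked.index
    n = arr.size
    rng = np.random.default_rng(seed)

    obs: list[GeneSetResult] = []
    null_nes_all: list[float] = []
    for name, members in gene_sets.items():
        present = set(members) & set(ids)
        if not present:
            continue
        es, _, leading = enrichment_score(ranked, present, weight_exponent)
        k = len(present)
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            null_es[i] = _es_only(arr, mask, weight_exponent)
        p = (1.0 + float((np.abs(null_es) >= abs(es)).sum())) / (1.0 + n_perm)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = float(np.abs(same_sign).mean()) if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            null_nes = np.where(
                null_es >= 0,
                null_es / (np.abs(null_es[null_es >= 0]).mean() or np.nan),
                null_es / (np.abs(null_es[null_es < 0]).mean() or np.nan),
            )
        null_nes_all.extend(null_nes[np.isfinite(null_nes)].tolist())
        obs.append(GeneSetResult(name, k, es, nes, p, np.nan, leading))

    null_nes_arr = np.asarray(null_nes_all)
    obs_nes = np.asarray([r.nes for r in obs])
    for r in obs:
        if r.nes >= 0:
            null_tail = float((null_nes_arr >= r.nes).mean()) if null_nes_arr.size else 1.0
            obs_tail = float((obs_nes >= r.nes).mean())
        else:
            null_tail = float((null_nes_arr <= r.nes).mean()) if null_nes_arr.size else 1.0
            obs_tail = float((obs_nes <= r.nes).mean())
        r.fdr_q = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0

    df = pd.DataFrame(
        {
            "name": [r.name for r in obs],
            "size": [r.size for r in obs],
            "es": [r.es for r in obs],
            "nes": [r.nes for r in obs],
            "p_perm": [r.p_perm for r in obs],
            "fdr_q": [r.fdr_q for r in obs],
            "core_enriched": [";".join(r.core_enriched) for r in obs],
        }
    )
    if fdr_max is not None:
        df = df[df["fdr_q"] < fdr_max].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------


def nearest_rank_percentile(values: pd.Series, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th smallest value."""
    if not 0.0 < q < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    vals = np.sort(values.to_numpy(dtype=float))
    k = int(np.ceil(q * vals.size))
    return float(vals[max(k, 1) - 1])


def select_candidates(
    sexbias_records: pd.DataFrame,
    expression: pd.Series,
    neuro_go: Iterable[str] = (),
    upregulated: Iterable[str] = (),
    gsea_core: Iterable[str] = (),
    literature: Iterable[str] = (),
    percentile: float = 0.70,
) -> pd.DataFrame:
    """Annotate final-timepoint sex-biased genes and pick candidates.

    A gene is a candidate when it carries at least one neuro-implication
    flag (GO slim, upregulated-at-final-timepoint trajectory, core-enriched
    GSEA membership, or literature evidence) and its expression lies
    strictly above the nearest-rank ``percentile`` of the flagged genes'
    expression.  Output is sorted by adjusted p.
    """
    flags = {
        "neuro_go": set(neuro_go),
        "upregulated_at_D37": set(upregulated),
        "in_neural_gsea_cluster": set(gsea_core),
        "literature": set(literature),
    }
    df = sexbias_records.copy()
    for col, members in flags.items():
        df[col] = df["gene_id"].isin(members)
    df["any_neuro_flag"] = df[list(flags)].any(axis=1)
    df["expression"] = expression.reindex(df["gene_id"]).to_numpy()
    flagged = df[df["any_neuro_flag"]]
    if flagged.empty:
        df["expression_percentile"] = np.nan
        df["is_candidate"] = False
        return df.sort_values("padj", kind="mergesort").reset_index(drop=True)
    cut = nearest_rank_percentile(flagged["expression"].dropna(), percentile)
    # percentile rank of each gene within the flagged reference set
    ref = np.sort(flagged["expression"].dropna().to_numpy())
    df["expression_percentile"] = [
        float(np.searchsorted(ref, v, side="right")) / ref.size if np.isfinite(v) else np.nan
        for v in df["expression"]
    ]
    df["is_candidate"] = df["any_neuro_flag"] & (df["expression"] > cut)
    return df.sort_values("padj", kind="mergesort").reset_index(drop=True)
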