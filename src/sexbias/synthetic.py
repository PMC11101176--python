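"""Synthetic count-matrix generator with planted ground truth.

Emulates the design of a sex-balanced stem-cell differentiation timecourse:
3 cell lines per sex x 4 timepoints x 3 replicates, negative-binomial
counts, Y genes silent in XX samples, XCI-escapee dosage, per-line XCI
erosion, planted sex-biased genes, trajectory classes and X/Y gametolog
pairs.  Everything planted is recorded in a :class:`TruthTable` so
downstream estimators can be validated against known truth.

Count model
-----------
For gene *g* in sample *j* (line l, timepoint t, replicate r):

    counts ~ NB(mean = s_j * mu_g,l,t,  dispersion alpha)

with ``Var = mu + alpha * mu**2``.  The per-condition mean decomposes as

    mu_g,l,t = base_g * traj_g(t) * jitter_g,l * sexfactor_g,sex(l)

* ``base_g`` — lognormal baseline expression.
* ``traj_g(t)`` — trajectory multiplier (peak at one timepoint, declining
  from D0, or flat).
* ``jitter_g,l`` — per-(gene, line) lognormal factor so within-sex
  line-to-line variation is nonzero (exercises the CV filter).
* ``sexfactor`` — 0 for Y genes in XX; escapee dosage boost in XX;
  erosion boost in eroded (gene, line) combinations; planted sex-bias
  fold changes at their designated timepoints.

Erosion-prone genes are shared across lines: each non-escapee X gene gets a
rank in a single erosion-propensity order and a line with erosion fraction
*f* reactivates the top-*f* slice.  Culture-induced erosion recurs at the
same loci across lines, and this makes the planted XX:XY ratio analytic:
a gene eroded in *k* of the XX lines has expected pooled ratio
``(k*boost + (n-k))/n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneAnnotation,
    SampleSheet,
    DEFAULT_TIMEPOINT_ORDER,
)

TRAJECTORY_CLASSES = ("stable", "peak_D4", "peak_D9", "peak_D37", "decreasing")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study design."""

    n_lines_per_sex: int = 3
    n_replicates: int = 3
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINT_ORDER
    n_autosomal: int = 2000
    n_x: int = 300
    n_y: int = 23
    n_gametolog_pairs: int = 12
    frac_escapee: float = 0.1
    #: multiplicative XX dosage boost for XCI escapees (biallelic expression)
    escapee_dosage: float = 1.29
    #: cell_line -> fraction of non-escapee X genes reactivated in that line
    erosion_fraction_per_line: Mapping[str, float] | None = None
    erosion_boost: float = 2.0
    n_planted_sexbiased: int = 0
    planted_log2fc: float = 1.0
    #: timepoints at which the planted sex effect applies; None = all
    planted_timepoints: tuple[str, ...] | None = None
    #: lognormal location/scale of baseline gene means
    baseline_mean_log: float = math.log(200.0)
    baseline_mean_sd: float = 1.0
    #: NB dispersion alpha (Var = mu + alpha mu^2); replicate-level noise of
    #: clonal lines — between-line variability comes from the jitter term
    dispersion: float = 0.02
    #: optional lognormal sigma for per-gene dispersion around ``dispersion``
    per_gene_dispersion_sd: float = 0.0
    #: per-(gene, line) lognormal jitter, sigma on the log2 scale
    line_jitter_sd_log2: float = 0.1
    library_size_range: tuple[float, float] = (0.5, 2.0)
    trajectory_classes: Mapping[str, float] = field(
        default_factory=lambda: {
            "stable": 0.29,
            "peak_D4": 0.05,
            "peak_D9": 0.06,
            "peak_D37": 0.34,
            "decreasing": 0.26,
        }
    )
    #: multiplier at the peak (or at D0 for decreasing genes)
    trajectory_fold: float = 3.0
    #: Y:X expression ratio for gametolog Y members (scalar or one per pair)
    gametolog_y_x_ratio: float | Sequence[float] = 1.0
    #: multiplier on X-gene means in XX samples (dosage-balance experiments)
    x_dosage_xx: float = 1.0
    #: restrict the design to one sex, e.g. ("XX",); None = both
    sexes: tuple[str, ...] | None = None
    #: Poisson background added to Y genes in XX samples (0 = perfectly silent)
    y_leak_mean: float = 0.0
    #: planted genes are drawn among autosomal genes with base mean >= this,
    #: so the planted truth is detectable in principle
    planted_min_base_mean: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_escapee",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.erosion_fraction_per_line:
            for line, f in self.erosion_fraction_per_line.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"erosion fraction for {line} must be in [0,1]")
        props = dict(self.trajectory_classes)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("trajectory_classes proportions must sum to 1")
        unknown = set(props) - set(TRAJECTORY_CLASSES)
        if unknown:
            raise ValueError(f"unknown trajectory classes: {sorted(unknown)}")
        if self.n_gametolog_pairs > min(self.n_x, self.n_y):
            raise ValueError("n_gametolog_pairs exceeds available X or Y genes")


@dataclass
class TruthTable:
    """Everything the generator planted, for use as a test oracle."""

    genes: pd.DataFrame          # indexed by gene_id
    eroded: pd.DataFrame         # X genes x XX lines, boolean
    size_factors: pd.Series      # true per-sample library size factor
    line_jitter: pd.DataFrame    # genes x lines multiplicative factors
    config: SimulationConfig


def _design(config: SimulationConfig) -> SampleSheet:
    sexes = config.sexes or ("XX", "XY")
    rows = []
    for sex in sexes:
        prefix = "F" if sex == "XX" else "M"
        for i in range(1, config.n_lines_per_sex + 1):
            line = f"{prefix}{i}"
            for tp in config.timepoints:
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{line}_{tp}_r{rep}",
                            "cell_line": line,
                            "sex": sex,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    return SampleSheet(pd.DataFrame(rows), tuple(config.timepoints))


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    n_a, n_x, n_y = config.n_autosomal, config.n_x, config.n_y
    width = max(5, len(str(max(n_a, n_x, n_y, 1))))
    auto = [f"GA{str(i).zfill(width)}" for i in range(1, n_a + 1)]
    xg = [f"GX{str(i).zfill(width)}" for i in range(1, n_x + 1)]
    yg = [f"GY{str(i).zfill(width)}" for i in range(1, n_y + 1)]
    return auto, xg, yg


#: autosomes over which simulated autosomal genes are spread (round-robin)
DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))


def simulate(
    config: SimulationConfig,
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
) -> tuple[CountMatrix, TruthTable]:
    """Draw a full synthetic dataset.  Identical config => identical output.

    Parameters
    ----------
    autosomes
        Chromosome labels to spread autosomal genes over; pass e.g.
        ``("5", "16")`` to build a dedicated ratio-baseline gene pool.
    """
    config.validate()
    samples = _design(config)
    if config.erosion_fraction_per_line:
        known = set(samples.frame["cell_line"])
        bad = set(config.erosion_fraction_per_line) - known
        if bad:
            raise ValueError(f"erosion fractions given for unknown lines: {sorted(bad)}")

    # one master seed; deterministic child streams per stage
    children = np.random.SeedSequence(config.seed).spawn(6)
    rng_base, rng_assign, rng_jitter, rng_lib, rng_counts, rng_leak = (
        np.random.default_rng(s) for s in children
    )

    auto_ids, x_ids, y_ids = _gene_ids(config)
    gene_ids = auto_ids + x_ids + y_ids
    n_genes = len(gene_ids)

    # -- static gene properties ---------------------------------------------
    chroms = pd.Series(index=gene_ids, dtype=object)
    chroms[auto_ids] = [autosomes[i % len(autosomes)] for i in range(len(auto_ids))]
    chroms[x_ids] = "X"
    chroms[y_ids] = "Y"

    base = pd.Series(
        rng_base.lognormal(config.baseline_mean_log, config.baseline_mean_sd, n_genes),
        index=gene_ids,
    )

    # trajectory class per gene
    classes = list(config.trajectory_classes)
    probs = np.array([config.trajectory_classes[c] for c in classes])
    traj_class = pd.Series(
        rng_assign.choice(classes, size=n_genes, p=probs), index=gene_ids
    )
    tps = list(config.timepoints)
    traj = pd.DataFrame(1.0, index=gene_ids, columns=tps)
    fold = config.trajectory_fold
    for cls in classes:
        members = traj_class.index[traj_class == cls]
        if cls == "stable" or len(members) == 0:
            continue
        if cls == "decreasing":
            # geometric decline from D0
            expo = np.linspace(1.0, 0.0, len(tps))
            traj.loc[members, :] = np.power(fold, expo)[None, :]
        else:
            peak_tp = cls.split("_", 1)[1]
            if peak_tp in traj.columns:
                traj.loc[members, peak_tp] = fold
            # a peak class whose timepoint is absent degrades to flat

    # escapees among X genes
    n_esc = int(round(config.frac_escapee * config.n_x))
    escapee_ids = list(rng_assign.choice(x_ids, size=n_esc, replace=False)) if n_esc else []
    escapee = pd.Series(False, index=gene_ids)
    escapee[escapee_ids] = True

    # gametolog pairs: i-th X gene <-> i-th Y gene
    partner = pd.Series(None, index=gene_ids, dtype=object)
    ratios = config.gametolog_y_x_ratio
    if np.isscalar(ratios):
        ratios = [float(ratios)] * config.n_gametolog_pairs
    y_x_ratio = pd.Series(np.nan, index=gene_ids)
    for i in range(config.n_gametolog_pairs):
        xg, yg = x_ids[i], y_ids[i]
        partner[xg], partner[yg] = yg, xg
        y_x_ratio[yg] = ratios[i]
        # tie the Y homolog baseline to its X partner
        base[yg] = base[xg] * ratios[i]

    # erosion: shared propensity order over non-escapee X genes
    non_esc_x = [g for g in x_ids if not escapee[g]]
    propensity = list(rng_assign.permutation(non_esc_x))
    xx_lines = samples.lines_of_sex("XX")
    eroded = pd.DataFrame(False, index=x_ids, columns=xx_lines)
    for line in xx_lines:
        f = (config.erosion_fraction_per_line or {}).get(line, 0.0)
        k = int(round(f * len(propensity)))
        eroded.loc[propensity[:k], line] = True

    # planted sex-biased genes: autosomal, adequately expressed, alternate dir
    planted = pd.Series(False, index=gene_ids)
    direction = pd.Series(None, index=gene_ids, dtype=object)
    if config.n_planted_sexbiased:
        eligible = [g for g in auto_ids if base[g] >= config.planted_min_base_mean]
        if len(eligible) < config.n_planted_sexbiased:
            raise ValueError(
                f"only {len(eligible)} autosomal genes have base mean >= "
                f"{config.planted_min_base_mean}; cannot plant "
                f"{config.n_planted_sexbiased}"
            )
        chosen = list(rng_assign.choice(eligible, config.n_planted_sexbiased, replace=False))
        planted[chosen] = True
        direction[chosen] = ["male_up" if i % 2 == 0 else "female_up"
                             for i in range(len(chosen))]

    # per-(gene, line) jitter
    all_lines = sorted(samples.frame["cell_line"].unique())
    sigma_ln = config.line_jitter_sd_log2 * math.log(2.0)
    jitter = pd.DataFrame(
        rng_jitter.lognormal(0.0, sigma_ln, size=(n_genes, len(all_lines)))
        if sigma_ln > 0 else np.ones((n_genes, len(all_lines))),
        index=gene_ids,
        columns=all_lines,
    )

    # -- per-(line, timepoint) means ----------------------------------------
    sex_of = samples.sex_of_line()
    planted_tps = set(config.planted_timepoints or config.timepoints)
    half_fc = 2.0 ** (config.planted_log2fc / 2.0)

    mean_blocks: dict[tuple[str, str], np.ndarray] = {}
    base_arr = base.to_numpy()
    is_y = chroms.to_numpy() == "Y"
    is_x = chroms.to_numpy() == "X"
    esc_arr = escapee.to_numpy()
    for line in all_lines:
        sex = sex_of[line]
        sexfac = np.ones(n_genes)
        if sex == "XX":
            sexfac[is_y] = 0.0
            sexfac[is_x] *= config.x_dosage_xx
            sexfac[esc_arr] *= config.escapee_dosage
            er = eroded[line].reindex(gene_ids, fill_value=False).to_numpy(dtype=bool)
            sexfac[er] *= config.erosion_boost
        for tp in tps:
            fac = sexfac.copy()
            if tp in planted_tps:
                up_m = (direction == "male_up").to_numpy()
                up_f = (direction == "female_up").to_numpy()
                if sex == "XY":
                    fac[up_m] *= half_fc
                    fac[up_f] /= half_fc
                else:
                    fac[up_f] *= half_fc
                    fac[up_m] /= half_fc
            mean_blocks[(line, tp)] = (
                base_arr * traj[tp].to_numpy() * jitter[line].to_numpy() * fac
            )

    # -- draw counts ---------------------------------------------------------
    sdf = samples.frame
    lo, hi = config.library_size_range
    size_factors = pd.Series(
        rng_lib.uniform(lo, hi, len(sdf)), index=sdf["sample_id"].to_numpy()
    )

    if config.per_gene_dispersion_sd > 0:
        alpha_g = rng_base.lognormal(
            math.log(config.dispersion), config.per_gene_dispersion_sd, n_genes
        )
    else:
        alpha_g = np.full(n_genes, config.dispersion)

    counts = np.empty((n_genes, len(sdf)), dtype=np.int64)
    for j, (sid, line, tp) in enumerate(
        sdf[["sample_id", "cell_line", "timepoint"]].astype(str).itertuples(index=False, name=None)
    ):
        mu = mean_blocks[(line, tp)] * size_factors[sid]
        counts[:, j] = _rnb(rng_counts, mu, alpha_g)
    if config.y_leak_mean > 0:
        xx_cols = np.array([sex_of[l] == "XX" for l in sdf["cell_line"]])
        leak = rng_leak.poisson(
            config.y_leak_mean, size=(int(is_y.sum()), int(xx_cols.sum()))
        )
        counts[np.ix_(is_y, xx_cols)] += leak

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sdf["sample_id"].to_numpy())

    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "symbol": gene_ids,
                "chromosome": chroms.to_numpy(),
                # round-number lengths keep TPM hand-checkable
                "length_bp": np.full(n_genes, 1000, dtype=int),
                "escapee": escapee.to_numpy(),
                "gametolog_partner": partner.to_numpy(),
            }
        )
    )
    cm = CountMatrix(counts_df, annotation, samples)

    truth_genes = pd.DataFrame(
        {
            "chromosome": chroms,
            "base_mean": base,
            "trajectory_class": traj_class,
            "escapee": escapee,
            "planted": planted,
            "planted_direction": direction,
            "planted_log2fc": np.where(planted, config.planted_log2fc, 0.0),
            "gametolog_partner": partner,
            "y_x_ratio": y_x_ratio,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = TruthTable(
        genes=truth_genes,
        eroded=eroded,
        size_factors=size_factors,
        line_jitter=jitter,
        config=config,
    )
    return cm, truth


def _rnb(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draw with mean ``mu`` and Var = mu + alpha mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        lam = rng.gamma(shape=1.0 / alpha[nb], scale=alpha[nb] * mu[nb])
        out[nb] = rng.poisson(lam)
    return out


def truth_expected_ratio(truth: TruthTable) -> pd.Series:
    """Analytic expected pooled XX:XY expression ratio per X-linked gene.

    Escapees: the configured escapee dosage.  Eroded genes: the erosion
    boost averaged over XX lines, ``(sum of per-line boosts) / n_lines``.
    Everything else: 1.0.  The ``x_dosage_xx`` factor scales all of them.
    """
    cfg = truth.config
    x_genes = truth.genes.index[truth.genes["chromosome"] == "X"]
    ratio = pd.Series(1.0, index=x_genes)
    esc = truth.genes.loc[x_genes, "escapee"]
    ratio[esc] = cfg.escapee_dosage
    er = truth.eroded.reindex(index=x_genes).fillna(False)
    if er.shape[1]:
        boost = np.where(er.to_numpy(), cfg.erosion_boost, 1.0).mean(axis=1)
        ratio[~esc] = boost[~esc.to_numpy()]
    return ratio * cfg.x_dosage_xx


# alias matching the operation name used elsewhere in the docs
truth_escapee_ratio = truth_expected_ratio


def write_simulation(cm: CountMatrix, truth: TruthTable, outdir) -> dict[str, str]:
    """Write counts, sample sheet, annotation and truth table as TSVs."""
    from pathlib import Path
    from .io_formats import write_counts, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_counts(cm, paths["counts"])
    cm.samples.frame.to_csv(paths["samples"], sep="\t", index=False)
    cm.genes.frame.to_csv(paths["annotation"], sep="\t", index=False)
    write_table(truth.genes.reset_index(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
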