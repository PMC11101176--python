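"""End-to-end orchestration: normalize -> DE -> stringent filter -> summary
-> XCI -> gametologs -> timecourse -> GSEA -> candidates, driven by one
config, with per-stage structured logging and a manifest of output hashes.

The manifest records every written file with its SHA-256, so a rerun with
the same config and seed can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import normalization as nm
from . import filtering, gametologs, timecourse, xci, enrichment
from .io_formats import (
    read_counts,
    read_gene_annotation,
    read_gmt,
    read_sample_sheet,
    read_table,
    write_table,
    DEFAULT_TIMEPOINT_ORDER,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None          # GMT, optional
    neuro_flags: str | None = None        # TSV: gene_id, neuro_go, literature
    outdir: str = "sexbias_out"
    counts_format: str = "tsv"
    timepoint_order: tuple[str, ...] = DEFAULT_TIMEPOINT_ORDER
    de_method: str = "nb_wald"
    de_table: str | None = None           # externally produced DE table
    seed: int = 0
    n_perm: int = 1000
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    xci: xci.XCIConfig = field(default_factory=xci.XCIConfig)
    gametolog: gametologs.GametologConfig = field(
        default_factory=gametologs.GametologConfig
    )
    stable_max_fold: float = 1.5
    candidate_percentile: float = 0.70

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {
            "filter": filtering.FilterConfig,
            "xci": xci.XCIConfig,
            "gametolog": gametologs.GametologConfig,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**(val or {}))
            elif key == "timepoint_order":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("counts", "samples", "annotation"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"pipeline config missing required path: {name}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("gene_sets", "neuro_flags", "de_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        write_table(df, path)
        written.append(path)
        logger.info("stage output: %s (%d rows)", name, len(df))

    try:
        stage = "load"
        samples = read_sample_sheet(config.samples, config.timepoint_order)
        annotation = read_gene_annotation(config.annotation)
        cm = read_counts(config.counts, samples, annotation, config.counts_format)
        logger.info("loaded %d genes x %d samples", *cm.shape)

        stage = "normalize"
        norm = nm.normalize(cm)
        emit(
            norm.size_factor.rename_axis("sample_id").reset_index(), "size_factors.tsv"
        )

        stage = "de"
        de_by_tp: dict[str, pd.DataFrame] = {}
        if config.de_table:
            ext = read_table(config.de_table)
            for contrast, sub in ext.groupby("contrast"):
                if str(contrast).startswith("sex_"):
                    de_by_tp[str(contrast)[4:]] = sub.set_index(
                        sub["gene_id"]
                    ).rename_axis(None)
            logger.info("using external DE table: %s", config.de_table)
        else:
            for tp in samples.timepoints:
                de_by_tp[tp] = nm.sex_contrast(
                    norm, tp, method=config.de_method,
                    min_count=config.filter.min_count,
                )
                logger.info("de sex_%s: %d genes tested", tp, len(de_by_tp[tp]))
        emit(pd.concat(de_by_tp.values(), ignore_index=True), "de_sex.tsv")

        stage = "filter"
        records = []
        for tp, de in de_by_tp.items():
            rec = filtering.stringent_filter(de, norm, annotation, tp, config.filter)
            logger.info(
                "filter %s: %d tested -> %d sex-biased", tp, len(de), len(rec)
            )
            records.append(rec)
        records = (
            pd.concat(records, ignore_index=True)
            if records
            else pd.DataFrame(
                columns=["gene_id", "timepoint", "direction", "log2fc", "padj",
                         "cv_xx", "cv_xy", "min_pairwise_diff_observed",
                         "chrom_class"]
            )
        )
        emit(records, "sexbias_records.tsv")

        stage = "table2"
        emit(filtering.table2_summary(records), "table2_summary.tsv")

        stage = "xci"
        tpm = norm.tpm()
        report = xci.xci_report(tpm, samples, annotation, config.xci)
        emit(report.gene_ratios.reset_index(), "xci_gene_ratios.tsv")
        emit(report.line_summary, "xci_line_summary.tsv")
        emit(report.x_to_a.reset_index(), "xci_x_to_a.tsv")
        var = pd.DataFrame([{k: v for k, v in report.variance.items()
                             if k != "line_average"}])
        emit(var, "xci_variance.tsv")

        stage = "gametologs"
        dosage, groups = gametologs.gametolog_report(norm, annotation, config.gametolog)
        emit(dosage, "gametolog_dosage.tsv")
        emit(groups, "gametolog_groups.tsv")

        stage = "timecourse"
        classes = timecourse.classify_trajectory(
            norm, stable_max_fold=config.stable_max_fold,
            min_count=config.filter.min_count,
        )
        emit(classes.reset_index(), "trajectory_classes.tsv")
        emit(timecourse.trajectory_summary(classes, annotation), "trajectory_summary.tsv")

        stage = "enrich"
        final_tp = samples.timepoints[-1]
        gsea = pd.DataFrame(
            columns=["name", "size", "es", "nes", "p_perm", "fdr_q", "core_enriched"]
        )
        core_genes: set[str] = set()
        if config.gene_sets:
            sets = read_gmt(config.gene_sets)
            scores = de_by_tp[final_tp].set_index("gene_id")["stat"]
            gsea = enrichment.significance(
                scores, sets, n_perm=config.n_perm, seed=config.seed
            )
            sig = gsea[gsea["fdr_q"] < 0.1]
            for leading in sig["core_enriched"]:
                core_genes.update(g for g in str(leading).split(";") if g)
            logger.info(
                "gsea %s: %d sets, %d below q<0.1", final_tp, len(gsea), len(sig)
            )
        emit(gsea, "gsea.tsv")

        stage = "candidates"
        d37_records = records[records["timepoint"] == final_tp]
        neuro, literature = set(), set()
        if config.neuro_flags:
            flags = read_table(config.neuro_flags)
            if "neuro_go" in flags.columns:
                neuro = set(flags.loc[flags["neuro_go"].astype(bool), "gene_id"])
            if "literature" in flags.columns:
                literature = set(flags.loc[flags["literature"].astype(bool), "gene_id"])
        upreg = set(
            classes.index[classes["trajectory_class"] == f"peak_{final_tp}"]
        )
        expr_final = norm.norm[samples.select(timepoint=final_tp)].mean(axis=1)
        candidates = enrichment.select_candidates(
            d37_records,
            expr_final,
            neuro_go=neuro,
            upregulated=upreg,
            gsea_core=core_genes,
            literature=literature,
            percentile=config.candidate_percentile,
        )
        emit(candidates, "candidates.tsv")
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _jsonable(config),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["timepoint_order"] = list(d["timepoint_order"])
    return d
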