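"""Readers, writers and validated in-memory containers.

Every external table the pipeline touches — counts (TSV or MatrixMarket),
sample sheet, gene annotation, GMT gene sets, and the report TSVs — passes
through this module, so downstream code always operates on checked,
canonically ordered structures.

Canonical ordering: genes sorted lexicographically by ``gene_id``; samples
sorted by ``(cell_line, timepoint, replicate)`` with the timepoint order
declared on the sample sheet (default D0 < D4 < D9 < D37). Reading a
permuted file therefore yields an identical :class:`CountMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINT_ORDER: tuple[str, ...] = ("D0", "D4", "D9", "D37")

SEXES = ("XX", "XY")

SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_line", "sex", "timepoint", "replicate")
ANNOTATION_COLUMNS = (
    "gene_id",
    "symbol",
    "chromosome",
    "length_bp",
    "escapee",
    "gametolog_partner",
)

#: fixed precision used for every float written by :func:`write_table`;
#: 12 significant digits so reports round-trip losslessly at test tolerance.
FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Raised when an input table violates a schema invariant."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Experimental design: one row per sequenced sample.

    Parameters
    ----------
    frame
        Columns ``sample_id, cell_line, sex, timepoint, replicate``.
    timepoint_order
        Declared ordering of the differentiation timepoints.  The order is
        configuration, not parsed from labels, so additional timepoints
        (e.g. D17, D27) extend the schema without code changes.
    """

    frame: pd.DataFrame
    timepoint_order: tuple[str, ...] = DEFAULT_TIMEPOINT_ORDER

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["cell_line"] = df["cell_line"].astype(str)
        df["timepoint"] = df["timepoint"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"sex must be one of {SEXES}, got {sorted(bad_sex)}")
        bad_tp = set(df["timepoint"]) - set(self.timepoint_order)
        if bad_tp:
            raise ValidationError(
                f"timepoints {sorted(bad_tp)} not in declared order {self.timepoint_order}"
            )
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate must be a positive integer")
        trip = df[["cell_line", "timepoint", "replicate"]]
        if trip.duplicated().any():
            raise ValidationError(
                "duplicate (cell_line, timepoint, replicate) triples in sample sheet"
            )
        n_sex = df.groupby("cell_line")["sex"].nunique()
        if (n_sex > 1).any():
            bad = n_sex[n_sex > 1].index.tolist()
            raise ValidationError(f"cell lines mapped to more than one sex: {bad}")
        tp_cat = pd.CategoricalDtype(categories=list(self.timepoint_order), ordered=True)
        df["timepoint"] = df["timepoint"].astype(tp_cat)
        df = df.sort_values(["cell_line", "timepoint", "replicate"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.frame = df

    # -- convenience views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def timepoints(self) -> list[str]:
        """Timepoints present, in declared order."""
        present = set(self.frame["timepoint"].astype(str))
        return [t for t in self.timepoint_order if t in present]

    def sex_of_line(self) -> dict[str, str]:
        return dict(
            self.frame.drop_duplicates("cell_line")[["cell_line", "sex"]].itertuples(
                index=False, name=None
            )
        )

    def lines_of_sex(self, sex: str) -> list[str]:
        return sorted(
            self.frame.loc[self.frame["sex"] == sex, "cell_line"].unique().tolist()
        )

    def select(self, sex: str | None = None, timepoint: str | None = None,
               cell_line: str | None = None) -> list[str]:
        """Sample ids matching the given design coordinates."""
        df = self.frame
        mask = pd.Series(True, index=df.index)
        if sex is not None:
            mask &= df["sex"] == sex
        if timepoint is not None:
            mask &= df["timepoint"].astype(str) == timepoint
        if cell_line is not None:
            mask &= df["cell_line"] == cell_line
        return df.loc[mask, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Per-gene metadata: chromosome, length, XCI-escapee flag, gametolog link.

    Gene identifiers are opaque strings; ``symbol`` is display-only and never
    participates in joins.  ``escapee`` marks X-linked genes known to escape
    X-chromosome inactivation (user-supplied, not computed).
    ``gametolog_partner`` links an X-chromosome gene to its Y homolog and
    must be symmetric.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = set(ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"gene annotation missing columns: {sorted(missing)}")
        df["gene_id"] = df["gene_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        df["length_bp"] = df["length_bp"].astype(int)
        if (df["length_bp"] < 1).any():
            bad = df.loc[df["length_bp"] < 1, "gene_id"].tolist()
            raise ValidationError(f"length_bp must be >= 1, offending genes: {bad}")
        if df["escapee"].dtype != bool:
            df["escapee"] = (
                df["escapee"].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
            if df["escapee"].isna().any():
                raise ValidationError("escapee column must be boolean")
        bad_esc = df.loc[df["escapee"] & (df["chromosome"] != "X"), "gene_id"]
        if len(bad_esc):
            raise ValidationError(
                f"escapee=True only allowed on chromosome X: {bad_esc.tolist()}"
            )
        part = df["gametolog_partner"]
        part = part.where(~part.isna(), None)
        part = part.map(lambda v: None if v in (None, "", "nan", "None") else str(v))
        df["gametolog_partner"] = part
        by_id = df.set_index("gene_id")
        for gid, pid in part.dropna().set_axis(df["gene_id"][part.notna()]).items():
            if pid not in by_id.index:
                raise ValidationError(f"gametolog partner {pid} of {gid} not annotated")
            back = by_id.at[pid, "gametolog_partner"]
            if back != gid:
                raise ValidationError(
                    f"gametolog_partner not symmetric: {gid}->{pid} but {pid}->{back}"
                )
            chroms = {by_id.at[gid, "chromosome"], by_id.at[pid, "chromosome"]}
            if chroms != {"X", "Y"}:
                raise ValidationError(
                    f"gametolog pair {gid}/{pid} must link one X and one Y gene"
                )
        df = df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
        self.frame = df

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()

    def chromosome_of(self) -> pd.Series:
        return self.frame.set_index("gene_id")["chromosome"]

    def genes_on(self, chromosomes: str | Sequence[str]) -> list[str]:
        if isinstance(chromosomes, str):
            chromosomes = [chromosomes]
        df = self.frame
        return df.loc[df["chromosome"].isin(list(chromosomes)), "gene_id"].tolist()

    def escapees(self) -> list[str]:
        df = self.frame
        return df.loc[df["escapee"], "gene_id"].tolist()

    def lengths(self) -> pd.Series:
        return self.frame.set_index("gene_id")["length_bp"]

    def chrom_class(self) -> pd.Series:
        """Map each gene to Y / X_escapee / X_other / autosomal."""
        df = self.frame.set_index("gene_id")
        cls = pd.Series("autosomal", index=df.index, dtype=object)
        cls[df["chromosome"] == "X"] = "X_other"
        cls[(df["chromosome"] == "X") & df["escapee"]] = "X_escapee"
        cls[df["chromosome"] == "Y"] = "Y"
        return cls

    def gametolog_pairs(self) -> list[tuple[str, str]]:
        """(x_gene, y_gene) tuples, each pair reported once."""
        df = self.frame
        pairs = []
        for gid, chrom, pid in df[["gene_id", "chromosome", "gametolog_partner"]].itertuples(
            index=False, name=None
        ):
            if pid is not None and chrom == "X":
                pairs.append((gid, pid))
        return sorted(pairs)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with aligned metadata.

    Invariants enforced at construction: the count index matches the
    annotation exactly and the columns match the sample sheet exactly (no
    orphans either way); entries are non-negative whole numbers; no missing
    values.  Rows/columns are put in canonical order.
    """

    counts: pd.DataFrame
    genes: GeneAnnotation
    samples: SampleSheet

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.isna().any().any():
            raise ValidationError("count matrix contains missing values")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at gene {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {arr[r, c]}"
                )
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            r, c = np.argwhere(counts.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at gene {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}"
            )
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids in counts: {dup}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in counts: {dup}")
        gene_ids = self.genes.gene_ids
        sample_ids = self.samples.sample_ids
        extra_g = set(counts.index) - set(gene_ids)
        miss_g = set(gene_ids) - set(counts.index)
        if extra_g or miss_g:
            raise ValidationError(
                f"gene index mismatch with annotation: extra={sorted(extra_g)[:5]}, "
                f"missing={sorted(miss_g)[:5]}"
            )
        extra_s = set(counts.columns) - set(sample_ids)
        miss_s = set(sample_ids) - set(counts.columns)
        if extra_s or miss_s:
            raise ValidationError(
                f"sample mismatch with sheet: extra={sorted(extra_s)}, "
                f"missing={sorted(miss_s)}"
            )
        # canonical ordering from the metadata, never from file order
        counts = counts.loc[gene_ids, sample_ids].astype(np.int64)
        counts.index.name = "gene_id"
        counts.columns.name = None
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path,
                      timepoint_order: Sequence[str] = DEFAULT_TIMEPOINT_ORDER) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df, tuple(timepoint_order))


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["gametolog_partner"] = df["gametolog_partner"].where(
        df["gametolog_partner"].notna(), None
    )
    return GeneAnnotation(df)


def read_counts(path: str | Path, samples: SampleSheet, genes: GeneAnnotation,
                format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count table.

    ``tsv``: gene-id first column, sample-id header.  ``mtx``: MatrixMarket
    coordinate file with sidecar name files ``<path>.rownames.txt`` and
    ``<path>.colnames.txt`` (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        mat = scipy.io.mmread(str(path))
        rows = _read_names(Path(str(path) + ".rownames.txt"))
        cols = _read_names(Path(str(path) + ".colnames.txt"))
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        if dense.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match name files "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        df = pd.DataFrame(dense, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown counts format: {format!r}")
    return CountMatrix(df, genes, samples)


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise ValidationError(f"missing sidecar name file: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        # mmwrite appends .mtx if absent; normalise so sidecars sit next to it
        mtx_path = path if path.suffix == ".mtx" else Path(str(path) + ".mtx")
        Path(str(mtx_path) + ".rownames.txt").write_text(
            "\n".join(cm.counts.index) + "\n"
        )
        Path(str(mtx_path) + ".colnames.txt").write_text(
            "\n".join(cm.counts.columns) + "\n"
        )
    else:
        raise ValueError(f"unknown counts format: {format!r}")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [member ids]}``.

    Duplicate members within a set are dropped (first occurrence kept);
    empty sets are dropped with a logged warning.
    """
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}: unreadable GMT line {i}")
        name = parts[0]
        members = list(dict.fromkeys(m for m in parts[2:] if m))
        if not members:
            logger.warning("GMT set %r (line %d) is empty; dropped", name, i)
            continue
        sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a flat report with deterministic order and fixed float precision.

    Rows are sorted by ``gene_id`` then ``contrast``/``timepoint`` when those
    columns exist, otherwise left in the given order; floats render with 12
    significant digits so a write/read cycle is lossless at that precision.
    """
    df = records.copy()
    if "gene_id" in df.columns:
        sort_cols = ["gene_id"] + [c for c in ("contrast", "timepoint") if c in df.columns]
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
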