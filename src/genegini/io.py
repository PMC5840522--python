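"""Reading and writing expression tables.

Two table shapes are supported:

* **long** — one row per (gene, sample) observation, as distributed by the
  Human Protein Atlas (``rna_tissue.tsv`` / ``rna_celline.tsv``: columns
  ``Gene``, ``Gene name``, ``Sample``, ``Value``).  Replicate rows for the
  same (gene, sample) pair are collapsed by arithmetic mean when pivoting.
* **wide** — the canonical matrix layout: first column ``gene``, one column
  per sample, TPM values in the cells.

A converter is included for supplementary spreadsheets (XLSX) that hold a
wide gene x sample grid, emitting the canonical wide TSV.

Gene-class annotation (SLC / ABC / other) is symbol-pattern based with an
override table for transporters whose names do not follow the official
nomenclature (e.g. the mitochondrial carrier homologue MTCH1, which is
functionally an SLC).
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyAnalysisError, ValidationError
from .matrix import ExpressionMatrix, SampleKind

__all__ = [
    "Dialect",
    "HPA_DIALECT",
    "SIMPLE_DIALECT",
    "ExpressionRecord",
    "GeneClass",
    "GeneAnnotation",
    "PivotResult",
    "read_long_tsv",
    "write_long_tsv",
    "pivot_matrix",
    "read_wide_tsv",
    "write_wide_tsv",
    "convert_xlsx_to_tsv",
    "annotate_genes",
    "filter_low_expression",
]


# ----------------------------------------------------------------------
# long-format records
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a long-format expression table."""

    gene_symbol: str
    sample: str
    tpm: str
    gene_id: str | None = None


#: Human Protein Atlas long-table column names.
HPA_DIALECT = Dialect(gene_id="Gene", gene_symbol="Gene name", sample="Sample", tpm="Value")

#: Minimal three-column layout used by the package's own writers.
SIMPLE_DIALECT = Dialect(gene_symbol="gene", sample="sample", tpm="tpm")


@dataclass(frozen=True)
class ExpressionRecord:
    """One (gene, sample, TPM) observation."""

    gene_symbol: str
    sample: str
    tpm: float
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be nonempty")
        if not self.sample:
            raise ValidationError("sample must be nonempty")
        if not np.isfinite(self.tpm) or self.tpm < 0:
            raise ValidationError(f"tpm must be a non-negative real, got {self.tpm!r}")


def read_long_tsv(path: str | Path, dialect: Dialect = HPA_DIALECT) -> list[ExpressionRecord]:
    """Parse a long-format TSV into validated records.

    Rows whose value column is not a non-negative real raise a
    :class:`ValidationError` naming the offending 1-based data-row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ExpressionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        needed = [dialect.gene_symbol, dialect.sample, dialect.tpm]
        missing = [c for c in needed if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing mapped column(s) {missing}; header={header}")
        for i, row in enumerate(reader, start=1):
            raw = row[dialect.tpm]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"{path}: row {i}: non-numeric TPM value {raw!r}") from None
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{path}: row {i}: invalid TPM value {raw!r}")
            gene_id = row.get(dialect.gene_id, "") if dialect.gene_id else ""
            records.append(
                ExpressionRecord(
                    gene_symbol=row[dialect.gene_symbol],
                    sample=row[dialect.sample],
                    tpm=value,
                    gene_id=gene_id or "",
                )
            )
    return records


def write_long_tsv(matrix: ExpressionMatrix, path: str | Path, dialect: Dialect = SIMPLE_DIALECT) -> None:
    """Write every cell of a matrix (zeros included) as long-format TSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([dialect.gene_symbol, dialect.sample, dialect.tpm])
        for gene in matrix.genes:
            for sample, value in zip(matrix.samples, matrix.profile(gene)):
                writer.writerow([gene, sample, repr(float(value))])


@dataclass
class PivotResult:
    """A pivoted matrix plus bookkeeping on cells filled with 0 TPM."""

    matrix: ExpressionMatrix
    n_filled: int
    filled_cells: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):  # allows `matrix, n_filled = pivot_matrix(...)`
        return iter((self.matrix, self.n_filled))


def pivot_matrix(
    records: Sequence[ExpressionRecord],
    sample_kind: SampleKind | str = SampleKind.OTHER,
) -> PivotResult:
    """Pivot long records to a gene x sample matrix.

    Duplicate (gene, sample) observations — replicates — are collapsed by
    arithmetic mean.  Missing combinations are filled with 0 TPM and counted,
    since long tables may omit zero rows while the Gini coefficient needs a
    complete profile.  Gene and sample order is lexicographic, so the result
    is invariant to record order.
    """
    if not records:
        raise ValidationError("no records to pivot")
    frame = pd.DataFrame(
        {
            "gene": [r.gene_symbol for r in records],
            "sample": [r.sample for r in records],
            "tpm": [r.tpm for r in records],
        }
    )
    grouped = frame.groupby(["gene", "sample"], sort=True)["tpm"].mean()
    wide = grouped.unstack("sample")
    missing_mask = wide.isna()
    filled = [
        (str(wide.index[i]), str(wide.columns[j]))
        for i, j in zip(*np.nonzero(missing_mask.to_numpy()))
    ]
    wide = wide.fillna(0.0).sort_index(axis=0).sort_index(axis=1)
    gene_ids: dict[str, str] = {}
    for r in records:
        if r.gene_id:
            gene_ids.setdefault(r.gene_symbol, r.gene_id)
    matrix = ExpressionMatrix(wide, sample_kind=SampleKind(sample_kind), gene_ids=gene_ids)
    return PivotResult(matrix=matrix, n_filled=len(filled), filled_cells=filled)


# ----------------------------------------------------------------------
# wide-format matrices
# ----------------------------------------------------------------------
def read_wide_tsv(path: str | Path, sample_kind: SampleKind | str = SampleKind.OTHER) -> ExpressionMatrix:
    """Read the canonical wide TSV (first column ``gene``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.index.name = "gene"
    return ExpressionMatrix(frame, sample_kind=SampleKind(sample_kind))


def write_wide_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.data.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def convert_xlsx_to_tsv(
    xlsx_path: str | Path,
    tsv_path: str | Path,
    sheet: str | int = 0,
    gene_column: str | int = 0,
) -> ExpressionMatrix:
    """Convert a wide gene x sample spreadsheet to canonical TSV.

    Non-numeric columns besides the gene column (e.g. family or description
    columns that supplementary tables often carry) are dropped with a
    warning.  Returns the matrix that was written.
    """
    frame = pd.read_excel(xlsx_path, sheet_name=sheet, engine="openpyxl")
    if isinstance(gene_column, int):
        gene_col_name = frame.columns[gene_column]
    else:
        gene_col_name = gene_column
    frame = frame.set_index(gene_col_name)
    frame.index = frame.index.astype(str)
    numeric = frame.select_dtypes(include=[np.number])
    dropped = [c for c in frame.columns if c not in numeric.columns]
    if dropped:
        warnings.warn(f"dropping non-numeric columns: {dropped}", stacklevel=2)
    matrix = ExpressionMatrix(numeric)
    write_wide_tsv(matrix, tsv_path)
    return matrix


# ----------------------------------------------------------------------
# gene-class annotation
# ----------------------------------------------------------------------
class GeneClass(str, enum.Enum):
    SLC = "SLC"
    ABC = "ABC"
    OTHER = "other"


@dataclass(frozen=True)
class GeneAnnotation:
    """Class and family membership of one gene symbol."""

    gene_symbol: str
    gene_class: GeneClass
    family: str = ""
    is_override: bool = False

    def __post_init__(self) -> None:
        if (self.gene_class is not GeneClass.OTHER) != bool(self.family):
            raise ValidationError(
                f"{self.gene_symbol}: family must be set iff class is SLC/ABC"
            )


_SLC_RE = re.compile(r"^SLC(\d+)[A-Z]\d*$")
_ABC_RE = re.compile(r"^ABC([A-G])\d+$")


def annotate_genes(
    symbols: Sequence[str],
    overrides: Mapping[str, GeneClass | str | tuple] | None = None,
) -> list[GeneAnnotation]:
    """Assign SLC / ABC / other classes by symbol pattern plus overrides.

    ``SLC<family><subfamily letter><member>`` parses to class SLC with family
    ``SLC<family>``; ``ABC<A-G><member>`` to class ABC with family
    ``ABC<letter>``.  Overrides (symbol -> class, or -> (class, family)) take
    precedence and are flagged; an override naming a symbol absent from the
    input only warns.  Every symbol receives exactly one class.
    """
    if len(set(symbols)) != len(symbols):
        raise ValidationError("gene symbols must be unique")
    overrides = dict(overrides or {})
    unknown = [s for s in overrides if s not in set(symbols)]
    if unknown:
        warnings.warn(f"overrides for symbols not in input: {unknown}", stacklevel=2)
    annotations: list[GeneAnnotation] = []
    for symbol in symbols:
        if symbol in overrides:
            spec = overrides[symbol]
            if isinstance(spec, tuple):
                cls, family = GeneClass(spec[0]), str(spec[1])
            else:
                cls = GeneClass(spec)
                family = cls.value if cls is not GeneClass.OTHER else ""
            annotations.append(
                GeneAnnotation(symbol, cls, family=family, is_override=True)
            )
            continue
        m = _SLC_RE.match(symbol)
        if m:
            annotations.append(GeneAnnotation(symbol, GeneClass.SLC, family=f"SLC{m.group(1)}"))
            continue
        m = _ABC_RE.match(symbol)
        if m:
            annotations.append(GeneAnnotation(symbol, GeneClass.ABC, family=f"ABC{m.group(1)}"))
            continue
        annotations.append(GeneAnnotation(symbol, GeneClass.OTHER))
    return annotations


# ----------------------------------------------------------------------
# expression filter
# ----------------------------------------------------------------------
def filter_low_expression(
    matrix: ExpressionMatrix, max_tpm_threshold: float = 0.25
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose *maximum* TPM over samples is <= the threshold.

    Mirrors the practice of ignoring genes with very little expression
    anywhere (default 0.25 TPM, inclusive so that a gene peaking exactly at
    the threshold is removed).  Returns the filtered matrix (original order
    preserved) and the removed gene symbols.
    """
    if max_tpm_threshold < 0:
        raise ValidationError("threshold must be >= 0")
    maxima = matrix.data.max(axis=1)
    removed = [str(g) for g in matrix.data.index[maxima <= max_tpm_threshold]]
    kept = [g for g in matrix.genes if g not in set(removed)]
    if not kept:
        raise EmptyAnalysisError("expression filter removed every gene")
    return matrix.subset_genes(kept), removed
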