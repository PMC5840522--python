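"""The in-memory expression container: a gene x sample grid of TPM values.

All downstream statistics operate on :class:`ExpressionMatrix`, a thin,
validated wrapper around a pandas DataFrame whose rows are gene symbols and
whose columns are tissue or cell-line names.  Values are transcripts per
million (TPM): non-negative, finite, within-sample normalized abundances.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


class SampleKind(str, enum.Enum):
    """What the columns of a matrix represent."""

    TISSUE = "tissue"
    CELL_LINE = "cell_line"
    OTHER = "other"


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with light metadata.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene symbols with unique sample-name
        columns; every value must be a finite, non-negative real.
    sample_kind
        Whether the samples are tissues, cell lines, or something else.
    gene_ids
        Optional mapping from gene symbol to a stable identifier (e.g. an
        Ensembl gene ID).  Retained as metadata only; joining is by symbol.
    """

    data: pd.DataFrame
    sample_kind: SampleKind = SampleKind.OTHER
    gene_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        self.sample_kind = SampleKind(self.sample_kind)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample names: {dupes[:5]}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if values.size and (values < 0).any():
            raise ValidationError("expression values must be non-negative TPM")
        self.data = self.data.astype(float)

    # ------------------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    # ------------------------------------------------------------------
    def profile(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        if gene not in self.data.index:
            raise KeyError(gene)
        return self.data.loc[gene].to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[list(genes)],
            sample_kind=self.sample_kind,
            gene_ids={g: self.gene_ids[g] for g in genes if g in self.gene_ids},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.sample_kind == other.sample_kind
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"kind={self.sample_kind.value})"
        )
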