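"""Per-gene profile summaries and class-level Gini aggregation.

For every gene the summary carries the Gini coefficient of its expression
profile together with min / smallest-nonzero / max / median / total TPM, the
zero count, the dominant sample (where the maximum sits) and the dominance
fold (maximum over second-largest value — large folds flag single-tissue
specificity).  Class summaries aggregate Ginis within SLC / ABC / other and
count genes above and below the conventional high (0.9) and low (0.25)
inequality thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyAnalysisError, ValidationError
from .gini import gini
from .io import GeneAnnotation, GeneClass
from .matrix import ExpressionMatrix

__all__ = [
    "GeneProfileStats",
    "ClassSummary",
    "SampleTotals",
    "CorrelationSummary",
    "profile_summary",
    "class_gini_summary",
    "sample_totals",
    "gini_median_correlation",
    "stats_to_frame",
    "write_stats_tsv",
    "read_stats_tsv",
]


@dataclass(frozen=True)
class GeneProfileStats:
    gene_symbol: str
    gene_class: GeneClass
    family: str
    gini: float | None  # None => undefined (all-zero profile)
    min: float
    min_nonzero: float | None
    max: float
    median: float
    total: float
    n_zero: int
    dominant_sample: str
    dominance_fold: float  # max / second-largest; inf if second-largest is 0

    @property
    def gini_defined(self) -> bool:
        return self.gini is not None


def _summarize_profile(values: np.ndarray, samples: Sequence[str]) -> dict:
    total = float(values.sum())
    nonzero = values[values > 0]
    vmax = float(values.max())
    # tie-break the dominant sample lexicographically so the result is
    # invariant to column order
    top_names = [str(samples[i]) for i in np.flatnonzero(values == vmax)]
    dominant = min(top_names)
    sorted_desc = np.sort(values)[::-1]
    second = float(sorted_desc[1]) if values.size > 1 else 0.0
    if vmax == 0.0:
        fold = 1.0  # constant zero profile: no dominance
    elif second == 0.0:
        fold = math.inf
    else:
        fold = vmax / second
    return dict(
        gini=None if total == 0 else gini(values),
        min=float(values.min()),
        min_nonzero=float(nonzero.min()) if nonzero.size else None,
        max=vmax,
        median=float(np.median(values)),
        total=total,
        n_zero=int((values == 0).sum()),
        dominant_sample=dominant,
        dominance_fold=fold,
    )


def profile_summary(
    matrix: ExpressionMatrix, annotations: Sequence[GeneAnnotation]
) -> list[GeneProfileStats]:
    """One :class:`GeneProfileStats` row per gene of the matrix.

    All-zero genes get ``gini=None`` (undefined) and are excluded from
    downstream medians and correlations but still reported.  Medians are
    taken over all samples, zeros included.  Raises if any gene lacks an
    annotation.
    """
    if matrix.n_genes == 0:
        raise EmptyAnalysisError("empty matrix")
    ann_by_symbol = {a.gene_symbol: a for a in annotations}
    missing = [g for g in matrix.genes if g not in ann_by_symbol]
    if missing:
        raise ValidationError(f"annotation missing for genes: {missing[:5]}")
    out: list[GeneProfileStats] = []
    samples = matrix.samples
    for gene in matrix.genes:
        ann = ann_by_symbol[gene]
        parts = _summarize_profile(matrix.profile(gene), samples)
        out.append(
            GeneProfileStats(
                gene_symbol=gene, gene_class=ann.gene_class, family=ann.family, **parts
            )
        )
    return out


@dataclass(frozen=True)
class ClassSummary:
    gene_class: GeneClass
    n_genes: int
    n_defined: int
    median_gini: float | None  # None when no gene in the class has a defined Gini
    n_ge_hi: int
    n_lt_lo: int
    frac_gt_075: float
    hi: float
    lo: float


def class_gini_summary(
    stats: Sequence[GeneProfileStats], hi: float = 0.9, lo: float = 0.25
) -> list[ClassSummary]:
    """Median Gini and threshold counts per gene class.

    Counts use ``gini >= hi`` ("at hi or above") and ``gini < lo`` ("below
    lo"); the median is over defined Ginis only.  Classes are returned in
    SLC, ABC, other order, restricted to classes present.
    """
    if not stats:
        raise EmptyAnalysisError("no gene stats to summarize")
    summaries: list[ClassSummary] = []
    for cls in (GeneClass.SLC, GeneClass.ABC, GeneClass.OTHER):
        members = [s for s in stats if s.gene_class is cls]
        if not members:
            continue
        ginis = np.array([s.gini for s in members if s.gini is not None], dtype=float)
        summaries.append(
            ClassSummary(
                gene_class=cls,
                n_genes=len(members),
                n_defined=int(ginis.size),
                median_gini=float(np.median(ginis)) if ginis.size else None,
                n_ge_hi=int((ginis >= hi).sum()),
                n_lt_lo=int((ginis < lo).sum()),
                frac_gt_075=float((ginis > 0.75).mean()) if ginis.size else 0.0,
                hi=hi,
                lo=lo,
            )
        )
    return summaries


@dataclass(frozen=True)
class SampleTotals:
    """Per-sample total TPM over a gene subset, with the extreme samples."""

    totals: pd.Series
    max_sample: str
    max_total: float
    min_sample: str
    min_total: float


def sample_totals(matrix: ExpressionMatrix, gene_subset: Sequence[str] | None = None) -> SampleTotals:
    """Column sums of TPM over a gene subset (default: all genes)."""
    if gene_subset is not None:
        if len(gene_subset) == 0:
            raise EmptyAnalysisError("empty gene subset")
        matrix = matrix.subset_genes(list(gene_subset))
    totals = matrix.data.sum(axis=0)
    return SampleTotals(
        totals=totals,
        max_sample=str(totals.idxmax()),
        max_total=float(totals.max()),
        min_sample=str(totals.idxmin()),
        min_total=float(totals.min()),
    )


@dataclass(frozen=True)
class CorrelationSummary:
    """Gini-vs-median-expression association across genes."""

    pearson_r_log10median: float
    pearson_r_raw: float
    spearman_rho: float
    n_used: int


def gini_median_correlation(stats: Sequence[GeneProfileStats]) -> CorrelationSummary:
    """Correlate per-gene Gini with log10(median TPM).

    Genes with undefined Gini or zero median are dropped (log10 needs a
    positive median; the same genes are used for every reported statistic).
    The expected direction in transcriptome-wide data is negative: the more
    a gene is expressed overall, the more evenly it tends to be expressed.
    """
    usable = [s for s in stats if s.gini is not None and s.median > 0]
    if len(usable) < 3:
        raise EmptyAnalysisError("need at least 3 genes with defined Gini and median > 0")
    g = np.array([s.gini for s in usable], dtype=float)
    med = np.array([s.median for s in usable], dtype=float)
    r_log = float(sps.pearsonr(g, np.log10(med)).statistic)
    r_raw = float(sps.pearsonr(g, med).statistic)
    rho = float(sps.spearmanr(g, med).statistic)
    return CorrelationSummary(
        pearson_r_log10median=r_log,
        pearson_r_raw=r_raw,
        spearman_rho=rho,
        n_used=len(usable),
    )


# ----------------------------------------------------------------------
# tabular output
# ----------------------------------------------------------------------
_COLUMNS = [
    "gene", "class", "family", "gini", "min", "min_nonzero", "max",
    "median", "total", "n_zero", "dominant_sample", "dominance_fold",
]


def stats_to_frame(stats: Sequence[GeneProfileStats]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene_symbol,
            "class": s.gene_class.value,
            "family": s.family,
            "gini": s.gini,
            "min": s.min,
            "min_nonzero": s.min_nonzero,
            "max": s.max,
            "median": s.median,
            "total": s.total,
            "n_zero": s.n_zero,
            "dominant_sample": s.dominant_sample,
            "dominance_fold": s.dominance_fold,
        }
        for s in stats
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_stats_tsv(stats: Sequence[GeneProfileStats], path: str | Path) -> None:
    """Write the per-gene stats table; undefined values appear as NA."""
    stats_to_frame(stats).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_stats_tsv(path: str | Path) -> list[GeneProfileStats]:
    """Read back a stats table written by :func:`write_stats_tsv`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    out: list[GeneProfileStats] = []
    for row in frame.itertuples(index=False):
        out.append(
            GeneProfileStats(
                gene_symbol=str(row.gene),
                gene_class=GeneClass(row._1),  # "class" is a keyword; positional name
                family="" if pd.isna(row.family) else str(row.family),
                gini=None if pd.isna(row.gini) else float(row.gini),
                min=float(row.min),
                min_nonzero=None if pd.isna(row.min_nonzero) else float(row.min_nonzero),
                max=float(row.max),
                median=float(row.median),
                total=float(row.total),
                n_zero=int(row.n_zero),
                dominant_sample=str(row.dominant_sample),
                dominance_fold=float(row.dominance_fold),
            )
        )
    return out
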