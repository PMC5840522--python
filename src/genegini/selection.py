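"""Candidate reference (housekeeping) genes and tissue-specific genes.

Reference candidates are genes whose expression is nearly uniform across
samples (low Gini) *and* adequately expressed (median TPM above a floor), so
that they are practical for normalizing qPCR or expression-profiling data.
Tissue-specific candidates sit at the other end: very high Gini and a large
dominance fold, i.e. one sample carries essentially all the expression.

Default thresholds (Gini <= 0.15 with median >= 20 TPM for references;
Gini >= 0.9 with >= 100-fold dominance for specific genes) reflect the
regimes in which well-behaved reference genes (e.g. PCBP1, GC ~ 0.14 at
~200 TPM) and archetypal single-tissue transporters (e.g. the urate
transporter SLC22A12 in kidney, GC ~ 0.98) live; all are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .profiles import GeneProfileStats

__all__ = [
    "ReferenceCandidate",
    "SpecificCandidate",
    "select_reference_genes",
    "select_specific_genes",
    "write_reference_tsv",
    "write_specific_tsv",
]


@dataclass(frozen=True)
class ReferenceCandidate:
    gene_symbol: str
    gini: float
    median_tpm: float
    rank: int


@dataclass(frozen=True)
class SpecificCandidate:
    gene_symbol: str
    gini: float
    dominant_sample: str
    dominance_fold: float
    max_tpm: float


def select_reference_genes(
    stats: Sequence[GeneProfileStats],
    gini_max: float = 0.15,
    median_min: float = 20.0,
) -> list[ReferenceCandidate]:
    """Rank low-Gini, adequately expressed genes as normalization references.

    Ranking is by ascending Gini; ties break by descending median TPM, then
    lexicographic symbol, so reports are reproducible.  An empty result is
    allowed (no error): with strict thresholds nothing may qualify.
    """
    if gini_max < 0 or median_min < 0:
        raise ValidationError("thresholds must be non-negative")
    eligible = [
        s
        for s in stats
        if s.gini is not None and s.gini <= gini_max and s.median >= median_min
    ]
    eligible.sort(key=lambda s: (s.gini, -s.median, s.gene_symbol))
    return [
        ReferenceCandidate(
            gene_symbol=s.gene_symbol, gini=float(s.gini), median_tpm=s.median, rank=i
        )
        for i, s in enumerate(eligible, start=1)
    ]


def select_specific_genes(
    stats: Sequence[GeneProfileStats],
    gini_min: float = 0.9,
    fold_min: float = 100.0,
    max_tpm_min: float = 0.0,
) -> list[SpecificCandidate]:
    """High-Gini, strongly dominant genes, sorted by descending Gini.

    ``max_tpm_min`` optionally requires a minimum peak expression (default 0:
    dominance alone decides).
    """
    if fold_min < 1:
        raise ValidationError("fold_min must be >= 1")
    if gini_min < 0 or max_tpm_min < 0:
        raise ValidationError("thresholds must be non-negative")
    chosen = [
        s
        for s in stats
        if s.gini is not None
        and s.gini >= gini_min
        and s.dominance_fold >= fold_min
        and s.max >= max_tpm_min
    ]
    chosen.sort(key=lambda s: (-s.gini, s.gene_symbol))
    return [
        SpecificCandidate(
            gene_symbol=s.gene_symbol,
            gini=float(s.gini),
            dominant_sample=s.dominant_sample,
            dominance_fold=s.dominance_fold,
            max_tpm=s.max,
        )
        for s in chosen
    ]


def _fmt(value: float) -> str:
    return "inf" if math.isinf(value) else f"{value:.6g}"


def write_reference_tsv(
    candidates: Sequence[ReferenceCandidate],
    path: str | Path,
    gini_max: float = 0.15,
    median_min: float = 20.0,
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# reference candidates: gini_max={gini_max} median_min={median_min}\n")
        fh.write("rank\tgene\tgini\tmedian_tpm\n")
        for c in candidates:
            fh.write(f"{c.rank}\t{c.gene_symbol}\t{c.gini:.6f}\t{_fmt(c.median_tpm)}\n")


def write_specific_tsv(
    candidates: Sequence[SpecificCandidate],
    path: str | Path,
    gini_min: float = 0.9,
    fold_min: float = 100.0,
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# specific candidates: gini_min={gini_min} fold_min={fold_min}\n")
        fh.write("gene\tgini\tdominant_sample\tdominance_fold\tmax_tpm\n")
        for c in candidates:
            fh.write(
                f"{c.gene_symbol}\t{c.gini:.6f}\t{c.dominant_sample}\t"
                f"{_fmt(c.dominance_fold)}\t{_fmt(c.max_tpm)}\n"
            )
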