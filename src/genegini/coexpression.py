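"""Co-expression analyses: pairwise correlation, PCA of samples, heatmaps.

Expression profiles span orders of magnitude, so Pearson correlation between
two genes (or two samples) is computed in log-log space; zeros are handled
either by dropping pairs where either value is 0 or by a +0.01 TPM
pseudocount.  Spearman rank correlation works on raw values with zeros
retained (midrank ties).  PCA treats samples as observations after scaling
every gene row to unit variance.  The heatmap helper orders rows and columns
by independent hierarchical clustering of the transformed matrix.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import EmptyAnalysisError, ValidationError
from .matrix import ExpressionMatrix

__all__ = [
    "CorrelationMethod",
    "ZeroPolicy",
    "CorrelationReport",
    "PcaResult",
    "CoclusterResult",
    "pairwise_correlation",
    "pca_samples",
    "cocluster",
]


class CorrelationMethod(str, enum.Enum):
    PEARSON_LOGLOG = "pearson_loglog"
    SPEARMAN = "spearman"


class ZeroPolicy(str, enum.Enum):
    DROP_PAIRS = "drop_pairs"
    PSEUDOCOUNT = "pseudocount"


#: pseudocount in TPM added under ZeroPolicy.PSEUDOCOUNT (a common display floor)
PSEUDOCOUNT_TPM = 0.01


@dataclass(frozen=True)
class CorrelationReport:
    item_a: str
    item_b: str
    method: CorrelationMethod
    r: float
    r2: float
    n_used: int


def pairwise_correlation(
    x,
    y,
    method: CorrelationMethod | str = CorrelationMethod.PEARSON_LOGLOG,
    zero_policy: ZeroPolicy | str = ZeroPolicy.DROP_PAIRS,
    item_a: str = "x",
    item_b: str = "y",
) -> CorrelationReport:
    """Correlation between two equally long expression profiles.

    ``pearson_loglog`` applies the zero policy, log10-transforms both
    profiles and computes Pearson r; ``spearman`` ranks the raw values with
    zeros retained.  Fewer than 3 usable pairs is an error.
    """
    method = CorrelationMethod(method)
    zero_policy = ZeroPolicy(zero_policy)
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise ValidationError("profiles must have equal length")
    if method is CorrelationMethod.PEARSON_LOGLOG:
        if zero_policy is ZeroPolicy.DROP_PAIRS:
            keep = (xv > 0) & (yv > 0)
            xv, yv = xv[keep], yv[keep]
        else:
            xv = xv + PSEUDOCOUNT_TPM
            yv = yv + PSEUDOCOUNT_TPM
        if xv.size < 3:
            raise EmptyAnalysisError("fewer than 3 usable pairs after zero handling")
        r = float(sps.pearsonr(np.log10(xv), np.log10(yv)).statistic)
    else:
        if xv.size < 3:
            raise EmptyAnalysisError("fewer than 3 pairs")
        r = float(sps.spearmanr(xv, yv).statistic)
    return CorrelationReport(
        item_a=item_a, item_b=item_b, method=method, r=r, r2=r * r, n_used=int(xv.size)
    )


@dataclass(frozen=True)
class PcaResult:
    """Principal-component scores of samples plus the scree."""

    scores: pd.DataFrame  # samples x components
    explained_fraction: np.ndarray
    n_components: int
    dropped_genes: list[str]


def pca_samples(matrix: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples on gene-wise unit-variance expression.

    Every gene row is centered and scaled to unit (sample) variance;
    zero-variance genes carry no information after scaling and are dropped
    with a warning.  Components are computed with samples as observations
    and genes as features, deterministically (full SVD, fixed sign
    convention).  With all components kept the explained fractions sum to 1.
    """
    if matrix.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(matrix.genes, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)", stacklevel=2)
    if int(keep.sum()) < 2:
        raise EmptyAnalysisError("fewer than 2 genes with nonzero variance")
    scaled = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    observations = scaled.T  # samples x genes
    max_rank = min(observations.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(observations)
    scores = pd.DataFrame(
        coords, index=matrix.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcaResult(
        scores=scores,
        explained_fraction=pca.explained_variance_ratio_.copy(),
        n_components=k,
        dropped_genes=dropped,
    )


class HeatmapTransform(str, enum.Enum):
    LOG10P1 = "log10p1"
    UNIT_VARIANCE = "unit_variance"


class DistanceMetric(str, enum.Enum):
    CORRELATION = "correlation"
    EUCLIDEAN = "euclidean"


class LinkageMethod(str, enum.Enum):
    AVERAGE = "average"
    COMPLETE = "complete"


@dataclass(frozen=True)
class CoclusterResult:
    row_order: list[str]
    col_order: list[str]
    row_cluster_labels: dict[str, int]


def _transform(values: np.ndarray, transform: HeatmapTransform) -> np.ndarray:
    if transform is HeatmapTransform.LOG10P1:
        return np.log10(values + 1.0)
    sd = values.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0  # constant rows stay centered at zero
    return (values - values.mean(axis=1, keepdims=True)) / sd[:, None]


def cocluster(
    matrix: ExpressionMatrix,
    transform: HeatmapTransform | str = HeatmapTransform.LOG10P1,
    distance: DistanceMetric | str = DistanceMetric.CORRELATION,
    linkage: LinkageMethod | str = LinkageMethod.AVERAGE,
    k_rows: int = 4,
) -> CoclusterResult:
    """Hierarchically co-cluster genes (rows) and samples (columns).

    Rows and columns are clustered independently on the transformed matrix;
    dendrogram leaf orders give the heatmap ordering and a ``k_rows``-cut of
    the row dendrogram labels the major gene clusters.  Deterministic for a
    fixed input.
    """
    transform = HeatmapTransform(transform)
    distance = DistanceMetric(distance)
    linkage = LinkageMethod(linkage)
    if matrix.n_genes < 2 or matrix.n_samples < 2:
        raise ValidationError("matrix must be at least 2x2")
    if k_rows < 1 or k_rows > matrix.n_genes:
        raise ValidationError("k_rows must be between 1 and the number of genes")
    values = _transform(matrix.values, transform)

    def _cluster(data: np.ndarray):
        dist = pdist(data, metric=distance.value)
        # identical rows give zero variance => NaN correlation distance; they
        # are maximally similar, so use zero distance
        dist = np.nan_to_num(dist, nan=0.0)
        link = hierarchy.linkage(dist, method=linkage.value)
        return link, hierarchy.leaves_list(link)

    row_link, row_leaves = _cluster(values)
    _, col_leaves = _cluster(values.T)
    labels = hierarchy.fcluster(row_link, t=k_rows, criterion="maxclust")
    genes = matrix.genes
    return CoclusterResult(
        row_order=[genes[i] for i in row_leaves],
        col_order=[matrix.samples[i] for i in col_leaves],
        row_cluster_labels={g: int(l) for g, l in zip(genes, labels)},
    )
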