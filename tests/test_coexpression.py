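"""Pairwise correlation, unit-variance PCA of samples and co-clustering."""

import numpy as np
import pandas as pd
import pytest

from genegini import (
    EmptyAnalysisError,
    ExpressionMatrix,
    ValidationError,
    cocluster,
    pairwise_correlation,
    pca_samples,
)
from genegini.coexpression import _transform, HeatmapTransform


# ----------------------------------------------------------------------
# pairwise correlation
# ----------------------------------------------------------------------
def test_identity_profile_r_one():
    x = [1.0, 5.0, 30.0, 200.0]
    for method in ("pearson_loglog", "spearman"):
        report = pairwise_correlation(x, x, method=method)
        assert report.r == pytest.approx(1.0)
        assert report.r2 == pytest.approx(1.0)


def test_correlation_symmetry(rng):
    x = rng.gamma(1.0, 50.0, size=20)
    y = rng.gamma(1.0, 50.0, size=20)
    for method in ("pearson_loglog", "spearman"):
        a = pairwise_correlation(x, y, method=method)
        b = pairwise_correlation(y, x, method=method)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.r2 == pytest.approx(a.r**2, abs=1e-15)


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.gamma(1.0, 50.0, size=30)
    y = rng.gamma(1.0, 50.0, size=30)
    base = pairwise_correlation(x, y, method="spearman").r
    assert pairwise_correlation(np.sqrt(x), y, method="spearman").r == pytest.approx(base)
    assert pairwise_correlation(x, y**3, method="spearman").r == pytest.approx(base)


def test_zero_policies():
    x = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
    y = np.array([5.0, 2.0, 20.0, 200.0, 0.0])
    dropped = pairwise_correlation(x, y, zero_policy="drop_pairs")
    assert dropped.n_used == 3  # first and last pairs contain a zero
    pseudo = pairwise_correlation(x, y, zero_policy="pseudocount")
    assert pseudo.n_used == 5
    assert dropped.r != pseudo.r


def test_correlation_errors():
    with pytest.raises(EmptyAnalysisError):
        pairwise_correlation([0, 0, 1, 2], [1, 2, 0, 0], zero_policy="drop_pairs")
    with pytest.raises(ValidationError):
        pairwise_correlation([1, 2, 3], [1, 2])


# ----------------------------------------------------------------------
# PCA of samples
# ----------------------------------------------------------------------
def _matrix(array, genes=None, samples=None):
    array = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return ExpressionMatrix(pd.DataFrame(array, index=genes, columns=samples))


def test_scree_conservation(default_simulation):
    matrix, _ = default_simulation
    result = pca_samples(matrix)
    assert result.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(result.explained_fraction) <= 1e-12).all()
    assert (result.explained_fraction >= -1e-15).all()


def test_duplicated_sample_gets_identical_scores(rng):
    base = rng.gamma(1.0, 50.0, size=(30, 5))
    dup = np.column_stack([base, base[:, 2]])
    result = pca_samples(_matrix(dup))
    np.testing.assert_allclose(
        result.scores.iloc[2].to_numpy(), result.scores.iloc[5].to_numpy(), atol=1e-9
    )


def test_unit_variance_scaling_property(rng):
    values = rng.gamma(1.0, 50.0, size=(12, 8))
    scaled = _transform(values, HeatmapTransform.UNIT_VARIANCE)
    np.testing.assert_allclose(scaled.var(axis=1, ddof=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(scaled.mean(axis=1), 0.0, atol=1e-12)


def test_pca_matches_eigendecomposition_oracle():
    """3-sample toy: component variances equal the eigenvalues of the sample
    covariance of the scaled observations (constant gene row dropped)."""
    m = _matrix([[1, 2, 3], [1, 3, 5], [2, 2, 2]])
    with pytest.warns(UserWarning, match="zero-variance"):
        result = pca_samples(m)
    assert result.dropped_genes == ["g2"]
    values = m.values[:2]
    scaled = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1)[:, None]
    obs = scaled.T
    cov = np.cov(obs.T, ddof=1)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    got = result.explained_fraction * eigvals.sum()
    np.testing.assert_allclose(got, eigvals[: len(got)], atol=1e-9)


def test_pca_errors():
    # all gene rows constant: nothing informative survives scaling
    with pytest.warns(UserWarning, match="zero-variance"):
        with pytest.raises(EmptyAnalysisError):
            pca_samples(_matrix([[1, 1, 1], [2, 2, 2]]))
    # a single informative gene is still too few
    with pytest.warns(UserWarning, match="zero-variance"):
        with pytest.raises(EmptyAnalysisError):
            pca_samples(_matrix([[1, 1, 1], [2, 2, 2], [3, 4, 5]]))
    # fewer than 2 samples is rejected outright
    with pytest.raises(ValidationError):
        pca_samples(_matrix(np.ones((3, 1))))


# ----------------------------------------------------------------------
# co-clustering
# ----------------------------------------------------------------------
def test_identical_rows_cluster_together(rng):
    distinct = rng.gamma(1.0, 50.0, size=4)
    data = np.vstack([distinct, distinct, rng.gamma(1.0, 500.0, size=4) + 1000])
    result = cocluster(_matrix(data, genes=["a", "a2", "z"]), k_rows=2, distance="euclidean")
    order = result.row_order
    assert abs(order.index("a") - order.index("a2")) == 1
    labels = result.row_cluster_labels
    assert labels["a"] == labels["a2"] != labels["z"]


def test_k_one_single_label(toy_matrix):
    result = cocluster(toy_matrix, k_rows=1)
    assert set(result.row_cluster_labels.values()) == {1}


def test_k_too_large_is_error(toy_matrix):
    with pytest.raises(ValidationError):
        cocluster(toy_matrix, k_rows=toy_matrix.n_genes + 1)


def _two_block_matrix(rng, n_per_block=10, n_samples=12):
    """Two gene blocks, each following its own sample template closely."""
    t1 = rng.gamma(2.0, 50.0, size=n_samples)
    t2 = rng.permutation(t1)[::-1].copy()
    rows, genes = [], []
    for b, template in enumerate((t1, t2)):
        for i in range(n_per_block):
            rows.append(template * rng.uniform(0.5, 2.0) * np.exp(rng.normal(0, 0.05, n_samples)))
            genes.append(f"b{b}g{i}")
    return _matrix(np.vstack(rows), genes=genes), genes


def test_two_block_recovery(rng):
    matrix, genes = _two_block_matrix(rng)
    result = cocluster(matrix, transform="log10p1", distance="correlation", k_rows=2)
    labels = result.row_cluster_labels
    block0 = {labels[g] for g in genes[:10]}
    block1 = {labels[g] for g in genes[10:]}
    assert len(block0) == 1 and len(block1) == 1 and block0 != block1


def test_cocluster_partition_invariant_to_row_permutation(rng):
    matrix, genes = _two_block_matrix(rng)
    result = cocluster(matrix, k_rows=2)
    perm = list(rng.permutation(genes))
    permuted = cocluster(matrix.subset_genes(perm), k_rows=2)

    def partition(labels):
        groups = {}
        for g, l in labels.items():
            groups.setdefault(l, set()).add(g)
        return {frozenset(v) for v in groups.values()}

    assert partition(result.row_cluster_labels) == partition(permuted.row_cluster_labels)
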