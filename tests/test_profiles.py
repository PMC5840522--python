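"""Per-gene profile summaries, class aggregation, sample totals and the
Gini-vs-median-expression correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from genegini import (
    EmptyAnalysisError,
    ExpressionMatrix,
    GeneClass,
    ValidationError,
    annotate_genes,
    class_gini_summary,
    gini_median_correlation,
    profile_summary,
    read_stats_tsv,
    sample_totals,
    write_stats_tsv,
)
from genegini.profiles import GeneProfileStats


def _matrix(rows: dict, samples=None) -> ExpressionMatrix:
    samples = samples or [f"s{i+1}" for i in range(len(next(iter(rows.values()))))]
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


def _stats(rows: dict, **kwargs):
    m = _matrix(rows, **kwargs)
    return profile_summary(m, annotate_genes(m.genes))


def test_profile_summary_worked_example():
    (s,) = _stats({"g": [0.0, 0.0, 10.0, 10.0]})
    assert s.min == 0 and s.min_nonzero == 10 and s.max == 10
    assert s.median == 5 and s.total == 20 and s.n_zero == 2
    assert s.gini == pytest.approx(0.5, abs=1e-12)  # pairwise oracle: 8/(2*16*0.5)
    assert s.dominance_fold == 1.0  # two tied maxima


def test_profile_summary_constant_and_zero_profiles():
    stats = _stats({"const": [7.0, 7.0, 7.0], "dead": [0.0, 0.0, 0.0]})
    const, dead = stats
    assert const.gini == 0.0 and const.dominance_fold == 1.0
    assert dead.gini is None and not dead.gini_defined
    assert dead.min_nonzero is None and dead.n_zero == 3


def test_dominant_sample_and_fold():
    (s,) = _stats({"g": [1.0, 0.0, 500.0, 5.0]}, samples=["a", "b", "liver", "d"])
    assert s.dominant_sample == "liver"
    assert s.dominance_fold == pytest.approx(100.0)
    (one_hot,) = _stats({"g": [0.0, 3.0]})
    assert math.isinf(one_hot.dominance_fold)


def test_profile_summary_requires_annotations(toy_matrix):
    with pytest.raises(ValidationError, match="annotation missing"):
        profile_summary(toy_matrix, annotate_genes(toy_matrix.genes[:2]))


def test_profile_summary_sample_order_invariant(toy_matrix):
    anns = annotate_genes(toy_matrix.genes)
    base = profile_summary(toy_matrix, anns)
    shuffled = ExpressionMatrix(
        toy_matrix.data[["testis", "kidney", "liver"]], sample_kind=toy_matrix.sample_kind
    )
    again = profile_summary(shuffled, anns)
    for a, b in zip(base, again):
        assert a.gini == b.gini and a.median == b.median and a.dominance_fold == b.dominance_fold
        assert a.dominant_sample == b.dominant_sample


# ----------------------------------------------------------------------
# class summaries
# ----------------------------------------------------------------------
def _fake_stat(symbol, cls, g, median=10.0):
    return GeneProfileStats(
        gene_symbol=symbol, gene_class=cls, family="SLC1" if cls is GeneClass.SLC else "",
        gini=g, min=0.0, min_nonzero=1.0, max=100.0, median=median, total=500.0,
        n_zero=0, dominant_sample="s1", dominance_fold=2.0,
    )


def test_class_summary_two_genes():
    stats = [_fake_stat("A1", GeneClass.SLC, 0.2), _fake_stat("B1", GeneClass.SLC, 0.4)]
    (summary,) = class_gini_summary(stats)
    assert summary.median_gini == pytest.approx(0.3)
    assert summary.n_ge_hi == 0 and summary.n_lt_lo == 1


def test_class_summary_counts_partition(default_simulation):
    matrix, _ = default_simulation
    stats = profile_summary(matrix, annotate_genes(matrix.genes))
    for summary in class_gini_summary(stats):
        ginis = [s.gini for s in stats if s.gene_class is summary.gene_class and s.gini is not None]
        mid = sum(1 for g in ginis if summary.lo <= g < summary.hi)
        assert summary.n_ge_hi + mid + summary.n_lt_lo == summary.n_defined


def test_class_summary_undefined_class():
    stats = [_fake_stat("DEADG", GeneClass.OTHER, None)]
    (summary,) = class_gini_summary(stats)
    assert summary.median_gini is None and summary.n_defined == 0
    with pytest.raises(EmptyAnalysisError):
        class_gini_summary([])


# ----------------------------------------------------------------------
# sample totals
# ----------------------------------------------------------------------
def test_sample_totals_toy():
    m = _matrix({"g1": [1.0, 2.0], "g2": [3.0, 4.0]})
    totals = sample_totals(m)
    assert totals.totals.tolist() == [4.0, 6.0]
    assert totals.max_sample == "s2" and totals.min_sample == "s1"
    assert totals.max_total == 6.0 and totals.min_total == 4.0


def test_sample_totals_subset_and_errors(toy_matrix):
    totals = sample_totals(toy_matrix, gene_subset=["SLC22A4"])
    assert totals.max_sample == "liver"
    with pytest.raises(EmptyAnalysisError):
        sample_totals(toy_matrix, gene_subset=[])
    with pytest.raises(ValidationError):
        sample_totals(toy_matrix, gene_subset=["NOPE"])


# ----------------------------------------------------------------------
# gini vs median correlation
# ----------------------------------------------------------------------
def test_exact_linear_relation_gives_r_minus_one():
    stats = [
        _fake_stat(f"G{i}", GeneClass.OTHER, 1.0 - 0.1 * np.log10(m), median=m)
        for i, m in enumerate([1.0, 10.0, 100.0, 1000.0, 10000.0])
    ]
    report = gini_median_correlation(stats)
    assert report.pearson_r_log10median == pytest.approx(-1.0, abs=1e-12)
    assert report.spearman_rho == pytest.approx(-1.0, abs=1e-12)
    assert report.n_used == 5


def test_correlation_drops_zero_medians_and_needs_three():
    stats = [
        _fake_stat("A", GeneClass.OTHER, 0.5, median=0.0),  # dropped
        _fake_stat("B", GeneClass.OTHER, 0.4, median=2.0),
        _fake_stat("C", GeneClass.OTHER, 0.3, median=3.0),
    ]
    with pytest.raises(EmptyAnalysisError):
        gini_median_correlation(stats)
    stats.append(_fake_stat("D", GeneClass.OTHER, 0.2, median=4.0))
    assert gini_median_correlation(stats).n_used == 3


def test_simulated_correlation_is_negative(default_simulation):
    """Housekeeping genes are both even and well expressed while broad genes
    are spotty, so Gini falls with median expression overall."""
    matrix, _ = default_simulation
    stats = profile_summary(matrix, annotate_genes(matrix.genes))
    report = gini_median_correlation(stats)
    assert report.pearson_r_log10median < 0
    assert report.spearman_rho < 0


# ----------------------------------------------------------------------
# stats TSV round trip
# ----------------------------------------------------------------------
def test_stats_tsv_roundtrip(tmp_path, toy_matrix):
    stats = profile_summary(toy_matrix, annotate_genes(toy_matrix.genes))
    path = tmp_path / "stats.tsv"
    write_stats_tsv(stats, path)
    again = read_stats_tsv(path)
    assert [s.gene_symbol for s in again] == [s.gene_symbol for s in stats]
    for a, b in zip(stats, again):
        assert a.gene_class == b.gene_class and a.family == b.family
        assert (a.gini is None) == (b.gini is None)
        if a.gini is not None:
            assert b.gini == pytest.approx(a.gini, rel=1e-12)
        assert b.dominance_fold == pytest.approx(a.dominance_fold) or (
            math.isinf(a.dominance_fold) and math.isinf(b.dominance_fold)
        )
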