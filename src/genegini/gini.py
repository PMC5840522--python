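"""Gini coefficient and Lorenz curve of a non-negative expression profile.

The Gini coefficient (GC) summarizes how unequally a quantity is spread over
a set of observations.  For a gene expressed at TPM levels ``x_1..x_n`` in
``n`` samples it is the normalized mean absolute pairwise difference

    G = sum_i sum_j |x_i - x_j| / (2 n^2 mu),

the *unadjusted* convention (no ``n/(n-1)`` small-sample correction), which
is also the default of the R ``ineq`` package.  Equivalently G is the ratio
A/(A+B) of the area A between the equality diagonal and the Lorenz curve to
the whole area A+B under the diagonal.  G is 0 for a constant profile and
attains its maximum (n-1)/n when all expression sits in a single sample
("one-hot"); it is undefined when every value is zero.

Three formulations are provided and cross-check one another:

* :func:`gini` — the production O(n log n) sorted-rank formula;
* :func:`gini_pairwise` — the O(n^2) mean-difference definition, kept as an
  independent oracle for tests;
* :func:`gini_from_lorenz` — trapezoidal integration of the Lorenz curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedGiniError, ValidationError

__all__ = [
    "LorenzCurve",
    "gini",
    "gini_pairwise",
    "lorenz_curve",
    "gini_from_lorenz",
]


def _validated(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("empty profile")
    if not np.isfinite(x).all():
        raise ValidationError("profile contains non-finite values")
    if (x < 0).any():
        raise ValidationError("profile contains negative values")
    return x


def gini(values) -> float:
    """Unadjusted Gini coefficient of a non-negative profile.

    Uses the sorted-rank identity ``G = 2 sum_k k x_(k) / (n sum x) - (n+1)/n``
    with ``x_(1) <= ... <= x_(n)``.  Ties may be ordered arbitrarily; the
    statistic is tie-order invariant.

    Raises
    ------
    UndefinedGiniError
        If every value is zero (the mean is zero and G is undefined).
    ValidationError
        If any value is negative or non-finite, or the profile is empty.
    """
    x = _validated(values)
    total = x.sum()
    if total == 0:
        raise UndefinedGiniError("Gini undefined for an all-zero profile")
    n = x.size
    xs = np.sort(x)
    ranks = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.dot(ranks, xs) / (n * total) - (n + 1.0) / n)


def gini_pairwise(values) -> float:
    """O(n^2) mean-absolute-difference Gini; the test oracle formulation."""
    x = _validated(values)
    mu = x.mean()
    if mu == 0:
        raise UndefinedGiniError("Gini undefined for an all-zero profile")
    n = x.size
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff_sum / (2.0 * n * n * mu))


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative (population fraction, expression fraction) polyline.

    Point ``k`` is ``(k/n, sum of k smallest values / total)``; the curve
    starts at (0, 0), ends at (1, 1), and is convex, lying on or below the
    equality diagonal.
    """

    population_fraction: np.ndarray
    expression_fraction: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = np.asarray(self.population_fraction, dtype=float)
        e = np.asarray(self.expression_fraction, dtype=float)
        if p.shape != e.shape or p.ndim != 1 or p.size != self.n + 1:
            raise ValidationError("curve must hold n+1 matched points")
        if not (np.isclose(p[0], 0) and np.isclose(e[0], 0)):
            raise ValidationError("Lorenz curve must start at (0, 0)")
        if not (np.isclose(p[-1], 1) and np.isclose(e[-1], 1)):
            raise ValidationError("Lorenz curve must end at (1, 1)")
        if (np.diff(p) < -1e-12).any() or (np.diff(e) < -1e-12).any():
            raise ValidationError("Lorenz curve coordinates must be non-decreasing")
        # convexity: cumulative-share increments never shrink
        if (np.diff(np.diff(e)) < -1e-9).any():
            raise ValidationError("Lorenz curve must be convex")
        object.__setattr__(self, "population_fraction", p)
        object.__setattr__(self, "expression_fraction", e)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.population_fraction.tolist(), self.expression_fraction.tolist()))


def lorenz_curve(values) -> LorenzCurve:
    """Lorenz curve of a profile: values sorted ascending, cumulated.

    Raises the same errors as :func:`gini`.
    """
    x = _validated(values)
    total = x.sum()
    if total == 0:
        raise UndefinedGiniError("Lorenz curve undefined for an all-zero profile")
    xs = np.sort(x)
    cum = np.concatenate(([0.0], np.cumsum(xs))) / total
    pop = np.arange(x.size + 1, dtype=float) / x.size
    return LorenzCurve(population_fraction=pop, expression_fraction=cum, n=int(x.size))


def gini_from_lorenz(curve: LorenzCurve) -> float:
    """Gini as ``1 - 2 * (trapezoid area under the Lorenz curve)``.

    Agrees with :func:`gini` on the same data to within 1e-12.
    """
    area = float(np.trapezoid(curve.expression_fraction, curve.population_fraction))
    return 1.0 - 2.0 * area
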