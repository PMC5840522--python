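"""Synthetic TPM matrices with planted expression-inequality structure.

Three gene roles are planted, chosen to span the Gini range observed in
real tissue/cell-line atlases (roughly 0.11 to 0.98):

* **housekeeping** — log-normal profiles with a small log-scale sigma,
  i.i.d. across samples: nearly uniform expression, low Gini;
* **specific** — one uniformly chosen dominant sample at
  ``base_tpm * specific_fold`` (times multiplicative noise), all other
  samples at ``base_tpm`` (times noise): a near-one-hot profile whose Gini
  approaches the (n-1)/n maximum as the fold grows;
* **broad** — log-normal with a large sigma plus per-cell zero-inflation:
  widely variable, intermediate-to-high Gini.

Log-normal noise is used throughout because TPM is positive and because the
population Gini of a log-normal has the closed form ``2*Phi(sigma/sqrt(2)) - 1``
(:func:`expected_gini_lognormal`), giving an analytic calibration oracle.
Zero-inflation is restricted to broad genes so the housekeeping and specific
expectations stay analytic.  Generation is bit-reproducible for a fixed
config and seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .matrix import ExpressionMatrix, SampleKind

__all__ = [
    "GeneRole",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_matrix",
    "expected_gini_lognormal",
    "write_truth_tsv",
]


class GeneRole(str, enum.Enum):
    HOUSEKEEPING = "housekeeping"
    SPECIFIC = "specific"
    BROAD = "broad"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generator; defaults emulate a 59-tissue atlas."""

    n_samples: int = 59
    n_housekeeping: int = 50
    n_specific: int = 50
    n_broad: int = 200
    sigma_hk: float = 0.2          # log-scale s.d. of housekeeping (and specific) noise
    sigma_broad: float = 1.0       # log-scale s.d. of broad genes
    specific_fold: float = 1000.0  # dominant / background TPM ratio
    base_tpm: float = 100.0        # median expression scale
    zero_inflation_broad: float = 0.2  # P(a broad-gene cell is zeroed)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_housekeeping, self.n_specific, self.n_broad) < 0:
            raise ValidationError("gene counts must be >= 0")
        if self.n_housekeeping + self.n_specific + self.n_broad == 0:
            raise ValidationError("at least one gene must be requested")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.sigma_hk < 0 or self.sigma_broad < 0:
            raise ValidationError("sigmas must be >= 0")
        if self.specific_fold < 1:
            raise ValidationError("specific_fold must be >= 1")
        if not 0 <= self.zero_inflation_broad <= 1:
            raise ValidationError("zero_inflation_broad must be in [0, 1]")
        if self.base_tpm <= 0:
            raise ValidationError("base_tpm must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted role per gene, and the dominant sample of each specific gene."""

    roles: dict[str, GeneRole]
    dominant_sample: dict[str, str] = field(default_factory=dict)

    def genes_with_role(self, role: GeneRole) -> list[str]:
        return [g for g, r in self.roles.items() if r is role]


def expected_gini_lognormal(sigma: float) -> float:
    """Population Gini of a log-normal with log-scale s.d. ``sigma``.

    ``G = 2 * Phi(sigma / sqrt(2)) - 1`` with Phi the standard normal CDF;
    0 for the degenerate sigma = 0 case and increasing in sigma.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    return float(2.0 * norm.cdf(sigma / np.sqrt(2.0)) - 1.0)


def simulate_matrix(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate an expression matrix and the planted ground truth.

    Gene symbols carry role-mnemonic prefixes (``GENEsim`` housekeeping,
    ``SLCsim`` specific, ``ABCsim`` broad) so the symbol-pattern annotator
    can be exercised on synthetic input (none match the official transporter
    patterns, so all annotate as *other* unless overridden).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"sample{i + 1:02d}" for i in range(n)]

    rows: list[np.ndarray] = []
    genes: list[str] = []
    roles: dict[str, GeneRole] = {}
    dominant: dict[str, str] = {}

    for i in range(config.n_housekeeping):
        gene = f"GENEsim{i + 1:04d}"
        rows.append(config.base_tpm * np.exp(rng.normal(0.0, config.sigma_hk, size=n)))
        genes.append(gene)
        roles[gene] = GeneRole.HOUSEKEEPING

    for i in range(config.n_specific):
        gene = f"SLCsim{i + 1:04d}"
        profile = config.base_tpm * np.exp(rng.normal(0.0, config.sigma_hk, size=n))
        top = int(rng.integers(0, n))
        profile[top] *= config.specific_fold
        rows.append(profile)
        genes.append(gene)
        roles[gene] = GeneRole.SPECIFIC
        dominant[gene] = samples[top]

    for i in range(config.n_broad):
        gene = f"ABCsim{i + 1:04d}"
        profile = config.base_tpm * np.exp(rng.normal(0.0, config.sigma_broad, size=n))
        zeroed = rng.random(n) < config.zero_inflation_broad
        profile[zeroed] = 0.0
        rows.append(profile)
        genes.append(gene)
        roles[gene] = GeneRole.BROAD

    data = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    matrix = ExpressionMatrix(data, sample_kind=SampleKind.OTHER)
    return matrix, SyntheticTruth(roles=roles, dominant_sample=dominant)


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\trole\tdominant_sample\n")
        for gene, role in truth.roles.items():
            fh.write(f"{gene}\t{role.value}\t{truth.dominant_sample.get(gene, '')}\n")
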