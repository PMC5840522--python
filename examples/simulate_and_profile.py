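"""Generate a synthetic expression atlas and profile every gene.

The generator plants three gene roles with known Gini structure —
housekeeping (low Gini), tissue-specific (near one-hot, high Gini) and
broad (variable, zero-inflated) — then the pipeline filters barely
expressed genes, computes per-gene statistics and aggregates Ginis per
role.  The printed medians show the planted separation the selection step
relies on.
"""

import numpy as np

from genegini import (
    GeneRole,
    SimulationConfig,
    annotate_genes,
    expected_gini_lognormal,
    filter_low_expression,
    profile_summary,
    simulate_matrix,
)

config = SimulationConfig(seed=1)
matrix, truth = simulate_matrix(config)
print(f"simulated {matrix.n_genes} genes x {matrix.n_samples} samples")

filtered, removed = filter_low_expression(matrix, 0.25)
print(f"expression filter removed {len(removed)} gene(s) with max TPM <= 0.25")

stats = profile_summary(filtered, annotate_genes(filtered.genes))
by_role = {role: [] for role in GeneRole}
for s in stats:
    if s.gini is not None:
        by_role[truth.roles[s.gene_symbol]].append(s.gini)

print("\nmedian Gini by planted role (analytic housekeeping value "
      f"{expected_gini_lognormal(config.sigma_hk):.4f}):")
for role, ginis in by_role.items():
    print(f"  {role.value:13s} n={len(ginis):3d} median gini={np.median(ginis):.4f}")
print("\nHousekeeping genes sit far below the broad/specific genes, so a "
      "simple Gini threshold separates the roles.")
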