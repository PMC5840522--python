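"""End-to-end workflow for real tissue/cell-line atlas tables.

Shows the commands and calls used to analyze Human Protein Atlas style
long tables (rna_tissue.tsv / rna_celline.tsv) or supplementary wide
transporter spreadsheets.  The data files are not bundled (users download
them); when absent this script prints the recipe and exits, and it runs
the identical code path on a small synthetic long table instead.
"""

from pathlib import Path

from genegini import (
    HPA_DIALECT,
    SIMPLE_DIALECT,
    SimulationConfig,
    annotate_genes,
    class_gini_summary,
    filter_low_expression,
    pivot_matrix,
    profile_summary,
    read_long_tsv,
    sample_totals,
    simulate_matrix,
    write_long_tsv,
)

hpa_path = Path("rna_tissue.tsv")

if hpa_path.exists():
    records = read_long_tsv(hpa_path, dialect=HPA_DIALECT)
    dialect = HPA_DIALECT
else:
    print("rna_tissue.tsv not found — recipe for real data:")
    print("  1. download rna_tissue.tsv / rna_celline.tsv (proteinatlas.org)")
    print("  2. records = read_long_tsv('rna_tissue.tsv', dialect=HPA_DIALECT)")
    print("  3. matrix = pivot_matrix(records, sample_kind='tissue').matrix")
    print("     (replicates are averaged; missing cells filled with 0 TPM)")
    print("  4. continue exactly as below; or use the CLI:")
    print("     genegini convert mmc_slc.xlsx slc.tsv   # supplementary sheets")
    print("     genegini gini --input slc.tsv --out stats.tsv")
    print("\nrunning the same path on a synthetic long table instead:\n")
    matrix, _ = simulate_matrix(SimulationConfig(seed=3))
    write_long_tsv(matrix, "/tmp/synthetic_long.tsv")
    records = read_long_tsv("/tmp/synthetic_long.tsv", dialect=SIMPLE_DIALECT)

pivoted = pivot_matrix(records, sample_kind="tissue")
matrix = pivoted.matrix
print(f"pivoted to {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"({pivoted.n_filled} absent cells filled with 0 TPM)")

filtered, removed = filter_low_expression(matrix, 0.25)
print(f"removed {len(removed)} genes with max TPM <= 0.25")

stats = profile_summary(filtered, annotate_genes(filtered.genes))
for summary in class_gini_summary(stats):
    print(f"class {summary.gene_class.value:6s}: n={summary.n_genes:4d} "
          f"median gini={summary.median_gini:.3f}  "
          f">= {summary.hi}: {summary.n_ge_hi}   < {summary.lo}: {summary.n_lt_lo}")

totals = sample_totals(filtered)
print(f"sample with the most total expression: {totals.max_sample} "
      f"(sum {totals.max_total:,.0f} TPM); least: {totals.min_sample} "
      f"(sum {totals.min_total:,.0f} TPM)")
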