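"""QC-filter a raw count matrix and transform it to Pearson residuals.

Simulates a small genes x cells count matrix with a few failing cells
and rare genes, applies the standard thresholds (scaled down to the toy
size), and prints the filter report and the residual matrix shape that
would feed the selection pipeline.
"""

import numpy as np

from qubofs import CountMatrix, pearson_residuals, qc_filter

rng = np.random.default_rng(0)
n_genes, n_cells = 120, 60
counts = rng.negative_binomial(2, 0.3, size=(n_genes, n_cells))
counts[:, 0] = 0  # an empty cell
counts[5, :] = 0  # an undetected gene
genes = ["MT-ND1", "MT-CO1"] + [f"GENE{i}" for i in range(n_genes - 2)]
cells = [f"cell{j}" for j in range(n_cells)]

M = CountMatrix(counts, genes, cells)
filtered, report = qc_filter(
    M,
    min_reads_per_cell=200,
    max_mito_frac=0.15,
    min_cells_per_gene=10,
    min_genes_per_cell=30,
)
for key, value in report.to_dict().items():
    print(f"{key}: {value}")

residuals = pearson_residuals(filtered, theta=100)
print("\nresiduals (cells x genes):", residuals.shape)
print("residual range:", float(residuals.min().min()), "to",
      float(residuals.max().max()))
# Residuals are clipped to +/- sqrt(n_cells); a positive residual means
# the gene is expressed above its depth-expected level in that cell.
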