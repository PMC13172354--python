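"""QC-filter a raw count matrix and log-normalize it.

Builds a small raw-count matrix with a few deliberately bad cells (too
few features, too mitochondrial), applies the cultured-skin preset
(1000-8000 features, mito < 7%), and normalizes the survivors.
"""

import numpy as np
import pandas as pd
from anndata import AnnData

import hsetools as h

rng = np.random.default_rng(0)
n_genes = 9000
genes = ["MT-CO1", "MT-ND1"] + [f"G{j}" for j in range(n_genes - 2)]
X = rng.poisson(0.6, size=(8, n_genes)).astype(float)
X[0, :] = 0.0
X[0, :200] = 1.0          # only 200 features: fails the lower bound
X[1, 0] = X[1].sum()      # half mitochondrial: fails the mito rule
adata = AnnData(X=X, obs=pd.DataFrame(index=[f"cell{i}" for i in range(8)]),
                var=pd.DataFrame(index=genes))

kept, report = h.qc_filter_cells(adata, h.QCThresholds.in_vitro())
print(report.round(3))
print(f"retained {kept.n_obs} of {adata.n_obs} cells")

normalized = h.lognormalize(kept, scale_total=1e4)
print("per-cell value range after ln(1 + c*1e4/total):",
      np.asarray(normalized.X).min().round(3), "-",
      np.asarray(normalized.X).max().round(3))
# Every retained cell now contributes the same total signal; values are
# natural-log counts per 10k.
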