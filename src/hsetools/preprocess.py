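"""Cell-level quality control and total-count log-normalization.

Raw droplet count matrices are filtered on two per-cell criteria — the
number of detected RNA features and the fraction of counts coming from
mitochondrial genes — and then normalized so every cell contributes the
same total signal before the log(1 + x) transform.  Two presets mirror
common practice for cultured-tissue versus biopsy data:

* ``in_vitro``: 1000–8000 features (inclusive), mitochondrial fraction
  strictly below 7%.
* ``in_vivo``: fewer than 7500 features (strict), mitochondrial fraction
  strictly below 5%.

Matrices are carried as :class:`anndata.AnnData` (cells x genes) with a
``layer_tag`` entry in ``.uns`` recording whether values are raw counts
or log-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["QCThresholds", "qc_filter_cells", "lognormalize"]

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell QC rules.

    Parameters
    ----------
    min_features, max_features
        Bounds on the number of detected genes (count > 0).  ``max_features``
        may be ``None`` for no upper bound.  ``max_inclusive`` controls
        whether the upper bound itself passes (a "1000 to 8000" range is
        inclusive; a "fewer than 7500" rule is strict).
    max_mito_fraction
        Cells with mitochondrial count fraction >= this value are removed
        (the bound itself fails: "less than 7%" is a strict inequality).
    mito_gene_prefix
        Genes whose identifier starts with this prefix are counted as
        mitochondrial.
    """

    min_features: int = 0
    max_features: int | None = None
    max_mito_fraction: float = 1.0
    mito_gene_prefix: str = "MT-"
    max_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_features is not None and self.min_features > self.max_features:
            raise ValueError(
                f"min_features ({self.min_features}) exceeds max_features "
                f"({self.max_features})"
            )
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")

    @classmethod
    def in_vitro(cls, mito_gene_prefix: str = "MT-") -> "QCThresholds":
        """Cultured-skin preset: 1000-8000 features, mito < 7%."""
        return cls(1000, 8000, 0.07, mito_gene_prefix, max_inclusive=True)

    @classmethod
    def in_vivo(cls, mito_gene_prefix: str = "MT-") -> "QCThresholds":
        """Biopsy preset: fewer than 7500 features (strict), mito < 5%."""
        return cls(0, 7500, 0.05, mito_gene_prefix, max_inclusive=False)


def _dense_sums(X):
    """(features-per-cell, total counts, X as something indexable)."""
    if sp.issparse(X):
        n_features = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        n_features = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
    return n_features, totals


def qc_filter_cells(
    adata: AnnData, thresholds: QCThresholds
) -> tuple[AnnData, pd.DataFrame]:
    """Filter cells on detected-feature count and mitochondrial fraction.

    Returns the retained submatrix (a copy) and a per-cell report with
    columns ``n_features``, ``mito_fraction``, ``passed`` and
    ``fail_reason`` (empty string for passing cells; the first failing
    rule otherwise).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty expression matrix: nothing to QC-filter")

    n_features, totals = _dense_sums(adata.X)

    mito_mask = np.fromiter(
        (str(g).startswith(thresholds.mito_gene_prefix) for g in adata.var_names),
        dtype=bool,
        count=adata.n_vars,
    )
    if not mito_mask.any():
        warnings.warn(
            f"no genes match mitochondrial prefix {thresholds.mito_gene_prefix!r}; "
            "treating mitochondrial fraction as 0",
            stacklevel=2,
        )
        mito_frac = np.zeros(adata.n_obs)
    else:
        Xm = adata.X[:, mito_mask]
        mito_counts = (
            np.asarray(Xm.sum(axis=1)).ravel() if sp.issparse(Xm) else np.asarray(Xm).sum(axis=1)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)

    too_few = n_features < thresholds.min_features
    if thresholds.max_features is None:
        too_many = np.zeros(adata.n_obs, dtype=bool)
    elif thresholds.max_inclusive:
        too_many = n_features > thresholds.max_features
    else:
        too_many = n_features >= thresholds.max_features
    too_mito = mito_frac >= thresholds.max_mito_fraction

    passed = ~(too_few | too_many | too_mito)
    fail_reason = np.where(
        too_few, "min_features", np.where(too_many, "max_features", np.where(too_mito, "max_mito_fraction", ""))
    )

    report = pd.DataFrame(
        {
            "n_features": n_features,
            "mito_fraction": mito_frac,
            "passed": passed,
            "fail_reason": fail_reason,
        },
        index=pd.Index(adata.obs_names, name="cell_id"),
    )
    return adata[passed].copy(), report


def lognormalize(adata: AnnData, scale_total: float = 1e4) -> AnnData:
    """Total-count normalization followed by the natural-log transform.

    Each value becomes ``ln(1 + count * scale_total / cell_total)``, so
    cells with proportional count vectors map to identical rows.  The
    result is a new object tagged ``log_normalized``.

    Raises
    ------
    ValueError
        If any cell has a zero total count (the scaling is undefined);
        the error names the first offending cell.
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    _, totals = _dense_sums(adata.X)
    if np.any(totals <= 0):
        bad = adata.obs_names[np.argmax(totals <= 0)]
        raise ValueError(f"cell {bad!r} has zero total count; cannot normalize")

    out = adata.copy()
    if sp.issparse(out.X):
        X = out.X.tocsr().astype(np.float64)
        scale = scale_total / totals
        X = sp.diags(scale) @ X
        X.data = np.log1p(X.data)
        out.X = X
    else:
        X = np.asarray(out.X, dtype=np.float64)
        out.X = np.log1p(X * (scale_total / totals)[:, None])
    out.uns["layer_tag"] = LOG_NORMALIZED
    return out
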