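"""Gene-dynamics scoring along pseudotime.

The procedure characterizes how each gene's log-normalized expression
changes along a differentiation trajectory:

1. **Prefilter** — keep genes detected (expression above a threshold,
   default > 0) in at least a minimum fraction of the selected cells
   (default 10%).
2. **LOESS fit** — model expression as a smooth function of pseudotime
   with tricube-weighted local polynomial regression (span 0.3, degree 2
   by default, single pass).
3. **Dynamics range** — score each gene by

       (max ŷ − min ŷ) / (max y − min y)

   the fraction of the observed expression spread captured by the
   smooth trend.  Genes scoring below a cutoff (0.05 for the
   pericyte-directed branch, 0.1 for the fibroblast branch) are
   "static" and excluded downstream; ties at the cutoff count as
   dynamic (the rule is strictly "below").
4. **Spearman ranking** — correlate each dynamic gene with pseudotime
   (mid-rank Spearman, large-sample t p-value, Bonferroni over the
   dynamic genes tested), keep the |rho| > 0.7 set, and report the
   top-k genes per direction (rho > 0 up, rho < 0 down) by |rho|.

LOESS can overshoot the observed extrema, so dynamics-range scores may
slightly exceed 1; they are reported as computed, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
from anndata import AnnData
from statsmodels.stats.multitest import multipletests

from .trajectory import CellSelection

__all__ = [
    "DynamicsConfig",
    "DynamicsResult",
    "LoessSmoother",
    "prefilter_genes",
    "fit_loess",
    "dynamics_range",
    "classify_dynamics",
    "spearman_rank",
    "rank_fate_genes",
    "run_dynamics_pipeline",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Tunable parameters of the dynamics pipeline.

    ``pericyte_branch``/``fibroblast_branch`` presets differ only in the
    static cutoff (0.05 vs 0.1).
    """

    detection_min_fraction: float = 0.10
    detection_threshold: float = 0.0
    loess_span: float = 0.3
    loess_degree: int = 2
    static_cutoff: float = 0.05
    top_k: int = 20
    rho_cutoff: float = 0.7
    adjust_method: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ValueError("loess_degree must be 1 or 2")
        if not 0.0 <= self.static_cutoff <= 1.0:
            raise ValueError("static_cutoff must lie in [0, 1]")
        if not 0.0 <= self.detection_min_fraction <= 1.0:
            raise ValueError("detection_min_fraction must lie in [0, 1]")
        if self.adjust_method != "bonferroni":
            raise ValueError("only bonferroni adjustment is supported")

    @classmethod
    def pericyte_branch(cls, **kw) -> "DynamicsConfig":
        return cls(static_cutoff=0.05, **kw)

    @classmethod
    def fibroblast_branch(cls, **kw) -> "DynamicsConfig":
        return cls(static_cutoff=0.1, **kw)


# ---------------------------------------------------------------------------
# LOESS


class LoessSmoother:
    """Tricube local polynomial smoother evaluated at the sample points.

    The fit at each point is a weighted least-squares polynomial of the
    given degree over the ``ceil(span * n)`` nearest neighbours, with
    tricube weights on the scaled distances.  Because the fitted values
    are linear in y, the smoother is precomputed as an (n, n) matrix and
    applied to any number of response vectors sharing the same
    pseudotime — which is exactly the per-gene situation.
    """

    def __init__(self, x: np.ndarray, span: float = 0.3, degree: int = 2):
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("x must be 1-D")
        if not np.all(np.isfinite(x)):
            raise ValueError("pseudotime values must be finite")
        n = len(x)
        if n < max(10, degree + 2):
            raise ValueError(f"need at least {max(10, degree + 2)} points, got {n}")
        if np.ptp(x) == 0:
            raise ValueError("all pseudotime values are equal; cannot smooth")
        self.x = x
        self.span = float(span)
        self.degree = int(degree)
        k = min(n, max(int(np.ceil(span * n)), degree + 1))
        L = np.zeros((n, n))
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argpartition(d, k - 1)[:k]
            h = d[idx].max()
            if h == 0.0:
                tied = d == 0.0
                L[i, tied] = 1.0 / tied.sum()
                continue
            w = (1.0 - (d[idx] / h) ** 3) ** 3
            sw = np.sqrt(np.maximum(w, 0.0))
            dx = x[idx] - x[i]
            A = np.vander(dx, degree + 1, increasing=True) * sw[:, None]
            # fitted value at x[i] is the intercept of the local fit:
            # e0' A^+ (sw * y), hence the smoother row below.
            L[i, idx] = np.linalg.pinv(A)[0] * sw
        self.matrix = L

    def smooth(self, y: np.ndarray) -> np.ndarray:
        """Fitted values for one response vector."""
        y = np.asarray(y, dtype=float)
        if y.shape != self.x.shape:
            raise ValueError("y length must match pseudotime length")
        return self.matrix @ y

    def smooth_many(self, Y: np.ndarray) -> np.ndarray:
        """Fitted values for a (n_series, n_points) response matrix."""
        Y = np.asarray(Y, dtype=float)
        return Y @ self.matrix.T


def fit_loess(
    pseudotime: np.ndarray, y: np.ndarray, span: float = 0.3, degree: int = 2
) -> np.ndarray:
    """LOESS fitted values of ``y`` at the observed pseudotime points."""
    return LoessSmoother(pseudotime, span=span, degree=degree).smooth(y)


# ---------------------------------------------------------------------------
# Scores and tests


def prefilter_genes(
    adata: AnnData,
    selection: CellSelection | None,
    config: DynamicsConfig = DynamicsConfig(),
) -> tuple[list[str], pd.Series]:
    """Detection-rate prefilter over the selected cells.

    A gene is retained when the fraction of selected cells with
    expression strictly above ``detection_threshold`` is at least
    ``detection_min_fraction``.  Returns the retained gene ids and the
    full per-gene detection-rate series.
    """
    if selection is None:
        sub = adata
    else:
        cells = list(selection.cell_ids)
        if len(cells) == 0:
            raise ValueError("empty cell selection")
        missing = set(cells) - set(adata.obs_names)
        if missing:
            raise ValueError(f"selection cells not in matrix: {sorted(missing)[:5]}")
        sub = adata[cells]
    X = sub.X
    import scipy.sparse as sp

    if sp.issparse(X):
        detected = np.asarray((X > config.detection_threshold).sum(axis=0)).ravel()
    else:
        detected = (np.asarray(X) > config.detection_threshold).sum(axis=0)
    rates = pd.Series(detected / sub.n_obs, index=adata.var_names, name="detection_rate")
    kept = [g for g, r in rates.items() if r >= config.detection_min_fraction]
    return kept, rates


def dynamics_range(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Fitted-spread over observed-spread ratio; NaN when y is flat."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    denom = y.max() - y.min()
    if denom == 0.0:
        return float("nan")
    return float((y_hat.max() - y_hat.min()) / denom)


def classify_dynamics(scores: pd.Series, static_cutoff: float = 0.05) -> pd.Series:
    """Label genes static (score strictly below cutoff), dynamic, or degenerate."""
    out = pd.Series("dynamic", index=scores.index, name="dynamics_class")
    out[scores < static_cutoff] = "static"
    out[scores.isna()] = "degenerate"
    return out


def spearman_rank(pseudotime: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (mid-rank) and its large-sample t-test p-value.

    If all ``y`` values are tied the correlation is undefined; by
    convention (0, 1) is returned.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(pseudotime) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pseudotime) == 0:
        raise ValueError("all pseudotime values tied; correlation undefined")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    rho, p = scipy.stats.spearmanr(pseudotime, y)
    return float(rho), float(p)


def rank_fate_genes(records: pd.DataFrame, config: DynamicsConfig = DynamicsConfig()):
    """Bonferroni-adjust and rank dynamic genes by correlation strength.

    ``records`` must be indexed by gene id with columns ``rho`` and
    ``p_value`` for the dynamic-class genes (others NaN).  Returns
    ``(records, fate_genes, top_up, top_down)`` where ``fate_genes`` is
    the |rho| strictly greater than ``rho_cutoff`` subset and the top
    tables hold at most ``top_k`` genes per direction, ranked by |rho|
    descending with ties broken by smaller p then gene id.
    """
    records = records.copy()
    tested = records.index[records["rho"].notna()]
    records["p_adjusted"] = np.nan
    if len(tested):
        records.loc[tested, "p_adjusted"] = multipletests(
            records.loc[tested, "p_value"].to_numpy(), method="bonferroni"
        )[1]

    dyn = records.loc[tested].copy()
    dyn["abs_rho"] = dyn["rho"].abs()
    fate_genes = dyn[dyn["abs_rho"] > config.rho_cutoff].sort_values(
        ["abs_rho", "p_value"], ascending=[False, True], kind="mergesort"
    )

    records["direction"] = pd.NA
    records.loc[tested[records.loc[tested, "rho"] > 0], "direction"] = "up"
    records.loc[tested[records.loc[tested, "rho"] < 0], "direction"] = "down"

    def _top(direction: str) -> pd.DataFrame:
        sub = dyn[records.loc[dyn.index, "direction"] == direction].copy()
        sub = sub.reset_index()
        gene_col = sub.columns[0]
        sub = sub.sort_values(
            ["abs_rho", "p_value", gene_col], ascending=[False, True, True], kind="mergesort"
        ).set_index(gene_col)
        return sub.head(config.top_k)

    top_up = _top("up")
    top_down = _top("down")

    records["rank_in_direction"] = pd.NA
    for table in (top_up, top_down):
        records.loc[table.index, "rank_in_direction"] = np.arange(1, len(table) + 1)
    return records, fate_genes.drop(columns="abs_rho"), top_up.drop(columns="abs_rho"), top_down.drop(columns="abs_rho")


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class DynamicsResult:
    """Full per-gene table plus the derived fate-gene selections."""

    records: pd.DataFrame
    fate_genes: pd.DataFrame
    top_up: pd.DataFrame
    top_down: pd.DataFrame
    config: DynamicsConfig
    n_cells_used: int


def run_dynamics_pipeline(
    adata: AnnData,
    selection: CellSelection | None,
    pseudotime: pd.Series,
    config: DynamicsConfig = DynamicsConfig(),
    rho_on_all: bool = False,
) -> DynamicsResult:
    """Prefilter, LOESS-fit, score, classify, correlate, and rank genes.

    ``pseudotime`` is indexed by cell id and must cover the selected
    cells.  By default the Spearman stage and the |rho| > cutoff
    fate-gene set are restricted to dynamic-class genes (static genes
    are excluded before correlation); ``rho_on_all=True`` instead
    correlates every prefiltered, non-degenerate gene and draws the
    fate set from all of them, for sensitivity analysis.

    The returned records table has one row per input gene with
    provenance at every stage: detection rate, prefilter flag,
    dynamics-range score, class, rho, p, Bonferroni-adjusted p,
    direction and per-direction rank.
    """
    cells = list(selection.cell_ids) if selection is not None else list(adata.obs_names)
    missing = set(cells) - set(pseudotime.index)
    if missing:
        raise ValueError(f"cells lacking pseudotime: {sorted(missing)[:5]}")

    kept, rates = prefilter_genes(adata, selection, config)
    records = pd.DataFrame(
        {
            "detection_rate": rates,
            "passed_prefilter": rates.index.isin(kept),
            "dynamics_range": np.nan,
            "dynamics_class": pd.NA,
            "rho": np.nan,
            "p_value": np.nan,
        },
        index=rates.index.copy(),
    )
    records.index.name = "gene_id"

    # order selected cells by pseudotime (stable on ties)
    pt = pseudotime.loc[cells]
    order = np.argsort(pt.to_numpy(), kind="mergesort")
    cells_sorted = [cells[i] for i in order]
    x = pt.to_numpy()[order]

    if kept:
        sub = adata[cells_sorted, kept]
        X = sub.X
        import scipy.sparse as sp

        Y = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
        smoother = LoessSmoother(x, span=config.loess_span, degree=config.loess_degree)
        Y_hat = smoother.smooth_many(Y.T).T  # (cells, genes) -> fitted

        spread_obs = Y.max(axis=0) - Y.min(axis=0)
        spread_fit = Y_hat.max(axis=0) - Y_hat.min(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(spread_obs > 0, spread_fit / np.maximum(spread_obs, 1e-300), np.nan)
        records.loc[kept, "dynamics_range"] = scores
        records.loc[kept, "dynamics_class"] = classify_dynamics(
            pd.Series(scores, index=kept), config.static_cutoff
        )

        test_mask = records.loc[kept, "dynamics_class"] == "dynamic"
        if rho_on_all:
            test_mask = records.loc[kept, "dynamics_class"] != "degenerate"
        to_test = {g for g, m in test_mask.items() if m}
        for j, g in enumerate(kept):
            if g in to_test:
                rho, p = spearman_rank(x, Y[:, j])
                records.loc[g, "rho"] = rho
                records.loc[g, "p_value"] = p

    records, fate, top_up, top_down = rank_fate_genes(records, config)
    return DynamicsResult(records, fate, top_up, top_down, config, len(cells))
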