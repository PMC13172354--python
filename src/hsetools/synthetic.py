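"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data the analysis consumes:

* :func:`generate_trajectory_dataset` — a 2D embedding of cells strung
  along a piecewise-linear principal graph with monotone pseudotime, a
  log-normalized-scale expression matrix in which a known subset of
  genes follows a smooth function of pseudotime (logistic up/down or a
  Gaussian bump) while the rest are pseudotime-independent noise, plus
  dropout zeros.
* :func:`generate_fiber_image` — sinusoidal stripes at a controllable
  fiber angle blended with white noise by a coherence parameter.
* :func:`generate_suction_curve` — a parametric suction/relaxation
  displacement curve whose elastic and total recovery fractions are
  specified exactly, so downstream R7 and R2 are known by construction.

All randomness flows from the single ``seed`` through one
``numpy.random.default_rng`` instance per call.  Stream order for the
trajectory generator: (1) cell arc-length positions, (2) embedding
jitter, (3) gene-label shuffle, (4) static-gene baselines,
(5) expression noise, (6) dropout mask.  Identical configs therefore
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .preprocess import LOG_NORMALIZED
from .trajectory import PrincipalGraph, TrajectoryPath, extract_path
from .biomech import SuctionCurve

__all__ = [
    "TrajectorySimConfig",
    "SimulatedDataset",
    "generate_trajectory_dataset",
    "generate_fiber_image",
    "generate_suction_curve",
]

PROFILES = ("monotone_up", "monotone_down", "transient")


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Ground-truth parameters of a simulated differentiation trajectory.

    Defaults are the package's reference conditions: 500 cells, 500
    genes of which 10% are dynamic with amplitude 2 (log-normalized
    units), Gaussian noise sd 0.3, 20% dropout.
    """

    n_cells: int = 500
    n_genes: int = 500
    frac_dynamic: float = 0.1
    dynamic_profiles: tuple[str, ...] = PROFILES
    amplitude: float = 2.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.2
    n_branch_nodes: int = 20
    side_branch_nodes: int = 0
    jitter_sd: float = 0.3
    baseline: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if not 0.0 <= self.frac_dynamic <= 1.0:
            raise ValueError("frac_dynamic must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.amplitude < 0 or self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("amplitude, noise_sd and jitter_sd must be >= 0")
        if not np.isfinite(self.amplitude) or not np.isfinite(self.noise_sd):
            raise ValueError("amplitude and noise_sd must be finite")
        if self.n_branch_nodes < 2:
            raise ValueError("n_branch_nodes must be at least 2")
        unknown = set(self.dynamic_profiles) - set(PROFILES)
        if unknown or not self.dynamic_profiles:
            raise ValueError(f"dynamic_profiles must be a nonempty subset of {PROFILES}")

    @property
    def n_dynamic(self) -> int:
        return int(round(self.frac_dynamic * self.n_genes))

    @property
    def jitter_max(self) -> float:
        """Hard cap on embedding jitter radius (3 sd)."""
        return 3.0 * self.jitter_sd


@dataclass
class SimulatedDataset:
    """A trajectory dataset with full ground truth.

    ``adata`` holds the expression matrix (cells x genes, log-normalized
    scale) with the embedding in ``obsm['X_embed']``, pseudotime in
    ``obs['pseudotime']`` and truth labels in ``var['truth']``; the same
    values are exposed as standalone fields for convenience.
    """

    adata: AnnData
    embedding: pd.DataFrame
    graph: PrincipalGraph
    path: TrajectoryPath
    pseudotime: pd.Series
    truth: pd.Series
    config: TrajectorySimConfig


def _mean_curve(profile: str, s_norm: np.ndarray, amplitude: float, baseline: float) -> np.ndarray:
    if profile == "monotone_up":
        return baseline + amplitude / (1.0 + np.exp(-(s_norm - 0.5) / 0.12))
    if profile == "monotone_down":
        return baseline + amplitude / (1.0 + np.exp((s_norm - 0.5) / 0.12))
    if profile == "transient":
        return baseline + amplitude * np.exp(-((s_norm - 0.5) ** 2) / (2 * 0.12**2))
    raise ValueError(f"unknown profile {profile!r}")


def _build_graph(config: TrajectorySimConfig) -> tuple[PrincipalGraph, TrajectoryPath]:
    m = config.n_branch_nodes
    t = np.linspace(0.0, 1.0, m)
    main = np.column_stack([10.0 * t, 2.0 * np.sin(np.pi * t)])
    ids = [f"Y_{i}" for i in range(m)]
    edges = [(ids[i], ids[i + 1]) for i in range(m - 1)]
    coords = main
    if config.side_branch_nodes > 0:
        # short branch leaving the middle node, orthogonal to the x-axis
        mid = m // 2
        sb = config.side_branch_nodes
        off = np.column_stack(
            [np.full(sb, main[mid, 0]), main[mid, 1] + 1.5 * np.arange(1, sb + 1) / sb]
        )
        sb_ids = [f"Y_{m + j}" for j in range(sb)]
        edges.append((ids[mid], sb_ids[0]))
        edges += [(sb_ids[j], sb_ids[j + 1]) for j in range(sb - 1)]
        ids = ids + sb_ids
        coords = np.vstack([main, off])
    graph = PrincipalGraph(tuple(ids), coords, tuple(edges))
    path = extract_path(graph, f"Y_0", f"Y_{m - 1}")
    return graph, path


def generate_trajectory_dataset(config: TrajectorySimConfig = TrajectorySimConfig()) -> SimulatedDataset:
    """Simulate cells along a principal-graph path with known gene dynamics.

    Dynamic genes' mean expression is a smooth function of normalized
    arc-length pseudotime (strictly monotone logistic for the monotone
    profiles, a mid-path Gaussian bump for transient); static genes have
    a constant mean.  Gaussian noise (sd ``noise_sd``) is added and
    values are floored at 0; dropout then zeroes each entry
    independently with probability ``dropout_rate``.  Embedding points
    are polyline positions plus isotropic Gaussian jitter whose radius
    is capped at ``config.jitter_max``.
    """
    rng = np.random.default_rng(config.seed)
    graph, path = _build_graph(config)
    L = path.arc_length

    # 1) arc-length positions -> pseudotime
    s = np.sort(rng.uniform(0.0, L, config.n_cells))
    pseudotime_values = s.copy()

    # 2) embedding jitter (isotropic Gaussian, radius capped at 3 sd)
    base_points = np.array([path.point_at(v) for v in s])
    jitter = rng.normal(0.0, config.jitter_sd, size=(config.n_cells, 2))
    norms = np.linalg.norm(jitter, axis=1)
    too_far = norms > config.jitter_max
    if too_far.any():
        jitter[too_far] *= (config.jitter_max / norms[too_far])[:, None]
    points = base_points + jitter

    # 3) truth labels: which genes are dynamic, and their profiles
    n_dyn = config.n_dynamic
    gene_order = rng.permutation(config.n_genes)
    profiles = [config.dynamic_profiles[i % len(config.dynamic_profiles)] for i in range(n_dyn)]
    truth = np.array(["static"] * config.n_genes, dtype=object)
    label = {"monotone_up": "dynamic_up", "monotone_down": "dynamic_down", "transient": "dynamic_transient"}
    for i in range(n_dyn):
        truth[gene_order[i]] = label[profiles[i]]

    # 4) static baselines
    static_means = rng.uniform(0.5, 1.5, config.n_genes)

    s_norm = s / L if L > 0 else np.zeros_like(s)
    means = np.tile(static_means, (config.n_cells, 1))
    for i in range(n_dyn):
        g = gene_order[i]
        means[:, g] = _mean_curve(profiles[i], s_norm, config.amplitude, config.baseline)

    # 5) noise, floored at zero (log-normalized values are nonnegative)
    X = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    np.clip(X, 0.0, None, out=X)

    # 6) dropout
    if config.dropout_rate > 0:
        X[rng.random(X.shape) < config.dropout_rate] = 0.0

    cell_ids = [f"cell_{i:05d}" for i in range(config.n_cells)]
    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    truth_s = pd.Series(truth, index=pd.Index(gene_ids, name="gene_id"), name="truth")
    pt = pd.Series(pseudotime_values, index=pd.Index(cell_ids, name="cell_id"), name="pseudotime")
    emb = pd.DataFrame(points, index=pt.index, columns=["x", "y"])

    adata = AnnData(
        X=X,
        obs=pd.DataFrame({"pseudotime": pt}, index=pt.index),
        var=pd.DataFrame({"truth": truth_s}, index=truth_s.index),
    )
    adata.obsm["X_embed"] = points
    adata.uns["layer_tag"] = LOG_NORMALIZED
    adata.uns["jitter_max"] = config.jitter_max
    return SimulatedDataset(adata, emb, graph, path, pt, truth_s, config)


def generate_fiber_image(
    width: int = 256,
    height: int = 256,
    angle: float = 0.0,
    coherence: float = 1.0,
    seed: int = 0,
    wavelength_px: float = 4.0,
) -> np.ndarray:
    """Grayscale image of oriented stripes blended with isotropic noise.

    ``angle`` (degrees in [0, 180)) is the fiber axis in the (col, row)
    plane; ``coherence`` 1 gives pure parallel sinusoidal stripes, 0
    pure uniform noise, intermediate values a linear blend.  Values lie
    in [0, 1].  The default 4 px stripe wavelength puts the spectral
    peak far from the origin, where angular quantization is fine.
    """
    if width < 32 or height < 32:
        raise ValueError("width and height must be at least 32")
    if not 0.0 <= angle < 180.0:
        raise ValueError("angle must lie in [0, 180) degrees")
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    if wavelength_px <= 0:
        raise ValueError("wavelength_px must be positive")
    rng = np.random.default_rng(seed)
    theta = np.radians(angle)
    rows, cols = np.mgrid[0:height, 0:width]
    # stripes constant along the fiber direction (cos t, sin t) in (x, y)=(col, row)
    phase = (-cols * np.sin(theta) + rows * np.cos(theta)) * (2 * np.pi / wavelength_px)
    stripes = 0.5 + 0.5 * np.sin(phase)
    noise = rng.random((height, width))
    return coherence * stripes + (1.0 - coherence) * noise


def generate_suction_curve(
    uf: float = 0.3,
    elastic_fraction: float = 0.5,
    recovery_fraction: float = 0.8,
    dt: float = 0.01,
    suction_s: float = 2.0,
    relax_s: float = 2.0,
    settle_s: float = 0.15,
) -> SuctionCurve:
    """Parametric suction/relaxation displacement curve.

    During suction the displacement rises along a saturating exponential
    that reaches its maximum ``uf`` exactly at release.  At release the
    curve drops instantly by ``elastic_fraction * uf``, holds that level
    for ``settle_s`` (so the immediate retraction read shortly after
    release equals the elastic drop exactly), then declines linearly so
    that total recovery at the end of relaxation equals
    ``recovery_fraction * uf``.  The sampled grid has spacing ``dt`` and
    phase timestamps 0 / ``suction_s`` / ``suction_s + relax_s``.
    """
    if dt <= 0 or suction_s <= 0 or relax_s <= 0:
        raise ValueError("dt, suction_s and relax_s must be positive")
    if uf < 0:
        raise ValueError("uf must be nonnegative")
    for name, v in (("elastic_fraction", elastic_fraction), ("recovery_fraction", recovery_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if recovery_fraction < elastic_fraction:
        raise ValueError("recovery_fraction must be >= elastic_fraction")

    total = suction_s + relax_s
    n = int(round(total / dt)) + 1
    t = np.linspace(0.0, total, n)
    d = np.empty_like(t)

    rise = t <= suction_s
    tau = suction_s / 3.0
    d[rise] = uf * (1.0 - np.exp(-t[rise] / tau)) / (1.0 - np.exp(-suction_s / tau))

    tr = t[~rise] - suction_s
    plateau_level = uf * (1.0 - elastic_fraction)
    end_level = uf * (1.0 - recovery_fraction)
    settle = min(settle_s, relax_s)
    decay_span = max(relax_s - settle, np.finfo(float).tiny)
    frac = np.clip((tr - settle) / decay_span, 0.0, 1.0)
    d[~rise] = plateau_level - (plateau_level - end_level) * frac
    np.clip(d, 0.0, None, out=d)
    return SuctionCurve(t, d, 0.0, suction_s, total)
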