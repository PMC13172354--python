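"""Principal-graph paths and distance-based cell selection.

A principal graph is the piecewise-linear skeleton a trajectory-inference
tool fits through cells in a 2D embedding: named nodes with coordinates
plus undirected edges.  The differentiation axis of interest is an
ordered node-to-node path through that graph (e.g. from a fibroblast
node to a pericyte node).  Cells are attributed to the axis by their
Euclidean distance in embedding space to the path polyline, keeping the
cells below a chosen percentile of the full distance distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PrincipalGraph",
    "TrajectoryPath",
    "CellSelection",
    "extract_path",
    "distance_to_path",
    "select_cells_near_path",
]


@dataclass(frozen=True)
class PrincipalGraph:
    """Named 2D nodes plus undirected edges (no self-loops)."""

    node_ids: tuple[str, ...]
    node_coords: np.ndarray  # (n_nodes, 2)
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.node_coords, dtype=float)
        object.__setattr__(self, "node_coords", coords)
        if coords.shape != (len(self.node_ids), 2):
            raise ValueError("node_coords must be (n_nodes, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("node coordinates must be finite")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        known = set(self.node_ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at node {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")

    def coords_of(self, node_id: str) -> np.ndarray:
        return self.node_coords[self.node_ids.index(node_id)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        pos = {nid: self.node_coords[i] for i, nid in enumerate(self.node_ids)}
        g.add_nodes_from(self.node_ids)
        for a, b in self.edges:
            w = float(np.linalg.norm(pos[a] - pos[b]))
            g.add_edge(a, b, weight=w)
        return g


@dataclass(frozen=True)
class TrajectoryPath:
    """An ordered node path with its polyline geometry."""

    ordered_nodes: tuple[str, ...]
    polyline: np.ndarray  # (n_nodes, 2), in node order
    arc_length: float = field(init=False)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        object.__setattr__(self, "polyline", poly)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] != len(self.ordered_nodes):
            raise ValueError("polyline must be (len(ordered_nodes), 2)")
        seg = np.diff(poly, axis=0)
        object.__setattr__(self, "arc_length", float(np.linalg.norm(seg, axis=1).sum()))

    def point_at(self, s: float) -> np.ndarray:
        """Point on the polyline at arc-length position ``s`` (clamped)."""
        poly = self.polyline
        if len(poly) == 1:
            return poly[0].copy()
        seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        if seg_len[i] == 0:
            return poly[i].copy()
        t = (s - cum[i]) / seg_len[i]
        return poly[i] + t * (poly[i + 1] - poly[i])


@dataclass(frozen=True)
class CellSelection:
    """Cells retained near a path, with their distances and the cutoff."""

    cell_ids: tuple[str, ...]
    distances: pd.Series  # all cells, indexed by cell id
    threshold: float
    percentile: float

    def to_frame(self) -> pd.DataFrame:
        selected = self.distances.index.isin(self.cell_ids)
        return pd.DataFrame(
            {"distance": self.distances, "selected": selected},
            index=self.distances.index,
        )


def extract_path(graph: PrincipalGraph, start: str, end: str) -> TrajectoryPath:
    """Minimum-Euclidean-length node path from ``start`` to ``end``.

    Edge weights are the embedding-space lengths of the edges.  Among
    equally short routes the lexicographically smallest node sequence is
    returned, so the result is deterministic.
    """
    for nid in (start, end):
        if nid not in graph.node_ids:
            raise KeyError(f"unknown node id {nid!r}")
    pos = {nid: graph.node_coords[i] for i, nid in enumerate(graph.node_ids)}
    if start == end:
        return TrajectoryPath((start,), pos[start][None, :])

    g = graph.to_networkx()
    dist_s = nx.single_source_dijkstra_path_length(g, start)
    if end not in dist_s:
        raise ValueError(f"nodes {start!r} and {end!r} are disconnected")
    dist_e = nx.single_source_dijkstra_path_length(g, end)
    total = dist_s[end]
    tol = 1e-9 * max(1.0, total)

    # Greedy reconstruction: always step to the smallest-id neighbour that
    # still lies on some optimal route; yields the lexicographically
    # smallest shortest node sequence.
    path = [start]
    seen = {start}
    u = start
    while u != end:
        candidates = [
            v
            for v in g.neighbors(u)
            if v not in seen
            and abs(dist_s[u] + g[u][v]["weight"] + dist_e.get(v, math.inf) - total) <= tol
        ]
        if not candidates:  # numerical corner; fall back to Dijkstra's own path
            nodes = nx.dijkstra_path(g, start, end)
            return TrajectoryPath(tuple(nodes), np.array([pos[n] for n in nodes]))
        u = min(candidates)
        seen.add(u)
        path.append(u)
    return TrajectoryPath(tuple(path), np.array([pos[n] for n in path]))


def _segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of each point to the closed segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def distances_to_path(points: np.ndarray, path: TrajectoryPath) -> np.ndarray:
    """Vectorized minimum distance from each 2D point to the path polyline."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = path.polyline
    if len(poly) == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    d = np.full(len(points), np.inf)
    for i in range(len(poly) - 1):
        d = np.minimum(d, _segment_distances(points, poly[i], poly[i + 1]))
    return d


def distance_to_path(point, path: TrajectoryPath) -> float:
    """Minimum Euclidean distance from one point to the path polyline.

    Each consecutive node pair is treated as a closed segment (orthogonal
    projection clamped to the endpoints); a single-node path degenerates
    to plain point-to-point distance.
    """
    return float(distances_to_path(np.asarray(point, dtype=float)[None, :], path)[0])


def select_cells_near_path(
    embedding: pd.DataFrame,
    path: TrajectoryPath,
    percentile: float = 0.20,
    interpolation: str = "linear",
) -> CellSelection:
    """Keep cells whose distance to the path is at or below a percentile cutoff.

    ``embedding`` is a cell-indexed DataFrame with two coordinate columns.
    The threshold is the given percentile (fraction in (0, 1]) of *all*
    cell-to-path distances, computed with the stated quantile convention
    (``linear`` interpolation between order statistics by default;
    ``lower``/``higher``/``nearest`` are accepted for sensitivity checks).
    Selection is inclusive (distance <= threshold).
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    if len(embedding) < 5:
        raise ValueError("need at least 5 cells to select from")
    coords = embedding.iloc[:, :2].to_numpy(dtype=float)
    d = distances_to_path(coords, path)
    threshold = float(np.quantile(d, percentile, method=interpolation))
    dist = pd.Series(d, index=embedding.index, name="distance")
    selected = tuple(dist.index[d <= threshold])
    return CellSelection(selected, dist, threshold, percentile)
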