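"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as Matrix-Market coordinate triplets in the
droplet convention (genes x cells ``matrix.mtx`` plus ``features.tsv``
and ``barcodes.tsv``); embeddings, pseudotime and truth labels as
headered CSV; principal graphs as ``nodes.tsv`` / ``edges.tsv``;
suction curves as CSV with a JSON phase sidecar; images as
single-channel TIFF or PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .biomech import SuctionCurve
from .trajectory import PrincipalGraph

__all__ = [
    "write_expression_dir",
    "read_expression_dir",
    "write_graph",
    "read_graph",
    "write_suction_curve",
    "read_suction_curve",
    "write_image",
    "read_image",
]


def write_expression_dir(adata: AnnData, path: str | Path) -> Path:
    """Write cells x genes AnnData as genes x cells MTX + TSV sidecars."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    return path


def read_expression_dir(path: str | Path, layer_tag: str | None = None) -> AnnData:
    """Read an MTX directory back into cells x genes AnnData (CSR)."""
    path = Path(path)
    mat = scipy.io.mmread(str(path / "matrix.mtx")).tocsr().T.tocsr()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )
    if layer_tag is not None:
        adata.uns["layer_tag"] = layer_tag
    return adata


def write_graph(graph: PrincipalGraph, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {"node_id": graph.node_ids, "x": graph.node_coords[:, 0], "y": graph.node_coords[:, 1]}
    )
    nodes.to_csv(directory / "nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(graph.edges, columns=["node_a", "node_b"])
    edges.to_csv(directory / "edges.tsv", sep="\t", index=False)
    return directory


def read_graph(directory: str | Path) -> PrincipalGraph:
    directory = Path(directory)
    nodes = pd.read_csv(directory / "nodes.tsv", sep="\t", dtype={"node_id": str})
    edges = pd.read_csv(directory / "edges.tsv", sep="\t", dtype=str)
    return PrincipalGraph(
        tuple(nodes["node_id"]),
        nodes[["x", "y"]].to_numpy(dtype=float),
        tuple(zip(edges["node_a"], edges["node_b"])),
    )


def write_suction_curve(curve: SuctionCurve, csv_path: str | Path) -> Path:
    """CSV of (time_s, displacement_mm) plus a ``.phases.json`` sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": curve.time_s, "displacement_mm": curve.displacement_mm}).to_csv(
        csv_path, index=False
    )
    sidecar = csv_path.with_suffix(csv_path.suffix + ".phases.json")
    sidecar.write_text(
        json.dumps(
            {
                "suction_start_s": curve.suction_start_s,
                "release_s": curve.release_s,
                "end_s": curve.end_s,
            }
        )
    )
    return csv_path


def read_suction_curve(csv_path: str | Path) -> SuctionCurve:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    phases = json.loads(csv_path.with_suffix(csv_path.suffix + ".phases.json").read_text())
    return SuctionCurve(
        df["time_s"].to_numpy(),
        df["displacement_mm"].to_numpy(),
        phases["suction_start_s"],
        phases["release_s"],
        phases["end_s"],
    )


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a grayscale image; TIFF via tifffile, other formats via imageio."""
    path = Path(path)
    arr = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.float32))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, (np.clip(arr, 0, 1) * 255).astype(np.uint8))
    return path


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr
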