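"""Atlas node table and inter-node Euclidean distances.

The pipeline works on the 94 cortical nodes of the Harvard-Oxford atlas
(nodes 1-47 left hemisphere, 48-94 right).  Anatomical distance enters the
edge-weight model through a normalized Euclidean distance matrix D whose
entries lie in [0, 1]; the distance-weighting constant eta is absorbed into
that normalization and defaults to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datasets import load_fixture

N_NODES = 94


def load_atlas() -> pd.DataFrame:
    """The packaged 94-row atlas table (node_id, hemisphere, region_name)."""
    table = load_fixture("atlas")
    if len(table) != N_NODES or list(table["node_id"]) != list(range(1, N_NODES + 1)):
        raise ValueError("packaged atlas table is corrupted")
    return table


def region_name(node_id: int, atlas: pd.DataFrame | None = None) -> str:
    """Region name for a 1-based atlas node id."""
    if atlas is None:
        atlas = load_atlas()
    if not 1 <= node_id <= len(atlas):
        raise KeyError(f"node id {node_id} outside atlas range 1..{len(atlas)}")
    return str(atlas.loc[atlas["node_id"] == node_id, "region_name"].iloc[0])


def load_centroids(path) -> pd.DataFrame:
    """Read a delimited centroid table with columns node_id, x, y, z (mm)."""
    table = pd.read_csv(path)
    missing = {"node_id", "x", "y", "z"} - set(table.columns)
    if missing:
        raise ValueError(f"centroid file lacks columns: {sorted(missing)}")
    if table["node_id"].duplicated().any():
        dupes = sorted(table.loc[table["node_id"].duplicated(), "node_id"])
        raise ValueError(f"duplicated centroid node ids: {dupes}")
    return table


def distance_matrix(
    centroids: pd.DataFrame, normalize: bool = True, n_nodes: int | None = None
) -> np.ndarray:
    """Pairwise Euclidean distance matrix from node centroids.

    Parameters
    ----------
    centroids
        Table with columns node_id, x, y, z; must cover nodes 1..n contiguously.
    normalize
        Divide by the maximum off-diagonal distance so entries lie in [0, 1]
        with max exactly 1.  Normalization is idempotent.
    n_nodes
        Expected node count (defaults to the number of centroids given).
    """
    if centroids["node_id"].duplicated().any():
        raise ValueError("duplicated node_id in centroid set")
    n = n_nodes if n_nodes is not None else len(centroids)
    missing = sorted(set(range(1, n + 1)) - set(centroids["node_id"].astype(int)))
    if missing:
        raise ValueError(f"missing centroids for nodes: {missing}")
    pts = (
        centroids.sort_values("node_id")[["x", "y", "z"]].to_numpy(dtype=float)
    )
    D = squareform(pdist(pts, metric="euclidean"))
    if normalize:
        dmax = D.max()
        if dmax > 0:
            D = D / dmax
    return D


def normalize_distances(D: np.ndarray) -> np.ndarray:
    """Scale a distance matrix so its maximum entry is 1 (no-op on zeros)."""
    dmax = float(np.max(D))
    return D / dmax if dmax > 0 else D.copy()


def load_distance_matrix(path, normalize: bool = True) -> np.ndarray:
    """Read a delimited square distance matrix, optionally normalizing it."""
    D = np.loadtxt(path, delimiter=",")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix is not square: shape {D.shape}")
    return normalize_distances(D) if normalize else D
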