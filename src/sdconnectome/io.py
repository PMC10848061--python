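"""Connectivity-matrix I/O, validation, edge thresholding and ROI-volume correction.

A connectome here is one subject's weighted, undirected white-matter network:
an N x N symmetric matrix of streamline (fiber) counts between parcellated
brain regions, with optional region labels, MNI coordinates and volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: relative tolerance below which an asymmetric input is silently symmetrized
ASYMMETRY_RTOL = 1e-6


class ConnectomeValidationError(ValueError):
    """Base class for invalid connectivity-matrix input."""


class NonSquareMatrixError(ConnectomeValidationError):
    pass


class NegativeWeightError(ConnectomeValidationError):
    pass


class AsymmetryError(ConnectomeValidationError):
    pass


class MissingMetadataError(ConnectomeValidationError):
    pass


def _default_labels(n: int) -> list[str]:
    return [f"region_{i + 1:03d}" for i in range(n)]


@dataclass
class Connectome:
    """One subject's weighted undirected structural network.

    weights : (N, N) nonnegative symmetric array, zero diagonal. Integer
        streamline counts on input; real-valued after ROI-volume correction.
    node_labels : region names, length N.
    node_volumes : optional per-region volumes in mm^3 (positive).
    node_coords : optional (N, 3) MNI coordinates in mm.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    node_volumes: np.ndarray | None = None
    node_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareMatrixError(f"expected square matrix, got shape {w.shape}")
        if np.any(w < 0):
            raise NegativeWeightError("negative weights are not allowed")
        scale = float(np.abs(w).max()) if w.size else 0.0
        asym = float(np.abs(w - w.T).max()) if w.size else 0.0
        if asym > ASYMMETRY_RTOL * max(scale, 1.0):
            raise AsymmetryError(
                f"matrix asymmetry {asym:g} exceeds tolerance "
                f"{ASYMMETRY_RTOL:g} (relative)"
            )
        if asym > 0:
            w = 0.5 * (w + w.T)
        if w.size and np.any(np.diagonal(w) != 0):
            warnings.warn("nonzero diagonal forced to 0", stacklevel=2)
            np.fill_diagonal(w, 0.0)
        self.weights = w
        n = w.shape[0]
        if not self.node_labels:
            self.node_labels = _default_labels(n)
        if len(self.node_labels) != n:
            raise ConnectomeValidationError(
                f"{len(self.node_labels)} labels for {n} nodes"
            )
        if self.node_volumes is not None:
            v = np.asarray(self.node_volumes, dtype=float)
            if v.shape != (n,):
                raise ConnectomeValidationError("node_volumes must have length N")
            self.node_volumes = v
        if self.node_coords is not None:
            c = np.asarray(self.node_coords, dtype=float)
            if c.shape != (n, 3):
                raise ConnectomeValidationError("node_coords must be (N, 3)")
            self.node_coords = c

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of present (strictly positive) undirected edges."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def copy_with(self, weights: np.ndarray) -> "Connectome":
        return Connectome(
            weights=weights,
            node_labels=list(self.node_labels),
            node_volumes=None if self.node_volumes is None else self.node_volumes.copy(),
            node_coords=None if self.node_coords is None else self.node_coords.copy(),
        )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a node-metadata TSV with columns label, x, y, z, volume."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise MissingMetadataError(f"metadata missing columns: {sorted(missing)}")
    return df


def write_metadata(connectome: Connectome, path: str | Path) -> None:
    if connectome.node_coords is None or connectome.node_volumes is None:
        raise MissingMetadataError("coordinates and volumes required for metadata export")
    df = pd.DataFrame(
        {
            "label": connectome.node_labels,
            "x": connectome.node_coords[:, 0],
            "y": connectome.node_coords[:, 1],
            "z": connectome.node_coords[:, 2],
            "volume": connectome.node_volumes,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, metadata_path: str | Path | None = None) -> Connectome:
    """Read an N x N connectivity matrix (whitespace- or comma-delimited).

    The delimiter is auto-detected from the first non-empty line. Small
    asymmetries (below ``ASYMMETRY_RTOL``) are averaged out; larger ones raise
    :class:`AsymmetryError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    delimiter = "," if "," in first else None
    w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    labels: list[str] = []
    volumes = coords = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        if len(meta) != w.shape[0]:
            raise MissingMetadataError(
                f"metadata has {len(meta)} rows for a {w.shape[0]}-node matrix"
            )
        labels = meta["label"].astype(str).tolist()
        volumes = meta["volume"].to_numpy(dtype=float)
        coords = meta[["x", "y", "z"]].to_numpy(dtype=float)
    return Connectome(w, node_labels=labels, node_volumes=volumes, node_coords=coords)


def write_matrix(
    connectome: Connectome,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the weight matrix as plain text (12 significant digits)."""
    np.savetxt(path, connectome.weights, fmt="%.12g")
    if metadata_path is not None:
        write_metadata(connectome, metadata_path)


def export_brainnet(connectome: Connectome, prefix: str | Path) -> tuple[Path, Path]:
    """Export BrainNet-Viewer style ``.node`` and ``.edge`` files.

    The ``.node`` file has one row per region: x, y, z, color, size, label;
    color is constant and size is the node degree. Coordinates are required.
    """
    if connectome.node_coords is None:
        raise MissingMetadataError(".node export requires node coordinates")
    prefix = Path(prefix)
    node_path = prefix.with_suffix(".node")
    edge_path = prefix.with_suffix(".edge")
    degree = (connectome.weights > 0).sum(axis=1)
    with open(node_path, "w") as fh:
        for i, label in enumerate(connectome.node_labels):
            x, y, z = connectome.node_coords[i]
            fh.write(f"{x:.6g}\t{y:.6g}\t{z:.6g}\t1\t{degree[i]}\t{label}\n")
    np.savetxt(edge_path, connectome.weights, fmt="%.12g")
    return node_path, edge_path


def apply_fiber_threshold(connectome: Connectome, t: int) -> Connectome:
    """Zero out edges with fewer than ``t`` streamlines.

    The threshold is inclusive: an edge with exactly ``t`` streamlines
    survives. ``t = 0`` keeps all strictly positive edges (identity on any
    nonnegative matrix). Applied to raw counts, before ROI-volume correction.
    """
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    w = connectome.weights.copy()
    if t > 0:
        w[w < t] = 0.0
    return connectome.copy_with(w)


def roi_volume_correction(connectome: Connectome) -> Connectome:
    """Divide each weight by the mean volume of the two connected regions.

    w'_ij = w_ij / ((v_i + v_j) / 2). Corrects for larger regions collecting
    more streamlines. Requires positive node volumes.
    """
    v = connectome.node_volumes
    if v is None:
        raise MissingMetadataError("ROI-volume correction requires node volumes")
    if np.any(v <= 0):
        raise ConnectomeValidationError("node volumes must be positive")
    mean_vol = 0.5 * (v[:, None] + v[None, :])
    w = connectome.weights / mean_vol
    np.fill_diagonal(w, 0.0)
    return connectome.copy_with(w)
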