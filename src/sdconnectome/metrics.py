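"""Weighted graph measures for structural connectomes.

All path-based measures map edge weight (streamline count) to length by the
reciprocal, l_ij = 1 / w_ij: stronger connections are shorter. Clustering uses
the Onnela geometric-mean formula on weights normalized by the network-wide
maximum. Unreachable pairs contribute 0 to efficiency sums; the characteristic
path length is averaged over finite pairs with a warning when any pair is
unreachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import skew

from .io import Connectome


class DisconnectedGraphError(ValueError):
    pass


@dataclass
class GlobalMetrics:
    """Subject-level global network measures.

    strength : mean node strength Sp
    e_global : global efficiency
    e_local : local efficiency
    path_length : characteristic (weighted) shortest path length Lp
    clustering : mean Onnela clustering coefficient Cp
    gamma, lambda_ : small-world coefficients Cp/Cp_rand and Lp/Lp_rand,
        None until normalized against a null ensemble
    """

    strength: float
    e_global: float
    e_local: float
    path_length: float
    clustering: float
    gamma: float | None = None
    lambda_: float | None = None


@dataclass
class NodalMetrics:
    degree: np.ndarray
    strength: np.ndarray
    e_nodal: np.ndarray


def _as_weights(x) -> np.ndarray:
    return x.weights if isinstance(x, Connectome) else np.asarray(x, dtype=float)


def distance_matrix(connectome) -> np.ndarray:
    """All-pairs shortest weighted path lengths with l_ij = 1/w_ij.

    Dijkstra on the sparse length graph; d_ii = 0, unreachable pairs inf.
    """
    w = _as_weights(connectome)
    n = w.shape[0]
    ii, jj = np.nonzero(np.triu(w, 1))
    lengths = sparse.csr_matrix((1.0 / w[ii, jj], (ii, jj)), shape=(n, n))
    return shortest_path(lengths, method="D", directed=False)


def node_degrees(connectome) -> np.ndarray:
    w = _as_weights(connectome)
    return (w > 0).sum(axis=1).astype(int)


def node_strengths(connectome) -> np.ndarray:
    return _as_weights(connectome).sum(axis=1)


def network_strength(connectome) -> float:
    """Sp: average connection strength over nodes, Sp = (1/N) sum_i s_i."""
    return float(node_strengths(connectome).mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(connectome) -> float:
    """Average inverse shortest path length over ordered node pairs."""
    return _efficiency_from_distances(distance_matrix(connectome))


def nodal_efficiency(connectome) -> np.ndarray:
    """E_nodal(i) = (1/(N-1)) sum_{j != i} 1/d_ij; its mean is E_glob."""
    d = distance_matrix(connectome)
    n = d.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(connectome) -> float:
    """Mean over nodes of the global efficiency of each node's neighbor subgraph.

    The subgraph induced by the neighbors of i (i excluded) keeps original
    weights; nodes with fewer than two neighbors contribute 0.
    """
    w = _as_weights(connectome)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(w[i])[0]
        if nbrs.size < 2:
            continue
        total += _efficiency_from_distances(distance_matrix(w[np.ix_(nbrs, nbrs)]))
    return total / n if n else 0.0


def characteristic_path_length(connectome, on_disconnected: str = "warn") -> float:
    """Lp: mean shortest-path distance over ordered pairs with a finite path.

    on_disconnected: "warn" (default) averages over finite pairs with a
    warning, "raise" errors, "ignore" averages silently.
    """
    d = distance_matrix(connectome)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise DisconnectedGraphError("no finite path between any pair of nodes")
    if n_unreachable:
        if on_disconnected == "raise":
            raise DisconnectedGraphError(f"{n_unreachable} unreachable ordered pairs")
        if on_disconnected == "warn":
            warnings.warn(
                f"{n_unreachable} unreachable ordered pairs excluded from Lp",
                stacklevel=2,
            )
    return float(d[finite].mean())


def clustering_coefficient(connectome) -> tuple[float, np.ndarray]:
    """Weighted clustering (Onnela): geometric mean of normalized triangle weights.

    C_i = (1/(k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with
    w' = w / max(w) over the whole network; C_i = 0 for k_i < 2.
    Returns (Cp, per-node C_i).
    """
    w = _as_weights(connectome)
    n = w.shape[0]
    wmax = w.max()
    if n == 0 or wmax == 0:
        return 0.0, np.zeros(n)
    cw = np.cbrt(w / wmax)
    k = (w > 0).sum(axis=1)
    triangles = np.diagonal(cw @ cw @ cw)
    denom = k * (k - 1)
    c = np.zeros(n)
    mask = denom > 0
    c[mask] = triangles[mask] / denom[mask]
    return float(c.mean()), c


def degree_distribution(connectome) -> tuple[np.ndarray, np.ndarray, float]:
    """Binary degree histogram and its sample skewness.

    Returns (degree values per node, bin counts for degrees 0..max, skewness).
    Skewness is the bias-corrected sample (n-1) form; 0 when degenerate.
    """
    k = node_degrees(connectome)
    counts = np.bincount(k, minlength=int(k.max()) + 1 if k.size else 1)
    if k.size < 3 or np.all(k == k[0]):
        g = 0.0
    else:
        g = float(skew(k, bias=False))
    return k, counts, g


def nodal_metrics(connectome) -> NodalMetrics:
    return NodalMetrics(
        degree=node_degrees(connectome),
        strength=node_strengths(connectome),
        e_nodal=nodal_efficiency(connectome),
    )


def small_world_metrics(connectome, ensemble) -> tuple[float, float]:
    """Small-world coefficients against matched random networks.

    gamma = Cp / mean(Cp_rand), lambda = Lp / mean(Lp_rand) over the
    ensemble. gamma > 1 with lambda ~ 1 is the small-world signature.
    """
    networks = getattr(ensemble, "networks", ensemble)
    if len(networks) == 0:
        raise ValueError("null ensemble is empty")
    cp, _ = clustering_coefficient(connectome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lp = characteristic_path_length(connectome)
        cp_rand = np.mean([clustering_coefficient(g)[0] for g in networks])
        lp_rand = np.mean([characteristic_path_length(g) for g in networks])
    if cp_rand == 0 or lp_rand == 0:
        raise ZeroDivisionError("degenerate null ensemble (zero mean Cp or Lp)")
    return cp / cp_rand, lp / lp_rand


def global_metrics(connectome, ensemble=None) -> GlobalMetrics:
    """All subject-level global measures, optionally small-world normalized."""
    cp, _ = clustering_coefficient(connectome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lp = characteristic_path_length(connectome)
    gm = GlobalMetrics(
        strength=network_strength(connectome),
        e_global=global_efficiency(connectome),
        e_local=local_efficiency(connectome),
        path_length=lp,
        clustering=cp,
    )
    if ensemble is not None:
        gm.gamma, gm.lambda_ = small_world_metrics(connectome, ensemble)
    return gm
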