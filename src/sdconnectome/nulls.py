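"""Matched random-network null models.

Null networks preserve the source network's binary degree sequence exactly
(double-edge-swap rewiring) and its multiset of edge weights (the original
weights are randomly permuted over the rewired edge set). They normalize the
small-world coefficients and the weighted rich-club coefficient.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io import Connectome

DEFAULT_REWIRES_PER_EDGE = 10


def _child_seed(seed: int, index: int) -> np.random.SeedSequence:
    # deterministic per-member stream; independent of ensemble size
    return np.random.SeedSequence([int(seed), int(index)])


def source_digest(connectome: Connectome) -> str:
    w = np.ascontiguousarray(connectome.weights)
    return hashlib.sha256(w.tobytes()).hexdigest()[:16]


@dataclass
class NullEnsemble:
    networks: list[Connectome]
    n_rewires_per_edge: int
    seed: int
    source_hash: str

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)


@njit(cache=True)
def _swap_kernel(adj, ei, ej, e1s, e2s, flip1, flip2, target, swaps):
    """Apply double-edge swaps in place until ``target`` swaps succeed or the
    proposal arrays are exhausted. A proposal picks edges (u,v), (x,y) with
    random orientations and replaces them with (u,x), (v,y) when all four
    nodes are distinct and neither new edge exists. Degrees are invariant.
    """
    for t in range(e1s.shape[0]):
        if swaps >= target:
            break
        u, v = ei[e1s[t]], ej[e1s[t]]
        x, y = ei[e2s[t]], ej[e2s[t]]
        if flip1[t]:
            u, v = v, u
        if flip2[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = adj[v, u] = False
        adj[x, y] = adj[y, x] = False
        adj[u, x] = adj[x, u] = True
        adj[v, y] = adj[y, v] = True
        ei[e1s[t]] = u
        ej[e1s[t]] = x
        ei[e2s[t]] = v
        ej[e2s[t]] = y
        swaps += 1
    return swaps


def rewire_degree_preserving(
    connectome: Connectome,
    n_rewires_per_edge: int = DEFAULT_REWIRES_PER_EDGE,
    seed: int | np.random.SeedSequence = 0,
) -> Connectome:
    """One matched random network: degree-preserving rewire + weight permutation.

    Repeated double-edge swaps — pick edges (u,v), (x,y), replace with (u,x),
    (v,y) when no self-loop or multi-edge results — preserve every node's
    degree exactly. The original edge weights are then randomly reassigned to
    the rewired edge set, preserving the weight multiset. Graphs with no
    legal swap (fewer than 2 edges, or a complete graph) keep their
    topology; if the swap budget (100 attempts per requested swap) runs out
    early a warning reports the shortfall, with degrees still intact.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    w = connectome.weights
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, 1))
    m = iu.size
    if m < 2:
        warnings.warn("fewer than 2 edges: no legal swap, returning a copy", stacklevel=2)
        return connectome.copy_with(w.copy())
    if m == n * (n - 1) // 2:
        new_i, new_j = iu, ju  # complete graph: swap-invariant topology
    else:
        adj = w > 0
        ei = iu.astype(np.int64).copy()
        ej = ju.astype(np.int64).copy()
        target = n_rewires_per_edge * m
        max_tries = 100 * target
        swaps = tries = 0
        while swaps < target and tries < max_tries:
            block = min(max_tries - tries, 4 * target)
            e1s = rng.integers(0, m, block)
            e2s = rng.integers(0, m, block)
            flips = rng.random((block, 2)) < 0.5
            swaps = int(
                _swap_kernel(
                    adj, ei, ej, e1s, e2s,
                    np.ascontiguousarray(flips[:, 0]),
                    np.ascontiguousarray(flips[:, 1]),
                    target, swaps,
                )
            )
            tries += block
        if swaps < target:
            warnings.warn(
                f"rewiring stopped early: {swaps}/{target} swaps in {tries} tries",
                stacklevel=2,
            )
        new_i, new_j = np.minimum(ei, ej), np.maximum(ei, ej)
    perm = rng.permutation(m)
    out = np.zeros_like(w)
    out[new_i, new_j] = w[iu, ju][perm]
    out += out.T
    return connectome.copy_with(out)


def matched_ensemble(
    connectome: Connectome,
    n: int = 1000,
    seed: int = 0,
    n_rewires_per_edge: int = DEFAULT_REWIRES_PER_EDGE,
) -> NullEnsemble:
    """Ensemble of ``n`` independent matched random networks.

    Member i is seeded from (seed, i), so individual members are reproducible
    regardless of ensemble size.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n}")
    networks = [
        rewire_degree_preserving(
            connectome, n_rewires_per_edge=n_rewires_per_edge, seed=_child_seed(seed, i)
        )
        for i in range(n)
    ]
    return NullEnsemble(
        networks=networks,
        n_rewires_per_edge=n_rewires_per_edge,
        seed=seed,
        source_hash=source_digest(connectome),
    )
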