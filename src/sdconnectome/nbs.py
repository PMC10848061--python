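"""Network-based statistic (NBS).

Identifies connected subnetworks of edges whose weights differ between
groups, with family-wise error control by a max-component permutation null:
edge-wise pooled t tests (resistant minus vulnerable), a one-tailed primary
threshold, connected components of the supra-threshold graph, and group-label
permutations recording the largest null component size (in edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy import stats as sps

from .cohort import Cohort, RESISTANT, VULNERABLE
from .richclub import backbone_network


@dataclass
class Component:
    edges: list[tuple[int, int]]
    nodes: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


@dataclass
class NBSResult:
    t_matrix: np.ndarray  # (N, N), nan on untested pairs
    primary_threshold: float
    components: list[Component]  # sorted by edge count, descending
    max_component_size_null: np.ndarray  # (n_perm,) edge counts
    component_p: np.ndarray  # per observed component, FWE-corrected
    seed: int
    edge_mask: np.ndarray  # (N, N) bool, tested pairs


def union_backbone_mask(cohort: Cohort, alpha: float = 0.05, correction: str = "fdr_bh") -> np.ndarray:
    """Tested-edge mask: union of the two group sign-test backbones."""
    adj = np.zeros((cohort.n_nodes, cohort.n_nodes), dtype=bool)
    for group in (VULNERABLE, RESISTANT):
        subs = cohort.group_subjects(group)
        if len(subs) >= 2:
            adj |= backbone_network(subs, alpha=alpha, correction=correction).adjacency > 0
    return adj


def _pooled_t(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorized pooled two-sample t over the last axis of stacked samples.

    xa, xb: (n_a, E) and (n_b, E). Zero pooled variance gives t = 0 for equal
    means and +/-inf (flagged by the value) otherwise.
    """
    na, nb = xa.shape[0], xb.shape[0]
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    sp2 = ((xa.var(axis=0, ddof=1) * (na - 1)) + (xb.var(axis=0, ddof=1) * (nb - 1))) / (
        na + nb - 2
    )
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff == 0)] = 0.0
    return t


def edgewise_group_t(
    cohort: Cohort, edge_mask: np.ndarray | None = None, min_fraction: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-wise pooled t statistics for the resistant - vulnerable contrast.

    Only masked pairs are tested; the default mask is the union of the two
    group backbones, or (with ``min_fraction``) edges present in at least
    that fraction of all subjects. Returns (t_matrix with nan on untested
    pairs, mask).
    """
    mask_a = cohort.group_mask(RESISTANT)
    mask_b = cohort.group_mask(VULNERABLE)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    stack = cohort.weight_stack()
    n = cohort.n_nodes
    if edge_mask is None:
        if min_fraction is not None:
            frac = (stack > 0).mean(axis=0)
            edge_mask = frac >= min_fraction
        else:
            edge_mask = union_backbone_mask(cohort)
    edge_mask = np.triu(edge_mask, 1) | np.triu(edge_mask, 1).T
    iu, ju = np.nonzero(np.triu(edge_mask, 1))
    x = stack[:, iu, ju]
    t = _pooled_t(x[mask_a], x[mask_b])
    if np.any(np.isinf(t)):
        warnings.warn("infinite t on zero-variance edge(s)", stacklevel=2)
    tmat = np.full((n, n), np.nan)
    tmat[iu, ju] = t
    tmat[ju, iu] = t
    return tmat, edge_mask


def supra_threshold_components(t_matrix: np.ndarray, t_thresh: float) -> list[Component]:
    """Connected components of the graph of edges with t >= threshold.

    One-tailed (resistant > vulnerable). Components are returned as edge
    sets with their node lists, largest (by edge count) first.
    """
    t = np.asarray(t_matrix, dtype=float)
    n = t.shape[0]
    supra = np.triu(np.nan_to_num(t, nan=-np.inf) >= t_thresh, 1)
    iu, ju = np.nonzero(supra)
    if iu.size == 0:
        return []
    g = sparse.csr_matrix((np.ones(iu.size), (iu, ju)), shape=(n, n))
    n_comp, labels = connected_components(g, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(iu.tolist(), ju.tolist()):
        comps.setdefault(labels[i], []).append((i, j))
    out = [
        Component(edges=edges, nodes=np.unique([v for e in edges for v in e]))
        for edges in comps.values()
    ]
    out.sort(key=lambda c: (-c.n_edges, c.nodes[0]))
    return out


def _max_component_size(
    n: int, iu: np.ndarray, ju: np.ndarray, supra: np.ndarray, size_mode: str
) -> int:
    """Largest connected-component size (edges or nodes) among supra edges."""
    si, sj = iu[supra], ju[supra]
    if si.size == 0:
        return 0
    g = sparse.csr_matrix((np.ones(si.size), (si, sj)), shape=(n, n))
    _, labels = connected_components(g, directed=False)
    if size_mode == "nodes":
        touched = np.unique(np.concatenate([si, sj]))
        return int(np.bincount(labels[touched]).max())
    return int(np.bincount(labels[si]).max())


def t_threshold_from_edge_p(edge_p: float, df: int) -> float:
    """Primary t threshold from a one-tailed edge-wise p level."""
    return float(sps.t.ppf(1 - edge_p, df))


def nbs_permutation(
    cohort: Cohort,
    t_thresh: float | None = None,
    edge_p: float = 0.01,
    n_perm: int = 5000,
    seed: int = 0,
    edge_mask: np.ndarray | None = None,
    size_mode: str = "edges",
) -> NBSResult:
    """Max-component permutation test for group-different subnetworks.

    Group labels are permuted ``n_perm`` times; the largest supra-threshold
    component size per permutation forms the null, and each observed
    component gets p = (1 + #{null >= observed}) / (1 + n_perm). Component
    size is measured in edges by default (``size_mode="nodes"`` available).
    When ``t_thresh`` is None it is derived from the one-tailed ``edge_p``
    at the pooled-t degrees of freedom.
    """
    if size_mode not in ("edges", "nodes"):
        raise ValueError(f"unknown size_mode {size_mode!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives a coarse null", stacklevel=2)
    mask_a = cohort.group_mask(RESISTANT)
    mask_b = cohort.group_mask(VULNERABLE)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 subjects to permute")
    if t_thresh is None:
        t_thresh = t_threshold_from_edge_p(edge_p, na + nb - 2)
    tmat, edge_mask = edgewise_group_t(cohort, edge_mask=edge_mask)
    observed = supra_threshold_components(tmat, t_thresh)

    n = cohort.n_nodes
    iu, ju = np.nonzero(np.triu(edge_mask, 1))
    x = cohort.weight_stack()[:, iu, ju]
    labels = np.concatenate([np.ones(na, dtype=bool), np.zeros(nb, dtype=bool)])
    # reorder subjects so resistant come first; permutation then shuffles roles
    order = np.concatenate([np.nonzero(mask_a)[0], np.nonzero(mask_b)[0]])
    x = x[order]
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_perm):
            perm = rng.permutation(labels)
            t = _pooled_t(x[perm], x[~perm])
            null_max[k] = _max_component_size(
                n, iu, ju, np.nan_to_num(t, nan=-np.inf) >= t_thresh, size_mode
            )
    observed_sizes = [c.n_edges if size_mode == "edges" else c.n_nodes for c in observed]
    p = np.array(
        [(1 + int((null_max >= s).sum())) / (1 + n_perm) for s in observed_sizes]
    )
    return NBSResult(
        t_matrix=tmat,
        primary_threshold=float(t_thresh),
        components=observed,
        max_component_size_null=null_max,
        component_p=p,
        seed=seed,
        edge_mask=edge_mask,
    )
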