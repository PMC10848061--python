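"""Rich-club analysis: group backbone, hub identification, edge classes,
class connection strengths, and the weighted rich-club coefficient.

The hub ("rich club") set is defined on a group-level backbone network —
edges whose presence across subjects is significant under a one-tailed sign
test against zero, multiplicity-corrected — as the nodes whose backbone
degree is at least one standard deviation above the mean. Edges are then
classified as rich (hub-hub), feeder (hub-periphery) or local
(periphery-periphery), and per-subject class strengths and the weighted
rich-club coefficient phi are computed on each subject's own weights with
the group hub set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import Connectome
from .nulls import NullEnsemble

# edge class codes
ABSENT, RICH, FEEDER, LOCAL = 0, 1, 2, 3
EDGE_CLASS_NAMES = {ABSENT: "absent", RICH: "rich", FEEDER: "feeder", LOCAL: "local"}


class RichClubUndefinedError(ValueError):
    """Raised when phi is undefined (no hub-hub edges)."""


@dataclass
class BackboneNetwork:
    adjacency: np.ndarray  # (N, N) 0/1
    p_values: np.ndarray  # (N, N) corrected sign-test p-values
    degree: np.ndarray  # per-node backbone degree
    group: str = ""
    alpha: float = 0.05
    correction: str = "fdr_bh"


@dataclass
class RichClubResult:
    hub_set: np.ndarray  # sorted node indices
    edge_class: np.ndarray  # (N, N) class codes
    strength_rich: float
    strength_feeder: float
    strength_local: float
    ratio_rich_feeder: float  # nan when feeder strength is 0
    ratio_rich_local: float  # nan when local strength is 0
    phi: float  # nan when undefined
    phi_norm: float | None = None
    n_rich_edges: int = 0
    n_null_defined: int | None = field(default=None)


def sign_test_presence_p(presence_counts: np.ndarray) -> np.ndarray:
    """One-tailed sign-test p-value for 'median weight > 0' per node pair.

    With zero weights dropped, the test statistic is m, the number of
    subjects in which the edge is present; under H0 each nonzero sign is
    positive with probability 1/2, but weights are nonnegative, so every
    present observation is positive and p = 0.5^m (p = 1 when m = 0).
    """
    m = np.asarray(presence_counts, dtype=float)
    p = np.power(0.5, m)
    p[m == 0] = 1.0
    return p


def backbone_network(
    group_connectomes: list[Connectome],
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    group: str = "",
) -> BackboneNetwork:
    """Group backbone: edges significantly present across subjects.

    One-tailed sign test per node pair, corrected across all N(N-1)/2
    candidate pairs (Benjamini-Hochberg by default, "bonferroni" available);
    an edge is kept when its corrected p < alpha.
    """
    if len(group_connectomes) == 0:
        raise ValueError("empty group")
    if len(group_connectomes) < 2:
        raise ValueError("backbone requires at least 2 subjects")
    stack = np.stack([c.weights for c in group_connectomes])
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, 1)
    m = (stack[:, iu, ju] > 0).sum(axis=0)
    p_raw = sign_test_presence_p(m)
    if correction in ("none", None):
        p_corr = p_raw
    else:
        p_corr = multipletests(p_raw, alpha=alpha, method=correction)[1]
    keep = p_corr < alpha
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    pmat = np.ones((n, n))
    pmat[iu, ju] = p_corr
    pmat[ju, iu] = p_corr
    np.fill_diagonal(pmat, 1.0)
    return BackboneNetwork(
        adjacency=adj,
        p_values=pmat,
        degree=adj.sum(axis=1),
        group=group,
        alpha=alpha,
        correction=correction or "none",
    )


def identify_hubs(backbone: BackboneNetwork | np.ndarray) -> np.ndarray:
    """Hubs: nodes with degree >= mean degree + 1 sample standard deviation."""
    if isinstance(backbone, BackboneNetwork):
        k = backbone.degree.astype(float)
    else:
        adj = np.asarray(backbone)
        k = (adj > 0).sum(axis=1).astype(float)
    if k.size == 0 or k.sum() == 0:
        return np.array([], dtype=int)
    sd = k.std(ddof=1) if k.size > 1 else 0.0
    if sd == 0:
        warnings.warn(
            "degenerate degree distribution (sd = 0): every node meets the hub rule",
            stacklevel=2,
        )
    return np.nonzero(k >= k.mean() + sd)[0]


def classify_edges(connectome: Connectome | np.ndarray, hub_set: np.ndarray) -> np.ndarray:
    """Label every present edge rich / feeder / local; absent pairs 0."""
    w = connectome.weights if isinstance(connectome, Connectome) else np.asarray(connectome)
    n = w.shape[0]
    hub_set = np.asarray(hub_set, dtype=int)
    if hub_set.size and (hub_set.min() < 0 or hub_set.max() >= n):
        raise IndexError("hub index out of range")
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hub_set] = True
    n_hub_ends = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
    classes = np.where(n_hub_ends == 2, RICH, np.where(n_hub_ends == 1, FEEDER, LOCAL))
    classes = np.where(w > 0, classes, ABSENT)
    np.fill_diagonal(classes, ABSENT)
    return classes


def connection_strengths(
    connectome: Connectome, edge_class: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Per-class summed edge weights and rich/feeder, rich/local ratios.

    Each undirected edge counts once. A ratio with zero denominator is
    returned as nan (undefined flag).
    """
    w = np.triu(connectome.weights, 1)
    upper_class = np.triu(edge_class, 1)
    s_rich = float(w[upper_class == RICH].sum())
    s_feeder = float(w[upper_class == FEEDER].sum())
    s_local = float(w[upper_class == LOCAL].sum())
    r_rf = s_rich / s_feeder if s_feeder > 0 else float("nan")
    r_rl = s_rich / s_local if s_local > 0 else float("nan")
    return s_rich, s_feeder, s_local, r_rf, r_rl


def weighted_rich_club_coefficient(connectome: Connectome, hub_set: np.ndarray) -> float:
    """phi = (sum of the n hub-hub edge weights) / (sum of the n strongest
    edge weights network-wide), where n is the number of present hub-hub
    edges. phi is in (0, 1]; raises when there is no hub-hub edge.
    """
    w = connectome.weights
    hub_set = np.asarray(hub_set, dtype=int)
    iu, ju = np.triu_indices(w.shape[0], 1)
    weights = w[iu, ju]
    is_hub = np.zeros(w.shape[0], dtype=bool)
    is_hub[hub_set] = True
    hub_edge = is_hub[iu] & is_hub[ju] & (weights > 0)
    n = int(hub_edge.sum())
    if n == 0:
        raise RichClubUndefinedError("no edges among hub nodes: phi undefined")
    top_n = np.sort(weights)[::-1][:n]
    return float(weights[hub_edge].sum() / top_n.sum())


def normalized_rich_club(
    connectome: Connectome,
    hub_set: np.ndarray,
    ensemble: NullEnsemble | list[Connectome],
) -> tuple[float, int]:
    """phi_norm = phi / mean(phi over matched random networks).

    Ensemble members where phi is undefined are skipped; the count of
    defined members is returned alongside. phi_norm > 1 indicates rich-club
    organization (hub-hub edges stronger than degree and weight distribution
    alone predict).
    """
    phi = weighted_rich_club_coefficient(connectome, hub_set)
    networks = getattr(ensemble, "networks", ensemble)
    phis = []
    for g in networks:
        try:
            phis.append(weighted_rich_club_coefficient(g, hub_set))
        except RichClubUndefinedError:
            continue
    if not phis:
        raise RichClubUndefinedError("phi undefined on every ensemble member")
    return phi / float(np.mean(phis)), len(phis)


def rich_club_result(
    connectome: Connectome,
    hub_set: np.ndarray,
    ensemble: NullEnsemble | list[Connectome] | None = None,
) -> RichClubResult:
    """Assemble the full per-subject rich-club summary for a given hub set."""
    hub_set = np.sort(np.asarray(hub_set, dtype=int))
    classes = classify_edges(connectome, hub_set)
    s_rich, s_feeder, s_local, r_rf, r_rl = connection_strengths(connectome, classes)
    n_rich = int((np.triu(classes, 1) == RICH).sum())
    try:
        phi = weighted_rich_club_coefficient(connectome, hub_set)
    except RichClubUndefinedError:
        phi = float("nan")
    phi_norm = None
    n_defined = None
    if ensemble is not None and np.isfinite(phi):
        phi_norm, n_defined = normalized_rich_club(connectome, hub_set, ensemble)
    return RichClubResult(
        hub_set=hub_set,
        edge_class=classes,
        strength_rich=s_rich,
        strength_feeder=s_feeder,
        strength_local=s_local,
        ratio_rich_feeder=r_rf,
        ratio_rich_local=r_rl,
        phi=phi,
        phi_norm=phi_norm,
        n_rich_edges=n_rich,
        n_null_defined=n_defined,
    )
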