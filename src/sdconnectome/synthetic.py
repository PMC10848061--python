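"""Synthetic connectome cohort generator.

Emulates the study design this package analyzes: two groups of subjects
(vulnerable and resistant to sleep deprivation), each with a 90-node
AAL-style weighted structural network of integer streamline counts, a
planted rich club, and PVT lapse counts linked to rich-club strength.

Topology: a planted-hub stochastic block model. Hub nodes form a densely
interconnected block; hub-periphery edges are placed at random; the
periphery is wired with a ring-locality kernel (short-range pairs connect
with high probability, long-range pairs rarely) whose marginal density
equals ``p_periph_periph``. The locality kernel supplies the excess
clustering, and hub shortcuts the short paths, of small-world brain
networks; the hub block with its weight premium supplies the rich club and
the right-skewed degree distribution.

Weights: each edge gets a cohort-level baseline streamline count, log-normal
with log-mean ``weight_log_mean`` (plus ``hub_weight_log_boost`` on hub-hub
edges — large fiber bundles link hubs) and log-sd ``weight_log_sd``; each
subject multiplies the baseline by log-normal noise and rounds to integer.
Vulnerable subjects' hub-hub weights are attenuated by ``delta_rich``
before rounding — the planted group difference.

Lapse counts: negative binomial (lapse counts are overdispersed,
nonnegative), with log-mean = group baseline + slope x standardized
subject rich-club strength, so weaker rich clubs mean more lapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy import sparse

from .cohort import Cohort, EmptyCohortError, RESISTANT, VULNERABLE
from .io import Connectome

#: expected lapse count at rested wakefulness, all subjects
REST_LAPSE_MEAN = 0.5
#: probability of a short-range peripheral edge in the locality kernel
P_PERIPH_NEAR = 0.85


class InvalidConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Generator parameters; defaults reproduce the study's two-group design
    (n = 25 vulnerable / 24 resistant, 90 regions, lapse means per the
    demographics table of the emulated design).
    """

    n_nodes: int = 90
    n_hubs: int = 12
    p_hub_hub: float = 0.8
    p_hub_periph: float = 0.3
    p_periph_periph: float = 0.1
    weight_log_mean: float = 3.3
    weight_log_sd: float = 0.9
    hub_weight_log_boost: float = 0.6
    subject_noise_sd: float = 0.3
    delta_rich: float = 0.6
    n_vulnerable: int = 25
    n_resistant: int = 24
    lapse_mean_vulnerable: float = 9.56
    lapse_mean_resistant: float = 0.54
    lapse_dispersion: float = 2.0
    behavior_link_slope: float = -0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise InvalidConfigError("n_nodes must be >= 2")
        if self.n_hubs < 1 or self.n_hubs > self.n_nodes:
            raise InvalidConfigError(
                f"n_hubs must be in [1, n_nodes], got {self.n_hubs} for "
                f"{self.n_nodes} nodes"
            )
        for name in ("p_hub_hub", "p_hub_periph", "p_periph_periph"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        if not (self.p_hub_hub >= self.p_hub_periph >= self.p_periph_periph):
            warnings.warn(
                "edge probabilities are not ordered hub-hub >= hub-periph >= "
                "periph-periph; the planted hubs may not dominate",
                stacklevel=2,
            )
        if not 0 < self.delta_rich <= 1:
            raise InvalidConfigError("delta_rich must be in (0, 1]")
        if self.n_vulnerable < 0 or self.n_resistant < 0:
            raise InvalidConfigError("group sizes must be nonnegative")
        if self.weight_log_sd < 0 or self.subject_noise_sd < 0:
            raise InvalidConfigError("scale parameters must be nonnegative")
        if self.lapse_dispersion <= 0:
            raise InvalidConfigError("lapse_dispersion must be positive")
        if self.lapse_mean_vulnerable < 0 or self.lapse_mean_resistant < 0:
            raise InvalidConfigError("lapse means must be nonnegative")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class BinaryTopology:
    adjacency: np.ndarray  # (N, N) 0/1, symmetric, zero diagonal
    hub_flags: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=int)
        if not np.array_equal(a, a.T) or np.any(np.diagonal(a)):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a
        self.hub_flags = np.asarray(self.hub_flags, dtype=bool)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _repair_connectivity(adj: np.ndarray, rng: np.random.Generator) -> None:
    """Connect components in place by adding random cross-component edges."""
    n = adj.shape[0]
    while True:
        n_comp, labels = connected_components(sparse.csr_matrix(adj), directed=False)
        if n_comp == 1:
            return
        a = int(rng.choice(np.nonzero(labels == 0)[0]))
        b = int(rng.choice(np.nonzero(labels != 0)[0]))
        adj[a, b] = adj[b, a] = 1


def generate_template_topology(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> BinaryTopology:
    """Sample the cohort's shared binary topology (planted-hub block model).

    Hub nodes are indices 0..n_hubs-1. Peripheral nodes sit on a ring:
    pairs within ring distance K connect with probability
    ``P_PERIPH_NEAR``, farther pairs with the probability that keeps the
    overall peripheral density at ``p_periph_periph``. Disconnected samples
    are repaired by adding random edges between components, so every
    template supports finite path lengths.
    """
    config.validate()
    if rng is None:
        rng = _stream(config.seed, 0)
    n, h = config.n_nodes, config.n_hubs
    adj = np.zeros((n, n), dtype=int)
    iu, ju = np.triu_indices(n, 1)
    hub = np.zeros(n, dtype=bool)
    hub[:h] = True

    both_hub = hub[iu] & hub[ju]
    one_hub = hub[iu] ^ hub[ju]
    periph_pair = ~hub[iu] & ~hub[ju]

    p = np.zeros(iu.size)
    p[both_hub] = config.p_hub_hub
    p[one_hub] = config.p_hub_periph

    n_periph = n - h
    if n_periph >= 2:
        ring = np.full(n, -1)
        ring[h:] = np.arange(n_periph)
        d = np.abs(ring[iu] - ring[ju])
        d = np.minimum(d, n_periph - d)
        p_pp = config.p_periph_periph
        if p_pp >= P_PERIPH_NEAR:
            p[periph_pair] = p_pp  # dense periphery: locality adds nothing
        else:
            # near fraction f solves f * p_near + (1 - f) * p_far = p_pp
            p_far = min(p_pp / 5, 0.02)
            f = (p_pp - p_far) / (P_PERIPH_NEAR - p_far)
            k_near = max(1, round(f * (n_periph - 1) / 2)) if p_pp > 0 else 0
            if p_pp > 0:
                f_actual = min(1.0, 2 * k_near / (n_periph - 1))
                p_far = max(0.0, (p_pp - f_actual * P_PERIPH_NEAR) / (1 - f_actual)) if f_actual < 1 else 0.0
                near = periph_pair & (d <= k_near)
                p[near] = P_PERIPH_NEAR
                p[periph_pair & ~(d <= k_near)] = p_far

    draw = rng.random(iu.size) < p
    adj[iu[draw], ju[draw]] = 1
    adj += adj.T
    _repair_connectivity(adj, rng)
    return BinaryTopology(adjacency=adj, hub_flags=hub)


def _baseline_weights(config: CohortConfig, topo: BinaryTopology, rng: np.random.Generator):
    """Cohort-level log-normal baseline streamline count per template edge."""
    iu, ju = np.nonzero(np.triu(topo.adjacency, 1))
    hub_edge = topo.hub_flags[iu] & topo.hub_flags[ju]
    mu = np.where(hub_edge, config.weight_log_mean + config.hub_weight_log_boost,
                  config.weight_log_mean)
    base = rng.lognormal(mean=mu, sigma=config.weight_log_sd)
    return iu, ju, hub_edge, base


def _node_metadata(config: CohortConfig, rng: np.random.Generator):
    """Synthetic MNI-style coordinates (mm) and region volumes (mm^3)."""
    coords = rng.uniform([-70, -105, -60], [70, 70, 75], size=(config.n_nodes, 3))
    volumes = rng.lognormal(mean=math.log(15000), sigma=0.4, size=config.n_nodes)
    return coords, volumes


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-group cohort of weighted connectomes.

    All subjects share one template topology and baseline weights; each
    subject's integer weight matrix is round(baseline x exp(noise)), with
    hub-hub edges of vulnerable subjects attenuated by ``delta_rich`` before
    rounding. Subject s draws from a stream keyed by (seed, 2, s), so a
    subject's network is reproducible even when group sizes change.
    """
    config.validate()
    n_total = config.n_vulnerable + config.n_resistant
    if n_total == 0:
        raise EmptyCohortError("n_vulnerable and n_resistant are both 0")
    topo = generate_template_topology(config)
    iu, ju, hub_edge, base = _baseline_weights(config, topo, _stream(config.seed, 1))
    coords, volumes = _node_metadata(config, _stream(config.seed, 4))
    labels = [f"region_{i + 1:03d}" for i in range(config.n_nodes)]
    groups = [VULNERABLE] * config.n_vulnerable + [RESISTANT] * config.n_resistant
    subjects = []
    for s in range(n_total):
        rng_s = _stream(config.seed, 2, s)
        noise = rng_s.normal(0.0, config.subject_noise_sd, size=base.size)
        w_edges = base * np.exp(noise)
        if groups[s] == VULNERABLE:
            w_edges = np.where(hub_edge, w_edges * config.delta_rich, w_edges)
        w = np.zeros((config.n_nodes, config.n_nodes))
        w[iu, ju] = np.round(w_edges)
        w += w.T
        subjects.append(
            Connectome(w, node_labels=labels, node_volumes=volumes, node_coords=coords)
        )
    cohort = Cohort(
        subjects=subjects,
        groups=np.array(groups, dtype=object),
        template_hub_flags=topo.hub_flags,
    )
    return cohort


def rich_club_strength_per_subject(cohort: Cohort, hub_flags: np.ndarray) -> np.ndarray:
    """Summed hub-hub edge weight per subject (each edge counted once)."""
    hub_flags = np.asarray(hub_flags, dtype=bool)
    stack = cohort.weight_stack()
    sel = np.triu(np.outer(hub_flags, hub_flags), 1)
    return stack[:, sel].sum(axis=1)


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if math.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_lapse_scores(cohort: Cohort, config: CohortConfig) -> Cohort:
    """Attach PVT lapse counts linked to each subject's rich-club strength.

    Sleep-deprived lapse counts are negative binomial with
    log-mean = log(group baseline) + slope x z, where z is the subject's
    rich-club connection strength standardized across the cohort (z = 0
    when the cohort is degenerate, e.g. all-zero networks). A negative
    slope makes weak rich clubs lapse more, giving the negative
    strength-lapse correlation the analysis looks for. Rested-wakefulness
    counts are drawn at a common low baseline.
    """
    config.validate()
    if cohort.n_subjects == 0:
        raise EmptyCohortError("cohort has no subjects")
    hub_flags = cohort.template_hub_flags
    if hub_flags is None:
        raise ValueError("cohort has no template hub flags to standardize against")
    strength = rich_club_strength_per_subject(cohort, hub_flags)
    sd = strength.std()
    z = (strength - strength.mean()) / sd if sd > 0 else np.zeros_like(strength)
    base = np.where(
        cohort.group_mask(VULNERABLE),
        config.lapse_mean_vulnerable,
        config.lapse_mean_resistant,
    )
    with np.errstate(divide="ignore"):
        log_mu = np.log(base) + config.behavior_link_slope * z
    mu = np.where(base > 0, np.exp(log_mu), 0.0)
    rng = _stream(config.seed, 3)
    cohort.lapse_sd = _negbin(rng, mu, config.lapse_dispersion).astype(float)
    cohort.lapse_rw = _negbin(
        rng, np.full(cohort.n_subjects, REST_LAPSE_MEAN), config.lapse_dispersion
    ).astype(float)
    return cohort


def generate(config: CohortConfig) -> Cohort:
    """Cohort with networks and lapse scores in one call."""
    return generate_lapse_scores(generate_cohort(config), config)
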