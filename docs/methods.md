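# Methods

This package analyzes weighted white-matter structural connectomes — per
subject an N×N symmetric matrix of streamline counts between parcellated
brain regions — to ask how network topology differs between subjects who
are vulnerable versus resistant to total sleep deprivation, and whether
rich-club connectivity tracks psychomotor-vigilance (PVT) lapse counts.
Because the cohort that motivated this design is not public, the package
ships a synthetic cohort generator that emulates the study conditions, and
every downstream stage is validated against it.

## Network construction

Edges with fewer than `fiber_threshold` streamlines (default 10) are
removed. The threshold is *inclusive*: an edge with exactly 10 streamlines
survives. This reading makes the threshold a minimum-evidence rule and
`t = 0` the keep-all-nonzero limit; the reproducibility sweep covers
t ∈ {0, 10, 50, 100} so the choice is visible rather than buried.
ROI-volume correction divides each weight by the mean volume of the two
connected regions, w′_ij = w_ij / ((v_i + v_j)/2); it is applied *after*
thresholding, because the threshold targets noise in raw streamline counts.
Input matrices are validated (square, nonnegative, symmetric within a
relative tolerance of 1e-6, zero diagonal); sub-tolerance asymmetries are
averaged out, larger ones rejected.

## Graph measures

All path-based measures convert weight to length by the reciprocal,
l_ij = 1/w_ij — the standard convention for streamline counts, under which
stronger connections are shorter. Shortest paths use Dijkstra's algorithm.

- strength Sp = (1/N) Σ_i s_i with s_i = Σ_j w_ij;
- global efficiency E_glob = (1/(N(N−1))) Σ_{i≠j} 1/d_ij with 1/∞ := 0;
- nodal efficiency E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij (its mean is E_glob);
- local efficiency E_loc = mean over i of E_glob of the subgraph induced by
  i's neighbors (i excluded, original weights kept; nodes with < 2
  neighbors contribute 0);
- characteristic path length Lp = mean d_ij over ordered pairs with a
  finite path. Unreachable pairs are excluded with a warning (or raise, by
  option): real study networks are connected, but degenerate synthetic
  inputs must behave explicitly;
- clustering uses the Onnela geometric-mean form,
  C_i = (1/(k_i(k_i−1))) Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, with ŵ = w/max(w)
  normalized by the per-subject network-wide maximum. It is bounded in
  [0, 1] and standard in weighted-connectome software. (The generic textbook
  definition does not pin down a weighted variant; this is a documented
  choice, cross-checked against networkx in the tests.)
- degree skewness is the bias-corrected sample skewness of binary degrees.

Small-world coefficients divide by matched random networks:
γ = Cp / ⟨Cp_rand⟩ and λ = Lp / ⟨Lp_rand⟩; γ > 1 with λ ≈ 1 is the
small-world signature.

## Null models

A matched random network preserves the source's exact binary degree
sequence by repeated double-edge swaps — edges (u,v), (x,y) are replaced by
(u,x), (v,y) when all four nodes are distinct and neither new edge exists —
and then randomly permutes the original edge weights over the rewired edge
set, preserving the weight multiset. "Matched" is thus read as: same size,
same degree sequence, same weight distribution; strength sequences are not
preserved (a deliberately weaker null that the weighted rich-club
coefficient is tested against). Default mixing is 10 successful swaps per
edge with a budget of 100 attempts per requested swap; a shortfall warns
and never breaks degree preservation. Ensemble member i draws from a
stream keyed by (seed, i), so members are reproducible regardless of
ensemble size. The swap kernel is numba-compiled; at N = 90 and ~550 edges
one null network costs about a millisecond.

## Rich club

Group backbone: for each node pair, a one-tailed sign test of "median
weight > 0" across the group's subjects. With zeros dropped and weights
nonnegative, every present observation is a positive sign, so the p-value
has the closed form p = 0.5^m where m is the number of subjects with the
edge present (p = 1 at m = 0). p-values are corrected across all N(N−1)/2
candidate pairs — Benjamini–Hochberg by default, Bonferroni by option (the
emulated design says only "corrected") — and edges with corrected p < 0.05
are kept.

Hubs are backbone nodes with degree ≥ mean + 1 sample SD. A regular
backbone (SD = 0) makes every node satisfy the rule; this degenerate case
warns and proceeds, taking the rule literally. Edges are classified rich
(hub–hub), feeder (hub–periphery) or local (periphery–periphery); class
strengths are sums of the corresponding weights and conserve the total
network weight exactly.

The weighted rich-club coefficient is
φ = Σ(hub–hub weights) / Σ(top-n weights network-wide), with n the number
of present hub–hub edges; the top-n selection includes hub–hub edges
themselves, and weight ties at the n-th position cannot change the sum.
φ_norm = φ / ⟨φ_rand⟩ over the matched ensemble (undefined members are
skipped and counted); φ_norm > 1 indicates hub–hub edges stronger than
degree sequence and weight distribution alone predict.

Hub sets are defined at the group level (on the backbone) but φ and class
strengths are computed per subject with the subject's own weights — the
group comparison and the behavioral correlation need subject-level values.

## Network-based statistic

Edge-wise pooled two-sample t statistics (resistant − vulnerable) are
computed over a tested-edge mask, by default the union of the two group
backbones (a minimum-presence-fraction mask is available). The primary
threshold defaults to the one-tailed edge-wise p = 0.01 converted to a t
value at the pooled df — the emulated design does not state its threshold,
so the value is exposed in the config and the sweep reports component
sizes across thresholds rather than asserting any particular edge count.
Connected components of the supra-threshold graph are measured in edges
(node counts are also reported). Group labels are permuted n_perm times
(default 5000, reduced in the shipped drivers); the maximum null component
size gives each observed component the family-wise-corrected
p = (1 + #{null ≥ observed}) / (1 + n_perm), which is never exactly zero.

## Group statistics

Two-sample t tests use the pooled-variance (Student) form — it reproduces
the df = 47 and the printed t values of the emulated study's summary
tables, which is also how the worked examples are validated; Welch is not
the default for that reason. χ² for 2×2 tables is Pearson's without
continuity correction (again matching the printed value). The rank-sum Z
uses midranks and the tie-corrected normal approximation (lapse counts are
heavily tied). Spearman's ρ is Pearson on midranks with the t-approximation
p-value (exact enumeration is unnecessary at n = 49). Nodal-efficiency
comparisons are corrected by Benjamini–Hochberg FDR across the N regions
of one analysis.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed at the
emulated design: 90 regions, 12 hubs, 25 vulnerable / 24 resistant
subjects, group lapse means 9.56 and 0.54.

Topology (one template per cohort): a planted-hub stochastic block model.
Hub–hub pairs connect with probability 0.8, hub–periphery with 0.3.
Periphery–periphery wiring uses a ring-locality kernel — pairs within a
small ring distance connect with probability 0.85, distant pairs with the
low probability that keeps the overall peripheral density at 0.1. The
locality kernel supplies the excess clustering (γ > 1) and the hub block
the shortcuts (λ ≈ 1) of small-world brain networks; a plain homogeneous
block model reproduces neither, because a degree-preserving null already
expects dense hub–hub connectivity from the hub degrees alone. Disconnected
samples are repaired by adding random edges between components, since all
path-based metrics assume finite distances.

Weights: each template edge gets a cohort-level baseline streamline count,
log-normal with log-mean 3.3 (median ≈ 27 streamlines) and log-sd 0.9;
hub–hub edges get a log-mean premium of 0.6, reflecting the large fiber
bundles that link hubs in real connectomes. Without this premium the
weight-permuting null reproduces the planted network's expected hub–hub
weight mass and φ_norm ≈ 1; a weighted rich club *is* the statement that
hub–hub edges carry disproportionate weight. Each subject multiplies the
baselines by log-normal noise (log-sd 0.3) and rounds to integers;
vulnerable subjects' hub–hub weights are attenuated by `delta_rich`
(default 0.6) before rounding — the planted group difference that the
pipeline must recover.

Lapse counts are negative binomial (overdispersed nonnegative counts, the
reason the emulated design used rank-sum tests), dispersion 2.0, with
log-mean = log(group baseline) + slope·z where z is the subject's hub–hub
summed weight standardized across the cohort and the slope is −0.5; weak
rich clubs therefore lapse more, and the population correlation between
rich-club strength and lapses is negative. Rested-wakefulness counts use a
common baseline of 0.5 lapses. Degenerate cohorts (zero strength variance)
set z = 0 and fall back to the group baselines.

Randomness: one seed per cohort; the template, baseline weights, subject
noise, lapse draws and node metadata each use streams keyed by
(seed, purpose[, subject index]), so subject s is bit-reproducible even
when group sizes change.

What the generator does *not* emulate: spatial embedding beyond the ring
(no true geometry or distance-dependent costs), tractography biases
(length/curvature-dependent streamline loss, crossing fibers), homotopic
symmetry, inter-subject topology variation (all subjects share one
template), or any physiology of sleep. Passing tests therefore show that
the pipeline recovers planted effects of this kind at these noise levels —
not that the biological effect exists, nor how the pipeline behaves under
tractography artifacts.

Two visible artifacts of the design are worth knowing. Onnela clustering
normalizes by the per-subject maximum weight; attenuating the (heavy)
hub–hub weights of vulnerable subjects lowers that maximum and *raises*
their normalized clustering, so the synthetic Cp group difference runs
opposite to the other metrics. And because hub sets are estimated per
group, a strong planted attenuation can shift the vulnerable group's hub
set slightly, propagating into the feeder/local class composition. Neither
affects the planted-effect checks, which concern rich-club strength,
ratios, the lapse correlation and the NBS component.

## Problem sizes in the shipped analyses

The configurable defaults follow the emulated design (1000 null networks,
5000 permutations). The numbered drivers and the acceptance script use
reduced sizes chosen so a full desk re-run stays interactive while keeping
Monte-Carlo error well below the effects examined: 100 matched nulls per
subject (ensemble SE of φ_norm ≈ 1–2%), 1000 NBS permutations (p
resolution 1e-3), 200-permutation NBS inside the calibration studies, and
50–100 seeds for the seed-replication checks.

## Known limitations

- The vulnerable/resistant cutoff of the emulated study is unknown; the
  pipeline offers a median split on the lapse increase and a fixed cutoff,
  asserting neither as the original rule.
- φ_norm magnitudes on synthetic subjects (≈ 1.4–2.3) exceed the ≈ 1.15
  reported for real data; the generator plants a clean rich club where
  real connectomes carry more competing structure.
- The sign-test backbone needs groups of ≥ ~10 subjects before any edge
  can survive FDR across 4005 pairs (p = 0.5^m floors at 0.5^n); tiny
  cohorts yield empty hub sets, which the pipeline reports as undefined
  rather than failing.
- Strength-preserving or spatially embedded nulls are not implemented; the
  weight-permuting null is the documented reading of "matched".
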