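# sdconnectome

Graph-theoretical analysis of weighted white-matter structural connectomes
for studying individual vulnerability to sleep deprivation.

People differ sharply in how much total sleep deprivation degrades their
sustained attention: after 24 h awake, "vulnerable" individuals accumulate
many psychomotor-vigilance-task (PVT) lapses while "resistant" individuals
barely change. This package implements the structural-connectome analysis
used to ask whether that difference is visible in the white-matter network:
per-subject N×N streamline-count matrices are thresholded, reduced to
global and nodal graph measures, tested for rich-club organization against
matched random networks, and screened for group-different subnetworks with
the network-based statistic (NBS). It is written for researchers who have
connectivity matrices (e.g. from deterministic tractography over an
AAL-style parcellation) and want a tested, reproducible pipeline — plus a
synthetic cohort generator so every stage can be exercised and calibrated
without access to subject data.

## What it computes

For each subject's weighted network (edge length l_ij = 1/w_ij):

- network strength Sp, global efficiency E_glob, local efficiency E_loc,
  characteristic path length Lp, Onnela clustering Cp, nodal efficiency
  E_nodal(i);
- small-world coefficients γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ against
  degree-preserving, weight-permuting random networks;
- rich-club measures on group sign-test backbones: hub set (degree ≥ mean
  + 1 SD), rich/feeder/local edge classes and strengths, the weighted
  rich-club coefficient φ = Σ(hub–hub weights)/Σ(top-n weights) and its
  null-normalized φ_norm;
- NBS: edge-wise pooled t statistics, supra-threshold connected
  components, and family-wise-corrected component p-values from a
  max-component permutation null;
- group statistics: pooled two-sample t (from samples or printed
  mean ± SD summaries), χ² for 2×2 tables, tie-corrected rank-sum Z,
  Benjamini–Hochberg FDR, Spearman correlation.

The synthetic generator plants a rich-club attenuation (hub–hub weights of
vulnerable subjects scaled by `delta_rich`) in two-group cohorts with
negative-binomial lapse counts linked to rich-club strength; see
`docs/methods.md` for the full model and its limits.

## Worked example

Run the numbered analyses on the default synthetic cohort (seed 1):

```
python analysis/01_simulate_cohort.py
python analysis/02_global_metrics.py
python analysis/03_rich_club.py
python analysis/04_nbs.py
python analysis/05_reproducibility_sweep.py
```

`02_global_metrics.py` prints the group comparison of the global measures:

```
measure  mean_resistant  mean_vulnerable         t            p
     Sp      688.746296       635.928000 13.588889 6.776168e-18
  Eglob       38.796862        35.503850 12.060140 5.426915e-16
   Eloc       36.256632        31.716639 15.803010 1.963371e-20
     Lp        0.031750         0.033975 -9.453660 1.901415e-12
     Cp        0.010649         0.015397 -4.031880 2.015063e-04
```

Vulnerable subjects have lower strength and efficiency and a longer path
length: weakening only the hub–hub edges degrades integration of the whole
network. `03_rich_club.py` localizes the effect — rich-club strength drops
(t = 18.2) while feeder strength is untouched (t = −0.45), both groups stay
rich-club organized (φ_norm > 1), and rich-club strength correlates
negatively with lapse counts (ρ = −0.78) — and `04_nbs.py` finds a single
significant component (58 edges over 16 nodes, p ≈ 0.001) covering 100% of
the planted hub–hub edges. Each script writes its table under `results/`.

A `sdconnectome` CLI wraps the same library for file-based use:
`sdconnectome synth --out DIR --seed 7`, then
`sdconnectome run --config analysis.yaml --out DIR` on a directory of
matrices with a manifest.

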