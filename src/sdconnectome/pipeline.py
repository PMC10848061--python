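"""End-to-end analysis orchestration and the reproducibility sweep.

The full analysis: load or generate a cohort -> fiber-count threshold
(-> optional ROI-volume correction) -> per-subject global and nodal
metrics (with small-world normalization when a null ensemble size is
configured) -> group t tests on global metrics and FDR-corrected nodal
efficiency tests -> network-based statistic -> per-group backbones, hubs
and per-subject rich-club measures -> group tests on class strengths and
ratios -> Spearman correlations of class strengths with lapse counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nbs as nbs_mod
from .cohort import Cohort, RESISTANT, VULNERABLE, read_cohort
from .io import apply_fiber_threshold, roi_volume_correction
from .metrics import global_metrics, nodal_efficiency
from .nulls import matched_ensemble
from .richclub import backbone_network, identify_hubs, rich_club_result
from .stats import fdr_bh, one_tailed_p, spearman, two_sample_t
from .synthetic import CohortConfig, generate

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ["strength", "e_global", "e_local", "path_length", "clustering"]


@dataclass
class AnalysisConfig:
    """Analysis settings mirroring the flat YAML config file."""

    mode: str = "synthetic"  # "synthetic" | "directory"
    input_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fiber_threshold: int = 10
    roi_correction: bool = False
    n_null: int = 1000  # per-subject null networks; 0 disables gamma/lambda/phi_norm
    nbs_edge_p: float = 0.01
    nbs_t_thresh: float | None = None
    n_perm: int = 5000
    alpha: float = 0.05
    correction: str = "fdr_bh"
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "directory" and not self.input_dir:
            raise ValueError("directory mode requires input_dir")
        if self.fiber_threshold < 0:
            raise ValueError("fiber_threshold must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_null < 0 or self.n_perm < 1:
            raise ValueError("n_null must be >= 0 and n_perm >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_kwargs = raw.pop("cohort", {}) or {}
        cfg = cls(**raw, cohort=CohortConfig(**cohort_kwargs))
        cfg.validate()
        return cfg

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # output location is not a scientific setting
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def classify_vulnerability(
    lapse_rw, lapse_sd, method: str = "median_split", cutoff: float | None = None
) -> np.ndarray:
    """Assign vulnerable/resistant labels from lapse counts.

    Default: median split on the lapse increase (lapse_sd - lapse_rw);
    subjects above the median are vulnerable. "fixed_cutoff" labels
    subjects with an increase > cutoff as vulnerable.
    """
    rw = np.asarray(lapse_rw, dtype=float)
    sd = np.asarray(lapse_sd, dtype=float)
    if rw.size == 0 or rw.shape != sd.shape or np.any(np.isnan(rw)) or np.any(np.isnan(sd)):
        raise ValueError("matching, complete lapse scores required")
    change = sd - rw
    if method == "median_split":
        med = np.median(change)
        if np.all(change == change[0]):
            raise ValueError("all lapse changes identical: no median split exists")
        vulnerable = change > med
    elif method == "fixed_cutoff":
        if cutoff is None:
            raise ValueError("fixed_cutoff method requires a cutoff")
        vulnerable = change > cutoff
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.where(vulnerable, VULNERABLE, RESISTANT).astype(object)


def _load_cohort(config: AnalysisConfig) -> Cohort:
    if config.mode == "synthetic":
        return generate(config.cohort)
    cohort = read_cohort(config.input_dir)
    if not set(np.unique(cohort.groups)) <= {VULNERABLE, RESISTANT}:
        cohort.groups = classify_vulnerability(cohort.lapse_rw, cohort.lapse_sd)
    return cohort


def _group_test_row(name: str, values: np.ndarray, cohort: Cohort) -> dict:
    res = two_sample_t(
        values[cohort.group_mask(RESISTANT)], values[cohort.group_mask(VULNERABLE)]
    )
    return {
        "measure": name,
        "mean_resistant": float(values[cohort.group_mask(RESISTANT)].mean()),
        "mean_vulnerable": float(values[cohort.group_mask(VULNERABLE)].mean()),
        "t": res.statistic,
        "df": res.df,
        "p": res.p_value,
        "p_one_tailed_resistant_gt": one_tailed_p(res, "greater"),
    }


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the report dict and writes outputs
    (JSON summary, TSV tables, log) when ``config.out_dir`` is set."""
    config.validate()
    cohort = _load_cohort(config)
    cohort = cohort.map_subjects(lambda c: apply_fiber_threshold(c, config.fiber_threshold))
    if config.roi_correction:
        cohort = cohort.map_subjects(roi_volume_correction)

    # group backbones and hub sets (group-level definition, applied per subject)
    backbones = {
        g: backbone_network(
            cohort.group_subjects(g), alpha=config.alpha, correction=config.correction, group=g
        )
        for g in (VULNERABLE, RESISTANT)
    }
    hubs = {g: identify_hubs(bb) for g, bb in backbones.items()}

    # per-subject metrics; one shared ensemble per subject serves both the
    # small-world normalization and phi_norm
    global_rows, nodal_rows, rc_rows = [], [], []
    for idx, (sid, conn) in enumerate(zip(cohort.subject_ids, cohort.subjects)):
        group = cohort.groups[idx]
        ensemble = None
        if config.n_null > 0:
            ensemble = matched_ensemble(
                conn, n=config.n_null, seed=int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % 2**31)
            )
        gm = global_metrics(conn, ensemble=ensemble)
        global_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "Sp": gm.strength,
                "Eglob": gm.e_global,
                "Eloc": gm.e_local,
                "Lp": gm.path_length,
                "Cp": gm.clustering,
                "gamma": gm.gamma,
                "lambda": gm.lambda_,
            }
        )
        nodal_rows.append(nodal_efficiency(conn))
        rc = rich_club_result(conn, hubs[group], ensemble=ensemble)
        rc_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "strength_rich": rc.strength_rich,
                "strength_feeder": rc.strength_feeder,
                "strength_local": rc.strength_local,
                "ratio_rich_feeder": rc.ratio_rich_feeder,
                "ratio_rich_local": rc.ratio_rich_local,
                "phi": rc.phi,
                "phi_norm": rc.phi_norm,
            }
        )
    global_df = pd.DataFrame(global_rows)
    rc_df = pd.DataFrame(rc_rows)
    nodal = np.stack(nodal_rows)  # (S, N)

    # group tests on global metrics
    metric_cols = {"strength": "Sp", "e_global": "Eglob", "e_local": "Eloc",
                   "path_length": "Lp", "clustering": "Cp"}
    global_tests = [
        _group_test_row(name, global_df[col].to_numpy(), cohort)
        for name, col in metric_cols.items()
    ]

    # nodal efficiency tests, FDR across regions
    nodal_tests = []
    res_mask = cohort.group_mask(RESISTANT)
    vul_mask = cohort.group_mask(VULNERABLE)
    for j in range(cohort.n_nodes):
        r = two_sample_t(nodal[res_mask, j], nodal[vul_mask, j])
        nodal_tests.append(
            {"region": cohort.subjects[0].node_labels[j], "t": r.statistic, "p": r.p_value}
        )
    nodal_df = pd.DataFrame(nodal_tests)
    reject, p_adj = fdr_bh(nodal_df["p"].to_numpy(), q=config.alpha)
    nodal_df["p_fdr"] = p_adj
    nodal_df["significant"] = reject

    # network-based statistic
    nbs_result = nbs_mod.nbs_permutation(
        cohort,
        t_thresh=config.nbs_t_thresh,
        edge_p=config.nbs_edge_p,
        n_perm=config.n_perm,
        seed=config.seed,
    )

    # group tests on rich-club class strengths and ratios
    rc_tests = []
    for col in ["strength_rich", "strength_feeder", "strength_local",
                "ratio_rich_feeder", "ratio_rich_local"]:
        vals = rc_df[col].to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            continue
        rc_tests.append(_group_test_row(col, vals, cohort))

    # Spearman of class strengths vs lapse counts, pooled over all subjects
    correlations = []
    if cohort.lapse_sd is not None:
        for col in ["strength_rich", "strength_feeder", "strength_local"]:
            try:
                r = spearman(rc_df[col].to_numpy(dtype=float), cohort.lapse_sd)
                rho, p = r.statistic, r.p_value
            except ValueError:  # degenerate (e.g. empty hub set -> constant 0)
                rho, p = float("nan"), float("nan")
            correlations.append({"measure": col, "rho": rho, "p": p})

    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
        "n_nodes": cohort.n_nodes,
        "hubs": {g: np.asarray(h).tolist() for g, h in hubs.items()},
        "global_tests": global_tests,
        "nodal_significant_regions": nodal_df.loc[nodal_df["significant"], "region"].tolist(),
        "rich_club_tests": rc_tests,
        "correlations": correlations,
        "nbs": {
            "primary_threshold": nbs_result.primary_threshold,
            "components": [
                {"n_edges": c.n_edges, "n_nodes": c.n_nodes, "p": float(p)}
                for c, p in zip(nbs_result.components, nbs_result.component_p)
            ],
        },
        "group_means": {
            g: {
                col: float(global_df.loc[global_df["group"] == g, col].mean())
                for col in ["Sp", "Eglob", "Eloc", "Lp", "Cp"]
            }
            for g in (VULNERABLE, RESISTANT)
        },
    }
    if config.n_null > 0:
        report["small_world"] = {
            g: {
                "gamma": float(global_df.loc[global_df["group"] == g, "gamma"].mean()),
                "lambda": float(global_df.loc[global_df["group"] == g, "lambda"].mean()),
                "phi_norm": float(rc_df.loc[rc_df["group"] == g, "phi_norm"].mean()),
            }
            for g in (VULNERABLE, RESISTANT)
        }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        global_df.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
        labels0 = cohort.subjects[0].node_labels
        nodal_values = pd.DataFrame(nodal, columns=labels0)
        nodal_values.insert(0, "subject_id", cohort.subject_ids)
        nodal_values.to_csv(out / "nodal_efficiency.tsv", sep="\t", index=False)
        nodal_df.to_csv(out / "nodal_efficiency_tests.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"group": g, "hub_index": int(i), "region": labels0[int(i)]}
                for g, hs in hubs.items()
                for i in hs
            ]
        ).to_csv(out / "hubs.tsv", sep="\t", index=False)
        rc_df.to_csv(out / "rich_club.tsv", sep="\t", index=False)
        pd.DataFrame(global_tests).to_csv(out / "global_tests.tsv", sep="\t", index=False)
        pd.DataFrame(rc_tests).to_csv(out / "rich_club_tests.tsv", sep="\t", index=False)
        if nbs_result.components:
            labels = cohort.subjects[0].node_labels
            comp_rows = [
                {
                    "component_id": ci,
                    "region_i": labels[i],
                    "region_j": labels[j],
                    "t": nbs_result.t_matrix[i, j],
                }
                for ci, comp in enumerate(nbs_result.components)
                for i, j in comp.edges
            ]
            pd.DataFrame(comp_rows).to_csv(out / "nbs_component_edges.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            fh.write(f"seed={config.seed}\nconfig_digest={config.digest()}\n")
    return report


def reproducibility_sweep(
    config: AnalysisConfig,
    thresholds: tuple[int, ...] = (0, 10, 50, 100),
    roi_options: tuple[bool, ...] = (False, True),
) -> pd.DataFrame:
    """Re-run the analysis across fiber thresholds and ROI correction.

    Small-world/rich-club normalization and output writing are disabled in
    the per-condition runs; the comparison table reports the direction and
    p-value of every global-metric group difference per condition.
    """
    rows = []
    for roi in roi_options:
        for t in thresholds:
            sub = AnalysisConfig(
                **{
                    **asdict(config),
                    "cohort": config.cohort,
                    "fiber_threshold": t,
                    "roi_correction": roi,
                    "n_null": 0,
                    "out_dir": None,
                }
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = run_analysis(sub)
            for row in report["global_tests"]:
                rows.append(
                    {
                        "fiber_threshold": t,
                        "roi_correction": roi,
                        "measure": row["measure"],
                        "t": row["t"],
                        "p": row["p"],
                        "direction": "resistant_gt" if row["t"] > 0 else "vulnerable_gt",
                    }
                )
    df = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "reproducibility_sweep.tsv", sep="\t", index=False)
    return df
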