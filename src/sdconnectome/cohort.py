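"""Cohort container: per-subject connectomes, group labels, behavioral scores.

Groups follow the study design: "vulnerable" subjects show a large increase in
psychomotor-vigilance-task (PVT) lapses after 24 h of total sleep deprivation,
"resistant" subjects a small one. `lapse_rw` is the lapse count at rested
wakefulness, `lapse_sd` after sleep deprivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Connectome, read_matrix, write_matrix, write_metadata

VULNERABLE = "vulnerable"
RESISTANT = "resistant"


class EmptyCohortError(ValueError):
    pass


@dataclass
class Cohort:
    subjects: list[Connectome]
    groups: np.ndarray  # array of str, VULNERABLE or RESISTANT
    subject_ids: list[str] = field(default_factory=list)
    lapse_rw: np.ndarray | None = None
    lapse_sd: np.ndarray | None = None
    template_hub_flags: np.ndarray | None = None  # generator ground truth, if any

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise EmptyCohortError("cohort has no subjects")
        self.groups = np.asarray(self.groups, dtype=object)
        if len(self.groups) != len(self.subjects):
            raise ValueError("one group label per subject required")
        n = self.subjects[0].n_nodes
        if any(s.n_nodes != n for s in self.subjects):
            raise ValueError("all subjects must share the same node count")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(len(self.subjects))]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].n_nodes

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups], dtype=bool)

    def group_subjects(self, group: str) -> list[Connectome]:
        return [s for s, g in zip(self.subjects, self.groups) if g == group]

    def weight_stack(self) -> np.ndarray:
        """(n_subjects, N, N) array of weight matrices."""
        return np.stack([s.weights for s in self.subjects])

    def map_subjects(self, fn) -> "Cohort":
        """Apply a Connectome -> Connectome transform to every subject."""
        return Cohort(
            subjects=[fn(s) for s in self.subjects],
            groups=self.groups.copy(),
            subject_ids=list(self.subject_ids),
            lapse_rw=None if self.lapse_rw is None else self.lapse_rw.copy(),
            lapse_sd=None if self.lapse_sd is None else self.lapse_sd.copy(),
            template_hub_flags=(
                None if self.template_hub_flags is None else self.template_hub_flags.copy()
            ),
        )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject matrices, a manifest TSV and node metadata.

    Manifest columns: subject_id, group, lapse_rw, lapse_sd, path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (sid, conn) in enumerate(zip(cohort.subject_ids, cohort.subjects)):
        rel = f"{sid}.txt"
        write_matrix(conn, out_dir / rel)
        rows.append(
            {
                "subject_id": sid,
                "group": cohort.groups[i],
                "lapse_rw": "" if cohort.lapse_rw is None else cohort.lapse_rw[i],
                "lapse_sd": "" if cohort.lapse_sd is None else cohort.lapse_sd[i],
                "path": rel,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    first = cohort.subjects[0]
    if first.node_coords is not None and first.node_volumes is not None:
        write_metadata(first, out_dir / "nodes.tsv")
    return manifest


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (manifest + matrices)."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    df = pd.read_csv(manifest, sep="\t")
    meta = directory / "nodes.tsv"
    meta_path = meta if meta.exists() else None
    subjects = []
    for rel in df["path"]:
        p = directory / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest refers to missing file {p}")
        subjects.append(read_matrix(p, metadata_path=meta_path))
    def _scores(col):
        if col not in df or df[col].isna().all():
            return None
        return df[col].to_numpy(dtype=float)
    return Cohort(
        subjects=subjects,
        groups=df["group"].to_numpy(dtype=object),
        subject_ids=df["subject_id"].astype(str).tolist(),
        lapse_rw=_scores("lapse_rw"),
        lapse_sd=_scores("lapse_sd"),
    )
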