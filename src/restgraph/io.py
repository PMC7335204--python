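"""Delimiter-separated I/O for every pipeline artifact.

All matrices and tables round-trip through tab-separated UTF-8 files with
header rows; per-subject inputs follow the layout the synthetic generator
writes (``sub-XXX_roi.tsv``, ``sub-XXX_motion.tsv``, ``sub-XXX_nuisance.tsv``
plus a cohort ``participants.tsv`` and JSON manifest).  An optional NIfTI
path extracts per-node average time series from a 4-D image given a label
image and a gray-matter probability map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CensorMask, MotionTrace, RoiTimeSeries
from .synthetic import CohortConfig, SyntheticSubject

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "read_subject",
    "write_censor_mask",
    "extract_roi_series",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
NUISANCE_COLUMNS = ["wm", "csf", "global"]


def write_matrix(path: str | Path, matrix: np.ndarray, labels: list[str]) -> None:
    """Square matrix as TSV with node labels on both axes."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_cohort(
    directory: str | Path,
    subjects: list[SyntheticSubject],
    manifest: pd.DataFrame,
    config: CohortConfig,
    node_labels: list[str] | None = None,
) -> Path:
    """Write per-subject ROI/motion/nuisance TSVs, participants.tsv and a
    JSON manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = subjects[0].roi_series.n_nodes
    labels = node_labels or [f"node{i:02d}" for i in range(n)]
    for subject in subjects:
        sid = subject.record.subject_id
        pd.DataFrame(subject.roi_series.data, columns=labels).to_csv(
            directory / f"{sid}_roi.tsv", sep="\t", index=False
        )
        pd.DataFrame(subject.motion.parameters, columns=MOTION_COLUMNS).to_csv(
            directory / f"{sid}_motion.tsv", sep="\t", index=False
        )
        pd.DataFrame(subject.nuisance, columns=NUISANCE_COLUMNS).to_csv(
            directory / f"{sid}_nuisance.tsv", sep="\t", index=False
        )
    manifest.to_csv(directory / "participants.tsv", sep="\t")
    meta = {
        "cohort": config.cohort,
        "tr": config.tr,
        "n_volumes": config.n_volumes,
        "analyze_volumes": config.analyze_volumes,
        "n_nodes": config.n_nodes,
        "seed": config.seed,
        "subjects": [s.record.subject_id for s in subjects],
        "node_labels": labels,
    }
    (directory / "manifest.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_subject(
    directory: str | Path, subject_id: str, tr: float
) -> tuple[RoiTimeSeries, MotionTrace, np.ndarray]:
    directory = Path(directory)
    roi = pd.read_csv(directory / f"{subject_id}_roi.tsv", sep="\t", float_precision="round_trip")
    motion = pd.read_csv(directory / f"{subject_id}_motion.tsv", sep="\t", float_precision="round_trip")
    nuisance = pd.read_csv(directory / f"{subject_id}_nuisance.tsv", sep="\t", float_precision="round_trip")
    ts = RoiTimeSeries(roi.to_numpy(dtype=float), tr, node_labels=list(roi.columns))
    mt = MotionTrace(
        motion[MOTION_COLUMNS[:3]].to_numpy(dtype=float),
        motion[MOTION_COLUMNS[3:]].to_numpy(dtype=float),
    )
    return ts, mt, nuisance[NUISANCE_COLUMNS].to_numpy(dtype=float)


def write_censor_mask(path: str | Path, mask: CensorMask) -> None:
    pd.DataFrame(
        {
            "volume": np.arange(mask.n_volumes),
            "censored": mask.censored.astype(int),
            "reason": ["+".join(r) if r else "none" for r in mask.reasons],
        }
    ).to_csv(path, sep="\t", index=False)


def extract_roi_series(
    image_4d: str | Path,
    atlas_labels: str | Path,
    gm_map: str | Path,
    tr: float,
    threshold: float = 0.3,
) -> RoiTimeSeries:
    """Average 4-D image intensities per atlas node over gray-matter voxels.

    A voxel contributes to a node when its atlas label equals the node id
    and its gray-matter probability exceeds ``threshold``.  Requires
    nibabel; the three images must share a voxel grid.
    """
    import nibabel as nib  # optional dependency, imported lazily

    img = nib.load(str(image_4d)).get_fdata()
    labels = nib.load(str(atlas_labels)).get_fdata()
    gm = nib.load(str(gm_map)).get_fdata()
    if labels.shape != img.shape[:3] or gm.shape != img.shape[:3]:
        raise ValueError("image, atlas and GM map must share a voxel grid")
    node_ids = np.unique(labels)
    node_ids = node_ids[node_ids > 0].astype(int)
    series = []
    names = []
    for nid in node_ids:
        sel = (labels == nid) & (gm > threshold)
        if not sel.any():
            raise ValueError(f"node {nid} has no voxels with GM > {threshold}")
        series.append(img[sel].mean(axis=0))
        names.append(f"node{nid}")
    return RoiTimeSeries(np.column_stack(series), tr, node_labels=names)
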