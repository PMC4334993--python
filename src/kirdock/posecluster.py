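"""Greedy pose clustering by ligand CA RMSD in the receptor frame."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dockengine import Pose, PoseList
from .errors import ParameterError, ShapeError

__all__ = ["PoseCluster", "ligand_rmsd", "greedy_cluster", "clusters_table"]


@dataclass
class PoseCluster:
    """One greedy cluster: member pose indices and the selected center."""

    members: list[int]
    center: int

    @property
    def member_count(self) -> int:
        return len(self.members)


def _posed_coords(pose: Pose, ligand_ca: np.ndarray,
                  centroid: np.ndarray) -> np.ndarray:
    return pose.transform(ligand_ca, centroid)


def ligand_rmsd(
    pose_a: Pose, pose_b: Pose,
    ligand_ca_coords: np.ndarray,
    ligand_centroid: np.ndarray | None = None,
) -> float:
    """CA RMSD between two placements of the same ligand, no re-fit.

    Both poses are applied in the shared receptor frame; the deviation is
    measured directly (the receptor is the reference frame).
    """
    ligand_ca_coords = np.asarray(ligand_ca_coords, float)
    if ligand_ca_coords.ndim != 2 or ligand_ca_coords.shape[1] != 3:
        raise ShapeError("ligand CA coordinates must be (n, 3)")
    centroid = (np.asarray(ligand_centroid, float)
                if ligand_centroid is not None
                else ligand_ca_coords.mean(axis=0))
    a = _posed_coords(pose_a, ligand_ca_coords, centroid)
    b = _posed_coords(pose_b, ligand_ca_coords, centroid)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def greedy_cluster(
    poselist: PoseList,
    ligand_ca_coords: np.ndarray,
    radius: float = 9.0,
    m: int = 1000,
) -> list[PoseCluster]:
    """Greedy neighborhood clustering of the top-``m`` poses.

    Repeatedly select the unassigned pose with the most unassigned
    neighbors within ``radius`` (CA RMSD) as a center and assign that
    neighborhood as one cluster.  Ties are broken by higher docking score,
    then lower pose index — both collapse to lowest index in a sorted pose
    list, making runs fully reproducible.
    """
    if len(poselist) == 0:
        raise ParameterError("cannot cluster an empty pose list")
    if radius <= 0:
        raise ParameterError("cluster radius must be positive")
    if m < 1:
        raise ParameterError("pose pool size must be >= 1")
    poses = poselist.poses[:m]
    ligand_ca_coords = np.asarray(ligand_ca_coords, float)
    centroid = np.asarray(poselist.ligand_centroid, float)
    if centroid.shape != (3,):
        centroid = ligand_ca_coords.mean(axis=0)

    placed = np.stack([_posed_coords(p, ligand_ca_coords, centroid)
                       for p in poses])                    # (m, n_ca, 3)
    n = len(poses)
    rmsd_matrix = np.empty((n, n))
    block = max(1, int(2e6 // max(1, n * placed.shape[1])))
    for start in range(0, n, block):
        stop = min(n, start + block)
        diffs = placed[start:stop, None, :, :] - placed[None, :, :, :]
        rmsd_matrix[start:stop] = np.sqrt(
            np.mean(np.sum(diffs ** 2, axis=-1), axis=-1))
    neighbor = rmsd_matrix <= radius

    scores = np.array([p.score_total for p in poses])
    unassigned = np.ones(n, dtype=bool)
    clusters: list[PoseCluster] = []
    while np.any(unassigned):
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts = np.where(unassigned, counts, -1)
        best_count = counts.max()
        tied = np.flatnonzero(counts == best_count)
        center = int(tied[np.lexsort((tied, -scores[tied]))[0]])
        members = np.flatnonzero(neighbor[center] & unassigned)
        clusters.append(PoseCluster(members=members.tolist(), center=center))
        unassigned[members] = False
    return clusters


def clusters_table(clusters: list[PoseCluster], path: str | Path | None = None) -> str:
    """TSV rendering: cluster id, size, center pose index, member indices."""
    lines = ["cluster\tsize\tcenter\tmembers"]
    for i, cluster in enumerate(clusters, start=1):
        members = ",".join(str(m) for m in cluster.members)
        lines.append(f"{i}\t{cluster.member_count}\t{cluster.center}\t{members}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
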