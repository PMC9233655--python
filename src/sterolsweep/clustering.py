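"""Threshold clustering of selected poses and cross-study consensus.

Poses are sorted into clusters by simple threshold clustering: after sorting
by ascending docking energy, each pose joins the first existing cluster whose
representative lies within the rmsd cutoff (default 4 A), otherwise it seeds a
new cluster. Seeding by best energy makes the representative rule ("the
energetically most favourable pose in a cluster represents the cluster")
consistent with membership, and guarantees every member is within the cutoff
of its representative.

The rmsd is computed over matched heavy atoms in the common receptor frame,
deliberately *without* superposition: superposing would erase the spatial
distinctness of separate sites.

Because the stochastic search of the docking engine does not always populate
every site in a single study, the sweep is replicated (five independent
studies) and only clusters containing a member from every required study are
accepted as consensus sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .docking_adapter import Pose

__all__ = [
    "PoseCluster",
    "ConsensusSet",
    "pose_rmsd",
    "threshold_cluster",
    "consensus_filter",
]


def pose_rmsd(p1: Pose, p2: Pose) -> float:
    """Heavy-atom rmsd between two poses of the same ligand, no superposition.

    Atoms are matched by name; a topology mismatch is an error.
    """
    names1 = [p1.atom_names[i] for i in p1.heavy_indices]
    names2 = [p2.atom_names[i] for i in p2.heavy_indices]
    if sorted(names1) != sorted(names2):
        raise ValueError("ligand topologies differ: heavy-atom names do not match")
    pos2 = {}
    for i, name in zip(p2.heavy_indices, names2):
        if name in pos2:
            raise ValueError(f"duplicate heavy-atom name {name!r}")
        pos2[name] = p2.coords[i]
    sq = 0.0
    seen = set()
    for i, name in zip(p1.heavy_indices, names1):
        if name in seen:
            raise ValueError(f"duplicate heavy-atom name {name!r}")
        seen.add(name)
        d = p1.coords[i] - pos2[name]
        sq += float(d @ d)
    return float(np.sqrt(sq / len(names1)))


@dataclass
class PoseCluster:
    """A threshold cluster with its energy-best representative."""

    members: list[Pose] = field(default_factory=list)

    @property
    def representative(self) -> Pose:
        return min(self.members, key=lambda p: (p.energy, p.key))

    @property
    def studies_present(self) -> frozenset[int]:
        return frozenset(p.study for p in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSet:
    """Partition of clusters into consensus-accepted and rejected."""

    accepted: list[PoseCluster]
    rejected: list[PoseCluster]
    n_studies_required: int


def threshold_cluster(poses: list[Pose], rmsd_cutoff: float = 4.0) -> list[PoseCluster]:
    """Leader-style simple threshold clustering with energy-sorted seeding."""
    clusters: list[PoseCluster] = []
    for pose in sorted(poses, key=lambda p: (p.energy, p.key)):
        for cluster in clusters:
            if pose_rmsd(pose, cluster.representative) < rmsd_cutoff:
                cluster.members.append(pose)
                break
        else:
            clusters.append(PoseCluster(members=[pose]))
    return clusters


def consensus_filter(
    clusters: list[PoseCluster], n_studies_required: int = 5
) -> ConsensusSet:
    """Keep only clusters containing a member from every required study."""
    if n_studies_required < 1:
        raise ValueError("n_studies_required must be at least 1")
    accepted, rejected = [], []
    for cluster in clusters:
        if len(cluster.studies_present) >= n_studies_required:
            accepted.append(cluster)
        else:
            rejected.append(cluster)
    return ConsensusSet(accepted, rejected, n_studies_required)
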