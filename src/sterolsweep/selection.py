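"""Evidence-based selection of sterol docking poses.

A docking sweep over a transmembrane surface produces many poses; only those
matching the geometry of sterol sites actually resolved on membrane proteins
are treated as candidate binding sites. The two criteria, derived from the
large set of crystallographically resolved interfacial cholesterol molecules
on GPCRs, are:

* at least 8 protein residues with a heavy atom within 4 A of a ligand heavy
  atom, and
* a tilt of less than 30 degrees between the long axis of the sterol fused-ring
  system and the bilayer normal.

For docking to water-exposed domains (the aqueous scoring regime) the criteria
are disabled and every pose passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .docking_adapter import Pose
from .structure_io import MembraneFrame, OrientedStructure

__all__ = [
    "SelectionCriteria",
    "PoseAssessment",
    "contact_residues",
    "tilt_angle",
    "assess_pose",
    "select_poses",
    "match_to_resolved",
    "summarize_energies",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds defining an interfacial sterol-binding-site pose."""

    min_contacts: int = 8
    contact_cutoff: float = 4.0  # Angstrom
    max_tilt: float = 30.0  # degrees
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")
        if not 0 < self.max_tilt <= 90:
            raise ValueError("max tilt must be in (0, 90] degrees")

    @classmethod
    def tm(cls) -> "SelectionCriteria":
        return cls()

    @classmethod
    def aqueous(cls) -> "SelectionCriteria":
        return cls(enabled=False)


@dataclass(frozen=True)
class PoseAssessment:
    """Geometric verdict for one pose."""

    pose: Pose
    contact_residues: frozenset[tuple[str, int, str]]
    tilt_deg: float
    half: str
    hydroxyl_depth: float | None
    passes: bool

    @property
    def n_contacts(self) -> int:
        return len(self.contact_residues)


def contact_residues(
    pose: Pose, structure: OrientedStructure, cutoff: float = 4.0
) -> set[tuple[str, int, str]]:
    """Residues with any protein heavy atom within ``cutoff`` of a ligand heavy atom.

    Hydrogens and the interface pseudo-atom layers are excluded on the protein
    side; a residue counts once no matter how many atom pairs qualify.
    """
    protein = structure.protein_heavy()
    if not protein:
        return set()
    tree = cKDTree(np.array([a.xyz for a in protein], dtype=float))
    ligand = pose.coords[pose.heavy_indices]
    hits = tree.query_ball_point(ligand, r=cutoff)
    residues: set[tuple[str, int, str]] = set()
    for idx_list in hits:
        for i in idx_list:
            a = protein[i]
            residues.add((a.chain, a.resseq, a.resname))
    return residues


def tilt_angle(pose: Pose, frame: MembraneFrame) -> float:
    """Acute angle (degrees) between the sterol ring long axis and the normal.

    The long axis is the first principal component of the centered fused-ring
    carbon coordinates; the acute angle is taken via the absolute cosine, so
    the result lies in [0, 90].
    """
    ring = pose.ring_coords
    if ring.shape[0] < 3:
        raise ValueError("ring axis undefined: fewer than 3 ring atoms")
    centered = ring - ring.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-8 or (len(s) > 1 and s[1] < 1e-8):
        raise ValueError("ring atoms degenerate or collinear: axis ill-defined")
    axis = vt[0]
    cos = abs(float(np.dot(axis, np.asarray(frame.normal))))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def assess_pose(
    pose: Pose,
    structure: OrientedStructure,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> PoseAssessment:
    """Populate geometry verdicts and the pass/fail flag for one pose."""
    frame = structure.frame
    if frame is None:
        raise ValueError("structure has no membrane frame")
    residues = contact_residues(pose, structure, criteria.contact_cutoff)
    tilt = tilt_angle(pose, frame)
    half = "cytosolic" if pose.ring_centroid[2] >= frame.midplane else "luminal"
    oh = pose.hydroxyl_index
    depth: float | None = None
    if oh is not None:
        z = pose.coords[oh][2]
        # signed distance from the nearest interface plane, positive away from
        # the slab midplane (i.e. positive = outside the hydrophobic core)
        d_upper, d_lower = z - frame.z_upper, frame.z_lower - z
        depth = d_upper if abs(d_upper) <= abs(d_lower) else d_lower
    if criteria.enabled:
        passes = len(residues) >= criteria.min_contacts and tilt < criteria.max_tilt
    else:
        passes = True
    return PoseAssessment(
        pose=pose,
        contact_residues=frozenset(residues),
        tilt_deg=tilt,
        half=half,
        hydroxyl_depth=depth,
        passes=passes,
    )


def select_poses(
    poses: list[Pose],
    structure: OrientedStructure,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[PoseAssessment]:
    """Assess every pose; the passing subset is the selection (a pure filter)."""
    return [assess_pose(p, structure, criteria) for p in poses]


def match_to_resolved(
    poses: list[Pose],
    resolved: list[np.ndarray],
    threshold: float = 3.0,
) -> dict:
    """Match docking poses to crystallographically resolved sterol ligands.

    A resolved ligand (given by its fused-ring atom coordinates) is *matched*
    when some pose's ring centroid lies within ``threshold`` of the resolved
    ring centroid. Returns per-ligand best distances and the matched fraction;
    the threshold is a reporting choice, so it is echoed in the result.
    """
    if not resolved:
        raise ValueError("no resolved ligands to match against")
    records = []
    for k, ring in enumerate(resolved):
        target = np.asarray(ring, dtype=float).reshape(-1, 3).mean(axis=0)
        if poses:
            dists = [float(np.linalg.norm(p.ring_centroid - target)) for p in poses]
            best = min(dists)
            best_pose = poses[int(np.argmin(dists))]
        else:
            best, best_pose = float("inf"), None
        records.append(
            {
                "resolved_index": k,
                "best_distance": best,
                "matched": best <= threshold,
                "best_pose": best_pose,
            }
        )
    fraction = sum(r["matched"] for r in records) / len(records)
    return {"threshold": threshold, "per_ligand": records, "matched_fraction": fraction}


def summarize_energies(poses: list[Pose]) -> tuple[float, float, bool]:
    """Mean and sample standard deviation (n-1) of pose docking energies.

    Returns ``(mean, sd, single)`` where ``single`` flags n = 1 (sd reported
    as 0 in that case).
    """
    if not poses:
        raise ValueError("no poses to summarize")
    e = np.array([p.energy for p in poses], dtype=float)
    if e.size == 1:
        return float(e[0]), 0.0, True
    return float(e.mean()), float(e.std(ddof=1)), False
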