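"""End-to-end orchestration: dedupe -> select -> cluster -> consensus."""

from __future__ import annotations

import numpy as np

from .clustering import ConsensusSet, PoseCluster, consensus_filter, threshold_cluster
from .docking_adapter import DockingCampaign, dedupe_overlap_poses
from .selection import SelectionCriteria, select_poses
from .structure_io import OrientedStructure

__all__ = ["run_pipeline", "evaluate_against_truth"]


def run_pipeline(
    structure: OrientedStructure,
    campaign: DockingCampaign,
    criteria: SelectionCriteria | None = None,
    rmsd_cutoff: float = 4.0,
    duplicate_rmsd: float = 1.0,
    n_studies_required: int | None = None,
    prestudy_cluster: bool = False,
) -> dict:
    """Run the full pose-processing chain on an assembled campaign.

    Stages: remove box-overlap duplicates within each (study, run); assess
    every pose against the selection criteria (enabled for the TM regime,
    disabled for aqueous); pool the passing poses across studies; threshold
    clustering; cross-study consensus. With ``prestudy_cluster`` the selected
    poses are first clustered within each study and only the per-study
    representatives are pooled.
    """
    if criteria is None:
        criteria = (
            SelectionCriteria.tm()
            if campaign.regime.selection_enabled
            else SelectionCriteria.aqueous()
        )
    if n_studies_required is None:
        n_studies_required = campaign.n_studies
    deduped = dedupe_overlap_poses(campaign.poses, duplicate_rmsd)
    assessments = select_poses(deduped, structure, criteria)
    selected = [a.pose for a in assessments if a.passes]
    pooled = selected
    if prestudy_cluster:
        pooled = []
        for study in sorted({p.study for p in selected}):
            within = [p for p in selected if p.study == study]
            pooled.extend(c.representative for c in threshold_cluster(within, rmsd_cutoff))
    clusters = threshold_cluster(pooled, rmsd_cutoff)
    consensus = consensus_filter(clusters, n_studies_required)
    return {
        "deduped": deduped,
        "assessments": assessments,
        "selected": selected,
        "clusters": clusters,
        "consensus": consensus,
    }


def evaluate_against_truth(
    consensus: ConsensusSet,
    truth: list[dict],
    match_radius: float = 2.5,
) -> dict:
    """Compare accepted consensus clusters with a planted-campaign truth table.

    A truth entry expected ``accept`` must be matched by exactly one accepted
    cluster whose representative ring centroid lies within ``match_radius`` of
    the planted center; every other truth entry must match none. ``agreement``
    is True only when the correspondence is a perfect bijection.
    """
    reps = [c.representative for c in consensus.accepted]
    matched_clusters: set[int] = set()
    per_site = []
    ok = True
    for entry in truth:
        center = np.asarray(entry["center"], dtype=float)
        hits = [
            k
            for k, rep in enumerate(reps)
            if float(np.linalg.norm(rep.ring_centroid - center)) <= match_radius
        ]
        expected_hit = entry["expected"] == "accept"
        site_ok = (len(hits) == 1) if expected_hit else (len(hits) == 0)
        matched_clusters.update(hits)
        ok = ok and site_ok
        per_site.append({**entry, "n_matching_clusters": len(hits), "ok": site_ok})
    # accepted clusters not explained by any planted site are false positives
    unexplained = [k for k in range(len(reps)) if k not in matched_clusters]
    ok = ok and not unexplained
    return {
        "agreement": ok,
        "per_site": per_site,
        "n_accepted": len(reps),
        "unexplained_clusters": unexplained,
    }


def cluster_table(clusters: list[PoseCluster]):
    """Summary rows (id, size, studies, representative energy) for reporting."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster": k,
                "size": len(c),
                "n_studies": len(c.studies_present),
                "representative_energy": c.representative.energy,
            }
            for k, c in enumerate(clusters)
        ]
    )
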