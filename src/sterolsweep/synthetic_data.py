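"""Synthetic fixtures: oriented bundles and docking campaigns with ground truth.

Every input the analysis pipeline consumes can be generated here at desk
scale, with no structure downloads and no docking engine:

* an idealized OPM-oriented transmembrane helical bundle flanked by two planar
  DUM marker layers (:func:`make_membrane_bundle`);
* rigid sterol poses built from a cholesterol-skeleton template (17 fused-ring
  carbons, a hydroxyl oxygen, an 8-atom iso-octyl tail proxy) at a requested
  position and ring tilt (:func:`make_sterol_pose`);
* replicate docking campaigns with *planted* consensus sites, sites present in
  only a subset of studies, box-overlap duplicates, and decoys that each
  violate exactly one selection criterion (:func:`make_campaign`), together
  with a truth table stating what the full pipeline must accept.

Pose energies for planted sites default to draws from Normal(-14.2, 1.1)
truncated to [-18, -10] kcal/mol, the distribution observed for accepted
transmembrane cholesterol poses; decoy energies are drawn shallower. All
randomness flows from a single seeded NumPy generator per campaign, so
identical seeds give byte-identical fixture files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .docking_adapter import Pose
from .selection import SelectionCriteria, assess_pose
from .structure_io import (
    Atom,
    MembraneFrame,
    OrientedStructure,
    build_search_boxes,
    convert_dummies_to_donor_layers,
    derive_membrane_frame,
    write_pdb,
)

__all__ = [
    "PlantedSite",
    "CampaignBlueprint",
    "make_membrane_bundle",
    "make_sterol_pose",
    "default_blueprint",
    "make_campaign",
    "write_fixture_set",
    "poses_to_pdbqt",
    "TABLE1_SITES",
]

#: printed molar docking energies for the three interfacial sites (kcal/mol)
TABLE1_SITES = [
    ("scap_insig_dimer", -16.8),
    ("insig_monomer", -14.0),
    ("scap_monomer", -12.5),
]


def _build_sterol_template() -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Rigid cholesterol-skeleton template with ring PCA axis exactly +z.

    Two parallel, slightly puckered strands of ring carbons approximate the
    fused tetracyclic nucleus; the hydroxyl oxygen caps the -z end and an
    8-atom tail proxy extends past +z. Coordinates are rotated so the first
    principal component of the ring carbons is exactly the +z axis and the
    ring centroid is the origin.
    """
    names: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    k = 1
    for i in range(9):  # strand A
        names.append(f"C{k}")
        elements.append("C")
        coords.append([-0.75, 0.25 * (-1) ** i, 1.2 * i])
        k += 1
    for i in range(8):  # strand B
        names.append(f"C{k}")
        elements.append("C")
        coords.append([0.75, -0.25 * (-1) ** i, 0.6 + 1.2 * i])
        k += 1
    names.append("O1")
    elements.append("O")
    coords.append([0.0, 0.0, -1.4])
    for i in range(8):  # iso-octyl tail proxy
        names.append(f"C{k}")
        elements.append("C")
        coords.append([0.35 * (-1) ** i, 0.0, 10.2 + 1.25 * i])
        k += 1
    xyz = np.array(coords, dtype=float)
    ring = xyz[:17]
    centered = ring - ring.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
        xyz = xyz @ rot.T
    xyz -= xyz[:17].mean(axis=0)
    return tuple(names), tuple(elements), xyz


STEROL_ATOM_NAMES, STEROL_ELEMENTS, STEROL_TEMPLATE = _build_sterol_template()


def _rotation(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    t, a = math.radians(tilt_deg), math.radians(azimuth_deg)
    ry = np.array(
        [[math.cos(t), 0, math.sin(t)], [0, 1, 0], [-math.sin(t), 0, math.cos(t)]]
    )
    rz = np.array(
        [[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]]
    )
    return rz @ ry


def make_sterol_pose(
    center,
    tilt_deg: float,
    azimuth_deg: float = 0.0,
    energy: float = -14.2,
    study: int = 1,
    run: int = 1,
    box: int = 1,
    model: int = 1,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    ligand_name: str = "cholesterol",
) -> Pose:
    """Place the rigid sterol template at ``center`` with the requested tilt.

    ``tilt_deg`` is the angle between the ring long axis and +z before jitter;
    ``azimuth_deg`` rotates the tilted template about +z. Gaussian coordinate
    jitter of standard deviation ``jitter_sd`` (A, per axis) is applied last.
    """
    if not 0.0 <= tilt_deg <= 90.0:
        raise ValueError("tilt must be in [0, 90] degrees")
    coords = STEROL_TEMPLATE @ _rotation(tilt_deg, azimuth_deg).T
    coords = coords + np.asarray(center, dtype=float)
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
    return Pose(
        ligand_name=ligand_name,
        atom_names=STEROL_ATOM_NAMES,
        elements=STEROL_ELEMENTS,
        coords=coords,
        energy=energy,
        study=study,
        run=run,
        box=box,
        model=model,
    )


def make_membrane_bundle(
    n_helices: int = 8,
    radius: float = 12.0,
    thickness: float = 28.4,
    seed: int = 0,
    dum_grid_step: float = 5.0,
    dum_grid_margin: float = 8.0,
) -> OrientedStructure:
    """Idealized poly-alanine TM helical bundle between two DUM marker layers.

    Backbone-only helices (N, CA, C, O; 1.5 A rise and 100 deg twist per
    residue) stand on a circle of the given radius, leaving surface hollows
    between adjacent helices where sterol poses can be planted. Two square
    lateral grids of DUM dummy atoms at z = +-thickness/2 mark the interfaces.
    """
    if n_helices < 3:
        raise ValueError("need at least 3 helices")
    if thickness <= 0 or radius <= 0:
        raise ValueError("degenerate geometry: radius and thickness must be positive")
    del seed  # geometry is deterministic; kept for interface uniformity
    atoms: list[Atom] = []
    serial = 0
    n_res = int(math.ceil((thickness + 3.0) / 1.5))
    z0 = -0.75 * (n_res - 1)  # center the helix span on the midplane
    backbone = [("N", "N", 2.0, -30.0, -0.6), ("CA", "C", 2.3, 0.0, 0.0),
                ("C", "C", 2.0, 25.0, 0.55), ("O", "O", 2.6, 40.0, 0.7)]
    for h in range(n_helices):
        chain = chr(ord("A") + h)
        theta0 = 2.0 * math.pi * h / n_helices
        cx, cy = radius * math.cos(theta0), radius * math.sin(theta0)
        for i in range(n_res):
            for name, element, r_h, dphi, dz in backbone:
                phi = math.radians(100.0 * i + dphi) + theta0
                serial += 1
                atoms.append(
                    Atom(
                        serial,
                        name,
                        element,
                        "ALA",
                        i + 1,
                        chain,
                        (
                            cx + r_h * math.cos(phi),
                            cy + r_h * math.sin(phi),
                            z0 + 1.5 * i + dz,
                        ),
                        het=False,
                    )
                )
    half_extent = radius + dum_grid_margin
    ticks = np.arange(-half_extent, half_extent + 1e-9, dum_grid_step)
    resseq = 0
    dummy_indices: list[int] = []
    for z in (thickness / 2.0, -thickness / 2.0):
        for x in ticks:
            for y in ticks:
                serial += 1
                resseq += 1
                dummy_indices.append(len(atoms))
                atoms.append(
                    Atom(serial, "DUM", "N", "DUM", resseq, "Z",
                         (float(x), float(y), float(z)), het=True)
                )
    structure = OrientedStructure(atoms, dummy_indices, [])
    structure.frame = derive_membrane_frame(structure)
    return structure


@dataclass(frozen=True)
class PlantedSite:
    """A ground-truth sterol site planted into a synthetic campaign."""

    site_id: str
    center: tuple[float, float, float]
    tilt_deg: float
    energy: float
    studies: frozenset[int]


@dataclass
class CampaignBlueprint:
    """Recipe for a replicate docking campaign with known ground truth."""

    planted_sites: list[PlantedSite]
    n_decoys_tilt: int = 10
    n_decoys_contact: int = 6
    n_overlap_duplicates: int = 3
    jitter_sd: float = 0.15
    seed: int = 0
    n_studies: int = 5
    n_runs: int = 5
    rmsd_cutoff: float = 4.0
    decoy_tilt_deg: float = 60.0
    decoy_contact_offset: float = 5.5

    def __post_init__(self) -> None:
        centers = [np.asarray(s.center) for s in self.planted_sites]
        min_sep = 2.0 * self.rmsd_cutoff
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < min_sep:
                    raise ValueError(
                        f"planted sites {i} and {j} closer than {min_sep} A"
                    )


def _groove_angles(n_helices: int) -> list[float]:
    """Azimuths (deg) of the surface hollows between adjacent helices."""
    step = 360.0 / n_helices
    return [step * (k + 0.5) for k in range(n_helices)]


def default_blueprint(
    structure: OrientedStructure,
    seed: int = 0,
    n_decoys_tilt: int = 10,
    n_decoys_contact: int = 6,
    n_overlap_duplicates: int = 3,
    n_helices: int = 8,
    radius: float = 12.0,
) -> CampaignBlueprint:
    """Standard truth layout: 2 all-study sites, 1 four-study site, decoys.

    Site centers sit in surface hollows of the bundle; one all-study site lies
    in the lateral overlap band of the two search boxes so that box-overlap
    duplicates occur; the four-study site is on the luminal half.
    """
    frame = structure.frame or derive_membrane_frame(structure)
    rng = np.random.default_rng(seed)
    grooves = _groove_angles(n_helices)
    zc = frame.midplane + frame.thickness / 4.0  # cytosolic half
    zl = frame.midplane - frame.thickness / 4.0  # luminal half

    def groove_center(angle_deg: float, z: float) -> tuple[float, float, float]:
        a = math.radians(angle_deg)
        return (radius * math.cos(a), radius * math.sin(a), z)

    energies = np.clip(rng.normal(-14.2, 1.1, size=3), -18.0, -10.0)
    # the overlap site sits in the groove nearest the lateral box-overlap
    # band (|x| below ~an eighth of the bundle extent), nudged so its center
    # x lies inside the band while staying between the same two helices
    overlap_angle = math.degrees(math.acos(3.8 / radius))
    sites = [
        PlantedSite("site_overlap", groove_center(overlap_angle, zc),
                    5.0, float(energies[0]), frozenset({1, 2, 3, 4, 5})),
        PlantedSite("site_all", groove_center(grooves[4], zc),
                    5.0, float(energies[1]), frozenset({1, 2, 3, 4, 5})),
        PlantedSite("site_partial", groove_center(grooves[6], zl),
                    5.0, float(energies[2]), frozenset({1, 2, 3, 4})),
    ]
    return CampaignBlueprint(
        planted_sites=sites,
        n_decoys_tilt=n_decoys_tilt,
        n_decoys_contact=n_decoys_contact,
        n_overlap_duplicates=n_overlap_duplicates,
        seed=seed,
    )


def _half_of(z: float, frame: MembraneFrame) -> str:
    return "cytosolic" if z >= frame.midplane else "luminal"


def _box_ids_for(center, boxes_by_half, frame) -> list[int]:
    """Ids (1..4) of the search boxes whose lateral extent contains ``center``."""
    half = _half_of(center[2], frame)
    base = 0 if half == "cytosolic" else 2
    ids = []
    for k, box in enumerate(boxes_by_half[half]):
        c, s = box.center, box.size
        if (
            abs(center[0] - c[0]) <= s[0] / 2
            and abs(center[1] - c[1]) <= s[1] / 2
        ):
            ids.append(base + k + 1)
    return ids or [base + 1]


def make_campaign(
    structure: OrientedStructure,
    blueprint: CampaignBlueprint,
) -> tuple[dict[tuple[int, int, int], str], list[dict]]:
    """Generate PDBQT pose files and the matching truth table.

    Returns ``(files, truth)`` where ``files`` maps (study, run, box) to
    multi-MODEL PDBQT text (box ids 1-2 cytosolic, 3-4 luminal) and ``truth``
    lists, per planted site and decoy group, which studies contain it and
    whether the full pipeline must accept it (accept iff it passes the
    selection criteria and appears in all required studies).

    The generator verifies its own ground truth with the selection module:
    each planted pose must pass both criteria, and each decoy must fail
    exactly the intended one. A planted site outside the membrane slab is an
    error.
    """
    frame = structure.frame or derive_membrane_frame(structure)
    prepared = (
        convert_dummies_to_donor_layers(structure)
        if structure.dummy_indices
        else structure
    )
    boxes_by_half = {
        "cytosolic": build_search_boxes(structure, "cytosolic"),
        "luminal": build_search_boxes(structure, "luminal"),
    }
    rng = np.random.default_rng(blueprint.seed)
    criteria = SelectionCriteria.tm()
    poses_by_cell: dict[tuple[int, int, int], list[Pose]] = {}
    truth: list[dict] = []

    def emit(pose_kwargs, cell) -> Pose:
        study, run, box = cell
        bucket = poses_by_cell.setdefault(cell, [])
        pose = make_sterol_pose(
            study=study, run=run, box=box, model=len(bucket) + 1,
            jitter_sd=blueprint.jitter_sd, rng=rng, **pose_kwargs,
        )
        bucket.append(pose)
        return pose

    overlap_budget = blueprint.n_overlap_duplicates
    for site in blueprint.planted_sites:
        z = site.center[2]
        if not frame.z_lower <= z <= frame.z_upper:
            raise ValueError(f"planted site {site.site_id} outside the membrane slab")
        azimuth = float(rng.uniform(0.0, 360.0))
        box_ids = _box_ids_for(site.center, boxes_by_half, frame)
        for study in sorted(site.studies):
            run = int(rng.integers(1, blueprint.n_runs + 1))
            kwargs = dict(
                center=site.center, tilt_deg=site.tilt_deg,
                azimuth_deg=azimuth, energy=site.energy + float(rng.normal(0, 0.1)),
            )
            pose = emit(kwargs, (study, run, box_ids[0]))
            verdict = assess_pose(pose, prepared, criteria)
            if not verdict.passes:
                raise ValueError(
                    f"planted site {site.site_id} fails selection "
                    f"(contacts={verdict.n_contacts}, tilt={verdict.tilt_deg:.1f})"
                )
            if len(box_ids) > 1 and overlap_budget > 0:
                overlap_budget -= 1
                dup_kwargs = dict(kwargs, energy=kwargs["energy"] + 0.05)
                emit(dup_kwargs, (study, run, box_ids[1]))
        truth.append(
            {
                "site_id": site.site_id,
                "center": list(site.center),
                "studies": sorted(site.studies),
                "kind": "planted",
                "expected": (
                    "accept"
                    if len(site.studies) >= blueprint.n_studies
                    else "reject_consensus"
                ),
            }
        )
    if overlap_budget > 0:
        raise ValueError(
            "not enough planted-site emissions in the box-overlap region to "
            f"produce {blueprint.n_overlap_duplicates} duplicates"
        )

    grooves = _groove_angles(8)
    planted_xy = [np.asarray(s.center[:2]) for s in blueprint.planted_sites]
    site_radius = 12.0
    decoy_specs: list[tuple[str, tuple[float, float, float], float]] = []
    zs = [frame.midplane + frame.thickness / 4.0, frame.midplane - frame.thickness / 4.0]
    k = 0
    while len(decoy_specs) < blueprint.n_decoys_tilt:
        a = math.radians(grooves[k % len(grooves)])
        z = zs[(k // len(grooves)) % 2] + 0.8 * (k // (2 * len(grooves)))
        center = (site_radius * math.cos(a), site_radius * math.sin(a), z)
        k += 1
        if any(np.linalg.norm(np.asarray(center[:2]) - xy) < 8.0 for xy in planted_xy):
            continue
        decoy_specs.append(("tilt", center, blueprint.decoy_tilt_deg))
    k = 0
    far = site_radius + blueprint.decoy_contact_offset
    while len(decoy_specs) < blueprint.n_decoys_tilt + blueprint.n_decoys_contact:
        a = math.radians(grooves[k % len(grooves)] + 10.0)
        z = zs[(k // len(grooves)) % 2]
        center = (far * math.cos(a), far * math.sin(a), z)
        k += 1
        decoy_specs.append(("contact", center, 5.0))

    for d, (kind, center, tilt) in enumerate(decoy_specs):
        study = int(rng.integers(1, blueprint.n_studies + 1))
        run = int(rng.integers(1, blueprint.n_runs + 1))
        box_ids = _box_ids_for(center, boxes_by_half, frame)
        energy = float(rng.uniform(-9.8, -8.5))
        if kind == "tilt":
            # the ring must stay well-contacted while tilted: scan azimuths
            # for an orientation that hugs the bundle surface
            best_azimuth, best_contacts = 0.0, -1
            for a in np.arange(0.0, 360.0, 15.0):
                probe = make_sterol_pose(center, tilt, float(a))
                n = assess_pose(probe, prepared, criteria).n_contacts
                if n > best_contacts:
                    best_azimuth, best_contacts = float(a), n
            if best_contacts < criteria.min_contacts + 2:
                raise ValueError(
                    f"tilt decoy {d}: no azimuth keeps >= "
                    f"{criteria.min_contacts + 2} contacts at tilt {tilt}"
                )
            azimuth = best_azimuth
        else:
            azimuth = float(rng.uniform(0, 360))
        pose = emit(
            dict(center=center, tilt_deg=tilt, azimuth_deg=azimuth, energy=energy),
            (study, run, box_ids[0]),
        )
        verdict = assess_pose(pose, prepared, criteria)
        tilt_ok = verdict.tilt_deg < criteria.max_tilt
        contacts_ok = verdict.n_contacts >= criteria.min_contacts
        if kind == "tilt" and (tilt_ok or not contacts_ok):
            raise ValueError(
                f"tilt decoy {d} does not fail exactly the tilt criterion "
                f"(contacts={verdict.n_contacts}, tilt={verdict.tilt_deg:.1f})"
            )
        if kind == "contact" and (contacts_ok or not tilt_ok):
            raise ValueError(
                f"contact decoy {d} does not fail exactly the contact criterion "
                f"(contacts={verdict.n_contacts}, tilt={verdict.tilt_deg:.1f})"
            )
        truth.append(
            {
                "site_id": f"decoy_{kind}_{d}",
                "center": list(center),
                "studies": [study],
                "kind": f"decoy_{kind}",
                "expected": "reject_filter",
            }
        )

    files = {
        cell: poses_to_pdbqt(poses) for cell, poses in sorted(poses_by_cell.items())
    }
    return files, truth


def poses_to_pdbqt(poses: list[Pose]) -> str:
    """Serialize poses as a multi-MODEL PDBQT-dialect text with energy remarks."""
    lines: list[str] = []
    for m, pose in enumerate(poses, start=1):
        lines.append(f"MODEL {m}")
        lines.append(
            f"REMARK VINA RESULT:    {pose.energy:8.3f}      0.000      0.000"
        )
        for i, (name, element) in enumerate(zip(pose.atom_names, pose.elements)):
            x, y, z = pose.coords[i]
            nm = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {i + 1:5d} {nm:<4s} CLR L   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}    "
                f"{0.0:+6.3f} {element:<2s}"
            )
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


def write_fixture_set(outdir, seed: int = 17) -> dict:
    """Write the canonical small fixture suite and a checksum manifest.

    Contents: the oriented bundle PDB, the campaign PDBQT files, the truth
    table JSON, and a CSV of the printed molar docking energies for the three
    interfacial sites. Regeneration with the same seed gives identical
    checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = make_membrane_bundle(seed=seed)
    blueprint = default_blueprint(structure, seed=seed)
    files, truth = make_campaign(structure, blueprint)
    written: dict[str, str] = {}

    def write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written[name] = hashlib.sha256(text.encode()).hexdigest()

    write("bundle.pdb", write_pdb(structure))
    for (study, run, box), text in files.items():
        write(f"poses_s{study}_r{run}_b{box}.pdbqt", text)
    write("truth.json", json.dumps(truth, indent=2))
    write(
        "table1_docking_energies.csv",
        "site,dG_dock_molar\n"
        + "\n".join(f"{name},{dg}" for name, dg in TABLE1_SITES)
        + "\n",
    )
    manifest = {"seed": seed, "files": written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
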