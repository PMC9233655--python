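"""Reading and preparing OPM-oriented membrane-protein structures.

Structures from the Orientations of Proteins in Membranes (OPM) database come
pre-rotated so that the membrane normal is the +z axis, with two planar layers
of ``DUM`` dummy atoms marking the polar-hydrophobic interfaces of the bilayer.
This module derives the membrane frame from those layers, converts the dummies
into hydrogen-bond-donor (NH3) pseudo-atom layers for membrane-aware docking,
strips bound heteroligands, and builds the two overlapping search boxes per
membrane half used by the docking sweep.

Coordinates are in Angstrom throughout; the cytosolic interface is the +z one
by the OPM convention adopted here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "MembraneFrame",
    "OrientedStructure",
    "SearchBox",
    "read_opm_pdb",
    "derive_membrane_frame",
    "convert_dummies_to_donor_layers",
    "strip_heteroligands",
    "build_search_boxes",
    "write_pdb",
    "boxes_to_json",
]

DUMMY_RESNAME = "DUM"
PSEUDO_RESNAME = "NH3"
#: z half-width of the tolerance band around each interface plane (Angstrom)
LAYER_TOLERANCE = 1.5
#: minimum gap between the two dummy layers for a well-defined slab (Angstrom)
MIN_LAYER_GAP = 5.0
N_H_BOND_LENGTH = 1.01
#: angle between an N-H bond and the umbrella axis of an NH3 group (degrees)
UMBRELLA_HALF_ANGLE = 70.53


@dataclass(frozen=True)
class Atom:
    """One atom record from a PDB file (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    resname: str
    resseq: int
    chain: str
    xyz: tuple[float, float, float]
    het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane slab defined by the two OPM interface planes.

    The normal is +z by the OPM convention; ``z_upper`` is the cytosolic-side
    interface and ``z_lower`` the luminal-side one for this system.
    """

    z_upper: float
    z_lower: float
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not self.z_upper > self.z_lower:
            raise ValueError("z_upper must exceed z_lower")
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")

    @property
    def thickness(self) -> float:
        return self.z_upper - self.z_lower

    @property
    def midplane(self) -> float:
        return 0.5 * (self.z_upper + self.z_lower)


@dataclass
class OrientedStructure:
    """Protein atoms plus membrane-interface marker/pseudo-atom layers."""

    atoms: list[Atom]
    dummy_indices: list[int] = field(default_factory=list)
    pseudo_indices: list[int] = field(default_factory=list)
    frame: MembraneFrame | None = None

    def coords(self, indices=None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)

    def protein_atoms(self) -> list[Atom]:
        """ATOM-record atoms (the polymer); never dummies or pseudo-layers."""
        return [a for a in self.atoms if not a.het]

    def protein_heavy(self) -> list[Atom]:
        return [a for a in self.protein_atoms() if not a.is_hydrogen]

    def het_residues(self) -> list[tuple[str, int, str]]:
        """Distinct HETATM residues other than markers and pseudo-layers."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            if a.het and a.resname not in (DUMMY_RESNAME, PSEUDO_RESNAME):
                seen.setdefault((a.chain, a.resseq, a.resname), None)
        return list(seen)


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned docking search box (center and edge lengths in Angstrom)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    half: str
    index: int

    def __post_init__(self) -> None:
        if min(self.size) <= 0:
            raise ValueError("box sizes must be positive")
        if self.half not in ("cytosolic", "luminal"):
            raise ValueError(f"unknown membrane half {self.half!r}")

    def contains(self, xyz) -> bool:
        c = np.asarray(self.center)
        s = np.asarray(self.size)
        return bool(np.all(np.abs(np.asarray(xyz) - c) <= s / 2.0 + 1e-9))

    def intersection_volume(self, other: "SearchBox") -> float:
        vol = 1.0
        for d in range(3):
            lo = max(self.center[d] - self.size[d] / 2, other.center[d] - other.size[d] / 2)
            hi = min(self.center[d] + self.size[d] / 2, other.center[d] + other.size[d] / 2)
            if hi <= lo:
                return 0.0
            vol *= hi - lo
        return vol


def read_opm_pdb(text: str) -> OrientedStructure:
    """Parse an OPM-dialect PDB string into an :class:`OrientedStructure`.

    Raises
    ------
    ValueError
        If no ``DUM`` marker atoms are present ("not an OPM-oriented
        structure"), or the markers do not form two separable planes.
    """
    st = gemmi.read_pdb_string(text)
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=at.element.name,
                            resname=res.name,
                            resseq=res.seqid.num,
                            chain=chain.name,
                            xyz=(at.pos.x, at.pos.y, at.pos.z),
                            het=het,
                        )
                    )
        break  # single-model files; ignore any further models
    if not any(not a.het for a in atoms):
        raise ValueError("no protein ATOM records found")
    coords = np.array([a.xyz for a in atoms]) if atoms else np.empty((0, 3))
    if atoms and not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates in PDB input")
    dummy_indices = [i for i, a in enumerate(atoms) if a.resname == DUMMY_RESNAME]
    pseudo_indices = [i for i, a in enumerate(atoms) if a.resname == PSEUDO_RESNAME]
    structure = OrientedStructure(atoms, dummy_indices, pseudo_indices)
    if not dummy_indices and not pseudo_indices:
        raise ValueError("not an OPM-oriented structure: no DUM marker atoms")
    structure.frame = derive_membrane_frame(structure)
    return structure


def _split_layers(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2-means-on-z split of marker atoms into the two interface layers."""
    if z.size < 2:
        raise ValueError("cannot define slab: need markers in two planes")
    order = np.argsort(z)
    zs = z[order]
    gaps = np.diff(zs)
    k = int(np.argmax(gaps))
    if gaps[k] <= MIN_LAYER_GAP:
        raise ValueError(
            "degenerate layers: marker z values do not separate into two "
            f"planes with gap > {MIN_LAYER_GAP} A"
        )
    lower, upper = zs[: k + 1], zs[k + 1 :]
    for layer in (lower, upper):
        if np.ptp(layer) > 2 * LAYER_TOLERANCE:
            raise ValueError("degenerate layers: marker layer is not planar")
    return lower, upper


def derive_membrane_frame(structure: OrientedStructure) -> MembraneFrame:
    """Derive the membrane frame from the marker (or pseudo) layer z values."""
    idx = structure.dummy_indices or structure.pseudo_indices
    if not idx:
        raise ValueError("cannot define slab: structure has no interface markers")
    if structure.pseudo_indices and not structure.dummy_indices:
        # use only the nitrogen positions: they sit exactly on the planes
        idx = [i for i in idx if structure.atoms[i].element.upper() == "N"] or idx
    z = structure.coords(idx)[:, 2]
    lower, upper = _split_layers(z)
    return MembraneFrame(z_upper=float(np.mean(upper)), z_lower=float(np.mean(lower)))


def convert_dummies_to_donor_layers(structure: OrientedStructure) -> OrientedStructure:
    """Replace each DUM marker with an NH3 hydrogen-bond-donor pseudo-atom group.

    The nitrogen sits at the exact former marker coordinate; the three
    hydrogens form a tetrahedral umbrella whose axis points along the membrane
    normal away from the slab midplane, keeping the donors at the interface.
    """
    if not structure.dummy_indices:
        raise ValueError("no dummy atoms: structure already converted or not OPM")
    frame = structure.frame or derive_membrane_frame(structure)
    dummy_set = set(structure.dummy_indices)
    atoms: list[Atom] = [a for i, a in enumerate(structure.atoms) if i not in dummy_set]
    pseudo_start = len(atoms)
    serial = max((a.serial for a in atoms), default=0)
    resseq = max((a.resseq for a in atoms), default=0)
    sin_u = math.sin(math.radians(UMBRELLA_HALF_ANGLE))
    cos_u = math.cos(math.radians(UMBRELLA_HALF_ANGLE))
    for i in structure.dummy_indices:
        d = structure.atoms[i]
        n_xyz = np.asarray(d.xyz, dtype=float)
        axis = 1.0 if n_xyz[2] >= frame.midplane else -1.0
        resseq += 1
        serial += 1
        atoms.append(
            Atom(serial, "N", "N", PSEUDO_RESNAME, resseq, "Z", tuple(n_xyz), het=True)
        )
        for j, azim in enumerate((0.0, 120.0, 240.0)):
            phi = math.radians(azim)
            direction = np.array(
                [sin_u * math.cos(phi), sin_u * math.sin(phi), axis * cos_u]
            )
            h = n_xyz + N_H_BOND_LENGTH * direction
            serial += 1
            atoms.append(
                Atom(serial, f"H{j + 1}", "H", PSEUDO_RESNAME, resseq, "Z", tuple(h), het=True)
            )
    pseudo_indices = [
        i for i, a in enumerate(atoms) if a.resname == PSEUDO_RESNAME
    ]
    return OrientedStructure(atoms, [], pseudo_indices, frame)


def strip_heteroligands(structure: OrientedStructure) -> OrientedStructure:
    """Remove HETATM ligand residues (and waters), keeping markers and layers."""
    keep_resnames = {DUMMY_RESNAME, PSEUDO_RESNAME}
    atoms = [
        a
        for a in structure.atoms
        if not a.het or a.resname in keep_resnames
    ]
    dummy_indices = [i for i, a in enumerate(atoms) if a.resname == DUMMY_RESNAME]
    pseudo_indices = [i for i, a in enumerate(atoms) if a.resname == PSEUDO_RESNAME]
    return OrientedStructure(atoms, dummy_indices, pseudo_indices, structure.frame)


def build_search_boxes(
    structure: OrientedStructure,
    half: str,
    margin: float = 3.0,
    overlap_fraction: float = 0.25,
) -> list[SearchBox]:
    """Two overlapping search boxes covering one membrane half.

    Each box spans from the half's interface plane to the slab midplane in z
    (plus ``margin`` on each face). Laterally the two boxes tile the protein's
    x-y bounding rectangle, split at the x midline with ``overlap_fraction`` of
    the total width shared between them.
    """
    if half not in ("cytosolic", "luminal"):
        raise ValueError(f"unknown membrane half {half!r}")
    frame = structure.frame or derive_membrane_frame(structure)
    heavy = structure.protein_heavy()
    if half == "cytosolic":
        z_lo, z_hi = frame.midplane, frame.z_upper
    else:
        z_lo, z_hi = frame.z_lower, frame.midplane
    half_atoms = [a for a in heavy if z_lo <= a.xyz[2] <= z_hi]
    if not half_atoms:
        raise ValueError(f"no protein atoms in the {half} half-slab")
    xy = np.array([a.xyz[:2] for a in heavy], dtype=float)
    xmin, ymin = xy.min(axis=0) - margin
    xmax, ymax = xy.max(axis=0) + margin
    lx = xmax - xmin
    sy = ymax - ymin
    sz = (z_hi - z_lo) + 2 * margin
    cz = 0.5 * (z_lo + z_hi)
    cy = 0.5 * (ymin + ymax)
    sx = lx * (1 + overlap_fraction) / 2.0
    boxes = [
        SearchBox(
            center=(xmin + sx / 2.0, cy, cz), size=(sx, sy, sz), half=half, index=1
        ),
        SearchBox(
            center=(xmax - sx / 2.0, cy, cz), size=(sx, sy, sz), half=half, index=2
        ),
    ]
    assert boxes[0].intersection_volume(boxes[1]) > 0
    return boxes


def write_pdb(structure: OrientedStructure) -> str:
    """Serialize to PDB text (fixed columns, coordinates to 1e-3 A)."""
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:5d} {name:<4s}{a.resname:>4s} {a.chain:1s}"
            f"{a.resseq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def boxes_to_json(boxes: list[SearchBox]) -> str:
    payload = [
        {
            "half": b.half,
            "index": b.index,
            "center": list(b.center),
            "size": list(b.size),
        }
        for b in boxes
    ]
    return json.dumps(payload, indent=2)


def translate(structure: OrientedStructure, shift) -> OrientedStructure:
    """Rigid x,y,z translation of every atom (frame shifted in z accordingly)."""
    shift = np.asarray(shift, dtype=float)
    atoms = [replace(a, xyz=tuple(np.asarray(a.xyz) + shift)) for a in structure.atoms]
    frame = structure.frame
    if frame is not None and shift[2] != 0.0:
        frame = MembraneFrame(frame.z_upper + shift[2], frame.z_lower + shift[2])
    return OrientedStructure(
        atoms, list(structure.dummy_indices), list(structure.pseudo_indices), frame
    )
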