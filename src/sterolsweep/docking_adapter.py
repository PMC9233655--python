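"""Docking-engine configuration and multi-model pose-file ingestion.

The docking sweep runs AutoDock-Vina-style searches in two scoring regimes:

* ``TM`` - inside the bilayer hydrophobic core, with the hydrophobic-effect and
  hydrogen-bond weights set to -0.001 and -2.0 so that hydrogen bonding to the
  interfacial donor layers dominates, as appropriate when both ligand and
  receptor are already desolvated;
* ``aqueous`` - the engine defaults (-0.0351, -0.587) for water-exposed
  extra-membranous domains.

Engine invocation itself is optional and isolated behind a subprocess
boundary: every downstream stage consumes multi-model PDBQT pose files, so the
whole pipeline is testable without a docking engine.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .structure_io import SearchBox

__all__ = [
    "DockingRegime",
    "Pose",
    "DockingCampaign",
    "make_engine_config",
    "parse_pose_file",
    "assemble_campaign",
    "dedupe_overlap_poses",
]

_REGIME_WEIGHTS = {"TM": (-0.001, -2.0), "aqueous": (-0.0351, -0.587)}


@dataclass(frozen=True)
class DockingRegime:
    """Scoring-weight regime for the docking engine."""

    label: str
    weight_hydrophobic: float
    weight_hydrogen: float

    def __post_init__(self) -> None:
        expected = _REGIME_WEIGHTS.get(self.label)
        if expected is None:
            raise ValueError(f"unknown regime label {self.label!r}")
        if (self.weight_hydrophobic, self.weight_hydrogen) != expected:
            raise ValueError(
                f"regime {self.label!r} requires weights {expected}, got "
                f"({self.weight_hydrophobic}, {self.weight_hydrogen})"
            )

    @classmethod
    def tm(cls) -> "DockingRegime":
        return cls("TM", *_REGIME_WEIGHTS["TM"])

    @classmethod
    def aqueous(cls) -> "DockingRegime":
        return cls("aqueous", *_REGIME_WEIGHTS["aqueous"])

    @property
    def selection_enabled(self) -> bool:
        """Interfacial-site selection criteria apply only to TM docking."""
        return self.label == "TM"


@dataclass(frozen=True)
class Pose:
    """A rigid sterol placement with its docking energy (kcal/mol, molar)."""

    ligand_name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    energy: float
    study: int = 1
    run: int = 1
    box: int = 1
    model: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 3)
        )
        if not np.isfinite(self.energy):
            raise ValueError("pose energy must be finite")
        if len(self.ring_indices) == 0:
            raise ValueError("pose has no fused-ring atoms (C1..C17)")

    @property
    def ring_indices(self) -> list[int]:
        """Indices of the fused-ring carbons, named C1..C17 by convention."""
        ring = {f"C{i}" for i in range(1, 18)}
        return [i for i, n in enumerate(self.atom_names) if n in ring]

    @property
    def ring_coords(self) -> np.ndarray:
        return self.coords[self.ring_indices]

    @property
    def ring_centroid(self) -> np.ndarray:
        return self.ring_coords.mean(axis=0)

    @property
    def hydroxyl_index(self) -> int | None:
        for i, (name, el) in enumerate(zip(self.atom_names, self.elements)):
            if el.upper() == "O" and name.startswith("O"):
                return i
        return None

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el.upper() != "H"]

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.study, self.run, self.box, self.model)


@dataclass
class DockingCampaign:
    """Poses from a replicated docking sweep, organized studies x runs x boxes."""

    poses: list[Pose]
    regime: DockingRegime
    n_studies: int = 5
    n_runs: int = 5

    def __post_init__(self) -> None:
        for p in self.poses:
            if not 1 <= p.study <= self.n_studies:
                raise ValueError(f"study id {p.study} outside 1..{self.n_studies}")
            if not 1 <= p.run <= self.n_runs:
                raise ValueError(f"run id {p.run} outside 1..{self.n_runs}")

    def __len__(self) -> int:
        return len(self.poses)


def make_engine_config(
    regime: DockingRegime,
    box: SearchBox,
    receptor_path: str,
    ligand_path: str,
    **extra_options,
) -> str:
    """Emit an engine configuration text for one search box.

    Unrecognized engine options (``exhaustiveness``, ``num_modes``, ...) are
    passed through verbatim; no defaults are asserted for them.
    """
    if min(box.size) <= 0:
        raise ValueError("box sizes must be positive")
    lines = [
        f"receptor = {receptor_path}",
        f"ligand = {ligand_path}",
        f"center_x = {box.center[0]:.3f}",
        f"center_y = {box.center[1]:.3f}",
        f"center_z = {box.center[2]:.3f}",
        f"size_x = {box.size[0]:.3f}",
        f"size_y = {box.size[1]:.3f}",
        f"size_z = {box.size[2]:.3f}",
        f"weight_hydrophobic = {regime.weight_hydrophobic}",
        f"weight_hydrogen = {regime.weight_hydrogen}",
    ]
    for key in sorted(extra_options):
        lines.append(f"{key} = {extra_options[key]}")
    return "\n".join(lines) + "\n"


_VINA_RESULT = re.compile(r"^REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)")
_FALLBACK_ENERGY = re.compile(r"^REMARK\s+ENERGY[:=\s]+(-?\d+(?:\.\d+)?)")


def parse_pose_file(
    text: str,
    study: int = 1,
    run: int = 1,
    box: int = 1,
    ligand_name: str = "cholesterol",
) -> list[Pose]:
    """Parse a multi-MODEL PDBQT pose file into :class:`Pose` objects.

    Each MODEL block must carry an energy remark (``REMARK VINA RESULT:`` or
    ``REMARK ENERGY``); the first numeric field is the docking energy in
    kcal/mol.
    """
    poses: list[Pose] = []
    model_idx = 0
    in_model = False
    energy: float | None = None
    names: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    for line in text.splitlines():
        if line.startswith("MODEL"):
            in_model = True
            model_idx += 1
            energy, names, elements, coords = None, [], [], []
        elif line.startswith("ENDMDL"):
            if not in_model:
                continue
            if energy is None:
                raise ValueError(f"MODEL {model_idx} has no energy remark")
            poses.append(
                Pose(
                    ligand_name=ligand_name,
                    atom_names=tuple(names),
                    elements=tuple(elements),
                    coords=np.array(coords),
                    energy=energy,
                    study=study,
                    run=run,
                    box=box,
                    model=model_idx,
                )
            )
            in_model = False
        elif in_model and line.startswith("REMARK") and energy is None:
            m = _VINA_RESULT.match(line) or _FALLBACK_ENERGY.match(line)
            if m:
                energy = float(m.group(1))
        elif in_model and line.startswith(("ATOM", "HETATM")):
            name = line[12:16].strip()
            element = line[76:78].strip() or name[:1]
            names.append(name)
            elements.append(element)
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if not poses:
        raise ValueError("no MODEL blocks found in pose file")
    return poses


def assemble_campaign(
    pose_files: dict[tuple[int, int, int], str],
    regime: DockingRegime,
    n_studies: int = 5,
    n_runs: int = 5,
    boxes: tuple[int, ...] = (1, 2),
    ligand_name: str = "cholesterol",
) -> DockingCampaign:
    """Assemble pose files keyed by (study, run, box) into a campaign.

    Missing cells are reported as warnings (engine runs can fail); duplicate
    keys and out-of-range ids are errors.
    """
    seen: set[tuple[int, int, int]] = set()
    poses: list[Pose] = []
    for key in sorted(pose_files):
        study, run, box = key
        if key in seen:
            raise ValueError(f"duplicate campaign cell {key}")
        seen.add(key)
        if not 1 <= study <= n_studies:
            raise ValueError(f"study id {study} outside 1..{n_studies}")
        if not 1 <= run <= n_runs:
            raise ValueError(f"run id {run} outside 1..{n_runs}")
        if box not in boxes:
            raise ValueError(f"box id {box} not in {boxes}")
        poses.extend(
            parse_pose_file(pose_files[key], study, run, box, ligand_name)
        )
    expected = {(s, r, b) for s in range(1, n_studies + 1)
                for r in range(1, n_runs + 1) for b in boxes}
    missing = sorted(expected - seen)
    for cell in missing:
        warnings.warn(f"missing campaign cell {cell}", stacklevel=2)
    return DockingCampaign(poses, regime, n_studies, n_runs)


def _pose_pair_rmsd(p1: Pose, p2: Pose) -> float:
    # heavy-atom rmsd in the common receptor frame; topology assumed shared
    i1, i2 = p1.heavy_indices, p2.heavy_indices
    d = p1.coords[i1] - p2.coords[i2]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def dedupe_overlap_poses(poses: list[Pose], duplicate_rmsd: float = 1.0) -> list[Pose]:
    """Remove duplicate poses arising in the overlap region of the two boxes.

    Within each (study, run), poses from *different* boxes closer than
    ``duplicate_rmsd`` are grouped (transitively) and only the most favourable
    pose of each group is kept; poses from the same box are never merged.
    Idempotent, order-independent, deterministic (energy ties broken by the
    (study, run, box, model) key).
    """
    by_cell: dict[tuple[int, int], list[Pose]] = {}
    for p in poses:
        by_cell.setdefault((p.study, p.run), []).append(p)
    kept: list[Pose] = []
    for cell in sorted(by_cell):
        group = sorted(by_cell[cell], key=lambda p: (p.energy, p.key))
        cell_kept: list[Pose] = []
        for p in group:
            duplicate = any(
                q.box != p.box and _pose_pair_rmsd(p, q) < duplicate_rmsd
                for q in cell_kept
            )
            if not duplicate:
                cell_kept.append(p)
        kept.extend(cell_kept)
    return sorted(kept, key=lambda p: p.key)
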