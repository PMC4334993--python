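"""Interface analysis of docked complexes.

Solvent accessibility is computed with a deterministic Shrake-Rupley
sampler; the footprint classification, hydrogen-bond/salt-bridge detection
and contact-ring geometry all work on plain atom lists so a complex can be
assembled from any receptor + posed ligand pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._chemdata import HBOND_ACCEPTORS, HBOND_DONORS, vdw_radius
from .dockengine import Pose, assign_charges
from .errors import AddressingError, ParameterError
from .structio import AtomRecord, Residue, StructureBundle, iter_residues

__all__ = [
    "FootprintRow",
    "ContactRecord",
    "ContactRing",
    "RingDefinition",
    "InterfaceThresholds",
    "sasa",
    "residue_sasa",
    "classify_footprint",
    "detect_hbonds",
    "detect_salt_bridges",
    "contact_rings",
    "posed_ligand_atoms",
]


@dataclass(frozen=True)
class InterfaceThresholds:
    """Geometric criteria; all configurable, defaults documented."""

    probe_radius: float = 1.4
    sasa_points: int = 960
    interfacing_delta_sasa: float = 1.0   # A^2 of burial to call a residue interfacing
    inaccessible_sasa: float = 5.0        # free-receptor SASA below this = buried
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    saltbridge_distance: float = 4.0


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere sample."""
    indices = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * indices / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * indices
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(
    atoms: Sequence[AtomRecord] | StructureBundle,
    probe: float = 1.4,
    n_points: int = 960,
    model_index: int = 0,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), Shrake-Rupley style."""
    if isinstance(atoms, StructureBundle):
        atoms = atoms.model(model_index)
    if n_points < 10:
        raise ParameterError("need at least 10 sphere points")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms]) + probe
    if coords.size == 0:
        return np.zeros(0)
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_radius = float(radii.max())
    areas = np.zeros(len(atoms))
    for i, (center, radius) in enumerate(zip(coords, radii)):
        points = center + radius * sphere
        neighbor_idx = [j for j in tree.query_ball_point(center, radius + max_radius)
                        if j != i]
        if neighbor_idx:
            neighbor_coords = coords[neighbor_idx]
            neighbor_radii = radii[neighbor_idx]
            d2 = np.sum((points[:, None, :] - neighbor_coords[None, :, :]) ** 2,
                        axis=-1)
            buried = np.any(d2 < neighbor_radii[None, :] ** 2, axis=1)
            accessible = int(np.sum(~buried))
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * radius ** 2 * accessible / n_points
    return areas


def residue_sasa(atoms: Sequence[AtomRecord], areas: np.ndarray) -> dict:
    """Aggregate per-atom areas to residue keys (chain, seq, icode)."""
    totals: dict = {}
    for atom, area in zip(atoms, areas):
        totals[atom.residue_key] = totals.get(atom.residue_key, 0.0) + float(area)
    return totals


# ---------------------------------------------------------------------------
# Footprint classification
# ---------------------------------------------------------------------------

@dataclass
class FootprintRow:
    chain: str
    residue_seq: int
    residue_name: str
    category: str               # inaccessible | solvent-accessible | interfacing | bonded-link
    buried_area: float


def posed_ligand_atoms(
    ligand: StructureBundle, pose: Pose | None, model_index: int = 0,
    centroid: np.ndarray | None = None,
) -> list[AtomRecord]:
    """Ligand model atoms, transformed by ``pose`` when one is given."""
    atoms = ligand.model(model_index)
    if pose is None:
        return list(atoms)
    coords = np.array([a.coords for a in atoms])
    c = np.asarray(centroid, float) if centroid is not None else coords.mean(axis=0)
    moved = pose.transform(coords, c)
    return [a.moved(xyz) for a, xyz in zip(atoms, moved)]


def classify_footprint(
    receptor: StructureBundle,
    ligand_atoms: Sequence[AtomRecord],
    thresholds: InterfaceThresholds | None = None,
) -> list[FootprintRow]:
    """Per-residue footprint of a docked ligand on the receptor.

    A residue is *interfacing* when it buries more than the threshold SASA
    on complexation, *bonded-link* when it additionally makes a hydrogen
    bond or salt bridge, *inaccessible* when already buried in the free
    receptor, otherwise *solvent-accessible*.
    """
    t = thresholds or InterfaceThresholds()
    rec_atoms = receptor.model(0)
    free_areas = sasa(rec_atoms, t.probe_radius, t.sasa_points)
    complex_atoms = list(rec_atoms) + list(ligand_atoms)
    complex_areas = sasa(complex_atoms, t.probe_radius, t.sasa_points)
    free_by_res = residue_sasa(rec_atoms, free_areas)
    complex_by_res = residue_sasa(rec_atoms, complex_areas[:len(rec_atoms)])

    contacts = detect_hbonds(rec_atoms, ligand_atoms, t.hbond_distance,
                             t.hbond_angle)
    contacts += detect_salt_bridges(rec_atoms, ligand_atoms,
                                    t.saltbridge_distance)
    linked = {record.receptor_residue for record in contacts}

    rows: list[FootprintRow] = []
    for residue in iter_residues(rec_atoms):
        free = free_by_res.get(residue.key, 0.0)
        delta = max(0.0, free - complex_by_res.get(residue.key, 0.0))
        if delta > t.interfacing_delta_sasa:
            category = "bonded-link" if residue.key in linked else "interfacing"
        elif free < t.inaccessible_sasa:
            category = "inaccessible"
        else:
            category = "solvent-accessible"
        rows.append(FootprintRow(residue.chain_id, residue.residue_seq,
                                 residue.name, category, round(delta, 2)))
    return rows


def footprint_table(rows: list[FootprintRow], path: str | Path | None = None) -> str:
    lines = ["chain\tresidue_seq\tresidue\tcategory\tburied_area"]
    for r in rows:
        lines.append(f"{r.chain}\t{r.residue_seq}\t{r.residue_name}\t"
                     f"{r.category}\t{r.buried_area:.2f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

@dataclass
class ContactRecord:
    kind: str                   # "hbond" | "saltbridge"
    receptor_atom: str          # "A/GLU 90/OE1"
    ligand_atom: str
    receptor_residue: tuple
    ligand_residue: tuple
    distance: float
    angle: float | None = None  # D-H...A angle, hbond only

    def __str__(self) -> str:
        extra = f" angle={self.angle:.0f}" if self.angle is not None else ""
        return (f"{self.kind} {self.receptor_atom} -- {self.ligand_atom} "
                f"d={self.distance:.2f}{extra}")


def _atom_label(atom: AtomRecord) -> str:
    return f"{atom.chain_id}/{atom.residue_name} {atom.residue_seq}/{atom.name}"


def _covalent_neighbors(atom: AtomRecord, residue: Residue) -> np.ndarray:
    neighbors = [b.coords for b in residue.atoms
                 if b is not atom and np.linalg.norm(b.coords - atom.coords) < 1.8]
    return np.array(neighbors) if neighbors else np.zeros((0, 3))


def _donors(atoms: Sequence[AtomRecord]) -> list[tuple[AtomRecord, np.ndarray]]:
    """(donor atom, idealized H position) pairs.

    The hydrogen is placed 1.0 A from the donor, directed away from the
    centroid of its covalently bonded heavy atoms.
    """
    out = []
    for residue in iter_residues(atoms):
        names = set(HBOND_DONORS.get(residue.name.upper(), ()))
        for atom in residue.atoms:
            is_backbone_n = atom.name == "N" and residue.name.upper() != "PRO"
            if not (is_backbone_n or atom.name in names):
                continue
            neighbors = _covalent_neighbors(atom, residue)
            if len(neighbors) == 0:
                direction = np.array([0.0, 0.0, 1.0])
            else:
                direction = atom.coords - neighbors.mean(axis=0)
                norm = np.linalg.norm(direction)
                direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            out.append((atom, atom.coords + direction))
    return out


def _acceptors(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    out = []
    for residue in iter_residues(atoms):
        names = set(HBOND_ACCEPTORS.get(residue.name.upper(), ()))
        for atom in residue.atoms:
            # backbone carbonyl oxygen of every residue accepts
            if atom.name in ("O", "OXT") or atom.name in names:
                out.append(atom)
    return out


def detect_hbonds(
    receptor_atoms: Sequence[AtomRecord],
    ligand_atoms: Sequence[AtomRecord],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[ContactRecord]:
    """Inter-molecular hydrogen bonds by distance + idealized-H angle.

    Criteria: donor-acceptor heavy-atom distance <= ``d_max`` and
    D-H...A angle >= ``angle_min`` with the hydrogen at its idealized
    position.  Both donor->acceptor directions are evaluated; records are
    sorted by distance.
    """
    records: list[ContactRecord] = []

    def scan(donors, acceptors, donor_is_receptor: bool):
        for donor, h_pos in donors:
            for acceptor in acceptors:
                d = float(np.linalg.norm(donor.coords - acceptor.coords))
                if d > d_max or d < 1.5:
                    continue
                u = donor.coords - h_pos
                v = acceptor.coords - h_pos
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle < angle_min:
                    continue
                rec_atom, lig_atom = ((donor, acceptor) if donor_is_receptor
                                      else (acceptor, donor))
                records.append(ContactRecord(
                    kind="hbond",
                    receptor_atom=_atom_label(rec_atom),
                    ligand_atom=_atom_label(lig_atom),
                    receptor_residue=rec_atom.residue_key,
                    ligand_residue=lig_atom.residue_key,
                    distance=round(d, 3),
                    angle=round(angle, 1),
                ))

    scan(_donors(receptor_atoms), _acceptors(ligand_atoms), True)
    scan(_donors(ligand_atoms), _acceptors(receptor_atoms), False)
    records.sort(key=lambda r: (r.distance, r.receptor_atom, r.ligand_atom))
    return records


def _charged_atoms(atoms: Sequence[AtomRecord]) -> list[tuple[AtomRecord, float]]:
    bundle = StructureBundle([list(atoms)], identifier="charges")
    model = assign_charges(bundle)
    return [(a, q) for a, q in zip(atoms, model.charges) if q != 0.0]


def detect_salt_bridges(
    receptor_atoms: Sequence[AtomRecord],
    ligand_atoms: Sequence[AtomRecord],
    d_max: float = 4.0,
) -> list[ContactRecord]:
    """Opposite-sign charged-group heavy atoms within ``d_max``, inter-molecular."""
    records = []
    for rec_atom, rec_q in _charged_atoms(receptor_atoms):
        for lig_atom, lig_q in _charged_atoms(ligand_atoms):
            if rec_q * lig_q >= 0:
                continue
            d = float(np.linalg.norm(rec_atom.coords - lig_atom.coords))
            if d > d_max:
                continue
            records.append(ContactRecord(
                kind="saltbridge",
                receptor_atom=_atom_label(rec_atom),
                ligand_atom=_atom_label(lig_atom),
                receptor_residue=rec_atom.residue_key,
                ligand_residue=lig_atom.residue_key,
                distance=round(d, 3),
            ))
    records.sort(key=lambda r: (r.distance, r.receptor_atom, r.ligand_atom))
    return records


def contacts_table(records: list[ContactRecord],
                   path: str | Path | None = None) -> str:
    lines = ["kind\treceptor_atom\tligand_atom\tdistance\tangle"]
    for r in records:
        angle = f"{r.angle:.1f}" if r.angle is not None else ""
        lines.append(f"{r.kind}\t{r.receptor_atom}\t{r.ligand_atom}\t"
                     f"{r.distance:.3f}\t{angle}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Contact rings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingDefinition:
    """A named residue position forming a ring across the tetramer chains."""

    name: str
    residue_seq: int
    atom_name: str = "CA"
    insertion_code: str = ""


@dataclass
class ContactRing:
    name: str
    residues: dict               # chain -> residue_seq
    depth: float                 # mean z of ring atoms
    diameter: float              # mean over opposing-chain atom pairs
    ligand_contacts: int | None = None


def contact_rings(
    receptor_tetramer: StructureBundle,
    ring_definitions: Sequence[RingDefinition],
    ligand_atoms: Sequence[AtomRecord] | None = None,
    contact_cutoff: float = 4.5,
    model_index: int = 0,
) -> list[ContactRing]:
    """Ring geometry of named vestibule positions across a z-aligned tetramer.

    Diameter is the mean distance between opposing-chain ring atoms (A-C and
    B-D for a four-chain assembly); depth is the mean z coordinate.  With a
    posed ligand, per-ring contact counts (ligand atoms within the cutoff of
    any ring-residue atom) are included.
    """
    chains = receptor_tetramer.chain_ids(model_index)
    if len(chains) < 2:
        raise AddressingError("contact rings need at least 2 chains")
    residues = receptor_tetramer.residues(model_index)
    rings: list[ContactRing] = []
    lig_coords = (np.array([a.coords for a in ligand_atoms])
                  if ligand_atoms else None)
    for definition in ring_definitions:
        ring_atoms: dict[str, np.ndarray] = {}
        ring_residue_atoms: list[AtomRecord] = []
        for chain in chains:
            match = [r for r in residues
                     if r.chain_id == chain
                     and r.residue_seq == definition.residue_seq
                     and r.insertion_code == definition.insertion_code]
            if not match:
                raise AddressingError(
                    f"ring {definition.name!r}: residue {definition.residue_seq} "
                    f"missing in chain {chain}"
                )
            atom = match[0].atom(definition.atom_name)
            if atom is None:
                raise AddressingError(
                    f"ring {definition.name!r}: atom {definition.atom_name} "
                    f"missing in chain {chain}"
                )
            ring_atoms[chain] = atom.coords
            ring_residue_atoms.extend(match[0].atoms)
        positions = np.array(list(ring_atoms.values()))
        n = len(chains)
        opposing = [(chains[i], chains[(i + n // 2) % n]) for i in range(n // 2)]
        diameters = [np.linalg.norm(ring_atoms[a] - ring_atoms[b])
                     for a, b in opposing]
        contacts = None
        if lig_coords is not None:
            ring_coords = np.array([a.coords for a in ring_residue_atoms])
            tree = cKDTree(ring_coords)
            hits = tree.query_ball_point(lig_coords, r=contact_cutoff)
            contacts = int(sum(1 for h in hits if h))
        rings.append(ContactRing(
            name=definition.name,
            residues={c: definition.residue_seq for c in chains},
            depth=float(np.mean(positions[:, 2])),
            diameter=float(np.mean(diameters)),
            ligand_contacts=contacts,
        ))
    return rings


def rings_to_json(rings: list[ContactRing], path: str | Path | None = None) -> str:
    payload = [
        {
            "name": r.name, "residues": r.residues,
            "depth": r.depth, "diameter": r.diameter,
            "ligand_contacts": r.ligand_contacts,
        }
        for r in rings
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
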