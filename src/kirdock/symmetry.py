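"""Tetramer assembly from template-derived cyclic symmetry operators."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import AssemblyError
from .structio import AtomRecord, StructureBundle, superpose

__all__ = ["SymmetryOperator", "OperatorSet", "derive_operators", "assemble_oligomer"]

_CHAIN_IDS = ("A", "B", "C", "D")
#: Inter-chain backbone separation below which a clash is reported.
BACKBONE_CLASH_DISTANCE = 2.0


@dataclass(frozen=True)
class SymmetryOperator:
    """Rigid map taking the reference chain onto a target chain."""

    rotation: np.ndarray
    translation: np.ndarray
    source_chain: str
    target_chain: str
    rmsd: float = 0.0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": np.asarray(self.rotation).tolist(),
            "translation": np.asarray(self.translation).tolist(),
            "source_chain": self.source_chain,
            "target_chain": self.target_chain,
            "rmsd": self.rmsd,
        }


@dataclass
class OperatorSet:
    """Four cyclic operators plus the pore-axis frame of the template."""

    operators: list[SymmetryOperator]
    pore_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    pore_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __len__(self) -> int:
        return len(self.operators)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "operators": [op.to_dict() for op in self.operators],
            "pore_axis": self.pore_axis.tolist(),
            "pore_center": self.pore_center.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "OperatorSet":
        payload = json.loads(text)
        ops = [
            SymmetryOperator(
                rotation=np.array(d["rotation"], float),
                translation=np.array(d["translation"], float),
                source_chain=d["source_chain"],
                target_chain=d["target_chain"],
                rmsd=float(d.get("rmsd", 0.0)),
            )
            for d in payload["operators"]
        ]
        return cls(ops, np.array(payload["pore_axis"], float),
                   np.array(payload["pore_center"], float))


def _pore_frame(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pore axis = least-spread eigenvector of the chain-centroid scatter."""
    center = centroids.mean(axis=0)
    deviations = centroids - center
    covariance = deviations.T @ deviations
    eigvals, eigvecs = np.linalg.eigh(covariance)
    axis = eigvecs[:, 0]  # smallest eigenvalue: normal to the centroid plane
    if axis[2] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), center


def derive_operators(template_tetramer: StructureBundle, model_index: int = 0) -> OperatorSet:
    """Derive the four A->chain operators of a tetramer, in cyclic pore order.

    Chains must share residue topology.  Operator 0 is always the identity
    (A->A); subsequent operators are ordered by increasing rotation angle
    about the pore axis.
    """
    chain_ids = template_tetramer.chain_ids(model_index)
    if len(chain_ids) != 4:
        raise AssemblyError(f"expected 4 chains, found {len(chain_ids)}")
    ref_id = chain_ids[0]
    ref_atoms = template_tetramer.chain_atoms(ref_id, model_index)
    ref_names = [(a.residue_seq, a.insertion_code, a.name) for a in ref_atoms]
    ref_coords = np.array([a.coords for a in ref_atoms])

    centroids = np.array([
        np.mean([a.coords for a in template_tetramer.chain_atoms(c, model_index)], axis=0)
        for c in chain_ids
    ])
    axis, center = _pore_frame(centroids)

    operators = []
    for chain_id in chain_ids:
        atoms = template_tetramer.chain_atoms(chain_id, model_index)
        names = [(a.residue_seq, a.insertion_code, a.name) for a in atoms]
        if names != ref_names:
            raise AssemblyError(
                f"chain {chain_id} topology differs from chain {ref_id}"
            )
        coords = np.array([a.coords for a in atoms])
        if chain_id == ref_id:
            rotation, translation, fit = np.eye(3), np.zeros(3), 0.0
        else:
            rotation, translation, fit = superpose(ref_coords, coords)
        operators.append(SymmetryOperator(rotation, translation, ref_id,
                                          chain_id, fit))

    # order by rotation angle about the pore axis (identity first)
    basis = _perpendicular_basis(axis)
    ref_centroid = ref_coords.mean(axis=0)

    def cyclic_angle(op: SymmetryOperator) -> float:
        moved = op.apply(ref_centroid[None, :])[0] - center
        angle = np.arctan2(moved @ basis[1], moved @ basis[0])
        start = ref_centroid - center
        start_angle = np.arctan2(start @ basis[1], start @ basis[0])
        return float(np.mod(angle - start_angle, 2 * np.pi))

    identity, rest = operators[0], operators[1:]
    rest.sort(key=cyclic_angle)
    return OperatorSet([identity] + rest, axis, center)


def _perpendicular_basis(axis: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ axis) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - (trial @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.array([u, v, axis])


def assemble_oligomer(
    subunits: StructureBundle | list[StructureBundle],
    operators: OperatorSet,
    model_index: int = 0,
) -> tuple[StructureBundle, list[dict]]:
    """Assemble a tetramer from 1 subunit (homo) or 4 subunits (hetero).

    Chain IDs are fixed to A-D in cyclic operator order.  Returns the
    assembled structure and a (possibly empty) inter-chain backbone clash
    report; clashes are reported, not fatal.
    """
    if isinstance(subunits, StructureBundle):
        subunits = [subunits]
    if len(subunits) not in (1, 4):
        raise AssemblyError(
            f"unsupported subunit count {len(subunits)}: provide 1 "
            "(homotetramer) or 4 (heterotetramer)"
        )
    if len(operators) != 4:
        raise AssemblyError(f"expected 4 operators, got {len(operators)}")

    atoms: list[AtomRecord] = []
    serial = 0
    per_chain_backbone: dict[str, np.ndarray] = {}
    for k, op in enumerate(operators.operators):
        subunit = subunits[k % len(subunits)]
        chain_id = _CHAIN_IDS[k]
        model = subunit.model(model_index)
        coords = np.array([a.coords for a in model])
        moved = op.apply(coords)
        for atom, xyz in zip(model, moved):
            serial += 1
            atoms.append(replace(atom, serial=serial, chain_id=chain_id,
                                 coords=xyz))
        bb = np.array([xyz for atom, xyz in zip(model, moved)
                       if atom.name in ("N", "CA", "C", "O")])
        per_chain_backbone[chain_id] = bb

    clashes: list[dict] = []
    ids = list(per_chain_backbone)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = per_chain_backbone[ids[i]], per_chain_backbone[ids[j]]
            if len(a) == 0 or len(b) == 0:
                continue
            tree = cKDTree(b)
            dists, _ = tree.query(a, k=1)
            n_bad = int(np.sum(dists < BACKBONE_CLASH_DISTANCE))
            if n_bad:
                clashes.append({
                    "chains": (ids[i], ids[j]),
                    "n_pairs": n_bad,
                    "min_distance": float(np.min(dists)),
                })

    identifier = "+".join(s.identifier or "subunit" for s in subunits)
    return StructureBundle([atoms], identifier=f"tetramer({identifier})"), clashes
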