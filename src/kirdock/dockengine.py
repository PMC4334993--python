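"""Desk-scale rigid-body docking by FFT grid correlation.

One ligand orientation at a time, the translational search is an FFT
cross-correlation of receptor and ligand score grids: a surface-shell
overlap reward, a core interpenetration penalty and a grid-charge
electrostatic term.  A coarse pairwise contact potential re-ranks the
grid-score candidates.  The whole path is deterministic — identical inputs
give identical pose lists.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.fft import irfftn, next_fast_len, rfftn
from scipy.spatial import cKDTree

from ._chemdata import CONTACT_TYPES, SIDECHAIN_CHARGES, contact_value, vdw_radius
from .errors import GridError, ParameterError, ShapeError
from .geometry import rotation_about_axis
from .structio import StructureBundle, iter_residues

__all__ = [
    "ChargeModel",
    "ScoreGrids",
    "ScoreMaps",
    "Pose",
    "PoseList",
    "DockConfig",
    "assign_charges",
    "rotation_set",
    "build_grids",
    "scan_translations",
    "contact_energy",
    "dock_rigid",
    "read_poselist",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DockConfig:
    """Docking parameters.  Defaults are the documented desk-scale setting."""

    spacing: float = 1.2
    surface_thickness: float = 1.5
    rotation_step: float = 18.0
    top_n: int = 2000
    weight_shape: float = 1.0
    weight_electrostatic: float = 0.5
    weight_contact: float = 1.0
    core_penalty: float = 9.0
    per_rotation_keep: int = 3
    contact_cutoff: float = 6.0
    contact_pool: int = 5000
    max_grid_dim: int = 192

    def __post_init__(self) -> None:
        if not 0.5 <= self.spacing <= 3.0:
            raise ParameterError(f"spacing {self.spacing} outside [0.5, 3.0] A")
        if not 0.0 < self.rotation_step <= 90.0:
            raise ParameterError(f"rotation step {self.rotation_step} outside (0, 90]")
        if self.top_n <= 0:
            raise ParameterError("top_n must be positive")

    def snapshot(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Charge assignment
# ---------------------------------------------------------------------------

@dataclass
class ChargeModel:
    """Per-atom formal charges (elementary units) aligned with a model's atoms."""

    charges: np.ndarray
    scheme: str = "formal_pH7"
    warnings: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(np.sum(self.charges))


_KNOWN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def assign_charges(
    structure: StructureBundle,
    scheme: str = "formal_pH7",
    model_index: int = 0,
    his_charge: float = 0.0,
    charged_termini: bool = True,
) -> ChargeModel:
    """Formal pH-7 charges: Arg/Lys +1, Asp/Glu -1, His configurable,
    free N-terminus +1, C-terminus -1, disulfide-bonded Cys 0.

    Unknown residues get zero charge with a warning.
    """
    if scheme != "formal_pH7":
        raise ParameterError(f"unknown charge scheme {scheme!r}")
    atoms = structure.model(model_index)
    charges = np.zeros(len(atoms))
    warning_list: list[str] = []
    index_of = {id(a): i for i, a in enumerate(atoms)}

    residues = list(iter_residues(atoms))
    for chain_id in structure.chain_ids(model_index):
        chain = [r for r in residues if r.chain_id == chain_id]
        protein = [r for r in chain if r.name.upper() in _KNOWN_RESIDUES
                   or len(r.atoms) > 1]
        for r in chain:
            resname = r.name.upper()
            if resname in SIDECHAIN_CHARGES:
                group = SIDECHAIN_CHARGES[resname]
                for atom in r.atoms:
                    if atom.name in group:
                        charges[index_of[id(atom)]] += group[atom.name]
            elif resname == "HIS" and his_charge:
                for atom in r.atoms:
                    if atom.name in ("ND1", "NE2"):
                        charges[index_of[id(atom)]] += his_charge / 2.0
            elif resname == "K" or resname == "POT":
                charges[index_of[id(r.atoms[0])]] += 1.0
            elif resname not in _KNOWN_RESIDUES:
                warning_list.append(f"unknown residue {resname} "
                                    f"{chain_id}{r.residue_seq}: zero charge")
        if charged_termini and protein:
            first, last = protein[0], protein[-1]
            n_atom = first.atom("N")
            if n_atom is not None:
                charges[index_of[id(n_atom)]] += 1.0
            oxt = last.atom("OXT")
            target = oxt if oxt is not None else last.atom("O")
            if target is not None:
                charges[index_of[id(target)]] -= 1.0
    return ChargeModel(charges, scheme, warning_list)


# ---------------------------------------------------------------------------
# Rotational sampling
# ---------------------------------------------------------------------------

def rotation_set(angular_step: float) -> list[np.ndarray]:
    """Deterministic near-uniform SO(3) sample from a z-y-z Euler grid.

    Element 0 is always the identity.  Pole duplicates (beta = 0 or 180)
    collapse to a single gamma value and exact duplicates are removed.
    """
    if not 0.0 < angular_step <= 90.0:
        raise ParameterError(f"angular step {angular_step} outside (0, 90]")
    step = float(angular_step)
    betas = np.arange(0.0, 180.0 + 1e-9, step)
    gammas = np.arange(0.0, 360.0, step)
    seen: set[bytes] = set()
    rotations: list[np.ndarray] = []
    for beta in betas:
        if 0.0 < beta < 180.0:
            # shrink the alpha ring with sin(beta) for near-uniform coverage
            n_alpha = max(1, round(360.0 / step * np.sin(np.radians(beta))))
            alphas = np.arange(n_alpha) * (360.0 / n_alpha)
            gamma_values = gammas
        else:
            alphas = np.arange(0.0, 360.0, step)
            gamma_values = np.array([0.0])
        for alpha in alphas:
            for gamma in gamma_values:
                rot = (
                    rotation_about_axis([0, 0, 1], alpha)
                    @ rotation_about_axis([0, 1, 0], beta)
                    @ rotation_about_axis([0, 0, 1], gamma)
                )
                key = np.round(rot, 9).tobytes()
                if key in seen:
                    continue
                seen.add(key)
                rotations.append(rot)
    return rotations


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass
class ScoreGrids:
    """Rasterized structure: binary core/surface layers + splatted charges."""

    origin: np.ndarray
    spacing: float
    surface: np.ndarray
    core: np.ndarray
    charge: np.ndarray

    @property
    def dimensions(self) -> tuple[int, int, int]:
        return self.core.shape


def build_grids(
    structure: StructureBundle | np.ndarray,
    charge_model: ChargeModel | np.ndarray | None,
    spacing: float = 1.2,
    surface_thickness: float = 1.5,
    margin: float = 3.0,
    elements: Sequence[str] | None = None,
    model_index: int = 0,
    max_grid_dim: int = 192,
    dims: tuple[int, int, int] | None = None,
    dtype=np.float64,
) -> ScoreGrids:
    """Rasterize a structure onto core/surface/charge grids.

    Core voxels lie within an atom's van der Waals radius; surface voxels
    within ``radius + surface_thickness`` but outside the core.  Charges are
    deposited with trilinear splatting (conserving total charge).
    """
    if not 0.5 <= spacing <= 3.0:
        raise ParameterError(f"spacing {spacing} outside [0.5, 3.0] A")
    if isinstance(structure, StructureBundle):
        atoms = structure.model(model_index)
        coords = np.array([a.coords for a in atoms])
        radii = np.array([vdw_radius(a.element) for a in atoms])
    else:
        coords = np.asarray(structure, dtype=float)
        if elements is None:
            radii = np.full(len(coords), vdw_radius("C"))
        else:
            radii = np.array([vdw_radius(e) for e in elements])
    if coords.size == 0:
        raise GridError("cannot rasterize an empty structure")
    if charge_model is None:
        charges = np.zeros(len(coords))
    elif isinstance(charge_model, ChargeModel):
        charges = charge_model.charges
    else:
        charges = np.asarray(charge_model, dtype=float)
    if len(charges) != len(coords):
        raise ShapeError("charge array does not match atom count")

    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    if dims is None:
        dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    else:
        dims = np.asarray(dims, dtype=int)
        if np.any((lo + (dims - 1) * spacing) < hi - 1e-9):
            raise GridError("fixed grid dimensions too small for the structure")
    if np.any(dims > max_grid_dim):
        raise GridError(f"grid dimensions {tuple(dims)} exceed limit {max_grid_dim}")
    origin = lo
    core = np.zeros(dims, dtype=dtype)
    near = np.zeros(dims, dtype=dtype)

    axes = [origin[k] + spacing * np.arange(dims[k]) for k in range(3)]
    for xyz, radius in zip(coords, radii):
        reach = radius + surface_thickness
        slices = []
        local_axes = []
        for k in range(3):
            j0 = max(0, int(np.floor((xyz[k] - reach - origin[k]) / spacing)))
            j1 = min(dims[k] - 1, int(np.ceil((xyz[k] + reach - origin[k]) / spacing)))
            slices.append(slice(j0, j1 + 1))
            local_axes.append(axes[k][j0:j1 + 1] - xyz[k])
        dx, dy, dz = np.meshgrid(*local_axes, indexing="ij")
        dist2 = dx * dx + dy * dy + dz * dz
        core_block = core[tuple(slices)]
        near_block = near[tuple(slices)]
        np.maximum(core_block, (dist2 <= radius * radius).astype(dtype),
                   out=core_block)
        np.maximum(near_block, (dist2 <= reach * reach).astype(dtype),
                   out=near_block)
    surface = np.clip(near - core, 0.0, 1.0)

    charge_grid = np.zeros(dims, dtype=dtype)
    if np.any(charges):
        frac = (coords - origin) / spacing
        base = np.floor(frac).astype(int)
        rem = frac - base
        for (ix, iy, iz), (fx, fy, fz), q in zip(base, rem, charges):
            if q == 0.0:
                continue
            for ox, wx in ((0, 1 - fx), (1, fx)):
                for oy, wy in ((0, 1 - fy), (1, fy)):
                    for oz, wz in ((0, 1 - fz), (1, fz)):
                        charge_grid[ix + ox, iy + oy, iz + oz] += q * wx * wy * wz
    return ScoreGrids(origin, spacing, surface, core, charge_grid)


# ---------------------------------------------------------------------------
# Translational scan
# ---------------------------------------------------------------------------

@dataclass
class ScoreMaps:
    """Per-displacement score maps for one ligand orientation.

    Arrays are indexed by displacement ``d``; the ligand-grid voxel offset is
    ``d - (ligand_dims - 1)`` and the Cartesian shift of the ligand is
    ``shift(d) = receptor.origin - ligand.origin + offset * spacing``.
    """

    surface_overlap: np.ndarray
    core_overlap: np.ndarray
    electrostatic: np.ndarray
    shape: np.ndarray
    total: np.ndarray
    receptor_origin: np.ndarray
    ligand_origin: np.ndarray
    ligand_dims: tuple[int, int, int]
    spacing: float

    def shift(self, d_index: tuple[int, int, int]) -> np.ndarray:
        offset = np.asarray(d_index) - (np.asarray(self.ligand_dims) - 1)
        return (self.receptor_origin - self.ligand_origin
                + offset * self.spacing)


def _fft_correlate(f_receptor: np.ndarray, ligand: np.ndarray,
                   padded: tuple[int, ...], out_shape: tuple[int, ...],
                   lig_dims: tuple[int, ...]) -> np.ndarray:
    f_lig = rfftn(ligand, padded)
    full = irfftn(f_receptor * np.conj(f_lig), padded)
    # reorder circular output so index d corresponds to offset d-(nL-1)
    idx = [np.mod(np.arange(-(lig_dims[k] - 1), out_shape[k] - lig_dims[k] + 1),
                  padded[k]) for k in range(3)]
    return full[np.ix_(*idx)]


def scan_translations(
    receptor_grids: ScoreGrids,
    ligand_grids: ScoreGrids,
    config: DockConfig | None = None,
) -> ScoreMaps:
    """Full translational scan of one ligand orientation by FFT correlation.

    The result is bit-compatible (to ~1e-6) with direct summation over all
    voxel overlaps.
    """
    config = config or DockConfig()
    if abs(receptor_grids.spacing - ligand_grids.spacing) > 1e-9:
        raise GridError("receptor/ligand grid spacing mismatch")
    n_rec = receptor_grids.core.shape
    n_lig = ligand_grids.core.shape
    out_shape = tuple(n_rec[k] + n_lig[k] - 1 for k in range(3))
    padded = tuple(next_fast_len(s) for s in out_shape)

    f_surface = rfftn(receptor_grids.surface, padded)
    f_core = rfftn(receptor_grids.core, padded)
    f_charge = rfftn(receptor_grids.charge, padded)

    surface = _fft_correlate(f_surface, ligand_grids.surface, padded, out_shape, n_lig)
    core = _fft_correlate(f_core, ligand_grids.core, padded, out_shape, n_lig)
    electro = -_fft_correlate(f_charge, ligand_grids.charge, padded, out_shape, n_lig)
    shape = surface - config.core_penalty * core
    total = config.weight_shape * shape + config.weight_electrostatic * electro
    return ScoreMaps(
        surface_overlap=surface, core_overlap=core, electrostatic=electro,
        shape=shape, total=total,
        receptor_origin=np.asarray(receptor_grids.origin, float),
        ligand_origin=np.asarray(ligand_grids.origin, float),
        ligand_dims=n_lig, spacing=receptor_grids.spacing,
    )


# ---------------------------------------------------------------------------
# Contact potential
# ---------------------------------------------------------------------------

def _contact_type_indices(elements: Sequence[str]) -> np.ndarray:
    lookup = {t: i for i, t in enumerate(CONTACT_TYPES)}
    return np.array([lookup.get(e.strip().upper(), 0) for e in elements])


_CONTACT_MATRIX = np.array([
    [contact_value(a, b) for b in CONTACT_TYPES] for a in CONTACT_TYPES
])


def contact_energy(
    receptor_coords: np.ndarray,
    receptor_elements: Sequence[str],
    ligand_coords: np.ndarray,
    ligand_elements: Sequence[str],
    cutoff: float = 6.0,
    receptor_tree: cKDTree | None = None,
) -> float:
    """Sum of the coarse pair-potential over inter-molecular heavy-atom
    pairs within ``cutoff``.  Symmetric in molecule order; empty interface
    gives 0."""
    receptor_coords = np.asarray(receptor_coords, float)
    ligand_coords = np.asarray(ligand_coords, float)
    if len(receptor_coords) == 0 or len(ligand_coords) == 0:
        return 0.0
    tree = receptor_tree if receptor_tree is not None else cKDTree(receptor_coords)
    rec_types = _contact_type_indices(receptor_elements)
    lig_types = _contact_type_indices(ligand_elements)
    total = 0.0
    neighbor_lists = tree.query_ball_point(ligand_coords, r=cutoff)
    for lig_type, neighbors in zip(lig_types, neighbor_lists):
        if neighbors:
            total += float(np.sum(_CONTACT_MATRIX[lig_type, rec_types[neighbors]]))
    return total


# ---------------------------------------------------------------------------
# Poses
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """A scored rigid placement of the ligand in the receptor frame."""

    rotation_index: int
    rotation: np.ndarray
    translation: np.ndarray
    score_total: float
    score_components: dict

    def transform(self, coords: np.ndarray, centroid: np.ndarray) -> np.ndarray:
        """Apply the pose: rotate about the ligand centroid, then shift."""
        coords = np.asarray(coords, float)
        centroid = np.asarray(centroid, float)
        return (coords - centroid) @ self.rotation.T + centroid + self.translation


@dataclass
class PoseList:
    """Poses sorted by descending total score."""

    poses: list[Pose]
    receptor_id: str = ""
    ligand_id: str = ""
    ligand_centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.poses)

    def scores(self) -> np.ndarray:
        return np.array([p.score_total for p in self.poses])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["rank\tscore\tshape\telectrostatic\tcontact\t"
                 "rotation_index\ttx\tty\ttz"]
        for rank, p in enumerate(self.poses, start=1):
            c = p.score_components
            tx, ty, tz = p.translation
            lines.append(
                f"{rank}\t{p.score_total:.6f}\t{c.get('shape', 0.0):.6f}\t"
                f"{c.get('electrostatic', 0.0):.6f}\t{c.get('contact', 0.0):.6f}\t"
                f"{p.rotation_index}\t{tx:.3f}\t{ty:.3f}\t{tz:.3f}"
            )
        path.write_text("\n".join(lines) + "\n")
        sidecar = {
            "receptor_id": self.receptor_id,
            "ligand_id": self.ligand_id,
            "ligand_centroid": np.asarray(self.ligand_centroid).tolist(),
            "config": self.config,
        }
        config_path = path.with_suffix(path.suffix + ".config.json")
        config_path.write_text(json.dumps(sidecar, indent=2, default=str))
        return path


def read_poselist(path: str | Path) -> PoseList:
    """Rebuild a :class:`PoseList` from a TSV + its config sidecar."""
    path = Path(path)
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".config.json").read_text())
    config = sidecar["config"]
    rotations = rotation_set(float(config["rotation_step"]))
    poses: list[Pose] = []
    lines = path.read_text().strip().splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        rot_index = int(parts[5])
        poses.append(Pose(
            rotation_index=rot_index,
            rotation=rotations[rot_index],
            translation=np.array([float(parts[6]), float(parts[7]),
                                  float(parts[8])]),
            score_total=float(parts[1]),
            score_components={"shape": float(parts[2]),
                              "electrostatic": float(parts[3]),
                              "contact": float(parts[4])},
        ))
    return PoseList(
        poses,
        receptor_id=sidecar.get("receptor_id", ""),
        ligand_id=sidecar.get("ligand_id", ""),
        ligand_centroid=np.array(sidecar.get("ligand_centroid", [0, 0, 0]),
                                 dtype=float),
        config=config,
    )


def _overlap_components(
    receptor_grids: ScoreGrids, ligand_grids: ScoreGrids,
    offset: tuple[int, int, int],
) -> tuple[float, float, float]:
    """Exact surface/core/electrostatic overlap sums at one voxel offset."""
    n_rec = receptor_grids.core.shape
    n_lig = ligand_grids.core.shape
    rec_slices, lig_slices = [], []
    for k in range(3):
        r0 = max(0, offset[k])
        r1 = min(n_rec[k], n_lig[k] + offset[k])
        if r1 <= r0:
            return 0.0, 0.0, 0.0
        rec_slices.append(slice(r0, r1))
        lig_slices.append(slice(r0 - offset[k], r1 - offset[k]))
    rec_slices, lig_slices = tuple(rec_slices), tuple(lig_slices)
    surf = float(np.sum(receptor_grids.surface[rec_slices].astype(np.float64)
                        * ligand_grids.surface[lig_slices]))
    core = float(np.sum(receptor_grids.core[rec_slices].astype(np.float64)
                        * ligand_grids.core[lig_slices]))
    elec = -float(np.sum(receptor_grids.charge[rec_slices].astype(np.float64)
                         * ligand_grids.charge[lig_slices]))
    return surf, core, elec


def _pose_sort_key(entry: tuple) -> tuple:
    total, rot_index, shift = entry[0], entry[1], entry[2]
    return (-total, rot_index, tuple(np.round(shift, 6)))


def dock_rigid(
    receptor: StructureBundle,
    ligand: StructureBundle,
    config: DockConfig | None = None,
    ligand_model_index: int = 0,
) -> PoseList:
    """Exhaustive rigid-body scan: every sampled rotation, every translation.

    For each rotation the FFT translational scan is run and the best
    ``per_rotation_keep`` displacements enter a global candidate pool; the
    contact term is evaluated for the ``contact_pool`` best candidates and
    the final top-N poses are kept with full score decomposition.
    """
    config = config or DockConfig()
    rec_atoms = receptor.model(0)
    rec_coords = np.array([a.coords for a in rec_atoms])
    rec_elements = [a.element for a in rec_atoms]
    lig_atoms = ligand.model(ligand_model_index)
    lig_coords = np.array([a.coords for a in lig_atoms])
    lig_elements = [a.element for a in lig_atoms]
    centroid = lig_coords.mean(axis=0)

    lig_radius = float(np.max(np.linalg.norm(lig_coords - centroid, axis=1)))
    rec_margin = lig_radius + config.surface_thickness + config.spacing
    rec_charges = assign_charges(receptor)
    lig_charges = assign_charges(ligand, model_index=ligand_model_index)
    receptor_grids = build_grids(
        rec_coords, rec_charges.charges, config.spacing,
        config.surface_thickness, margin=rec_margin, elements=rec_elements,
        max_grid_dim=config.max_grid_dim,
    )
    receptor_tree = cKDTree(rec_coords)

    rotations = rotation_set(config.rotation_step)
    candidates: list[tuple] = []
    lig_margin = config.surface_thickness + config.spacing
    lig_dim = int(np.ceil((2 * lig_radius + 2 * lig_margin) / config.spacing)) + 2
    lig_dims = (lig_dim, lig_dim, lig_dim)

    n_rec = receptor_grids.core.shape
    out_shape = tuple(n_rec[k] + lig_dims[k] - 1 for k in range(3))
    padded = tuple(next_fast_len(s) for s in out_shape)
    f32 = np.float32
    f_surface = rfftn(receptor_grids.surface.astype(f32), padded)
    f_core = rfftn(receptor_grids.core.astype(f32), padded)
    f_charge = rfftn(receptor_grids.charge.astype(f32), padded)
    reorder = [np.mod(np.arange(-(lig_dims[k] - 1),
                                out_shape[k] - lig_dims[k] + 1), padded[k])
               for k in range(3)]
    reorder_ix = np.ix_(*reorder)

    for rot_index, rotation in enumerate(rotations):
        rotated = (lig_coords - centroid) @ rotation.T + centroid
        ligand_grids = build_grids(
            rotated, lig_charges.charges, config.spacing,
            config.surface_thickness, margin=lig_margin, elements=lig_elements,
            max_grid_dim=config.max_grid_dim, dims=lig_dims, dtype=f32,
        )
        f_comb = (
            config.weight_shape
            * (f_surface * np.conj(rfftn(ligand_grids.surface, padded))
               - config.core_penalty
               * (f_core * np.conj(rfftn(ligand_grids.core, padded))))
            - config.weight_electrostatic
            * (f_charge * np.conj(rfftn(ligand_grids.charge, padded)))
        )
        total = irfftn(f_comb, padded)[reorder_ix]
        flat = total.ravel()
        keep = min(config.per_rotation_keep, flat.size)
        top = np.argpartition(flat, -keep)[-keep:]
        for flat_index in top:
            d_index = np.unravel_index(int(flat_index), total.shape)
            offset = tuple(int(d_index[k]) - (lig_dims[k] - 1) for k in range(3))
            surf, core, elec = _overlap_components(receptor_grids, ligand_grids,
                                                   offset)
            shift = (receptor_grids.origin - ligand_grids.origin
                     + np.asarray(offset) * config.spacing)
            candidates.append((
                float(config.weight_shape
                      * (surf - config.core_penalty * core)
                      + config.weight_electrostatic * elec),
                rot_index, shift, surf, core, elec,
            ))

    candidates.sort(key=_pose_sort_key)
    pool = candidates[:max(config.top_n, min(len(candidates), config.contact_pool))]

    scored: list[tuple] = []
    for grid_total, rot_index, shift, surf, core, elec in pool:
        rotation = rotations[rot_index]
        placed = (lig_coords - centroid) @ rotation.T + centroid + shift
        contact = contact_energy(
            rec_coords, rec_elements, placed, lig_elements,
            cutoff=config.contact_cutoff, receptor_tree=receptor_tree,
        )
        shape = surf - config.core_penalty * core
        total = (config.weight_shape * shape
                 + config.weight_electrostatic * elec
                 + config.weight_contact * contact)
        scored.append((total, rot_index, shift, shape, surf, core, elec, contact))
    scored.sort(key=_pose_sort_key)

    poses = [
        Pose(
            rotation_index=rot_index,
            rotation=rotations[rot_index],
            translation=np.asarray(shift, float),
            score_total=total,
            score_components={
                "shape": shape,
                "surface_overlap": surf,
                "core_overlap": core,
                "electrostatic": elec,
                "contact": contact,
            },
        )
        for total, rot_index, shift, shape, surf, core, elec, contact
        in scored[:config.top_n]
    ]
    return PoseList(
        poses,
        receptor_id=receptor.identifier,
        ligand_id=f"{ligand.identifier}:{ligand_model_index}",
        ligand_centroid=centroid,
        config=config.snapshot(),
    )
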