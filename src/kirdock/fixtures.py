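"""Deterministic synthetic structures for end-to-end testing.

A toy C4 "channel" — four identical subunit strands descending a funnel
wall, with three named residue rings (turret / mid / pore) at distinct
depths and radii — plus a compact helical toy peptide with a basic
C-terminal tail.  Everything is generated from explicit geometry and a
single seeded generator, so the same parameters always give bit-identical
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sidechains import build_side_chain, enumerate_rotamers
from .errors import ParameterError
from .geometry import place_atom, rotation_about_axis
from .interface import RingDefinition
from .structio import AtomRecord, StructureBundle, one_to_three

__all__ = [
    "ToyRing",
    "ToyChannelParams",
    "ToyChannel",
    "make_toy_channel",
    "make_toy_peptide",
    "make_peptide",
    "build_backbone",
]

_BOND_CA_C = 1.52
_BOND_C_N = 1.33
_BOND_C_O = 1.23


def build_backbone(phis: np.ndarray, psis: np.ndarray) -> list[np.ndarray]:
    """Backbone N/CA/C/O coordinates from phi/psi torsions (omega = 180).

    Returns a flat list ``[N1, CA1, C1, O1, N2, ...]`` with ideal bond
    lengths and angles.
    """
    n_res = len(phis)
    if len(psis) != n_res:
        raise ParameterError("phi/psi lists must match")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    dummy = np.array([0.0, -1.0, 0.0])
    c = place_atom(dummy, n, ca, _BOND_CA_C, 111.0, float(phis[0]))
    atoms = [n, ca, c]
    coords: list[np.ndarray] = []
    for i in range(n_res):
        n_i, ca_i, c_i = atoms[3 * i], atoms[3 * i + 1], atoms[3 * i + 2]
        psi = float(psis[i])
        if i < n_res - 1:
            n_next = place_atom(n_i, ca_i, c_i, _BOND_C_N, 116.6, psi)
            ca_next = place_atom(ca_i, c_i, n_next, 1.458, 121.7, 180.0)
            c_next = place_atom(c_i, n_next, ca_next, _BOND_CA_C, 111.0,
                                float(phis[i + 1]))
            atoms.extend([n_next, ca_next, c_next])
        o_i = place_atom(n_i, ca_i, c_i, _BOND_C_O, 120.5, psi + 180.0)
        coords.extend([n_i, ca_i, c_i, o_i])
    return coords


def _backbone_between_ca(ca_path: np.ndarray, normals: np.ndarray) -> list[dict]:
    """Backbone atoms for a chain whose CA positions are prescribed.

    Each residue's C is placed 1.52 A from its CA, oriented so the next
    N (1.33 A further along the line to the next CA) remains 1.2-1.6 A
    from that CA — chemically sane bond lengths for any CA spacing in the
    buildable range.
    """
    n_res = len(ca_path)
    spacings = np.linalg.norm(np.diff(ca_path, axis=0), axis=1)
    if np.any(spacings < 1.8) or np.any(spacings > 4.25):
        raise ParameterError(
            f"CA spacing outside buildable range: {spacings.round(2)}"
        )
    residues: list[dict] = []
    n_atom = None
    for i in range(n_res):
        forward = (ca_path[i + 1] - ca_path[i] if i < n_res - 1
                   else ca_path[i] - ca_path[i - 1])
        gap = float(np.linalg.norm(forward))
        u = forward / gap
        normal = normals[i] - np.dot(normals[i], u) * u
        normal /= np.linalg.norm(normal)
        # pick the C orientation giving |C - next_CA| ~= 2.75 A
        target = np.clip(2.75, gap - _BOND_CA_C + 0.05, gap + _BOND_CA_C - 0.05)
        cos_phi = np.clip(
            (gap ** 2 + _BOND_CA_C ** 2 - target ** 2)
            / (2.0 * gap * _BOND_CA_C), -1.0, 1.0,
        )
        sin_phi = np.sqrt(1.0 - cos_phi ** 2)
        c_atom = ca_path[i] + _BOND_CA_C * (cos_phi * u + sin_phi * normal)
        if n_atom is None:  # chain start: mirror the C placement
            n_atom = ca_path[i] + 1.46 * (-cos_phi * u + sin_phi * normal)
        o_dir = normal + 0.35 * (c_atom - ca_path[i]) / _BOND_CA_C
        o_atom = c_atom + _BOND_C_O * o_dir / np.linalg.norm(o_dir)
        residues.append({"N": n_atom, "CA": ca_path[i], "C": c_atom, "O": o_atom})
        if i < n_res - 1:
            to_next = ca_path[i + 1] - c_atom
            n_atom = c_atom + _BOND_C_N * to_next / np.linalg.norm(to_next)
    return residues


def _min_clash_side_chain(letter, frame_n, frame_ca, frame_c, environment):
    """Least-clashing coarse rotamer (same sampling as the threading module)."""
    best = None
    for index, chis in enumerate(enumerate_rotamers(letter)):
        atoms = build_side_chain(letter, frame_n, frame_ca, frame_c, chis)
        if not atoms:
            return []
        coords = np.array([xyz for _, _, xyz in atoms])
        if len(environment):
            deltas = coords[:, None, :] - environment[None, :, :]
            min_dist = float(np.sqrt((deltas ** 2).sum(axis=-1)).min())
            n_clash = int((np.sqrt((deltas ** 2).sum(axis=-1)) < 2.4).sum())
        else:
            min_dist, n_clash = np.inf, 0
        key = (n_clash, -min_dist, index)
        if best is None or key < best[0]:
            best = (key, atoms)
    return best[1]


@dataclass(frozen=True)
class ToyRing:
    name: str
    depth: float          # z, A
    radius: float         # radial CA distance from the pore axis, A
    residue: str          # one-letter type


@dataclass(frozen=True)
class ToyChannelParams:
    n_residues_per_subunit: int = 9
    turret: ToyRing = ToyRing("turret", 14.0, 10.0, "D")
    mid: ToyRing = ToyRing("mid", 8.0, 7.2, "E")
    pore: ToyRing = ToyRing("pore", 0.0, 4.5, "Y")
    pocket_charge_pattern: str = "negative"   # negative | neutral | positive
    twist_per_residue: float = 8.0            # deg of azimuthal drift
    noise: float = 0.0                        # optional coordinate jitter, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues_per_subunit < 9:
            raise ParameterError("toy subunit needs >= 9 residues")
        for ring in (self.turret, self.mid, self.pore):
            if ring.radius <= 0:
                raise ParameterError(f"ring {ring.name}: radius must be > 0")


_PATTERN_RESIDUES = {
    "negative": ("D", "E", "Y"),
    "neutral": ("S", "S", "Y"),
    "positive": ("K", "K", "Y"),
}


@dataclass
class ToyChannel:
    structure: StructureBundle
    rings: list[RingDefinition]
    pocket_center: np.ndarray
    params: ToyChannelParams
    ring_residue_seqs: dict = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return self.structure.sequence(chain_id="A")


def make_toy_channel(params: ToyChannelParams | None = None) -> ToyChannel:
    """Build the toy C4 tetramer and its ring definitions.

    The subunit strand passes exactly through the three ring anchor points,
    so ring CA atoms sit at precisely the configured radii: opposing-chain
    ring diameter is exactly twice the radial placement.
    """
    params = params or ToyChannelParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_residues_per_subunit
    ring_index = {1: params.turret, (n + 1) // 2: params.mid, n - 1: params.pore}
    turret_letter, mid_letter, pore_letter = _PATTERN_RESIDUES[
        params.pocket_charge_pattern]
    letters = {1: turret_letter, (n + 1) // 2: mid_letter, n - 1: pore_letter}

    # piecewise-linear (radius, depth) path through the ring anchors
    anchors = [
        (0, params.turret.radius + 1.5, params.turret.depth + 2.5),
        (1, params.turret.radius, params.turret.depth),
        ((n + 1) // 2, params.mid.radius, params.mid.depth),
        (n - 1, params.pore.radius, params.pore.depth),
        (n, params.pore.radius + 0.5, params.pore.depth - 2.5),
    ]
    radii = np.empty(n)
    depths = np.empty(n)
    for (i0, r0, z0), (i1, r1, z1) in zip(anchors[:-1], anchors[1:]):
        for i in range(i0, min(i1 + 1, n)):
            f = (i - i0) / max(1, (i1 - i0))
            radii[i] = r0 + f * (r1 - r0)
            depths[i] = z0 + f * (z1 - z0)

    thetas = np.radians(params.twist_per_residue) * (np.arange(n) - n / 2.0)
    ca_path = np.column_stack([
        radii * np.cos(thetas), radii * np.sin(thetas), depths,
    ])
    if params.noise > 0:
        jitter = rng.normal(0.0, params.noise, size=(n, 3))
        for i in ring_index:  # ring anchors stay exact
            jitter[i] = 0.0
        ca_path = ca_path + jitter

    # outward normals keep carbonyls on the wall, side chains free to point in
    normals = np.column_stack([
        np.cos(thetas), np.sin(thetas), np.zeros(n),
    ])
    backbone = _backbone_between_ca(ca_path, normals)

    sequence = "".join(
        letters.get(i, "GA"[i % 2]) for i in range(n)
    )
    subunit_atoms: list[AtomRecord] = []
    all_backbone = np.array([xyz for res in backbone for xyz in res.values()])
    extra: list[np.ndarray] = []
    for i, res in enumerate(backbone):
        letter = sequence[i]
        resname = one_to_three(letter)
        for name in ("N", "CA", "C", "O"):
            subunit_atoms.append(AtomRecord(
                serial=0, name=name, element=name[0], residue_name=resname,
                chain_id="A", residue_seq=i + 1, coords=res[name],
            ))
        others = np.delete(all_backbone, slice(4 * i, 4 * i + 4), axis=0)
        environment = np.vstack([others] + extra) if extra else others
        side = _min_clash_side_chain(letter, res["N"], res["CA"], res["C"],
                                     environment)
        for name, element, xyz in side:
            subunit_atoms.append(AtomRecord(
                serial=0, name=name, element=element, residue_name=resname,
                chain_id="A", residue_seq=i + 1, coords=xyz,
            ))
        if side:
            extra.append(np.array([x for _, _, x in side]))

    atoms: list[AtomRecord] = []
    serial = 0
    for k, chain_id in enumerate("ABCD"):
        rot = rotation_about_axis([0, 0, 1], 90.0 * k)
        for atom in subunit_atoms:
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=atom.name, element=atom.element,
                residue_name=atom.residue_name, chain_id=chain_id,
                residue_seq=atom.residue_seq,
                coords=rot @ atom.coords,
            ))

    rings = [
        RingDefinition("turret", 2, "CA"),
        RingDefinition("mid", (n + 1) // 2 + 1, "CA"),
        RingDefinition("pore", n, "CA"),
    ]
    ring_residue_seqs = {"turret": 2, "mid": (n + 1) // 2 + 1, "pore": n}
    pocket_center = np.array([0.0, 0.0, params.mid.depth])
    structure = StructureBundle(
        [atoms], identifier=f"toy-channel-{params.pocket_charge_pattern}",
    )
    return ToyChannel(structure, rings, pocket_center, params, ring_residue_seqs)


def make_peptide(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "P",
    seed: int = 0,
    n_models: int = 1,
    mobile_from: int | None = None,
    jitter: float = 1.0,
    first_seq: int = 1,
) -> StructureBundle:
    """Build an idealized peptide of arbitrary sequence at uniform phi/psi.

    Side chains use the least-clashing coarse rotamer.  With
    ``n_models > 1``, residues from ``mobile_from`` (1-based, default:
    rigid) onward receive per-model rigid per-residue offsets drawn from
    the seeded generator.
    """
    sequence = sequence.upper()
    length = len(sequence)
    if length < 2:
        raise ParameterError("peptide needs at least 2 residues")
    rng = np.random.default_rng(seed)
    phis = np.full(length, phi)
    psis = np.full(length, psi)
    backbone = build_backbone(phis, psis)

    atoms: list[AtomRecord] = []
    all_backbone = np.array(backbone)
    extra: list[np.ndarray] = []
    for i, letter in enumerate(sequence):
        resname = one_to_three(letter)
        n_i, ca_i, c_i, o_i = backbone[4 * i:4 * i + 4]
        for name, xyz in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i)):
            atoms.append(AtomRecord(
                serial=0, name=name, element=name[0], residue_name=resname,
                chain_id=chain_id, residue_seq=first_seq + i, coords=xyz,
            ))
        others = np.delete(all_backbone, slice(4 * i, 4 * i + 4), axis=0)
        environment = np.vstack([others] + extra) if extra else others
        side = _min_clash_side_chain(letter, n_i, ca_i, c_i, environment)
        for name, element, xyz in side:
            atoms.append(AtomRecord(
                serial=0, name=name, element=element, residue_name=resname,
                chain_id=chain_id, residue_seq=first_seq + i, coords=xyz,
            ))
        if side:
            extra.append(np.array([x for _, _, x in side]))
    oxt = place_atom(backbone[-4], backbone[-3], backbone[-2],
                     1.25, 117.0, float(psis[-1]))
    atoms.append(AtomRecord(
        serial=0, name="OXT", element="O", residue_name=one_to_three(sequence[-1]),
        chain_id=chain_id, residue_seq=first_seq + length - 1, coords=oxt,
    ))
    for serial, atom in enumerate(atoms, start=1):
        atom.serial = serial

    models = [atoms]
    mobile_start = (first_seq + mobile_from - 1 if mobile_from is not None
                    else first_seq + length)  # default: nothing mobile
    for _ in range(1, n_models):
        offsets = {seq: rng.normal(0.0, jitter, size=3)
                   for seq in range(mobile_start, first_seq + length)}
        model = []
        for atom in atoms:
            shift = offsets.get(atom.residue_seq, np.zeros(3))
            model.append(atom.moved(atom.coords + shift))
        models.append(model)
    return StructureBundle(models, identifier=f"peptide-{sequence[:8]}")


def make_toy_peptide(
    length: int = 8,
    basic_tail: int = 3,
    seed: int = 0,
    n_models: int = 1,
    tail_jitter: float = 1.0,
) -> StructureBundle:
    """Compact helical peptide with ``basic_tail`` C-terminal lysines.

    With ``n_models > 1`` additional conformers are emitted in which only
    the tail residues are displaced (rigid per-residue offsets drawn from
    the seeded generator), mimicking a mobile basic C-terminus.
    """
    if length < 5:
        raise ParameterError("peptide length must be >= 5")
    if basic_tail > length:
        raise ParameterError("basic tail longer than the peptide")
    core = "".join("AVSLIATG"[i % 8] for i in range(length - basic_tail))
    sequence = core + "K" * basic_tail
    bundle = make_peptide(sequence, seed=seed, n_models=n_models,
                          mobile_from=length - basic_tail + 1,
                          jitter=tail_jitter)
    bundle.identifier = f"toy-peptide-{length}-{basic_tail}"
    return bundle
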