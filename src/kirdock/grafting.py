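"""Chimeric subunit construction by fixed-backbone vestibule threading.

The defining guarantee of this "limited" modelling style is that backbone
atoms (N, CA, C, O) and every atom of an unchanged residue are copied
bit-identically from the template; only substituted residues receive new
side chains, placed from idealized rotamers with clash minimization and no
global relaxation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._sidechains import build_side_chain, enumerate_rotamers
from .errors import AddressingError, MutationError, SpliceError
from .geometry import dihedral
from .structio import (
    AtomRecord,
    Residue,
    SegmentSpan,
    StructureBundle,
    one_to_three,
    resolve_span,
)

__all__ = [
    "ChimeraSpec",
    "BuildReport",
    "splice_vestibule",
    "apply_mutations",
    "thread_chimera",
    "ramachandran_report",
    "mutation_label",
]

#: Heavy-atom pair distance treated as a steric clash during rotamer search.
CLASH_DISTANCE = 2.4
#: Minimum separation below which a chosen rotamer is flagged in the report.
SEVERE_CLASH_DISTANCE = 2.0

_BACKBONE = ("N", "CA", "C", "O", "OXT")


def mutation_label(mutations: Sequence[tuple[int, str, str]]) -> str:
    """Canonical label like ``H8Y+A11D+C44F`` (sorted by position)."""
    return "+".join(f"{f}{p}{t}" for p, f, t in sorted(mutations)) or "wt"


@dataclass(frozen=True)
class ChimeraSpec:
    """Recipe for one chimeric subunit.

    ``mutations`` use 1-based positions within ``replacement_sequence``
    ("vestibule positions"); ``position_map`` optionally records the
    corresponding native numbering of the donor channel.
    """

    template_id: str
    span: SegmentSpan
    replacement_sequence: str
    mutations: tuple[tuple[int, str, str], ...] = ()
    label: str = ""
    position_map: tuple[tuple[int, int], ...] = ()

    def native_position(self, vestibule_position: int) -> int | None:
        return dict(self.position_map).get(vestibule_position)


def splice_vestibule(
    template_sequence: str,
    span_offsets: tuple[int, int],
    replacement: str,
    tolerance: int = 0,
) -> str:
    """Replace ``template_sequence[start:stop]`` with ``replacement``.

    Offsets are 0-based, half-open.  Length differences beyond ``tolerance``
    are rejected — no silent gap modelling.
    """
    start, stop = span_offsets
    if not (0 <= start <= stop <= len(template_sequence)):
        raise SpliceError(f"offsets {span_offsets} invalid for length "
                          f"{len(template_sequence)} sequence")
    span_len = stop - start
    if abs(len(replacement) - span_len) > tolerance:
        raise SpliceError(
            f"replacement length {len(replacement)} vs span length {span_len} "
            f"exceeds tolerance {tolerance}"
        )
    return template_sequence[:start] + replacement + template_sequence[stop:]


def apply_mutations(spec: ChimeraSpec) -> ChimeraSpec:
    """Apply the spec's mutation list to its replacement sequence.

    The result is order-independent; each mutation's ``from_aa`` must match
    the current sequence at that (1-based) position.
    """
    seq = list(spec.replacement_sequence)
    for position, from_aa, to_aa in sorted(spec.mutations):
        if not (1 <= position <= len(seq)):
            raise MutationError(f"position {position} outside 1..{len(seq)}")
        if seq[position - 1] != from_aa.upper():
            raise MutationError(
                f"mutation {from_aa}{position}{to_aa}: sequence has "
                f"{seq[position - 1]!r} at position {position}"
            )
        seq[position - 1] = to_aa.upper()
    return replace(spec, replacement_sequence="".join(seq), mutations=())


@dataclass
class BuildReport:
    """Provenance of one threading run: rotamers chosen, clashes seen."""

    label: str = ""
    substitutions: list[dict] = field(default_factory=list)
    clashes: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _rotamer_clash_score(
    coords: np.ndarray, environment: cKDTree | None
) -> tuple[int, float]:
    """(number of clashing environment atoms, minimum separation)."""
    if environment is None or coords.size == 0:
        return 0, np.inf
    dists, _ = environment.query(coords, k=1)
    return int(np.sum(dists < CLASH_DISTANCE)), float(np.min(dists))


def _place_residue_side_chain(
    residue: Residue,
    new_letter: str,
    environment_coords: np.ndarray,
) -> tuple[list[tuple[str, str, np.ndarray]], dict]:
    """Pick the least-clashing coarse rotamer for a substituted residue."""
    frame = residue.coords(("N", "CA", "C"))
    tree = cKDTree(environment_coords) if len(environment_coords) else None
    best = None
    for rot_index, chis in enumerate(enumerate_rotamers(new_letter)):
        atoms = build_side_chain(new_letter, frame[0], frame[1], frame[2], chis)
        coords = np.array([xyz for _, _, xyz in atoms]) if atoms else np.zeros((0, 3))
        n_clash, min_dist = _rotamer_clash_score(coords, tree)
        key = (n_clash, -min_dist, rot_index)  # fewest clashes, then widest gap
        if best is None or key < best[0]:
            best = (key, atoms, chis, n_clash, min_dist)
    _, atoms, chis, n_clash, min_dist = best
    info = {
        "residue_seq": residue.residue_seq,
        "chain_id": residue.chain_id,
        "to": new_letter,
        "chis": list(chis),
        "n_clashes": n_clash,
        "min_contact_distance": None if np.isinf(min_dist) else round(min_dist, 3),
    }
    return atoms, info


def thread_chimera(
    template: StructureBundle,
    spec: ChimeraSpec,
    model_index: int = 0,
    length_tolerance: int = 0,
) -> tuple[StructureBundle, BuildReport]:
    """Thread a chimeric sequence onto the fixed template backbone.

    Returns the single-chain subunit plus a :class:`BuildReport`.  Residues
    whose identity is unchanged are copied verbatim; substituted residues
    keep template backbone atoms and get idealized side chains chosen to
    minimize steric clash.  Irreparable clashes are recorded in the report,
    never silently accepted.
    """
    residues = [r for r in template.residues(model_index)
                if r.chain_id == spec.span.chain_id]
    if not residues:
        raise AddressingError(f"chain {spec.span.chain_id!r} not in template")
    i0, i1 = resolve_span(residues, spec.span)
    template_seq = "".join(r.letter for r in residues)
    chimera_seq = splice_vestibule(
        template_seq, (i0, i1 + 1), spec.replacement_sequence.upper(),
        tolerance=length_tolerance,
    )
    if len(chimera_seq) != len(residues):
        raise SpliceError("length-changing splices are not threadable "
                          "(fixed-backbone guarantee)")

    report = BuildReport(label=spec.label or mutation_label(spec.mutations))
    changed = [j for j, r in enumerate(residues) if r.letter != chimera_seq[j]]

    # environment = every atom that is certain to survive unchanged
    kept_atoms: list[AtomRecord] = []
    for j, residue in enumerate(residues):
        if j in changed:
            kept_atoms.extend(a for a in residue.atoms if a.name in _BACKBONE)
        else:
            kept_atoms.extend(residue.atoms)

    new_models: list[AtomRecord] = []
    placed_extra: list[np.ndarray] = []
    for j, residue in enumerate(residues):
        letter = chimera_seq[j]
        if j not in changed:
            new_models.extend(replace(a) for a in residue.atoms)
            continue
        env_coords = np.array([a.coords for a in kept_atoms
                               if a.residue_key != residue.key])
        new_name = one_to_three(letter)
        backbone = [replace(a, residue_name=new_name)
                    for a in residue.atoms if a.name in _BACKBONE]
        if len([a for a in backbone if a.name in ("N", "CA", "C")]) < 3:
            raise AddressingError(
                f"residue {residue.chain_id}{residue.residue_seq}: incomplete "
                "backbone, cannot thread"
            )
        environment = env_coords
        if placed_extra:
            environment = np.vstack([env_coords] + placed_extra)
        side_atoms, info = _place_residue_side_chain(residue, letter, environment)
        report.substitutions.append(info)
        if info["min_contact_distance"] is not None and \
                info["min_contact_distance"] < SEVERE_CLASH_DISTANCE:
            report.clashes.append(info)
            report.warnings.append(
                f"residue {residue.chain_id}{residue.residue_seq}->{letter}: "
                f"best rotamer still clashes "
                f"(min {info['min_contact_distance']} A)"
            )
        new_models.extend(backbone)
        for name, element, xyz in side_atoms:
            new_models.append(AtomRecord(
                serial=0, name=name, element=element, residue_name=new_name,
                chain_id=residue.chain_id, residue_seq=residue.residue_seq,
                insertion_code=residue.insertion_code, coords=xyz,
            ))
        if side_atoms:
            placed_extra.append(np.array([xyz for _, _, xyz in side_atoms]))

    for serial, atom in enumerate(new_models, start=1):
        atom.serial = serial
    subunit = StructureBundle(
        [new_models],
        identifier=spec.label or f"{spec.template_id}-chimera",
    )
    return subunit, report


# ---------------------------------------------------------------------------
# Ramachandran sanity check
# ---------------------------------------------------------------------------

#: Rectangular region boxes (an explicit approximation; the favored regions
#: are named A/B/L but published boundaries are contour-based).
_REGIONS = {
    "A": ((-160.0, -20.0), (-120.0, 50.0)),
    "L": ((20.0, 160.0), (-60.0, 90.0)),
}


def _classify_phi_psi(phi: float, psi: float) -> str:
    (amin, amax), (bmin, bmax) = _REGIONS["A"]
    if amin <= phi <= amax and bmin <= psi < bmax:
        return "A"
    if -180.0 <= phi <= -20.0 and (50.0 <= psi <= 180.0 or -180.0 <= psi < -170.0):
        return "B"
    (amin, amax), (bmin, bmax) = _REGIONS["L"]
    if amin <= phi <= amax and bmin <= psi <= bmax:
        return "L"
    return "outlier"


def ramachandran_report(
    subunit: StructureBundle, model_index: int = 0
) -> dict:
    """Per-residue phi/psi classes plus a favored-fraction summary.

    Chain termini (undefined phi or psi) and residues with missing backbone
    atoms are reported as unevaluable and excluded from the fraction.
    """
    rows: list[dict] = []
    counts = {"A": 0, "B": 0, "L": 0, "outlier": 0, "unevaluable": 0}
    for chain_id in subunit.chain_ids(model_index):
        residues = [r for r in subunit.residues(model_index)
                    if r.chain_id == chain_id]
        for j, residue in enumerate(residues):
            row = {
                "chain_id": chain_id,
                "residue_seq": residue.residue_seq,
                "residue": residue.name,
                "phi": None, "psi": None, "category": "unevaluable",
            }
            if 0 < j < len(residues) - 1:
                prev_c = residues[j - 1].atom("C")
                n, ca, c = (residue.atom(x) for x in ("N", "CA", "C"))
                next_n = residues[j + 1].atom("N")
                if all(a is not None for a in (prev_c, n, ca, c, next_n)):
                    phi = dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
                    psi = dihedral(n.coords, ca.coords, c.coords, next_n.coords)
                    row.update(phi=round(phi, 2), psi=round(psi, 2),
                               category=_classify_phi_psi(phi, psi))
            counts[row["category"]] += 1
            rows.append(row)
    evaluable = sum(counts[k] for k in ("A", "B", "L", "outlier"))
    favored = sum(counts[k] for k in ("A", "B", "L"))
    return {
        "residues": rows,
        "counts": counts,
        "n_evaluable": evaluable,
        "fraction_favored": favored / evaluable if evaluable else float("nan"),
    }
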