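"""Structure and sequence I/O, addressing, and rigid superposition.

All coordinates are in Angstrom.  Author (PDB) numbering is authoritative
throughout: residues are addressed by ``(chain_id, residue_seq,
insertion_code)`` exactly as deposited.  Hydrogens are dropped on read and
the highest-occupancy alternate location is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import (
    AddressingError,
    EmptyStructureError,
    ParameterError,
    ShapeError,
    StructureParseError,
)

__all__ = [
    "AtomRecord",
    "StructureBundle",
    "SegmentSpan",
    "Residue",
    "read_structure",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "extract_segment_sequence",
    "superpose",
    "iter_residues",
    "three_to_one",
    "one_to_three",
]

#: 3-letter -> 1-letter residue codes (upper-case keys).
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}

#: HETATM residue names retained by default (structural potassium ions).
_DEFAULT_KEEP_HET = frozenset({"K", "POT"})


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue code to 1-letter; non-standard codes -> ``X``."""
    return _THREE_TO_ONE.get(resname.strip().upper(), "X")


def one_to_three(letter: str) -> str:
    try:
        return _ONE_TO_THREE[letter.upper()]
    except KeyError as exc:
        raise AddressingError(f"no 3-letter code for residue letter {letter!r}") from exc


@dataclass(slots=True)
class AtomRecord:
    """A single heavy atom with author addressing."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ShapeError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureParseError(f"atom {self.name}: empty element")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    def moved(self, coords: np.ndarray) -> "AtomRecord":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(slots=True)
class Residue:
    """Atoms of one residue, in file order."""

    chain_id: str
    residue_seq: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def letter(self) -> str:
        return three_to_one(self.name)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.coords for a in self.atoms])
        picked = [self.atom(n) for n in names]
        missing = [n for n, a in zip(names, picked) if a is None]
        if missing:
            raise AddressingError(
                f"residue {self.name} {self.chain_id}{self.residue_seq}: "
                f"missing atoms {missing}"
            )
        return np.array([a.coords for a in picked])


def iter_residues(atoms: Iterable[AtomRecord]) -> Iterator[Residue]:
    """Group a flat atom list into residues, preserving file order."""
    current: Residue | None = None
    for atom in atoms:
        if current is None or atom.residue_key != current.key:
            if current is not None:
                yield current
            current = Residue(
                atom.chain_id, atom.residue_seq, atom.insertion_code,
                atom.residue_name, [],
            )
        current.atoms.append(atom)
    if current is not None:
        yield current


@dataclass
class StructureBundle:
    """One or more models (e.g. an NMR conformer bundle) of the same molecule."""

    models: list[list[AtomRecord]]
    identifier: str = ""
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise EmptyStructureError(f"{self.identifier or 'structure'}: no models")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model(self, index: int = 0) -> list[AtomRecord]:
        return self.models[index]

    def residues(self, model_index: int = 0) -> list[Residue]:
        return list(iter_residues(self.models[model_index]))

    def chain_ids(self, model_index: int = 0) -> list[str]:
        seen: list[str] = []
        for atom in self.models[model_index]:
            if atom.chain_id not in seen:
                seen.append(atom.chain_id)
        return seen

    def chain_atoms(self, chain_id: str, model_index: int = 0) -> list[AtomRecord]:
        return [a for a in self.models[model_index] if a.chain_id == chain_id]

    def coords(
        self,
        model_index: int = 0,
        atom_names: Sequence[str] | None = None,
        chain_id: str | None = None,
    ) -> np.ndarray:
        atoms = self.models[model_index]
        if chain_id is not None:
            atoms = [a for a in atoms if a.chain_id == chain_id]
        if atom_names is not None:
            wanted = set(atom_names)
            atoms = [a for a in atoms if a.name in wanted]
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms])

    def sequence(self, chain_id: str | None = None, model_index: int = 0) -> str:
        atoms = self.models[model_index]
        if chain_id is not None:
            atoms = [a for a in atoms if a.chain_id == chain_id]
        return "".join(r.letter for r in iter_residues(atoms))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureBundle":
        """Apply ``x -> R x + t`` to every atom of every model."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_models = []
        for model in self.models:
            coords = np.array([a.coords for a in model])
            moved = coords @ rotation.T + translation
            new_models.append([a.moved(c) for a, c in zip(model, moved)])
        return StructureBundle(new_models, self.identifier, self.source_path)


@dataclass(frozen=True)
class SegmentSpan:
    """An inclusive author-numbering residue span on one chain."""

    chain_id: str
    start: tuple[int, str]
    end: tuple[int, str]

    def __post_init__(self) -> None:
        if _span_key(self.start) > _span_key(self.end):
            raise AddressingError(
                f"span start {self.start} after end {self.end} (author order)"
            )

    @classmethod
    def of(cls, chain_id: str, start_seq: int, end_seq: int,
           start_icode: str = "", end_icode: str = "") -> "SegmentSpan":
        return cls(chain_id, (start_seq, start_icode), (end_seq, end_icode))


def _span_key(pos: tuple[int, str]) -> tuple[int, str]:
    seq, icode = pos
    return (seq, icode or "")


def resolve_span(residues: Sequence[Residue], span: SegmentSpan) -> tuple[int, int]:
    """Return (start_index, end_index) of ``span`` within a residue list.

    Indices are inclusive positions into the file-order residue list of the
    span's chain.  Raises :class:`AddressingError` when either endpoint is
    absent.
    """
    chain = [r for r in residues if r.chain_id == span.chain_id]
    if not chain:
        raise AddressingError(f"chain {span.chain_id!r} not found")
    keys = [(r.residue_seq, r.insertion_code or "") for r in chain]
    try:
        i0 = keys.index(_span_key(span.start))
        i1 = keys.index(_span_key(span.end))
    except ValueError as exc:
        raise AddressingError(f"span {span} not resolvable in chain") from exc
    if i1 < i0:
        raise AddressingError(f"span {span}: end precedes start in file order")
    return i0, i1


def extract_segment_sequence(
    structure: StructureBundle, span: SegmentSpan, model_index: int = 0
) -> str:
    """One-letter sequence of an inclusive span (non-standard residues -> X)."""
    residues = [r for r in structure.residues(model_index) if r.chain_id == span.chain_id]
    i0, i1 = resolve_span(residues, span)
    return "".join(r.letter for r in residues[i0:i1 + 1])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    dialect: str = "pdb",
    keep_hetero: str = "ions",
) -> StructureBundle:
    """Read a (possibly multi-model) PDB file into a :class:`StructureBundle`.

    Hydrogens and waters are dropped.  HETATM records are stripped except
    structural potassium ions (``keep_hetero='ions'``, the default);
    ``keep_hetero='all'`` retains every non-water HETATM and
    ``keep_hetero='none'`` strips all of them.
    """
    if dialect != "pdb":
        raise ParameterError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file not found")
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        bio_structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    models: list[list[AtomRecord]] = []
    for bio_model in bio_structure:
        atoms: list[AtomRecord] = []
        for bio_chain in bio_model:
            for bio_res in bio_chain:
                hetflag, resseq, icode = bio_res.id
                hetero = hetflag.strip() != ""
                if hetflag == "W":
                    continue
                resname = bio_res.get_resname().strip()
                if hetero:
                    if keep_hetero == "none":
                        continue
                    if keep_hetero == "ions" and resname not in _DEFAULT_KEEP_HET:
                        continue
                for bio_atom in bio_res:  # selected (highest-occupancy) altloc
                    element = (bio_atom.element or "").strip()
                    if element in ("H", "D"):
                        continue
                    atoms.append(AtomRecord(
                        serial=bio_atom.serial_number or len(atoms) + 1,
                        name=bio_atom.get_name(),
                        element=element or bio_atom.get_name()[0],
                        residue_name=resname,
                        chain_id=bio_chain.id,
                        residue_seq=resseq,
                        insertion_code=icode.strip(),
                        coords=np.asarray(bio_atom.coord, dtype=float),
                        occupancy=float(bio_atom.occupancy or 1.0),
                        altloc=(bio_atom.get_altloc() or "").strip(),
                        hetero=hetero,
                    ))
        if atoms:
            models.append(atoms)
    if not models:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    return StructureBundle(models, identifier=path.stem, source_path=str(path))


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(atom: AtomRecord, serial: int) -> str:
    record = "HETATM" if atom.hetero else "ATOM  "
    x, y, z = atom.coords
    return (
        f"{record}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc or ' '}{atom.residue_name:>3s} {atom.chain_id}"
        f"{atom.residue_seq:>4d}{atom.insertion_code or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_structure(structure: StructureBundle, path: str | Path) -> Path:
    """Write a bundle as PDB; round-trip read preserves atoms and models."""
    if not any(structure.models):
        raise EmptyStructureError("refusing to write a structure with no atoms")
    path = Path(path)
    lines: list[str] = []
    multi = structure.n_models > 1
    for model_index, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {model_index:>4d}")
        serial = 0
        prev_chain: str | None = None
        for atom in model:
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            serial += 1
            lines.append(_atom_line(atom, serial))
            prev_chain = atom.chain_id
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file as an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``mobile @ rotation.T + translation ~= target``.  The rotation is proper
    (determinant +1).  Collinear/degenerate point sets are flagged with a
    warning but still produce a best-fit result.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError(f"point sets must match: {mobile.shape} vs {target.shape}")
    if len(mobile) < 3:
        raise ShapeError("need at least 3 points for a rigid superposition")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    covariance = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(covariance)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        warnings.warn("degenerate (collinear) point set in superposition",
                      stacklevel=2)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = tc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rotation, translation, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) root-mean-square deviation between matched point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"point sets must match: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
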