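"""Idealized side-chain internal-coordinate templates.

Each heavy atom is placed by natural extension from three reference atoms
with ideal bond lengths and angles.  Torsions are either fixed (ring and
planar-group geometry) or symbolic ``("chi", k, offset)`` terms resolved
against a sampled rotamer.  Geometry is idealized, not library-derived; it
is intended for clash-aware threading, not refinement.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np

from .geometry import place_atom

# (atom, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
# torsion: float (fixed, degrees) or ("chi", index, offset_degrees)
_CB = ("CB", "C", ("N", "C", "CA"), 1.53, 110.6, -122.6)

SIDECHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG", "O", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 0, 0.0))],
    "C": [_CB, ("SG", "S", ("N", "CA", "CB"), 1.81, 114.4, ("chi", 0, 0.0))],
    "T": [_CB,
          ("OG1", "O", ("N", "CA", "CB"), 1.42, 109.6, ("chi", 0, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 0, -120.0))],
    "V": [_CB,
          ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 0, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 0, 122.0))],
    "I": [_CB,
          ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 0, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 0, -122.0)),
          ("CD1", "C", ("CA", "CB", "CG1"), 1.53, 114.0, ("chi", 1, 0.0))],
    "L": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 0, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.53, 110.7, ("chi", 1, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.53, 110.7, ("chi", 1, 122.0))],
    "M": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 0, 0.0)),
          ("SD", "S", ("CA", "CB", "CG"), 1.81, 112.7, ("chi", 1, 0.0)),
          ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 2, 0.0))],
    "P": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.50, 104.0, -25.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.51, 105.0, 35.0)],
    "D": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 113.0, ("chi", 0, 0.0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.25, 119.0, ("chi", 1, 0.0)),
          ("OD2", "O", ("CA", "CB", "CG"), 1.25, 119.0, ("chi", 1, 180.0))],
    "N": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 113.0, ("chi", 0, 0.0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.23, 121.0, ("chi", 1, 0.0)),
          ("ND2", "N", ("CA", "CB", "CG"), 1.33, 117.0, ("chi", 1, 180.0))],
    "E": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 0, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 113.0, ("chi", 1, 0.0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.25, 119.0, ("chi", 2, 0.0)),
          ("OE2", "O", ("CB", "CG", "CD"), 1.25, 119.0, ("chi", 2, 180.0))],
    "Q": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 0, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 113.0, ("chi", 1, 0.0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.23, 121.0, ("chi", 2, 0.0)),
          ("NE2", "N", ("CB", "CG", "CD"), 1.33, 117.0, ("chi", 2, 180.0))],
    "K": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 0, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.0, ("chi", 1, 0.0)),
          ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.0, ("chi", 2, 0.0)),
          ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.0, ("chi", 3, 0.0))],
    "R": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 0, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.0, ("chi", 1, 0.0)),
          ("NE", "N", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 2, 0.0)),
          ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.0, ("chi", 3, 0.0)),
          ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
          ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "H": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.49, 114.0, ("chi", 0, 0.0)),
          ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.0, ("chi", 1, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.36, 131.0, ("chi", 1, 180.0)),
          ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
          ("NE2", "N", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0)],
    "F": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, ("chi", 0, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 1, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 1, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "Y": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, ("chi", 0, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 1, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 1, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
          ("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0)],
    "W": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, ("chi", 0, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.37, 127.0, ("chi", 1, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.43, 127.0, ("chi", 1, 180.0)),
          ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.0, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.0, 180.0),
          ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.0, 0.0),
          ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.0, 180.0),
          ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.0, 180.0),
          ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.37, 117.0, 180.0)],
}

#: Sampled values (degrees) for each rotatable torsion.
CHI_SAMPLES = (-60.0, 60.0, 180.0)


def chi_count(letter: str) -> int:
    n = 0
    for entry in SIDECHAIN_TOPOLOGY.get(letter.upper(), []):
        torsion = entry[5]
        if isinstance(torsion, tuple):
            n = max(n, torsion[1] + 1)
    return n


def enumerate_rotamers(letter: str) -> list[tuple[float, ...]]:
    """All chi-angle combinations from the coarse sample set, in a fixed order."""
    n = chi_count(letter)
    if n == 0:
        return [()]
    return list(product(CHI_SAMPLES, repeat=n))


def build_side_chain(
    letter: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    chis: Sequence[float] = (),
) -> list[tuple[str, str, np.ndarray]]:
    """Heavy side-chain atoms ``(name, element, coords)`` for one residue.

    The backbone frame is given by the residue's own N, CA and C atoms.
    """
    letter = letter.upper()
    if letter not in SIDECHAIN_TOPOLOGY:
        raise KeyError(f"no side-chain template for residue {letter!r}")
    placed: dict[str, np.ndarray] = {
        "N": np.asarray(n, float),
        "CA": np.asarray(ca, float),
        "C": np.asarray(c, float),
    }
    out: list[tuple[str, str, np.ndarray]] = []
    for name, element, (ra, rb, rc), bond, angle, torsion in SIDECHAIN_TOPOLOGY[letter]:
        if isinstance(torsion, tuple):
            _, idx, offset = torsion
            tau = float(chis[idx]) + offset
        else:
            tau = torsion
        xyz = place_atom(placed[ra], placed[rb], placed[rc], bond, angle, tau)
        placed[name] = xyz
        out.append((name, element, xyz))
    return out
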