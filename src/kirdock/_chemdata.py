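"""Bundled chemical parameter tables (radii, charge groups, contact types)."""

from __future__ import annotations

#: Bondi-style van der Waals radii by element; fallback 1.8 A.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "K": 2.75,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.8


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)


#: Formal charge groups at pH 7: residue -> {atom: charge}.
#: Charge is spread evenly over the group's equivalent heavy atoms.
SIDECHAIN_CHARGES = {
    "ARG": {"NH1": 0.5, "NH2": 0.5},
    "LYS": {"NZ": 1.0},
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
}

#: Hydrogen-bond donor heavy atoms per residue (backbone N handled separately).
HBOND_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

#: Hydrogen-bond acceptor heavy atoms per residue (backbone O handled
#: separately; carbonyl O of every residue is an acceptor).
HBOND_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

#: Coarse element classes for the contact pair potential.
CONTACT_TYPES = ("C", "N", "O", "S")

#: Symmetric contact pair potential (dimensionless, higher = more
#: favorable), applied per inter-molecular heavy-atom pair within the
#: cutoff.  Values are a coarse declared-arbitrary analogue of
#: atomic-contact-energy statistics: hydrophobic carbon packing and
#: polar-pair contacts reward, like-polar contacts mildly penalize.
CONTACT_TABLE = {
    ("C", "C"): 0.40,
    ("C", "N"): 0.10,
    ("C", "O"): 0.10,
    ("C", "S"): 0.30,
    ("N", "N"): -0.10,
    ("N", "O"): 0.25,
    ("N", "S"): 0.10,
    ("O", "O"): -0.10,
    ("O", "S"): 0.10,
    ("S", "S"): 0.50,
}


def contact_value(element_a: str, element_b: str) -> float:
    a = element_a.strip().upper()
    b = element_b.strip().upper()
    a = a if a in CONTACT_TYPES else "C"
    b = b if b in CONTACT_TYPES else "C"
    return CONTACT_TABLE.get((a, b), CONTACT_TABLE.get((b, a), 0.0))
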