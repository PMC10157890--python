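"""Residue chemistry tables for interaction classification.

Classifies atoms of standard residues (PDB v3 atom naming) into the groups
the geometric detectors need:

* cationic-group hydrogens and their heavy partners (Arg guanidinium,
  Lys ε-ammonium, doubly protonated His imidazolium);
* anionic-group oxygens (Asp/Glu carboxylates, free C-terminal carboxylate);
* hydrogen-bond donor (heavy, hydrogen) pairs and acceptor heavy atoms,
  split into side-chain and backbone scopes.

Acetyllysine is the residue ``ALY`` whose side-chain amide (NZ–HZ) is a
donor and whose acetyl carbonyl oxygen (``OH`` in the chemical-component
naming) is an acceptor; the acetylated amine is neutral.  Peptides assayed
here are N-acetylated and C-amidated, so termini are neutral by default;
``terminal_charges=True`` re-enables the N-terminal ammonium and C-terminal
carboxylate.

All tables can be overridden with a JSON sidecar (see `load_topology_json`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

#: cationic groups: residue -> list of (heavy atom, [hydrogens])
CATIONIC_GROUPS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "ARG": [
        ("NE", ("HE",)),
        ("NH1", ("HH11", "HH12")),
        ("NH2", ("HH21", "HH22")),
    ],
    "LYS": [("NZ", ("HZ1", "HZ2", "HZ3"))],
    # imidazolium; only applies when the structure actually carries both H
    "HIS": [("ND1", ("HD1",)), ("NE2", ("HE2",))],
    "HIP": [("ND1", ("HD1",)), ("NE2", ("HE2",))],
}

#: anionic groups: residue -> oxygen atom names
ANIONIC_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: side-chain H-bond donors: residue -> list of (donor heavy, hydrogen)
SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "SER": [("OG", "HG")],
    "THR": [("OG1", "HG1")],
    "TYR": [("OH", "HH")],
    "CYS": [("SG", "HG")],
    "ASN": [("ND2", "HD21"), ("ND2", "HD22")],
    "GLN": [("NE2", "HE21"), ("NE2", "HE22")],
    "TRP": [("NE1", "HE1")],
    "HIS": [("ND1", "HD1"), ("NE2", "HE2")],
    "HIP": [("ND1", "HD1"), ("NE2", "HE2")],
    "ARG": [
        ("NE", "HE"),
        ("NH1", "HH11"), ("NH1", "HH12"),
        ("NH2", "HH21"), ("NH2", "HH22"),
    ],
    "LYS": [("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    "ALY": [("NZ", "HZ")],
}

#: side-chain H-bond acceptor heavy atoms
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "ALY": ("OH",),  # acetyl carbonyl oxygen
}

BACKBONE_DONOR: tuple[str, str] = ("N", "H")
BACKBONE_ACCEPTORS: tuple[str, ...] = ("O", "OXT")

#: residue letters able to form an ionic interaction (charged side chains)
CATIONIC_LETTERS = set("RKH")
ANIONIC_LETTERS = set("DE")


@dataclass
class ChemistryTables:
    """Bundle of classification tables, overridable per analysis."""

    cationic: dict = field(default_factory=lambda: dict(CATIONIC_GROUPS))
    anionic: dict = field(default_factory=lambda: dict(ANIONIC_OXYGENS))
    donors: dict = field(default_factory=lambda: dict(SIDECHAIN_DONORS))
    acceptors: dict = field(default_factory=lambda: dict(SIDECHAIN_ACCEPTORS))
    terminal_charges: bool = False

    def cationic_hydrogens(self, res_name: str) -> list[str]:
        return [h for _, hs in self.cationic.get(res_name, []) for h in hs]

    def anionic_oxygens(self, res_name: str) -> tuple[str, ...]:
        return self.anionic.get(res_name, ())

    def sidechain_donor_pairs(self, res_name: str) -> list[tuple[str, str]]:
        return self.donors.get(res_name, [])

    def sidechain_acceptor_atoms(self, res_name: str) -> tuple[str, ...]:
        return self.acceptors.get(res_name, ())

    def is_cationic_residue(self, res_name: str) -> bool:
        return res_name in self.cationic

    def is_anionic_residue(self, res_name: str) -> bool:
        return res_name in self.anionic


def load_topology_json(path) -> ChemistryTables:
    """Read a JSON sidecar overriding any of the default tables.

    Recognised keys: ``cationic``, ``anionic``, ``donors``, ``acceptors``,
    ``terminal_charges``; unknown keys raise.
    """
    with open(path) as fh:
        raw = json.load(fh)
    tables = ChemistryTables()
    for key, value in raw.items():
        if not hasattr(tables, key):
            raise KeyError(f"unknown topology key {key!r}")
        if key == "cationic":
            value = {
                res: [(heavy, tuple(hs)) for heavy, hs in groups]
                for res, groups in value.items()
            }
        elif key in ("anionic", "acceptors"):
            value = {res: tuple(v) for res, v in value.items()}
        elif key == "donors":
            value = {
                res: [tuple(pair) for pair in pairs]
                for res, pairs in value.items()
            }
        setattr(tables, key, value)
    return tables
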