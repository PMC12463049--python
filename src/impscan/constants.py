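"""Shared lookup tables (loaded from packaged data files where tabular)."""

from __future__ import annotations

import json
from importlib import resources

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _load(name: str) -> dict:
    with resources.files("impscan.data").joinpath(name).open() as fh:
        return json.load(fh)


_vdw = _load("vdw_radii.json")
VDW_RADII = {k: v for k, v in _vdw.items() if k != "default"}
VDW_DEFAULT = _vdw["default"]

_max_sasa = _load("max_sasa.json")
#: theoretical Gly-X-Gly maximum accessibility per amino acid, squared angstroms
MAX_SASA = {k: v for k, v in _max_sasa.items() if k != "comment"}

_classes = _load("polarity_classes.json")
#: amino acid -> {charged, polar, apolar}; shipped default map
POLARITY_CLASSES = dict(_classes["default"])
#: alternative map following the cited consensus affinity model exactly
POLARITY_CLASSES_CONSENSUS = dict(_classes["consensus_model"])

#: Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: formal side-chain charge at neutral pH (His treated as neutral)
RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: side-chain heavy atoms per amino acid (beyond N, CA, C, O)
SIDECHAIN_ATOMS = {
    "A": ["CB"],
    "C": ["CB", "SG"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "G": [],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "M": ["CB", "CG", "SD", "CE"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "P": ["CB", "CG", "CD"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "S": ["CB", "OG"],
    "T": ["CB", "OG1", "CG2"],
    "V": ["CB", "CG1", "CG2"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
}

#: hydrogen-bond donor heavy atoms (N/O carrying a polar hydrogen), by amino acid.
#: backbone N is a donor for every residue except proline.
HBOND_DONORS = {
    "R": {"NE", "NH1", "NH2"},
    "N": {"ND2"},
    "Q": {"NE2"},
    "H": {"ND1", "NE2"},
    "K": {"NZ"},
    "S": {"OG"},
    "T": {"OG1"},
    "Y": {"OH"},
    "W": {"NE1"},
}

#: hydrogen-bond acceptor heavy atoms (O/N with a lone pair), by amino acid.
#: backbone O is an acceptor for every residue.
HBOND_ACCEPTORS = {
    "N": {"OD1"},
    "D": {"OD1", "OD2"},
    "Q": {"OE1"},
    "E": {"OE1", "OE2"},
    "H": {"ND1", "NE2"},
    "S": {"OG"},
    "T": {"OG1"},
    "Y": {"OH"},
}

#: chi dihedral atom quadruples, in order chi1, chi2, ...
CHI_ATOMS = {
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "P": [],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
    "A": [],
    "G": [],
}
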