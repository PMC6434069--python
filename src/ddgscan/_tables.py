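"""Shared lookup data: amino-acid codes, pharmacophore typing, van der Waals
radii, ring and chi-angle definitions, solvent-accessibility references and the
packaged backbone-independent rotamer library.

All tables are plain Python constants so that every stage of the pipeline is a
pure function of its inputs.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Amino-acid codes
# ---------------------------------------------------------------------------

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Heavy side-chain atoms each residue type must carry to be complete.
SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

# ---------------------------------------------------------------------------
# Pharmacophore atom classes
#
# The eight classes are: hydrophobic, positive, negative, hbond_acceptor,
# hbond_donor, sulphur, aromatic, neutral.  Typing is a pure lookup on
# (residue name, atom name) for the 20 standard residues; HET-group atoms are
# typed by element + connectivity heuristics in structure_model.
# ---------------------------------------------------------------------------

PHARMACOPHORE_CLASSES = (
    "hydrophobic", "positive", "negative", "hbond_acceptor",
    "hbond_donor", "sulphur", "aromatic", "neutral",
)

# Backbone defaults (overridden for PRO N, which has no NH).
_BACKBONE_PHARM = {
    "N": {"hbond_donor"},
    "CA": {"neutral"},
    "C": {"neutral"},
    "O": {"hbond_acceptor"},
    "OXT": {"negative", "hbond_acceptor"},
}

_SIDECHAIN_PHARM = {
    "ALA": {"CB": {"hydrophobic"}},
    "ARG": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"}, "CD": {"neutral"},
            "NE": {"positive", "hbond_donor"}, "CZ": {"positive"},
            "NH1": {"positive", "hbond_donor"}, "NH2": {"positive", "hbond_donor"}},
    "ASN": {"CB": {"hydrophobic"}, "CG": {"neutral"},
            "OD1": {"hbond_acceptor"}, "ND2": {"hbond_donor"}},
    "ASP": {"CB": {"hydrophobic"}, "CG": {"neutral"},
            "OD1": {"negative", "hbond_acceptor"}, "OD2": {"negative", "hbond_acceptor"}},
    "CYS": {"CB": {"hydrophobic"}, "SG": {"sulphur"}},
    "GLN": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"}, "CD": {"neutral"},
            "OE1": {"hbond_acceptor"}, "NE2": {"hbond_donor"}},
    "GLU": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"}, "CD": {"neutral"},
            "OE1": {"negative", "hbond_acceptor"}, "OE2": {"negative", "hbond_acceptor"}},
    "GLY": {},
    "HIS": {"CB": {"hydrophobic"}, "CG": {"aromatic"},
            "ND1": {"aromatic", "positive", "hbond_donor", "hbond_acceptor"},
            "CD2": {"aromatic"}, "CE1": {"aromatic"},
            "NE2": {"aromatic", "positive", "hbond_donor", "hbond_acceptor"}},
    "ILE": {"CB": {"hydrophobic"}, "CG1": {"hydrophobic"},
            "CG2": {"hydrophobic"}, "CD1": {"hydrophobic"}},
    "LEU": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"},
            "CD1": {"hydrophobic"}, "CD2": {"hydrophobic"}},
    "LYS": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"}, "CD": {"hydrophobic"},
            "CE": {"neutral"}, "NZ": {"positive", "hbond_donor"}},
    "MET": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"},
            "SD": {"sulphur"}, "CE": {"hydrophobic"}},
    "PHE": {"CB": {"hydrophobic"}, "CG": {"aromatic", "hydrophobic"},
            "CD1": {"aromatic", "hydrophobic"}, "CD2": {"aromatic", "hydrophobic"},
            "CE1": {"aromatic", "hydrophobic"}, "CE2": {"aromatic", "hydrophobic"},
            "CZ": {"aromatic", "hydrophobic"}},
    "PRO": {"CB": {"hydrophobic"}, "CG": {"hydrophobic"}, "CD": {"neutral"}},
    "SER": {"CB": {"neutral"}, "OG": {"hbond_donor", "hbond_acceptor"}},
    "THR": {"CB": {"neutral"}, "OG1": {"hbond_donor", "hbond_acceptor"},
            "CG2": {"hydrophobic"}},
    "TRP": {"CB": {"hydrophobic"}, "CG": {"aromatic", "hydrophobic"},
            "CD1": {"aromatic"}, "CD2": {"aromatic", "hydrophobic"},
            "NE1": {"aromatic", "hbond_donor"}, "CE2": {"aromatic", "hydrophobic"},
            "CE3": {"aromatic", "hydrophobic"}, "CZ2": {"aromatic", "hydrophobic"},
            "CZ3": {"aromatic", "hydrophobic"}, "CH2": {"aromatic", "hydrophobic"}},
    "TYR": {"CB": {"hydrophobic"}, "CG": {"aromatic", "hydrophobic"},
            "CD1": {"aromatic", "hydrophobic"}, "CD2": {"aromatic", "hydrophobic"},
            "CE1": {"aromatic", "hydrophobic"}, "CE2": {"aromatic", "hydrophobic"},
            "CZ": {"aromatic", "hydrophobic"}, "OH": {"hbond_donor", "hbond_acceptor"}},
    "VAL": {"CB": {"hydrophobic"}, "CG1": {"hydrophobic"}, "CG2": {"hydrophobic"}},
}


def pharmacophores_for(resname: str, atom_name: str) -> frozenset | None:
    """Lookup-table pharmacophore set for a standard-residue heavy atom.

    Returns None when (resname, atom) is not covered by the table.
    """
    if resname not in SIDECHAIN_ATOMS:
        return None
    if atom_name in _BACKBONE_PHARM:
        if resname == "PRO" and atom_name == "N":
            return frozenset({"neutral"})
        return frozenset(_BACKBONE_PHARM[atom_name])
    side = _SIDECHAIN_PHARM.get(resname, {})
    if atom_name in side:
        return frozenset(side[atom_name])
    return None


# ---------------------------------------------------------------------------
# van der Waals radii (Bondi-style, Å); used for weak-hydrogen-bond/vdW
# contacts and the clash score.
# ---------------------------------------------------------------------------

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "MG": 1.73, "CA": 2.31, "MN": 1.97, "FE": 1.94,
    "NA": 2.27, "K": 2.75,
}
VDW_DEFAULT = 1.8

# Covalent radii (Å) for distance-based bond inference on HET groups.
COVALENT_RADII = {
    "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "H": 0.31,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "ZN": 1.22, "MG": 1.41, "FE": 1.32, "MN": 1.39,
}
COVALENT_DEFAULT = 1.1
COVALENT_TOLERANCE = 0.45

# ---------------------------------------------------------------------------
# Aromatic ring definitions for the standard residues.
# ---------------------------------------------------------------------------

RING_DEFINITIONS = {
    "PHE": [("ring", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("ring", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "HIS": [("ring", ["CG", "ND1", "CD2", "CE1", "NE2"])],
    "TRP": [("ring5", ["CG", "CD1", "CD2", "NE1", "CE2"]),
            ("ring6", ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"])],
}

# ---------------------------------------------------------------------------
# Chi dihedral definitions (atom name quadruples, chi1..chi4).
# ---------------------------------------------------------------------------

CHI_DEFINITIONS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

# ---------------------------------------------------------------------------
# Maximum accessible surface areas (Å²) per residue, theoretical values of
# Tien et al. 2013, used to normalize SASA into relative solvent
# accessibility.
# ---------------------------------------------------------------------------

MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# RSA thresholds for the accessibility axis of the structural environment.
RSA_BURIED = 0.07
RSA_EXPOSED = 0.43

# ---------------------------------------------------------------------------
# Amino-acid bulk properties used by the synthetic-label heuristic of the
# packaged signature regressor (volumes in Å³; Kyte-Doolittle hydropathy).
# ---------------------------------------------------------------------------

AA_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
AA_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
AA_CHARGE = {aa: 0.0 for aa in STANDARD_AA1}
AA_CHARGE.update({"R": 1.0, "K": 1.0, "H": 0.5, "D": -1.0, "E": -1.0})

# ---------------------------------------------------------------------------
# Backbone-independent rotamer library.
#
# A deliberately compact library: the most populated side-chain conformers
# with coarse prior probabilities in the spirit of the penultimate/backbone-
# independent libraries.  chi angles in degrees in (-180, 180]; priors per
# amino acid sum to 1.
# ---------------------------------------------------------------------------

ROTAMER_LIBRARY = {
    "ALA": [((), 1.0)],
    "GLY": [((), 1.0)],
    "PRO": [((25.0, -35.0), 0.5), ((-25.0, 35.0), 0.5)],
    "SER": [((-65.0,), 0.48), ((62.0,), 0.30), ((180.0,), 0.22)],
    "CYS": [((-65.0,), 0.50), ((-177.0,), 0.30), ((63.0,), 0.20)],
    "THR": [((-60.0,), 0.49), ((60.0,), 0.43), ((180.0,), 0.08)],
    "VAL": [((175.0,), 0.73), ((-60.0,), 0.20), ((64.0,), 0.07)],
    "ILE": [((-65.0, 170.0), 0.60), ((-57.0, -60.0), 0.15),
            ((62.0, 170.0), 0.15), ((-65.0, 100.0), 0.10)],
    "LEU": [((-65.0, 175.0), 0.60), ((-177.0, 65.0), 0.30),
            ((-85.0, 65.0), 0.10)],
    "MET": [((-65.0, -65.0, -70.0), 0.35), ((-65.0, 180.0, 75.0), 0.25),
            ((-177.0, 180.0, 75.0), 0.25), ((-65.0, 180.0, 180.0), 0.15)],
    "PHE": [((-65.0, 90.0), 0.45), ((-177.0, 80.0), 0.35), ((62.0, 90.0), 0.20)],
    "TYR": [((-65.0, 90.0), 0.45), ((-177.0, 80.0), 0.35), ((62.0, 90.0), 0.20)],
    "TRP": [((-65.0, 95.0), 0.35), ((-177.0, -105.0), 0.30),
            ((-65.0, -90.0), 0.20), ((62.0, 90.0), 0.15)],
    "HIS": [((-65.0, -70.0), 0.40), ((-177.0, 65.0), 0.35), ((62.0, -75.0), 0.25)],
    "ASP": [((-70.0, -15.0), 0.50), ((-177.0, 0.0), 0.30), ((62.0, -10.0), 0.20)],
    "ASN": [((-65.0, -20.0), 0.45), ((-177.0, -5.0), 0.30), ((62.0, -20.0), 0.25)],
    "GLU": [((-65.0, -65.0, -40.0), 0.35), ((-177.0, 180.0, 0.0), 0.30),
            ((-65.0, 180.0, -10.0), 0.35)],
    "GLN": [((-65.0, -65.0, -40.0), 0.35), ((-177.0, 180.0, 0.0), 0.30),
            ((-65.0, 180.0, -10.0), 0.35)],
    "LYS": [((-65.0, 180.0, 180.0, 180.0), 0.40),
            ((-177.0, 180.0, 180.0, 180.0), 0.35),
            ((-65.0, -65.0, 180.0, 180.0), 0.25)],
    "ARG": [((-65.0, 180.0, 180.0, 180.0), 0.35),
            ((-177.0, 180.0, 180.0, 180.0), 0.35),
            ((-65.0, -65.0, 180.0, 180.0), 0.30)],
}
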