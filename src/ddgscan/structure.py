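"""Structure and sequence I/O plus the atom/residue data model shared by all
pipeline stages.

The in-memory model is deliberately light: a :class:`StructureModel` holds
ordered polymer chains of :class:`Residue` objects, non-water HET groups as
*ligands* and single-atom ions as *metals*.  Author residue numbering (with
insertion codes) is canonical everywhere, matching the "Arg-93"-style labels
used in structural mutation studies.  The pipeline operates on heavy atoms
only; modelled structures usually lack hydrogens, so donor/acceptor geometry
is approximated through attached heavy atoms.

Atom typing assigns each heavy atom a set of coarse physicochemical
*pharmacophore* classes (hydrophobic, positive, negative, hydrogen-bond
acceptor/donor, sulphur, aromatic, neutral) — the vocabulary used by
cutoff-scanning stability signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from . import _tables as T
from ._geometry import fit_plane

logger = logging.getLogger("ddgscan")

ResidueId = tuple[str, int, str]  # (chain_id, author seq number, insertion code)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised for unparsable or degenerate structure input."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    pharmacophores: frozenset = frozenset()
    is_backbone: bool = False
    occupancy: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    aa3: str
    atoms: list[Atom] = field(default_factory=list)
    is_het: bool = False

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def aa1(self) -> str:
        return T.AA3_TO_AA1.get(self.aa3, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def label(self) -> str:
        return f"{self.aa3}-{self.seq_num}{self.icode.strip()}.{self.chain_id}"


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Residue] = field(default_factory=list)
    metals: list[Residue] = field(default_factory=list)
    title: str = ""
    provenance: str = ""

    # -- lookup -------------------------------------------------------------
    def polymer_residues(self) -> list[Residue]:
        out = []
        for cid in self.chains:
            out.extend(self.chains[cid])
        return out

    def get_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if res.seq_num == seq_num and res.icode.strip() == icode.strip():
                return res
        return None

    def get_ligand(self, name: str) -> Residue | None:
        for lig in self.ligands:
            if lig.aa3 == name:
                return lig
        return None

    def all_residues(self) -> list[Residue]:
        return self.polymer_residues() + self.ligands + self.metals

    def atom_table(self):
        """(owner residue, atom) pairs plus an (n, 3) coordinate array."""
        owners, coords = [], []
        for res in self.all_residues():
            for a in res.atoms:
                owners.append((res, a))
                coords.append(a.coords)
        return owners, np.array(coords) if coords else np.empty((0, 3))

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.all_residues())


@dataclass
class SiteSelection:
    """Ordered, duplicate-free list of residue identifiers with a label."""
    ids: list[ResidueId]
    label: str = ""

    def __post_init__(self):
        seen = set()
        for rid in self.ids:
            if rid in seen:
                raise ValueError(f"duplicate residue identifier {rid} in selection")
            seen.add(rid)

    def validate(self, structure: StructureModel) -> None:
        for cid, num, icode in self.ids:
            if structure.get_residue(cid, num, icode) is None:
                raise ValueError(f"selection {self.label!r}: residue "
                                 f"({cid}, {num}, {icode!r}) not in structure")

    def __iter__(self):
        return iter(self.ids)

    def __len__(self):
        return len(self.ids)


# ---------------------------------------------------------------------------
# Structure reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name; ties -> first."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    HET groups of >= 2 heavy atoms become ligands, single-atom ions become
    metals, waters are discarded and author numbering is preserved.  Raises
    :class:`StructureError` for unreadable files or files without a single
    polymer residue.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    model = StructureModel(title=st.name or path.stem, provenance=str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    gmodel = st[0]
    for chain in gmodel:
        for gres in chain:
            if gres.name in _WATER_NAMES:
                continue
            atoms = []
            for gatom in _pick_altloc(gres):
                if gatom.element.name == "H":
                    continue
                atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name.upper(),
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    is_backbone=gatom.name in T.BACKBONE_ATOMS,
                    occupancy=gatom.occ,
                ))
            if not atoms:
                continue
            res = Residue(
                chain_id=chain.name,
                seq_num=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                aa3=gres.name,
                atoms=atoms,
                is_het=gres.het_flag == "H" or gres.name not in T.SIDECHAIN_ATOMS,
            )
            if res.aa3 in T.SIDECHAIN_ATOMS and gres.het_flag != "H":
                model.chains.setdefault(chain.name, []).append(res)
            elif len(atoms) == 1:
                model.metals.append(res)
            else:
                model.ligands.append(res)
    if not model.polymer_residues():
        raise StructureError(f"{path}: structure contains no polymer residues")
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as PDB (default) or mmCIF (``.cif`` suffix)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.title or "ddgscan model"
    gmodel = gemmi.Model("1")

    def add_residue(gchain: gemmi.Chain, res: Residue, het: bool):
        gres = gemmi.Residue()
        gres.name = res.aa3
        gres.seqid = gemmi.SeqId(res.seq_num, res.icode if res.icode else " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            gatom = gemmi.Atom()
            gatom.name = a.name
            gatom.element = gemmi.Element(a.element.capitalize())
            gatom.pos = gemmi.Position(*a.coords)
            gatom.occ = a.occupancy
            gres.add_atom(gatom)
        gchain.add_residue(gres)

    for cid, residues in model.chains.items():
        gchain = gemmi.Chain(cid)
        for res in residues:
            add_residue(gchain, res, het=False)
        gmodel.add_chain(gchain)
    het_by_chain: dict[str, list[tuple[Residue, bool]]] = {}
    for lig in model.ligands:
        het_by_chain.setdefault(lig.chain_id or "X", []).append((lig, True))
    for met in model.metals:
        het_by_chain.setdefault(met.chain_id or "X", []).append((met, True))
    for cid, items in het_by_chain.items():
        gchain = gemmi.Chain(cid if cid not in model.chains else cid + "_h")
        for res, het in items:
            add_residue(gchain, res, het=het)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Bond inference and pharmacophore typing
# ---------------------------------------------------------------------------

def infer_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference within one group of atoms."""
    bonds = []
    coords = np.array([a.coords for a in atoms])
    for i in range(len(atoms)):
        ri = T.COVALENT_RADII.get(atoms[i].element, T.COVALENT_DEFAULT)
        for j in range(i + 1, len(atoms)):
            rj = T.COVALENT_RADII.get(atoms[j].element, T.COVALENT_DEFAULT)
            d = np.linalg.norm(coords[i] - coords[j])
            if 0.4 < d <= ri + rj + T.COVALENT_TOLERANCE:
                bonds.append((i, j))
    return bonds


def het_aromatic_rings(residue: Residue) -> list[list[int]]:
    """Detect planar 5/6-membered C/N rings in a HET group (atom indices)."""
    bonds = infer_bonds(residue.atoms)
    g = nx.Graph(bonds)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if not all(residue.atoms[i].element in ("C", "N") for i in cycle):
            continue
        pts = np.array([residue.atoms[i].coords for i in cycle])
        centroid, normal = fit_plane(pts)
        dev = np.abs((pts - centroid) @ normal)
        if dev.max() <= 0.15:
            rings.append(sorted(cycle))
    return rings


def _type_het_atoms(residue: Residue) -> None:
    """Element + connectivity heuristics for ligand atoms."""
    bonds = infer_bonds(residue.atoms)
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(residue.atoms))}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    ring_atoms = {i for ring in het_aromatic_rings(residue) for i in ring}
    for idx, atom in enumerate(residue.atoms):
        el = atom.element
        classes: set[str] = set()
        nbr_elements = [residue.atoms[j].element for j in neighbors[idx]]
        if el == "C":
            if idx in ring_atoms:
                classes |= {"aromatic", "hydrophobic"}
            elif all(e == "C" for e in nbr_elements) and nbr_elements:
                classes.add("hydrophobic")
            else:
                classes.add("neutral")
        elif el == "N":
            classes |= {"hbond_donor", "hbond_acceptor"}
            if idx in ring_atoms:
                classes.add("aromatic")
        elif el == "O":
            classes.add("hbond_acceptor")
            if "P" in nbr_elements:
                classes.add("negative")  # phosphate-like oxygen
            elif len(nbr_elements) == 1 and nbr_elements[0] == "C":
                # could be carbonyl or hydroxyl; hydroxyl keeps donor ability
                carbon = neighbors[idx][0]
                n_o_on_c = sum(1 for j in neighbors[carbon]
                               if residue.atoms[j].element == "O")
                if n_o_on_c >= 2:
                    classes.add("negative")  # carboxylate-like
                else:
                    classes.add("hbond_donor")
        elif el == "S":
            classes.add("sulphur")
        elif el == "P":
            classes.add("neutral")
        elif el in ("ZN", "MG", "CA", "MN", "FE", "NA", "K"):
            classes.add("positive")
        else:
            classes.add("neutral")
        atom.pharmacophores = frozenset(classes)


def assign_pharmacophores(structure: StructureModel) -> StructureModel:
    """Assign pharmacophore classes to every heavy atom, in place.

    Standard-residue atoms come from a fixed lookup table; HET atoms are typed
    by element and connectivity; metals are typed positive.  Unknown atoms of
    unknown residues fall back to {neutral} with a warning.  Returns the same
    structure for chaining.
    """
    for res in structure.polymer_residues():
        for atom in res.atoms:
            classes = T.pharmacophores_for(res.aa3, atom.name)
            if classes is None:
                logger.warning("unknown atom %s in residue %s typed {neutral}",
                               atom.name, res.label)
                classes = frozenset({"neutral"})
            atom.pharmacophores = classes
    for lig in structure.ligands:
        _type_het_atoms(lig)
    for met in structure.metals:
        for atom in met.atoms:
            atom.pharmacophores = frozenset({"positive"})
    return structure


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = T.STANDARD_AA1 + "X") -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence), validating characters."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or invalid FASTA file")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in alphabet:
                raise ValueError(f"{path}: record {rec.id!r} has illegal "
                                 f"character {ch!r} at position {pos}")
        out.append((rec.id, seq))
    return out


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global affine-gap alignment.

    BLOSUM62 with gap open 10 / extend 0.5 (Clustal-W-scale parameters);
    identity = identical aligned columns / aligned columns with residues in
    both sequences x 100.  Gap-only columns are excluded from the denominator.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    aligner = PairwiseAligner(
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-10.0,
        extend_gap_score=-0.5,
        mode="global",
    )
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    identical = 0
    aligned = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned += a1 - a0
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if seq_a[i].upper() == seq_b[j].upper():
                identical += 1
    if aligned == 0:
        return 0.0
    return 100.0 * identical / aligned
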