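"""Typing of non-covalent interatomic interactions and contact-based residue
set detection (ligand pockets, dimer interfaces).

Geometric criteria (heavy-atom, published-convention style):

* hydrogen_bond      donor-acceptor <= 3.5 A, angle(antecedent-donor...acceptor) >= 90 deg
* weak_hbond_vdw     pair distance <= sum of vdW radii + 0.5 A
* ionic              opposite formal-charge group centroids <= 4.0 A
* metal_coordination metal to N/O/S <= 3.0 A
* carbonyl           carbonyl C to O/N nucleophile <= 3.6 A, approach 109 +/- 30 deg
* ring_ring          centroid distance <= 6.0 A; subtype from interplanar
                     dihedral theta and centroid offset:
                     theta < 30 & offset < 1.5  -> FF_parallel
                     theta < 30 & offset >= 1.5 -> OF_offset
                     30 <= theta < 60           -> ET_edge_tilted
                     theta >= 60                -> EE_edge_edge if the edge of
                     the partner ring approaches in-plane, else EF_edge_face
* atom_ring          atom-centroid <= 4.5 A, angle from ring normal <= 35 deg;
                     donor class by pharmacophore (cation > sulphur > donor > carbon)
* proximal_hydrophobic  two hydrophobic carbons <= 4.5 A
* proximal_undefined    any remaining pair <= 5.0 A

Each qualifying pair/ring is emitted once with the most specific applicable
type (priority: metal_coordination > ionic > hydrogen_bond > carbonyl >
ring_ring > atom_ring > weak_hbond_vdw > proximal_hydrophobic >
proximal_undefined).  Covalently bonded neighbors (up to 1-4 across a peptide
or disulphide link) never pair, and all intra-residue pairs are out of scope.
His/metal contacts are reported as metal_coordination (rendered "ionic bonds"
in some published figure nomenclature).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import _tables as T
from ._geometry import angle as atom_angle
from ._geometry import fit_plane
from .mutant import _template
from .structure import (Residue, ResidueId, SiteSelection, StructureModel,
                        het_aromatic_rings, infer_bonds)

HBOND_MAX = 3.5
HBOND_MIN_ANGLE = 90.0
WEAK_VDW_PAD = 0.5
IONIC_MAX = 4.0
METAL_MAX = 3.0
CARBONYL_MAX = 3.6
CARBONYL_ANGLE = 109.0
CARBONYL_ANGLE_TOL = 30.0
RING_RING_MAX = 6.0
RING_PARALLEL_DIHEDRAL = 30.0
RING_TILTED_DIHEDRAL = 60.0
RING_OFFSET_PARALLEL = 1.5
ATOM_RING_MAX = 4.5
ATOM_RING_MAX_NORMAL_ANGLE = 35.0
HYDROPHOBIC_MAX = 4.5
UNDEFINED_MAX = 5.0
PEPTIDE_CN_MAX = 1.8
DISULPHIDE_MAX = 2.4

RING_SUBTYPES = ("FF_parallel", "OF_offset", "EE_edge_edge", "ET_edge_tilted", "EF_edge_face")
ATOM_RING_SUBTYPES = ("carbon_pi", "donor_pi", "sulphur_pi", "cation_pi")

ITYPE_PRIORITY = (
    "metal_coordination", "ionic", "hydrogen_bond", "carbonyl", "ring_ring",
    "atom_ring", "weak_hbond_vdw", "proximal_hydrophobic", "proximal_undefined",
)


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    """One typed non-covalent contact.

    Partners are identified by residue id plus the atom names involved; for
    ring partners the atom list holds the ring member names and the partner
    tag carries the ring name.
    """
    res_a: ResidueId
    res_b: ResidueId
    atoms_a: tuple[str, ...]
    atoms_b: tuple[str, ...]
    itype: str
    subtype: str | None
    distance: float
    geometry: tuple[tuple[str, float], ...] = ()

    @property
    def pair(self) -> frozenset:
        return frozenset((self.res_a, self.res_b))

    def signature(self):
        a, b = sorted([(self.res_a, self.atoms_a), (self.res_b, self.atoms_b)])
        return (a[0], a[1], b[0], b[1], self.itype, self.subtype)


@dataclass
class InteractionNetwork:
    structure: StructureModel
    records: list[InteractionRecord] = field(default_factory=list)
    _index: dict[frozenset, list[InteractionRecord]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for rec in self.records:
            self._index.setdefault(rec.pair, []).append(rec)

    def by_pair(self, rid_a: ResidueId, rid_b: ResidueId) -> list[InteractionRecord]:
        return list(self._index.get(frozenset((rid_a, rid_b)), []))

    def touching(self, rid: ResidueId) -> list[InteractionRecord]:
        return [r for r in self.records if rid in (r.res_a, r.res_b)]

    def __len__(self):
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "chain_a": r.res_a[0], "resnum_a": r.res_a[1], "icode_a": r.res_a[2],
                "atoms_a": "+".join(r.atoms_a),
                "chain_b": r.res_b[0], "resnum_b": r.res_b[1], "icode_b": r.res_b[2],
                "atoms_b": "+".join(r.atoms_b),
                "itype": r.itype, "subtype": r.subtype or "",
                "distance": round(r.distance, 3),
            }
            for key, val in r.geometry:
                row[key] = round(val, 2)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            self.to_dataframe().to_dict(orient="records"), indent=1) + "\n")


# ---------------------------------------------------------------------------
# Rings and covalent exclusions
# ---------------------------------------------------------------------------

@dataclass
class _Ring:
    residue: Residue
    name: str
    atom_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray
    coords: np.ndarray


def _collect_rings(structure: StructureModel) -> list[_Ring]:
    rings = []
    for res in structure.polymer_residues():
        for ring_name, names in T.RING_DEFINITIONS.get(res.aa3, []):
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                continue
            pts = np.array([a.coords for a in atoms])
            centroid, normal = fit_plane(pts)
            rings.append(_Ring(res, ring_name, tuple(names), centroid, normal, pts))
    for lig in structure.ligands:
        for k, idxs in enumerate(het_aromatic_rings(lig)):
            pts = np.array([lig.atoms[i].coords for i in idxs])
            centroid, normal = fit_plane(pts)
            rings.append(_Ring(lig, f"ring{k}" if k else "ring",
                               tuple(lig.atoms[i].name for i in idxs),
                               centroid, normal, pts))
    return rings


def _residue_bond_graph(res: Residue) -> dict[str, set[str]]:
    """Intra-residue heavy-atom bonds: template connectivity for standard
    residues, distance inference for HET groups."""
    adj: dict[str, set[str]] = {a.name: set() for a in res.atoms}
    if res.aa3 in T.SIDECHAIN_ATOMS:
        names, _, bonds = _template(res.aa3)
        present = {a.name for a in res.atoms}
        for i, j in bonds:
            ni, nj = names[i], names[j]
            if ni in present and nj in present:
                adj[ni].add(nj)
                adj[nj].add(ni)
        if "OXT" in present and "C" in present:
            adj["OXT"].add("C")
            adj["C"].add("OXT")
    else:
        for i, j in infer_bonds(res.atoms):
            ni, nj = res.atoms[i].name, res.atoms[j].name
            adj[ni].add(nj)
            adj[nj].add(ni)
    return adj


def _cross_link_exclusions(res_a: Residue, res_b: Residue,
                           link: tuple[str, str]) -> set[frozenset]:
    """Atom pairs within 3 covalent bonds across an inter-residue link."""
    adj_a = _residue_bond_graph(res_a)
    adj_b = _residue_bond_graph(res_b)
    la, lb = link

    def ring_distances(adj, start):
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj.get(node, ()):
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
            frontier = nxt
        return dist

    da = ring_distances(adj_a, la)
    db = ring_distances(adj_b, lb)
    out = set()
    for na, dista in da.items():
        for nb, distb in db.items():
            if dista + 1 + distb <= 3:
                out.add(frozenset(((id(res_a), na), (id(res_b), nb))))
    return out


def _covalent_exclusions(structure: StructureModel) -> set[frozenset]:
    excluded: set[frozenset] = set()
    for chain in structure.chains.values():
        for r1, r2 in zip(chain, chain[1:]):
            c, n = r1.atom("C"), r2.atom("N")
            if c is None or n is None:
                continue
            if np.linalg.norm(c.coords - n.coords) <= PEPTIDE_CN_MAX:
                excluded |= _cross_link_exclusions(r1, r2, ("C", "N"))
    # disulphide bridges
    cys = [r for r in structure.polymer_residues()
           if r.aa3 == "CYS" and r.atom("SG") is not None]
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = np.linalg.norm(cys[i].atom("SG").coords - cys[j].atom("SG").coords)
            if d <= DISULPHIDE_MAX:
                excluded |= _cross_link_exclusions(cys[i], cys[j], ("SG", "SG"))
    return excluded


# ---------------------------------------------------------------------------
# Charged groups
# ---------------------------------------------------------------------------

_CHARGED_GROUPS = {
    "ARG": (["NE", "NH1", "NH2"], +1),
    "LYS": (["NZ"], +1),
    "HIS": (["ND1", "NE2"], +1),
    "ASP": (["OD1", "OD2"], -1),
    "GLU": (["OE1", "OE2"], -1),
}


def _charged_groups(structure: StructureModel):
    """(residue, atom names, sign, centroid) for side-chain and ligand
    formal-charge groups.  Metals are handled by metal_coordination only."""
    groups = []
    for res in structure.polymer_residues():
        if res.aa3 in _CHARGED_GROUPS:
            names, sign = _CHARGED_GROUPS[res.aa3]
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                continue
            centroid = np.mean([a.coords for a in atoms], axis=0)
            groups.append((res, tuple(names), sign, centroid))
    for lig in structure.ligands:
        neg = [a for a in lig.atoms if "negative" in a.pharmacophores]
        if neg:
            # cluster bonded negative atoms into one group per moiety
            bonds = infer_bonds(lig.atoms)
            name_adj: dict[str, set[str]] = {a.name: set() for a in lig.atoms}
            for i, j in bonds:
                name_adj[lig.atoms[i].name].add(lig.atoms[j].name)
                name_adj[lig.atoms[j].name].add(lig.atoms[i].name)
            unassigned = {a.name: a for a in neg}
            while unassigned:
                seed_name = sorted(unassigned)[0]
                cluster = {seed_name}
                frontier = [seed_name]
                while frontier:
                    node = frontier.pop()
                    for nb in name_adj[node]:
                        for nb2 in name_adj[nb]:  # via shared central atom (e.g. P)
                            if nb2 in unassigned and nb2 not in cluster:
                                cluster.add(nb2)
                                frontier.append(nb2)
                atoms = [unassigned.pop(n) for n in sorted(cluster)]
                centroid = np.mean([a.coords for a in atoms], axis=0)
                groups.append((lig, tuple(a.name for a in atoms), -1, centroid))
        pos = [a for a in lig.atoms if "positive" in a.pharmacophores]
        for a in pos:
            groups.append((lig, (a.name,), +1, a.coords))
    return groups


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _is_carbonyl_carbon(res: Residue, atom_name: str) -> np.ndarray | None:
    """If the atom is a carbonyl carbon, return its oxygen's coordinates."""
    if res.aa3 in T.SIDECHAIN_ATOMS:
        mapping = {"C": "O"}
        if res.aa3 == "ASN":
            mapping["CG"] = "OD1"
        elif res.aa3 == "GLN":
            mapping["CD"] = "OE1"
        elif res.aa3 in ("ASP", "GLU"):
            return None  # carboxylate, treated as charged group
        o_name = mapping.get(atom_name)
        if o_name is not None:
            o = res.atom(o_name)
            return None if o is None else o.coords
        return None
    atom = res.atom(atom_name)
    if atom is None or atom.element != "C":
        return None
    bonds = infer_bonds(res.atoms)
    idx = next(i for i, a in enumerate(res.atoms) if a.name == atom_name)
    oxygens = []
    for i, j in bonds:
        if idx in (i, j):
            other = res.atoms[j if i == idx else i]
            if other.element == "O":
                n_nbrs = sum(1 for k, l in bonds
                             if other is res.atoms[k] or other is res.atoms[l])
                if n_nbrs == 1:
                    oxygens.append(other)
    if len(oxygens) == 1:
        return oxygens[0].coords
    return None


def detect_interactions(structure: StructureModel,
                        focus="all") -> InteractionNetwork:
    """Type every qualifying non-covalent contact in the structure.

    ``focus`` is "all", a :class:`SiteSelection` or a ligand name; with a
    focus only records touching the focused residues/ligand are kept.
    Requires pharmacophores to be assigned.
    """
    owners, coords = structure.atom_table()
    if len(owners) == 0:
        return InteractionNetwork(structure, [])
    if all(not a.pharmacophores for _, a in owners):
        raise InteractionError("pharmacophores not assigned; "
                               "call assign_pharmacophores first")

    metal_residues = set(id(m) for m in structure.metals)
    excluded = _covalent_exclusions(structure)
    rings = _collect_rings(structure)
    records: list[InteractionRecord] = []

    # --- ring-ring ---------------------------------------------------------
    ring_pairs: set[tuple[int, int]] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            ra, rb = rings[i], rings[j]
            if ra.residue is rb.residue:
                continue
            d = float(np.linalg.norm(ra.centroid - rb.centroid))
            if d > RING_RING_MAX:
                continue
            cosang = abs(float(np.dot(ra.normal, rb.normal)))
            theta = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            off_a = _in_plane_offset(ra, rb.centroid)
            off_b = _in_plane_offset(rb, ra.centroid)
            offset = min(off_a, off_b)
            if theta < RING_PARALLEL_DIHEDRAL:
                subtype = "FF_parallel" if offset < RING_OFFSET_PARALLEL else "OF_offset"
            elif theta < RING_TILTED_DIHEDRAL:
                subtype = "ET_edge_tilted"
            else:
                subtype = "EE_edge_edge" if _edge_approach(ra, rb) else "EF_edge_face"
            ring_pairs.add((i, j))
            records.append(InteractionRecord(
                ra.residue.rid, rb.residue.rid, ra.atom_names, rb.atom_names,
                "ring_ring", subtype, d,
                (("dihedral", theta), ("offset", offset))))

    ring_member_keys = [
        {(id(r.residue), n) for n in r.atom_names} for r in rings
    ]
    paired_with: dict[int, set[int]] = {}
    for i, j in ring_pairs:
        paired_with.setdefault(i, set()).add(j)
        paired_with.setdefault(j, set()).add(i)

    # --- atom-ring ---------------------------------------------------------
    atom_ring_cover: set[frozenset] = set()
    tree = cKDTree(coords)
    for k, ring in enumerate(rings):
        for idx in tree.query_ball_point(ring.centroid, r=ATOM_RING_MAX):
            res, atom = owners[idx]
            if res is ring.residue or id(res) in metal_residues:
                continue
            # aromatic atoms whose own ring already pairs with this ring
            skip = False
            for other_k in paired_with.get(k, ()):
                if (id(res), atom.name) in ring_member_keys[other_k]:
                    skip = True
                    break
            if skip:
                continue
            v = atom.coords - ring.centroid
            d = float(np.linalg.norm(v))
            if d > ATOM_RING_MAX or d < 1e-6:
                continue
            cosang = abs(float(np.dot(v / d, ring.normal)))
            normal_angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if normal_angle > ATOM_RING_MAX_NORMAL_ANGLE:
                continue
            ph = atom.pharmacophores
            if "positive" in ph:
                subtype = "cation_pi"
            elif "sulphur" in ph:
                subtype = "sulphur_pi"
            elif "hbond_donor" in ph:
                subtype = "donor_pi"
            elif atom.element == "C":
                subtype = "carbon_pi"
            else:
                continue
            records.append(InteractionRecord(
                res.rid, ring.residue.rid, (atom.name,), ring.atom_names,
                "atom_ring", subtype, d, (("normal_angle", normal_angle),)))
            for member in ring.atom_names:
                atom_ring_cover.add(frozenset(((id(res), atom.name),
                                               (id(ring.residue), member))))

    ring_cover: set[frozenset] = set()
    for i, j in ring_pairs:
        for ka in ring_member_keys[i]:
            for kb in ring_member_keys[j]:
                ring_cover.add(frozenset((ka, kb)))
    ring_cover |= atom_ring_cover

    # --- ionic (group based) ----------------------------------------------
    groups = _charged_groups(structure)
    ionic_cover: set[frozenset] = set()
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            res_a, names_a, sign_a, cen_a = groups[gi]
            res_b, names_b, sign_b, cen_b = groups[gj]
            if res_a is res_b or sign_a * sign_b >= 0:
                continue
            d = float(np.linalg.norm(cen_a - cen_b))
            if d > IONIC_MAX:
                continue
            records.append(InteractionRecord(
                res_a.rid, res_b.rid, names_a, names_b, "ionic", None, d))
            for na in names_a:
                for nb in names_b:
                    ionic_cover.add(frozenset(((id(res_a), na), (id(res_b), nb))))

    # --- atom-pair scan ----------------------------------------------------
    for ia, ib in tree.query_pairs(r=UNDEFINED_MAX):
        res_a, atom_a = owners[ia]
        res_b, atom_b = owners[ib]
        if res_a is res_b:
            continue
        key = frozenset(((id(res_a), atom_a.name), (id(res_b), atom_b.name)))
        if key in excluded:
            continue
        d = float(np.linalg.norm(atom_a.coords - atom_b.coords))

        a_is_metal = id(res_a) in metal_residues
        b_is_metal = id(res_b) in metal_residues
        if a_is_metal or b_is_metal:
            if a_is_metal and b_is_metal:
                continue
            metal_res, metal_atom = (res_a, atom_a) if a_is_metal else (res_b, atom_b)
            other_res, other_atom = (res_b, atom_b) if a_is_metal else (res_a, atom_a)
            if d <= METAL_MAX and other_atom.element in ("N", "O", "S"):
                records.append(InteractionRecord(
                    metal_res.rid, other_res.rid, (metal_atom.name,),
                    (other_atom.name,), "metal_coordination", None, d))
            continue

        if key in ionic_cover:
            continue

        rec = _hbond_record(res_a, atom_a, res_b, atom_b, d)
        if rec is None:
            rec = _carbonyl_record(res_a, atom_a, res_b, atom_b, d)
        if rec is not None:
            records.append(rec)
            continue

        if key in ring_cover:
            continue

        vdw_sum = (T.VDW_RADII.get(atom_a.element, T.VDW_DEFAULT)
                   + T.VDW_RADII.get(atom_b.element, T.VDW_DEFAULT))
        if d <= vdw_sum + WEAK_VDW_PAD:
            records.append(InteractionRecord(
                res_a.rid, res_b.rid, (atom_a.name,), (atom_b.name,),
                "weak_hbond_vdw", None, d))
        elif (d <= HYDROPHOBIC_MAX and atom_a.element == "C"
              and atom_b.element == "C"
              and "hydrophobic" in atom_a.pharmacophores
              and "hydrophobic" in atom_b.pharmacophores):
            records.append(InteractionRecord(
                res_a.rid, res_b.rid, (atom_a.name,), (atom_b.name,),
                "proximal_hydrophobic", None, d))
        elif d <= UNDEFINED_MAX:
            records.append(InteractionRecord(
                res_a.rid, res_b.rid, (atom_a.name,), (atom_b.name,),
                "proximal_undefined", None, d))

    network = InteractionNetwork(structure, records)
    return _apply_focus(network, structure, focus)


def _in_plane_offset(ring: _Ring, other_centroid: np.ndarray) -> float:
    v = other_centroid - ring.centroid
    along = float(np.dot(v, ring.normal))
    return float(np.sqrt(max(np.dot(v, v) - along * along, 0.0)))


def _edge_approach(ra: _Ring, rb: _Ring) -> bool:
    """For perpendicular rings: True if the closest partner atom approaches
    in the plane of the other ring (edge-to-edge), False if it approaches
    the ring face (edge-to-face)."""
    def elevation(ring: _Ring, pts: np.ndarray) -> float:
        dists = np.linalg.norm(pts - ring.centroid, axis=1)
        closest = pts[int(np.argmin(dists))]
        v = closest - ring.centroid
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            return 90.0
        sinang = abs(float(np.dot(v / norm, ring.normal)))
        return float(np.degrees(np.arcsin(np.clip(sinang, 0.0, 1.0))))

    face_a = elevation(ra, rb.coords) > 45.0
    face_b = elevation(rb, ra.coords) > 45.0
    return not (face_a or face_b)


def _antecedents(res: Residue, atom_name: str) -> list[np.ndarray]:
    adj = _residue_bond_graph(res)
    return [res.atom(n).coords for n in adj.get(atom_name, ())
            if res.atom(n) is not None]


def _hbond_record(res_a, atom_a, res_b, atom_b, d) -> InteractionRecord | None:
    if d > HBOND_MAX:
        return None
    for donor_res, donor, acc_res, acc in ((res_a, atom_a, res_b, atom_b),
                                           (res_b, atom_b, res_a, atom_a)):
        if "hbond_donor" not in donor.pharmacophores:
            continue
        if "hbond_acceptor" not in acc.pharmacophores:
            continue
        antecedents = _antecedents(donor_res, donor.name)
        if not antecedents:
            continue
        best = max(atom_angle(a, donor.coords, acc.coords) for a in antecedents)
        if best >= HBOND_MIN_ANGLE:
            return InteractionRecord(
                donor_res.rid, acc_res.rid, (donor.name,), (acc.name,),
                "hydrogen_bond", None, d, (("donor_angle", best),))
    return None


def _carbonyl_record(res_a, atom_a, res_b, atom_b, d) -> InteractionRecord | None:
    if d > CARBONYL_MAX:
        return None
    for c_res, c_atom, x_res, x_atom in ((res_a, atom_a, res_b, atom_b),
                                         (res_b, atom_b, res_a, atom_a)):
        if c_atom.element != "C" or x_atom.element not in ("O", "N"):
            continue
        o_coords = _is_carbonyl_carbon(c_res, c_atom.name)
        if o_coords is None:
            continue
        approach = atom_angle(o_coords, c_atom.coords, x_atom.coords)
        if abs(approach - CARBONYL_ANGLE) <= CARBONYL_ANGLE_TOL:
            return InteractionRecord(
                c_res.rid, x_res.rid, (c_atom.name,), (x_atom.name,),
                "carbonyl", None, d, (("approach_angle", approach),))
    return None


def _apply_focus(network: InteractionNetwork, structure: StructureModel,
                 focus) -> InteractionNetwork:
    if isinstance(focus, str) and focus == "all":
        return network
    if isinstance(focus, SiteSelection):
        focus.validate(structure)
        keep = set(focus.ids)
        recs = [r for r in network.records
                if r.res_a in keep or r.res_b in keep]
        return InteractionNetwork(structure, recs)
    if isinstance(focus, str):
        lig = structure.get_ligand(focus)
        if lig is None:
            raise InteractionError(f"no ligand named {focus!r} in structure")
        recs = [r for r in network.records if lig.rid in (r.res_a, r.res_b)]
        return InteractionNetwork(structure, recs)
    raise InteractionError(f"unsupported focus {focus!r}")


# ---------------------------------------------------------------------------
# Residue-set detection
# ---------------------------------------------------------------------------

def find_ligand_binding_residues(structure: StructureModel, ligand_id: str,
                                 network: InteractionNetwork | None = None,
                                 contact_cutoff: float = 4.5) -> SiteSelection:
    """Polymer residues interacting with the ligand (>= 1 typed record) plus
    any residue with a heavy atom within ``contact_cutoff`` of a ligand heavy
    atom, ordered by (chain, residue number)."""
    ligand = structure.get_ligand(ligand_id)
    if ligand is None:
        raise InteractionError(f"no ligand named {ligand_id!r} in structure")
    if network is None:
        network = detect_interactions(structure, focus=ligand_id)
    hits: set[ResidueId] = set()
    for rec in network.records:
        if ligand.rid == rec.res_a:
            hits.add(rec.res_b)
        elif ligand.rid == rec.res_b:
            hits.add(rec.res_a)
    lig_coords = ligand.coords()
    tree = cKDTree(lig_coords)
    for res in structure.polymer_residues():
        if res.rid in hits:
            continue
        if tree.query_ball_point(res.coords(), r=contact_cutoff, return_length=True).sum():
            hits.add(res.rid)
    polymer_ids = {r.rid for r in structure.polymer_residues()}
    ordered = sorted((rid for rid in hits if rid in polymer_ids),
                     key=lambda rid: (rid[0], rid[1], rid[2]))
    return SiteSelection(ordered, label=f"{ligand_id}_binding_site")


def find_interface_residues(structure: StructureModel, chain_a: str, chain_b: str,
                            cutoff: float = 5.0) -> tuple[SiteSelection, SiteSelection]:
    """Residues of each chain with any heavy atom within ``cutoff`` of the
    other chain (default 5.0 A heavy-atom convention)."""
    if chain_a == chain_b:
        raise InteractionError("interface requires two distinct chains")
    for cid in (chain_a, chain_b):
        if cid not in structure.chains:
            raise InteractionError(f"chain {cid!r} not in structure")
    res_a = structure.chains[chain_a]
    res_b = structure.chains[chain_b]
    coords_b = np.concatenate([r.coords() for r in res_b])
    owners_b = np.concatenate([[i] * len(r.atoms) for i, r in enumerate(res_b)])
    tree = cKDTree(coords_b)
    sel_a, sel_b = set(), set()
    for ra in res_a:
        idxs = tree.query_ball_point(ra.coords(), r=cutoff)
        flat = {j for sub in idxs for j in sub}
        if flat:
            sel_a.add(ra.rid)
            for j in flat:
                sel_b.add(res_b[int(owners_b[j])].rid)
    mk = lambda ids, label: SiteSelection(
        sorted(ids, key=lambda rid: (rid[0], rid[1], rid[2])), label=label)
    return (mk(sel_a, f"interface_{chain_a}"), mk(sel_b, f"interface_{chain_b}"))


# ---------------------------------------------------------------------------
# Network differencing
# ---------------------------------------------------------------------------

@dataclass
class NetworkDiff:
    lost: list[InteractionRecord]
    gained: list[InteractionRecord]
    retained: list[InteractionRecord]


def diff_networks(wild: InteractionNetwork, mutant: InteractionNetwork,
                  site: ResidueId) -> NetworkDiff:
    """Partition the records touching ``site`` into lost / gained / retained,
    matching on (partner residue, itype, subtype); geometry is ignored for
    matching.  The two structures must be identical outside the site."""
    _check_same_outside_site(wild.structure, mutant.structure, site)

    def keyed(network: InteractionNetwork):
        out = []
        for rec in network.touching(site):
            partner = rec.res_b if rec.res_a == site else rec.res_a
            out.append(((partner, rec.itype, rec.subtype), rec))
        return out

    wt = keyed(wild)
    mt = keyed(mutant)
    wt_count = Counter(k for k, _ in wt)
    mt_count = Counter(k for k, _ in mt)

    lost, gained, retained = [], [], []
    used = Counter()
    for k, rec in wt:
        if used[k] < mt_count.get(k, 0):
            retained.append(rec)
            used[k] += 1
        else:
            lost.append(rec)
    used = Counter()
    for k, rec in mt:
        if used[k] < wt_count.get(k, 0):
            used[k] += 1
        else:
            gained.append(rec)
    return NetworkDiff(lost=lost, gained=gained, retained=retained)


def _check_same_outside_site(a: StructureModel, b: StructureModel,
                             site: ResidueId, tol: float = 1e-6) -> None:
    res_a = {r.rid: r for r in a.all_residues()}
    res_b = {r.rid: r for r in b.all_residues()}
    if set(res_a) != set(res_b):
        raise InteractionError("structures differ in residue inventory outside the site")
    for rid, ra in res_a.items():
        if rid == site:
            continue
        rb = res_b[rid]
        names_a = sorted(at.name for at in ra.atoms)
        names_b = sorted(at.name for at in rb.atoms)
        if names_a != names_b:
            raise InteractionError(f"structures differ at residue {rid} outside the site")
        for name in names_a:
            if np.linalg.norm(ra.atom(name).coords - rb.atom(name).coords) > tol:
                raise InteractionError(f"coordinates differ at residue {rid} "
                                       f"outside the site")
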