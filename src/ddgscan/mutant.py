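"""Mutant side-chain construction with rotamer selection.

A mutant model is built on the fixed wild-type backbone: the side chain is
replaced by an ideal-geometry template (taken from the Chemical Component
Dictionary bundled with biotite), candidate conformers come from a compact
backbone-independent rotamer library, wild-type chi angles are inherited where
a library rotamer lies close to them, and the final conformer minimizes a
soft-sphere clash score.  Neither the backbone nor neighboring side chains are
relaxed or repacked; Pro and Gly are handled as rigid special cases.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _tables as T
from ._geometry import angular_difference, dihedral, kabsch, rotation_about_axis
from .structure import Atom, Residue, StructureModel, write_structure

PEPTIDE_BOND_MAX = 1.8  # Å; C(i)-N(i+1) distance for a real peptide link


class MutantBuildError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rotamer library
# ---------------------------------------------------------------------------

@dataclass
class RotamerLibrary:
    """Backbone-independent rotamer library: per amino acid a list of
    (chi-angle tuple in degrees, prior probability)."""

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]]

    def __post_init__(self):
        for aa3, rots in self.rotamers.items():
            total = sum(p for _, p in rots)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{aa3}: rotamer priors sum to {total}, not 1")
            n_chi = len(T.CHI_DEFINITIONS.get(aa3, []))
            for chis, _ in rots:
                if len(chis) != n_chi:
                    raise ValueError(f"{aa3}: rotamer {chis} has {len(chis)} "
                                     f"chi angles, expected {n_chi}")

    @classmethod
    def default(cls) -> "RotamerLibrary":
        return cls({aa: list(rots) for aa, rots in T.ROTAMER_LIBRARY.items()})

    def __getitem__(self, aa3: str):
        return self.rotamers[aa3]


@dataclass
class MutantModel:
    structure: StructureModel
    site: tuple[str, int, str]
    wt_aa: str
    mut_aa: str
    rotamer: tuple[float, ...]
    clash_score: float


# ---------------------------------------------------------------------------
# Ideal residue templates (CCD-derived, heavy atoms, cached)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _template(aa3: str):
    """Heavy-atom template for a standard residue: (names, coords, bonds)."""
    import biotite.structure.info as info

    arr = info.residue(aa3)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    arr = arr[keep]
    names = [str(n) for n in arr.atom_name]
    coords = np.array(arr.coord, dtype=float)
    bonds = []
    index_of = {n: i for i, n in enumerate(names)}
    for i, j, _ in arr.bonds.as_array():
        ni, nj = arr.atom_name[i], arr.atom_name[j]
        if ni in index_of and nj in index_of:
            bonds.append((index_of[ni], index_of[nj]))
    return names, coords, bonds


def _chi_distal_sets(aa3: str):
    """Per chi angle, the template atom names moved by rotating that chi."""
    names, _, bonds = _template(aa3)
    adj: dict[int, set[int]] = {i: set() for i in range(len(names))}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    index_of = {n: i for i, n in enumerate(names)}
    out = []
    for quad in T.CHI_DEFINITIONS.get(aa3, []):
        b, c = index_of[quad[1]], index_of[quad[2]]
        # component containing c when the b-c bond is removed
        seen = {b, c}
        stack = [c]
        comp = set()
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen and not (node == c and nb == b):
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        out.append([names[i] for i in comp])
    return out


# ---------------------------------------------------------------------------
# Chi angles
# ---------------------------------------------------------------------------

def compute_chi_angles(residue: Residue) -> tuple[float, ...]:
    """Standard side-chain chi dihedrals in degrees, (-180, 180]."""
    quads = T.CHI_DEFINITIONS.get(residue.aa3)
    if quads is None:
        raise MutantBuildError(f"{residue.label}: not a standard residue")
    chis = []
    for quad in quads:
        coords = []
        for name in quad:
            atom = residue.atom(name)
            if atom is None:
                raise MutantBuildError(
                    f"{residue.label}: missing atom {name} for chi computation")
            coords.append(atom.coords)
        chis.append(dihedral(*coords))
    return tuple(chis)


# ---------------------------------------------------------------------------
# Side-chain grafting
# ---------------------------------------------------------------------------

def set_sidechain(residue: Residue, aa3: str, chis: tuple[float, ...] | None = None) -> Residue:
    """Replace the residue's side chain by an ideal-geometry template.

    The template backbone (N, CA, C) is superimposed onto the residue's
    backbone; side-chain atoms are grafted and, unless the residue is Pro
    (rigid ring) or chis is None, rotated to the requested chi angles.
    Backbone atoms are untouched.
    """
    for name in ("N", "CA", "C"):
        if residue.atom(name) is None:
            raise MutantBuildError(f"{residue.label}: missing backbone atom {name}")
    names, tcoords, _ = _template(aa3)
    index_of = {n: i for i, n in enumerate(names)}
    bb_idx = [index_of[n] for n in ("N", "CA", "C")]
    target_bb = np.array([residue.atom(n).coords for n in ("N", "CA", "C")])
    r, t = kabsch(tcoords[bb_idx], target_bb)
    placed = tcoords @ r.T + t

    coord_of = {n: placed[i].copy() for i, n in enumerate(names)}
    # chi angles are defined against the residue's actual backbone, not the
    # superimposed template backbone
    for n in ("N", "CA", "C"):
        coord_of[n] = residue.atom(n).coords.copy()
    if chis is not None and aa3 != "PRO":
        for quad, target_chi, distal in zip(
                T.CHI_DEFINITIONS.get(aa3, []), chis, _chi_distal_sets(aa3)):
            p = [coord_of[n] for n in quad]
            current = dihedral(*p)
            axis_origin = coord_of[quad[1]]
            axis = coord_of[quad[2]] - axis_origin
            # rotating +theta about the b->c axis increases the a-b-c-d dihedral
            rot = rotation_about_axis(axis, target_chi - current)
            for n in distal:
                coord_of[n] = (coord_of[n] - axis_origin) @ rot.T + axis_origin

    backbone = [a for a in residue.atoms if a.name in T.BACKBONE_ATOMS]
    sidechain = []
    for n in T.SIDECHAIN_ATOMS[aa3]:
        classes = T.pharmacophores_for(aa3, n) or frozenset({"neutral"})
        sidechain.append(Atom(name=n, element=n[0] if n[0] != "O" else "O",
                              coords=coord_of[n], pharmacophores=classes,
                              is_backbone=False))
    # fix element symbols (first letter is the element for standard side chains)
    for a in sidechain:
        a.element = "S" if a.name.startswith("S") else a.name[0]
    residue.aa3 = aa3
    residue.atoms = backbone + sidechain
    for a in backbone:
        classes = T.pharmacophores_for(aa3, a.name)
        if classes is not None:
            a.pharmacophores = classes
    return residue


# ---------------------------------------------------------------------------
# Clash score
# ---------------------------------------------------------------------------

def _bonded_exclusions(structure: StructureModel, residue: Residue) -> set[tuple[int, str]]:
    """Atom keys (id(res), atom name) within 3 covalent bonds of the site's
    side chain through the backbone, i.e. pairs excluded from clash/contact
    scoring.  Only peptide-bonded sequence neighbors qualify."""
    excluded = set()
    chain = structure.chains.get(residue.chain_id, [])
    idx = next((i for i, r in enumerate(chain) if r is residue), None)
    if idx is None:
        return excluded

    def peptide_bonded(r1: Residue, r2: Residue) -> bool:
        c, n = r1.atom("C"), r2.atom("N")
        return (c is not None and n is not None
                and np.linalg.norm(c.coords - n.coords) <= PEPTIDE_BOND_MAX)

    # Side-chain atoms at graph distance <= 3 from neighbor-residue atoms:
    # CB-CA-C-N(i+1) and CB-CA-N-C(i-1); Pro's ring adds CD/CG paths.
    if idx + 1 < len(chain) and peptide_bonded(residue, chain[idx + 1]):
        excluded.add((id(chain[idx + 1]), "N"))
    if idx > 0 and peptide_bonded(chain[idx - 1], residue):
        excluded.add((id(chain[idx - 1]), "C"))
        if residue.aa3 == "PRO":
            excluded.add((id(chain[idx - 1]), "O"))
            excluded.add((id(chain[idx - 1]), "CA"))
    return excluded


def clash_score(structure: StructureModel, site: tuple[str, int, str] | Residue) -> float:
    """Soft-sphere overlap of the site's side chain against the rest of the
    structure: sum over non-bonded heavy-atom pairs of max(0, r_vdw_sum - d)^2.
    Zero iff no van-der-Waals overlap."""
    residue = site if isinstance(site, Residue) else \
        structure.get_residue(site[0], site[1], site[2])
    if residue is None:
        raise MutantBuildError(f"clash_score: site {site} not in structure")
    side = [a for a in residue.atoms if a.name not in T.BACKBONE_ATOMS]
    if not side:
        return 0.0
    excluded = _bonded_exclusions(structure, residue)

    others, other_coords = [], []
    for res in structure.all_residues():
        if res is residue:
            continue
        for a in res.atoms:
            others.append((id(res), a))
            other_coords.append(a.coords)
    if not others:
        return 0.0
    other_coords = np.array(other_coords)
    tree = cKDTree(other_coords)
    score = 0.0
    for a in side:
        ra = T.VDW_RADII.get(a.element, T.VDW_DEFAULT)
        for j in tree.query_ball_point(a.coords, r=ra + 2.4):
            res_id, b = others[j]
            if (res_id, b.name) in excluded and a.name == "CB" or \
               (res_id, b.name) in excluded and residue.aa3 == "PRO":
                continue
            rb = T.VDW_RADII.get(b.element, T.VDW_DEFAULT)
            d = float(np.linalg.norm(a.coords - b.coords))
            overlap = ra + rb - d
            if overlap > 0:
                score += overlap * overlap
    return float(score)


# ---------------------------------------------------------------------------
# Mutant construction
# ---------------------------------------------------------------------------

def build_mutant(structure: StructureModel, site: tuple[str, int, str],
                 mut_aa: str, library: RotamerLibrary | None = None) -> MutantModel:
    """Build a mutant structure by side-chain replacement at one site.

    Candidate rotamers come from the library; if the wild type shares leading
    chi angles with the target amino acid, candidates within 40 degrees of the
    wild-type values are preferred (chi inheritance); among the surviving
    candidates the one minimizing the clash score wins, ties broken by higher
    prior probability then library order.  Backbone coordinates are identical
    to the wild type everywhere.
    """
    library = library or RotamerLibrary.default()
    mut_aa3 = T.AA1_TO_AA3.get(mut_aa.upper(), mut_aa.upper())
    if mut_aa3 not in T.SIDECHAIN_ATOMS:
        raise MutantBuildError(f"unknown target amino acid {mut_aa!r}")
    chain_id, seq_num, icode = site
    wt_res = structure.get_residue(chain_id, seq_num, icode)
    if wt_res is None:
        raise MutantBuildError(f"site {site} not found in structure")
    for name in ("N", "CA", "C"):
        if wt_res.atom(name) is None:
            raise MutantBuildError(f"{wt_res.label}: missing backbone atom {name}")
    wt_aa = wt_res.aa1

    # identity mutation with complete coordinates: no rebuild
    if mut_aa3 == wt_res.aa3 and all(
            wt_res.atom(n) is not None for n in T.SIDECHAIN_ATOMS[wt_res.aa3]):
        mutant = copy.deepcopy(structure)
        res = mutant.get_residue(chain_id, seq_num, icode)
        chis = compute_chi_angles(res) if T.CHI_DEFINITIONS.get(res.aa3) else ()
        return MutantModel(mutant, site, wt_aa, mut_aa.upper(), tuple(chis),
                           clash_score(mutant, res))

    try:
        wt_chis = compute_chi_angles(wt_res)
    except MutantBuildError:
        wt_chis = ()

    candidates = library[mut_aa3]
    # chi angles transfer across types only at chi1 (deeper angles are not
    # chemically comparable between different side chains); a same-type
    # rebuild inherits the full shared prefix
    n_shared = min(len(wt_chis), len(T.CHI_DEFINITIONS.get(mut_aa3, [])))
    if mut_aa3 != wt_res.aa3:
        n_shared = min(n_shared, 1)
    pool = list(enumerate(candidates))
    for lead in range(n_shared, 0, -1):
        subset = [
            (i, (chis, p)) for i, (chis, p) in pool
            if all(angular_difference(chis[k], wt_chis[k]) <= 40.0
                   for k in range(lead))
        ]
        if subset:
            pool = subset
            break

    best = None
    for lib_index, (chis, prob) in pool:
        mutant = copy.deepcopy(structure)
        res = mutant.get_residue(chain_id, seq_num, icode)
        set_sidechain(res, mut_aa3, chis)
        score = clash_score(mutant, res)
        key = (round(score, 9), -prob, lib_index)
        if best is None or key < best[0]:
            measured = tuple(compute_chi_angles(res)) if T.CHI_DEFINITIONS.get(mut_aa3) else ()
            best = (key, mutant, measured, score)
    _, mutant, measured, score = best
    return MutantModel(mutant, site, wt_aa, mut_aa.upper(), measured, score)


def write_mutant_pdb(mutant: MutantModel, path: str | Path) -> None:
    """Write the mutant as PDB with a REMARK recording the substitution."""
    path = Path(path)
    write_structure(mutant.structure, path)
    chain, num, icode = mutant.site
    remark = (f"REMARK 300 DDGSCAN MUTANT {mutant.wt_aa}{num}{icode.strip()}"
              f"{mutant.mut_aa} CHAIN {chain} ROTAMER "
              f"{','.join(f'{c:.1f}' for c in mutant.rotamer) or '-'} "
              f"CLASH {mutant.clash_score:.4f}\n")
    text = path.read_text()
    path.write_text(remark + text)
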