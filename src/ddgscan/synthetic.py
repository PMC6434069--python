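"""Synthetic fixture generation: every pipeline stage is testable without
downloads.

The generators build idealized objects with *known ground truth*:

* :func:`make_helix` — ideal alpha-helices from internal coordinates;
* :func:`make_dimer` — two parallel helices with engineered interface
  contacts realized by deterministic side-chain placement in the inter-helix
  gap (side chains of contact residues are positioned geometrically rather
  than rotamerically, so every listed contact is realized exactly);
* :func:`make_pocket` — a small-molecule ligand (purine-like toy compound
  with one aromatic ring, H-bond partners and a phosphate-like tail)
  surrounded by engineered binding residues and optional metal ions;
* :func:`make_families` — aligned homolog families with controlled,
  environment-dependent substitution statistics for substitution-table
  derivation;
* :func:`make_mutation_table` — labelled mutation tables with exact class
  proportions (largest-remainder allocation);
* :func:`make_paralog_pair` — a synthetic pair of diverged paralog sequences
  with known alignment-frame identity (a stand-in for a real paralog pair
  when reference sequences are not available locally).

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tables as T
from ._geometry import fit_plane, place_atom, rotation_about_axis
from .mutant import RotamerLibrary, _template, set_sidechain
from .structure import (Atom, Residue, SiteSelection, StructureModel,
                        assign_pharmacophores)


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ideal helix
# ---------------------------------------------------------------------------

# Engh-Huber-style ideal backbone geometry
_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.8


@dataclass
class HelixSpec:
    sequence: str
    phi: float = -57.0
    psi: float = -47.0
    chain_id: str = "A"
    start_seq: int = 1
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not self.sequence:
            raise SyntheticError("helix sequence must be non-empty")
        for ch in self.sequence:
            if ch not in T.AA1_TO_AA3:
                raise SyntheticError(f"non-standard residue letter {ch!r}")


def _build_backbone(n: int, phi: float, psi: float, omega: float = 180.0):
    """N/CA/C/O coordinates for an ideal (phi, psi) repeat, NeRF-built."""
    ncoords, cacoords, ccoords = [], [], []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_NCA, 0.0, 0.0])
    ang = np.radians(_A_NCAC)
    c0 = ca0 + _B_CAC * np.array([-np.cos(ang), np.sin(ang), 0.0])
    ncoords.append(n0), cacoords.append(ca0), ccoords.append(c0)
    for i in range(1, n):
        n_next = place_atom(ncoords[-1], cacoords[-1], ccoords[-1], _B_CN, _A_CACN, psi)
        ca_next = place_atom(cacoords[-1], ccoords[-1], n_next, _B_NCA, _A_CNCA, omega)
        c_next = place_atom(ccoords[-1], n_next, ca_next, _B_CAC, _A_NCAC, phi)
        ncoords.append(n_next), cacoords.append(ca_next), ccoords.append(c_next)
    ocoords = []
    for i in range(n):
        if i + 1 < n:
            o = place_atom(ncoords[i + 1], cacoords[i], ccoords[i], _B_CO, _A_CACO, 180.0)
        else:
            o = place_atom(ncoords[i], cacoords[i], ccoords[i], _B_CO, _A_CACO, psi + 180.0)
        ocoords.append(o)
    return np.array(ncoords), np.array(cacoords), np.array(ccoords), np.array(ocoords)


def make_helix(spec: HelixSpec, library: RotamerLibrary | None = None) -> StructureModel:
    """Build an ideal helix; side chains carry the library's top rotamer.

    The helix axis (least-squares line through the C-alphas) is aligned onto
    ``spec.axis`` and the first C-alpha is shifted to ``spec.origin``.
    """
    library = library or RotamerLibrary.default()
    seq = spec.sequence
    ncoords, cacoords, ccoords, ocoords = _build_backbone(len(seq), spec.phi, spec.psi)

    residues = []
    for i, aa1 in enumerate(seq):
        aa3 = T.AA1_TO_AA3[aa1]
        atoms = [
            Atom("N", "N", ncoords[i], is_backbone=True),
            Atom("CA", "C", cacoords[i], is_backbone=True),
            Atom("C", "C", ccoords[i], is_backbone=True),
            Atom("O", "O", ocoords[i], is_backbone=True),
        ]
        res = Residue(spec.chain_id, spec.start_seq + i, "", aa3, atoms)
        if aa3 != "GLY":
            top_chis = library[aa3][0][0]
            set_sidechain(res, aa3, top_chis)
        residues.append(res)

    # orient: helix axis -> spec.axis, first CA -> origin
    if len(cacoords) >= 2:
        centroid = cacoords.mean(axis=0)
        _, _, vt = np.linalg.svd(cacoords - centroid)
        current_axis = vt[0]
        if np.dot(cacoords[-1] - cacoords[0], current_axis) < 0:
            current_axis = -current_axis
    else:
        current_axis = np.array([0.0, 0.0, 1.0])
    target_axis = np.asarray(spec.axis, dtype=float)
    target_axis = target_axis / np.linalg.norm(target_axis)
    v = np.cross(current_axis, target_axis)
    c = float(np.dot(current_axis, target_axis))
    if np.linalg.norm(v) < 1e-9:
        rot = np.eye(3) if c > 0 else rotation_about_axis(
            np.array([1.0, 0.0, 0.0]) if abs(current_axis[0]) < 0.9
            else np.array([0.0, 1.0, 0.0]), 180.0)
    else:
        angle_deg = float(np.degrees(np.arctan2(np.linalg.norm(v), c)))
        rot = rotation_about_axis(v, angle_deg)
    origin = np.asarray(spec.origin, dtype=float)
    shift = origin - cacoords[0] @ rot.T
    for res in residues:
        for a in res.atoms:
            a.coords = a.coords @ rot.T + shift

    model = StructureModel(chains={spec.chain_id: residues}, title="synthetic helix")
    return assign_pharmacophores(model)


# ---------------------------------------------------------------------------
# Engineered dimer interface
# ---------------------------------------------------------------------------

_CONTACT_KINDS = {
    "hbond": ("SER", "OG", 1.40),       # key atom offset from the mid-plane
    "proximal": ("LEU", "CD1", 2.00),
    "ring_stack": ("PHE", None, 1.90),  # ring centroid offset
}


def _graft_key_atom(res: Residue, key_atom: str, target: np.ndarray,
                    inward: np.ndarray) -> None:
    """Rigidly re-place the residue's side chain so its key atom lands on
    ``target`` with the CB->key direction along ``inward``.  The side chain
    detaches from its own backbone: acceptable for a geometric fixture."""
    side = [a for a in res.atoms if a.name not in T.BACKBONE_ATOMS]
    key = res.atom(key_atom)
    cb = res.atom("CB")
    v1 = key.coords - cb.coords
    v1 = v1 / np.linalg.norm(v1)
    inward = inward / np.linalg.norm(inward)
    cross = np.cross(v1, inward)
    dot = float(np.dot(v1, inward))
    if np.linalg.norm(cross) < 1e-9:
        rot = np.eye(3) if dot > 0 else -np.eye(3)
    else:
        rot = rotation_about_axis(cross, float(np.degrees(np.arctan2(np.linalg.norm(cross), dot))))
    pivot = key.coords.copy()
    for a in side:
        a.coords = (a.coords - pivot) @ rot.T + pivot
    shift = target - key.coords
    for a in side:
        a.coords = a.coords + shift


def _graft_ring(res: Residue, centroid_target: np.ndarray, normal: np.ndarray) -> None:
    """Place an aromatic side-chain ring at a target centroid with a target
    normal (used to realize exact parallel stacks)."""
    ring_names = T.RING_DEFINITIONS[res.aa3][0][1]
    side = [a for a in res.atoms if a.name not in T.BACKBONE_ATOMS]
    pts = np.array([res.atom(n).coords for n in ring_names])
    centroid, cur_normal = fit_plane(pts)
    normal = normal / np.linalg.norm(normal)
    cross = np.cross(cur_normal, normal)
    dot = float(np.dot(cur_normal, normal))
    if np.linalg.norm(cross) < 1e-9:
        rot = np.eye(3) if dot > 0 else rotation_about_axis(
            np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0]), 180.0)
    else:
        rot = rotation_about_axis(cross, float(np.degrees(np.arctan2(np.linalg.norm(cross), dot))))
    for a in side:
        a.coords = (a.coords - centroid) @ rot.T + centroid
    pts = np.array([res.atom(n).coords for n in ring_names])
    shift = centroid_target - pts.mean(axis=0)
    for a in side:
        a.coords = a.coords + shift


def make_dimer(spec_a: HelixSpec, spec_b: HelixSpec,
               interaxial_distance: float = 14.0,
               contacts: list[tuple[int, int, str]] = (),
               cutoff: float = 5.0) -> tuple[StructureModel, SiteSelection, SiteSelection]:
    """Two parallel helices with engineered interface contacts.

    ``contacts`` lists (position in chain A, position in chain B, kind) with
    kind in {hbond, proximal, ring_stack}; the named positions must carry the
    residue type the kind requires (SER/LEU/PHE).  Contact side chains are
    placed symmetrically about the inter-helix mid-plane so each listed
    interaction is realized exactly; the scaffold should be short-side-chain
    (Gly) so that *only* engineered positions cross the ``cutoff``.  The
    build verifies this and raises :class:`SyntheticError` otherwise.

    Returns (structure, ground-truth selection chain A, ground truth chain B).
    """
    helix_a = make_helix(HelixSpec(spec_a.sequence, spec_a.phi, spec_a.psi,
                                   chain_id=spec_a.chain_id or "A",
                                   start_seq=spec_a.start_seq,
                                   origin=(0, 0, 0), axis=(0, 0, 1)))
    helix_b = make_helix(HelixSpec(spec_b.sequence, spec_b.phi, spec_b.psi,
                                   chain_id=spec_b.chain_id or "B",
                                   start_seq=spec_b.start_seq,
                                   origin=(interaxial_distance, 0, 0), axis=(0, 0, 1)))
    cid_a = spec_a.chain_id or "A"
    cid_b = spec_b.chain_id or "B"
    if cid_a == cid_b:
        raise SyntheticError("dimer chains need distinct chain ids")
    model = StructureModel(
        chains={cid_a: helix_a.chains[cid_a], cid_b: helix_b.chains[cid_b]},
        title="synthetic dimer")

    mid_x = interaxial_distance / 2.0
    for pos_a, pos_b, kind in contacts:
        if kind not in _CONTACT_KINDS:
            raise SyntheticError(f"unknown contact kind {kind!r}")
        resname, key_atom, offset = _CONTACT_KINDS[kind]
        res_a = model.get_residue(cid_a, pos_a)
        res_b = model.get_residue(cid_b, pos_b)
        if res_a is None or res_b is None:
            raise SyntheticError(f"contact positions ({pos_a}, {pos_b}) not in helices")
        if res_a.aa3 != resname or res_b.aa3 != resname:
            raise SyntheticError(
                f"contact kind {kind!r} requires {resname} at both positions "
                f"(found {res_a.aa3}/{res_b.aa3})")
        z_c = (res_a.atom("CA").coords[2] + res_b.atom("CA").coords[2]) / 2.0
        y_c = (res_a.atom("CA").coords[1] + res_b.atom("CA").coords[1]) / 2.0
        center = np.array([mid_x, y_c, z_c])
        if kind == "ring_stack":
            _graft_ring(res_a, center - np.array([offset, 0, 0]), np.array([1.0, 0, 0]))
            _graft_ring(res_b, center + np.array([offset, 0, 0]), np.array([1.0, 0, 0]))
        else:
            _graft_key_atom(res_a, key_atom, center - np.array([offset, 0, 0]),
                            inward=np.array([1.0, 0, 0]))
            _graft_key_atom(res_b, key_atom, center + np.array([offset, 0, 0]),
                            inward=np.array([-1.0, 0, 0]))

    assign_pharmacophores(model)

    # ground-truth check: exactly the engineered positions cross the cutoff
    truth_a = sorted({pos for pos, _, _ in contacts})
    truth_b = sorted({pos for _, pos, _ in contacts})
    found_a, found_b = set(), set()
    for ra in model.chains[cid_a]:
        ca_coords = ra.coords()
        for rb in model.chains[cid_b]:
            d = np.linalg.norm(ca_coords[:, None, :] - rb.coords()[None, :, :], axis=2)
            if d.min() <= cutoff:
                found_a.add(ra.seq_num)
                found_b.add(rb.seq_num)
    if found_a != set(truth_a) or found_b != set(truth_b):
        raise SyntheticError(
            f"engineered interface not realized cleanly: designed "
            f"{truth_a}/{truth_b}, within cutoff {sorted(found_a)}/{sorted(found_b)}")
    sel_a = SiteSelection([(cid_a, p, "") for p in truth_a], label="dimer_interface_A")
    sel_b = SiteSelection([(cid_b, p, "") for p in truth_b], label="dimer_interface_B")
    return model, sel_a, sel_b


# ---------------------------------------------------------------------------
# Engineered ligand pocket
# ---------------------------------------------------------------------------

def make_ligand_template(name: str = "LIG") -> Residue:
    """Toy purine-like ligand: aromatic 6-ring, amine N, hydroxyl O and a
    phosphate-like tail, in the xy-plane centred at the origin."""
    atoms = []
    ring_radius = 1.39
    for i in range(6):
        ang = np.radians(60.0 * i)
        atoms.append(Atom(f"C{i+1}", "C",
                          [ring_radius * np.cos(ang), ring_radius * np.sin(ang), 0.0]))
    def radial(i):
        ang = np.radians(60.0 * i)
        return np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms.append(Atom("N7", "N", atoms[0].coords + 1.34 * radial(0)))
    atoms.append(Atom("O8", "O", atoms[3].coords + 1.36 * radial(3)))
    o10 = atoms[1].coords + 1.36 * radial(1)
    p9 = o10 + 1.60 * radial(1)
    atoms.append(Atom("O10", "O", o10))
    atoms.append(Atom("P9", "P", p9))
    atoms.append(Atom("O11", "O", p9 + 1.49 * (rotation_about_axis(np.array([0, 0, 1.0]), 109.0) @ radial(1))))
    atoms.append(Atom("O12", "O", p9 + 1.49 * np.array([0.35 * radial(1)[0], 0.35 * radial(1)[1], 0.94])))
    atoms.append(Atom("O13", "O", p9 + 1.49 * radial(1)))
    return Residue("L", 1, "", name, atoms, is_het=True)


_POCKET_ANCHORS = {
    "hbond": ["O8", "N7", "O10"],
    "proximal": ["C5", "C3"],
    "metal": ["O13", "O12"],
    "pi_stack": [None, None],  # ring face above / below
}
_POCKET_RESTYPE = {"hbond": "SER", "proximal": "LEU", "metal": "HIS", "pi_stack": "PHE"}


def _place_pocket_residue(aa3: str, key_atom: str, target: np.ndarray,
                          outward: np.ndarray, chain_id: str, seq_num: int) -> Residue:
    """A full ideal residue positioned so its key atom sits on target and the
    residue body extends outward from the ligand."""
    names, coords, _ = _template(aa3)
    atoms = [Atom(n, ("S" if n.startswith("S") else n[0]), c.copy(),
                  is_backbone=n in T.BACKBONE_ATOMS)
             for n, c in zip(names, coords)]
    res = Residue(chain_id, seq_num, "", aa3, atoms)
    key = res.atom(key_atom)
    ca = res.atom("CA")
    v1 = ca.coords - key.coords
    v1 = v1 / np.linalg.norm(v1)
    outward = outward / np.linalg.norm(outward)
    cross = np.cross(v1, outward)
    dot = float(np.dot(v1, outward))
    if np.linalg.norm(cross) < 1e-9:
        rot = np.eye(3) if dot > 0 else rotation_about_axis(np.array([0, 0, 1.0]), 180.0)
    else:
        rot = rotation_about_axis(cross, float(np.degrees(np.arctan2(np.linalg.norm(cross), dot))))
    pivot = key.coords.copy()
    for a in res.atoms:
        a.coords = (a.coords - pivot) @ rot.T + pivot
    shift = target - key.coords
    for a in res.atoms:
        a.coords = a.coords + shift
    return res


def make_pocket(interactions: list[str],
                ligand_name: str = "LIG",
                chain_id: str = "A") -> tuple[StructureModel, SiteSelection]:
    """A ligand surrounded by engineered binding residues.

    ``interactions`` lists kinds from {hbond, pi_stack, metal, proximal};
    each entry adds one residue (SER / PHE / HIS / LEU) placed so the listed
    interaction is realized (metal adds a Zn ion bridging ligand and His).
    Residues are numbered 10, 20, 30, ... so that no peptide bonds are
    implied.  Returns (structure, ground-truth binding-residue selection).
    """
    ligand = make_ligand_template(ligand_name)
    model = StructureModel(chains={chain_id: []}, ligands=[ligand],
                           title="synthetic pocket")
    anchors_used: dict[str, int] = {}
    pi_faces = iter([np.array([0, 0, 1.0]), np.array([0, 0, -1.0])])
    seq_num = 10
    truth: list[tuple[str, int, str]] = []
    metal_count = 0
    for kind in interactions:
        if kind not in _POCKET_RESTYPE:
            raise SyntheticError(f"unknown pocket interaction kind {kind!r}")
        aa3 = _POCKET_RESTYPE[kind]
        if kind == "pi_stack":
            try:
                normal = next(pi_faces)
            except StopIteration:
                raise SyntheticError("no free ring face for another pi_stack")
            names, coords, _ = _template(aa3)
            atoms = [Atom(n, ("S" if n.startswith("S") else n[0]), c.copy(),
                          is_backbone=n in T.BACKBONE_ATOMS)
                     for n, c in zip(names, coords)]
            res = Residue(chain_id, seq_num, "", aa3, atoms)
            ring_names = T.RING_DEFINITIONS[aa3][0][1]
            # rigidly orient the whole residue: ring normal along the face
            # normal, ring centroid stacked 3.8 A above the ligand ring
            pts = np.array([res.atom(n).coords for n in ring_names])
            centroid, cur_normal = fit_plane(pts)
            cross = np.cross(cur_normal, normal)
            dot = float(np.dot(cur_normal, normal))
            if np.linalg.norm(cross) < 1e-9:
                rot = np.eye(3) if dot > 0 else rotation_about_axis(
                    np.array([1.0, 0, 0]), 180.0)
            else:
                rot = rotation_about_axis(
                    cross, float(np.degrees(np.arctan2(np.linalg.norm(cross), dot))))
            for a in res.atoms:
                a.coords = (a.coords - centroid) @ rot.T + centroid
            # keep the residue body on the far side of the stack
            ca = res.atom("CA")
            pts = np.array([res.atom(n).coords for n in ring_names])
            centroid = pts.mean(axis=0)
            if float(np.dot(ca.coords - centroid, normal)) < 0:
                in_plane = pts[0] - centroid
                flip = rotation_about_axis(in_plane, 180.0)
                for a in res.atoms:
                    a.coords = (a.coords - centroid) @ flip.T + centroid
            pts = np.array([res.atom(n).coords for n in ring_names])
            shift = 3.8 * normal - pts.mean(axis=0)
            for a in res.atoms:
                a.coords = a.coords + shift
        else:
            idx = anchors_used.get(kind, 0)
            anchors = _POCKET_ANCHORS[kind]
            if idx >= len(anchors):
                raise SyntheticError(f"no free anchor for another {kind!r} contact")
            anchors_used[kind] = idx + 1
            anchor_atom = ligand.atom(anchors[idx])
            outward = anchor_atom.coords.copy()
            outward[2] = 0.0
            if np.linalg.norm(outward) < 1e-6:
                outward = np.array([1.0, 0, 0])
            outward = outward / np.linalg.norm(outward)
            if kind == "hbond":
                target = anchor_atom.coords + 2.85 * outward
                res = _place_pocket_residue(aa3, "OG", target, outward, chain_id, seq_num)
            elif kind == "proximal":
                target = anchor_atom.coords + 4.0 * outward
                res = _place_pocket_residue(aa3, "CD1", target, outward, chain_id, seq_num)
            else:  # metal: ligand O ... Zn ... His NE2
                metal_count += 1
                zn_pos = anchor_atom.coords + 2.05 * outward
                model.metals.append(Residue("M", 900 + metal_count, "", "ZN",
                                            [Atom("ZN", "ZN", zn_pos)], is_het=True))
                target = zn_pos + 2.15 * outward
                res = _place_pocket_residue(aa3, "NE2", target, outward, chain_id, seq_num)
        model.chains[chain_id].append(res)
        truth.append((chain_id, seq_num, ""))
        seq_num += 10
    assign_pharmacophores(model)
    return model, SiteSelection(truth, label="ligand_pocket")


# ---------------------------------------------------------------------------
# Random structures (for oracle-equivalence sweeps)
# ---------------------------------------------------------------------------

def random_structure(seed: int) -> StructureModel:
    """A small random synthetic structure (helix, dimer or pocket) suitable
    for all-pairs interaction-oracle comparisons (<= 500 atoms)."""
    rng = np.random.default_rng(seed)
    kind = rng.integers(0, 3)
    aa_pool = list("ACDEFGHIKLMNQRSTVWY")  # no Pro in helical fixtures
    if kind == 0:
        n = int(rng.integers(8, 20))
        seq = "".join(rng.choice(aa_pool, size=n))
        return make_helix(HelixSpec(seq))
    if kind == 1:
        n = int(rng.integers(12, 20))
        kinds = ["hbond", "proximal", "ring_stack"]
        pos = int(rng.integers(4, n - 4))
        k = kinds[int(rng.integers(0, 3))]
        resname = {"hbond": "S", "proximal": "L", "ring_stack": "F"}[k]
        seq = ["G"] * n
        seq[pos - 1] = resname
        seq = "".join(seq)
        return make_dimer(HelixSpec(seq, chain_id="A"), HelixSpec(seq, chain_id="B"),
                          contacts=[(pos, pos, k)])[0]
    kinds = ["hbond", "pi_stack", "metal", "proximal"]
    chosen = list(rng.choice(kinds, size=int(rng.integers(2, 5)), replace=True))
    # respect anchor capacity
    capped = []
    used: dict[str, int] = {}
    caps = {"hbond": 3, "pi_stack": 2, "metal": 2, "proximal": 2}
    for k in chosen:
        if used.get(k, 0) < caps[k]:
            capped.append(k)
            used[k] = used.get(k, 0) + 1
    return make_pocket(capped)[0]


# ---------------------------------------------------------------------------
# Homolog families with controlled substitution statistics
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    ancestral_sequence: str
    substitution_matrices: dict[str, np.ndarray]  # env label -> 20x20 row-stochastic
    env_labels: list[str] = field(default_factory=list)  # per column
    n_homologs: int = 100
    seed: int = 0

    def __post_init__(self):
        if len(self.env_labels) != len(self.ancestral_sequence):
            raise SyntheticError("one environment label per column required")
        for label, mat in self.substitution_matrices.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (20, 20) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise SyntheticError(f"substitution matrix {label!r} must be "
                                     f"20x20 row-stochastic")
            self.substitution_matrices[label] = mat


def environment_substitution_matrices(retention: float = 0.7) -> dict[str, np.ndarray]:
    """Row-stochastic 20x20 substitution matrices for the nine structural
    environments (secondary structure x accessibility).

    Each row keeps the ancestral residue with probability ``retention`` and
    spreads the rest according to environment-dependent acceptance weights:
    buried environments favor hydrophobic replacements, exposed ones polar
    or charged replacements, and the secondary-structure axis modulates
    helix/strand formers.  This gives every environment a distinct, known
    log-odds structure for substitution-table recovery tests.
    """
    aa = list(T.STANDARD_AA1)
    hydro = np.array([max(T.AA_HYDROPATHY[x], 0.0) + 0.3 for x in aa])
    polar = np.array([max(-T.AA_HYDROPATHY[x], 0.0) + 0.3 for x in aa])
    helix_formers = {"A": 1.6, "E": 1.5, "L": 1.4, "M": 1.3, "Q": 1.3, "K": 1.2}
    strand_formers = {"V": 1.6, "I": 1.5, "Y": 1.4, "F": 1.3, "W": 1.3, "T": 1.2}
    out = {}
    for ss in ("helix", "strand", "coil"):
        ss_w = np.array([
            helix_formers.get(x, 1.0) if ss == "helix"
            else strand_formers.get(x, 1.0) if ss == "strand" else 1.0
            for x in aa])
        for acc, acc_w in (("buried", hydro), ("partial", 0.5 * hydro + 0.5 * polar),
                           ("exposed", polar)):
            weights = acc_w * ss_w
            mat = np.zeros((20, 20))
            for i in range(20):
                w = weights.copy()
                w[i] = 0.0
                w = w / w.sum() * (1.0 - retention)
                mat[i] = w
                mat[i, i] = retention
            out[f"{ss}_{acc}"] = mat
    return out


def make_esst_family(seed: int = 11, n_homologs: int = 200,
                     columns_per_env: int = 40) -> tuple[FamilySpec, dict[str, np.ndarray]]:
    """A FamilySpec covering all nine environments with every amino acid
    represented (columns cycle through the alphabet), plus the generating
    matrices for recovery checks."""
    matrices = environment_substitution_matrices()
    envs = sorted(matrices)
    rng = np.random.default_rng(seed)
    ancestral, labels = [], []
    aa = list(T.STANDARD_AA1)
    for env in envs:
        block = [aa[(k + int(rng.integers(0, 20))) % 20] for k in range(columns_per_env)]
        ancestral += block
        labels += [env] * columns_per_env
    spec = FamilySpec(ancestral_sequence="".join(ancestral),
                      substitution_matrices=matrices,
                      env_labels=labels, n_homologs=n_homologs, seed=seed)
    return spec, matrices


def make_families(spec: FamilySpec) -> list[str]:
    """Sample aligned homologs column-independently: column j of homolog h is
    drawn from the row of the column's environment matrix indexed by the
    ancestral amino acid.  The alignment frame is the generation frame."""
    rng = np.random.default_rng(spec.seed)
    aa_order = list(T.STANDARD_AA1)
    aa_index = {aa: i for i, aa in enumerate(aa_order)}
    cols = []
    for j, (aa, env) in enumerate(zip(spec.ancestral_sequence, spec.env_labels)):
        probs = spec.substitution_matrices[env][aa_index[aa]]
        draws = rng.choice(20, size=spec.n_homologs, p=probs)
        cols.append([aa_order[k] for k in draws])
    return ["".join(cols[j][h] for j in range(len(cols)))
            for h in range(spec.n_homologs)]


# ---------------------------------------------------------------------------
# Mutation tables with exact class proportions
# ---------------------------------------------------------------------------

def make_mutation_table(structure: StructureModel, n: int,
                        proportions: dict[str, float], seed: int):
    """n mutation specs over the structure's residues with class labels
    allocated deterministically (largest remainder), seed-reproducible.

    Returns (list of (chain, seq_num, wt_aa, mut_aa, label)).
    """
    from .pipeline import MutationSpec, MutationTable

    if n <= 0:
        raise SyntheticError("n must be positive")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise SyntheticError("class proportions must sum to 1")
    labels = sorted(proportions)
    quotas = {lab: proportions[lab] * n for lab in labels}
    counts = {lab: int(np.floor(quotas[lab])) for lab in labels}
    remainder = n - sum(counts.values())
    by_frac = sorted(labels, key=lambda lab: (-(quotas[lab] - counts[lab]), lab))
    for lab in by_frac[:remainder]:
        counts[lab] += 1

    rng = np.random.default_rng(seed)
    residues = [r for r in structure.polymer_residues() if r.aa1 in T.AA1_TO_AA3]
    if n > 19 * len(residues):
        raise SyntheticError(f"cannot draw {n} unique substitutions from "
                             f"{len(residues)} residues")
    specs, true_labels = [], []
    seen = set()
    for lab in labels:
        for _ in range(counts[lab]):
            while True:
                res = residues[int(rng.integers(0, len(residues)))]
                others = [aa for aa in T.STANDARD_AA1 if aa != res.aa1]
                mut = others[int(rng.integers(0, len(others)))]
                key = (res.chain_id, res.seq_num, res.aa1, mut)
                if key not in seen:
                    seen.add(key)
                    break
            specs.append(MutationSpec(chain=res.chain_id, position=res.seq_num,
                                      wt_aa=res.aa1, mut_aa=mut, source="user"))
            true_labels.append(lab)
    return MutationTable(specs, provenance=f"synthetic seed={seed}"), true_labels


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def write_fixture_files(out_dir, seed: int = 0) -> list:
    """Write the standard fixture set (PDB/FASTA/CSV) into a directory."""
    from pathlib import Path

    from .structure import write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    helix = make_helix(HelixSpec("ALKAAEQFLAKA"))
    write_structure(helix, out / "helix.pdb")
    paths.append(out / "helix.pdb")

    seq = ["G"] * 24
    seq[5], seq[11], seq[17] = "S", "F", "L"
    seq = "".join(seq)
    dimer, _, _ = make_dimer(HelixSpec(seq, chain_id="A"),
                             HelixSpec(seq, chain_id="B"),
                             contacts=[(6, 6, "hbond"), (12, 12, "ring_stack"),
                                       (18, 18, "proximal")])
    write_structure(dimer, out / "dimer.pdb")
    paths.append(out / "dimer.pdb")

    pocket, _ = make_pocket(["hbond", "pi_stack", "metal", "proximal", "hbond"])
    write_structure(pocket, out / "pocket.pdb")
    paths.append(out / "pocket.pdb")

    seq_a, seq_b, truth = make_paralog_pair(seed=seed)
    (out / "synthetic_paralogs.fasta").write_text(
        f">synthetic_paralog_A ground_truth_identity={truth:.2f}\n{seq_a}\n"
        f">synthetic_paralog_B\n{seq_b}\n")
    paths.append(out / "synthetic_paralogs.fasta")

    table, labels = make_mutation_table(
        pocket, n=20, proportions={"stabilizing": 0.1,
                                   "slightly_destabilizing": 0.7,
                                   "highly_destabilizing": 0.2}, seed=seed)
    lines = ["gene_or_chain,protein_change,source"]
    lines += [f"{m.chain},{m.wt_aa}{m.position}{m.mut_aa},{m.source}" for m in table]
    (out / "mutations.csv").write_text("\n".join(lines) + "\n")
    paths.append(out / "mutations.csv")
    return paths


# ---------------------------------------------------------------------------
# Synthetic paralog pair (sequence-divergence stand-in)
# ---------------------------------------------------------------------------

def make_paralog_pair(length: int = 860, identity: float = 0.714,
                      n_indels: int = 3, indel_length: int = 6,
                      seed: int = 0) -> tuple[str, str, float]:
    """SYNTHETIC stand-in for a real diverged paralog pair.

    Generates an ancestral sequence and a derived copy with point
    substitutions sized to the requested alignment-frame identity, plus a few
    short indels to exercise affine-gap alignment.  Returns
    (sequence A, sequence B, ground-truth percent identity over aligned
    columns of the generation frame).
    """
    if not 0 < identity <= 1:
        raise SyntheticError("identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(T.STANDARD_AA1))
    seq_a = rng.choice(aa, size=length)
    n_sub = int(round((1.0 - identity) * length))
    sub_pos = rng.choice(length, size=n_sub, replace=False)
    seq_b = seq_a.copy()
    for p in sub_pos:
        choices = [x for x in T.STANDARD_AA1 if x != seq_a[p]]
        seq_b[p] = choices[int(rng.integers(0, 19))]

    # deletions from B (removing aligned columns) and insertions into B
    b_list = list(seq_b)
    deleted = set()
    for _ in range(n_indels):
        start = int(rng.integers(10, length - indel_length - 10))
        if any(p in deleted for p in range(start, start + indel_length)):
            continue
        deleted.update(range(start, start + indel_length))
    kept = [i for i in range(length) if i not in deleted]
    b_list = [b_list[i] for i in kept]
    insert_at = int(rng.integers(5, len(b_list) - 5))
    insertion = list(rng.choice(aa, size=indel_length))
    b_list = b_list[:insert_at] + insertion + b_list[insert_at:]

    aligned_cols = length - len(deleted)
    identical = sum(1 for i in kept if seq_b[i] == seq_a[i])
    truth = 100.0 * identical / aligned_cols
    return "".join(seq_a), "".join(b_list), truth
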