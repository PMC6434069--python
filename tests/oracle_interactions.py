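"""Independent all-pairs oracle for the interaction-typing criteria.

Re-implements the documented geometric decision procedure with plain nested
loops and its own vector math, sharing only the static lookup tables (atom
classes, radii, ring/bond definitions) with the package.  Used to check
``detect_interactions`` record-for-record on small structures.
"""

import math

import numpy as np

from ddgscan import _tables as T
from ddgscan.mutant import _template
from ddgscan.structure import het_aromatic_rings, infer_bonds


def _norm(v):
    return math.sqrt(float(v[0] * v[0] + v[1] * v[1] + v[2] * v[2]))


def _angle(a, b, c):
    v1, v2 = a - b, c - b
    cosang = float(np.dot(v1, v2)) / (_norm(v1) * _norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _plane(points):
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    n = vt[2]
    return centroid, n / _norm(n)


def _intra_bonds(res):
    adj = {a.name: set() for a in res.atoms}
    if res.aa3 in T.SIDECHAIN_ATOMS:
        names, _, bonds = _template(res.aa3)
        present = {a.name for a in res.atoms}
        for i, j in bonds:
            if names[i] in present and names[j] in present:
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
        if "OXT" in present:
            adj["OXT"].add("C")
            adj["C"].add("OXT")
    else:
        for i, j in infer_bonds(res.atoms):
            adj[res.atoms[i].name].add(res.atoms[j].name)
            adj[res.atoms[j].name].add(res.atoms[i].name)
    return adj


def _bfs_depths(adj, start):
    depth = {start: 0}
    queue = [start]
    while queue:
        node = queue.pop(0)
        for nb in adj.get(node, ()):
            if nb not in depth:
                depth[nb] = depth[node] + 1
                queue.append(nb)
    return depth


def oracle_records(structure):
    """Set of canonical record signatures for the whole structure."""
    polymer = structure.polymer_residues()
    ligands = structure.ligands
    metals = structure.metals
    residues = polymer + ligands + metals

    # --- covalent exclusions across peptide / disulphide links -------------
    excluded = set()

    def link_exclusions(r1, r2, a1, a2):
        d1 = _bfs_depths(_intra_bonds(r1), a1)
        d2 = _bfs_depths(_intra_bonds(r2), a2)
        for n1, k1 in d1.items():
            for n2, k2 in d2.items():
                if k1 + 1 + k2 <= 3:
                    excluded.add(frozenset(((id(r1), n1), (id(r2), n2))))

    for chain in structure.chains.values():
        for r1, r2 in zip(chain, chain[1:]):
            c, n = r1.atom("C"), r2.atom("N")
            if c is not None and n is not None and _norm(c.coords - n.coords) <= 1.8:
                link_exclusions(r1, r2, "C", "N")
    cys = [r for r in polymer if r.aa3 == "CYS" and r.atom("SG")]
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            if _norm(cys[i].atom("SG").coords - cys[j].atom("SG").coords) <= 2.4:
                link_exclusions(cys[i], cys[j], "SG", "SG")

    # --- rings --------------------------------------------------------------
    rings = []
    for res in polymer:
        for ring_name, names in T.RING_DEFINITIONS.get(res.aa3, []):
            if all(res.atom(n) for n in names):
                pts = np.array([res.atom(n).coords for n in names])
                centroid, normal = _plane(pts)
                rings.append((res, tuple(names), pts, centroid, normal))
    for lig in ligands:
        for idxs in het_aromatic_rings(lig):
            pts = np.array([lig.atoms[i].coords for i in idxs])
            centroid, normal = _plane(pts)
            rings.append((lig, tuple(lig.atoms[i].name for i in idxs), pts,
                          centroid, normal))

    records = set()

    def emit(res_a, atoms_a, res_b, atoms_b, itype, subtype):
        a = (res_a.rid, tuple(atoms_a))
        b = (res_b.rid, tuple(atoms_b))
        lo, hi = sorted([a, b])
        records.add((lo[0], lo[1], hi[0], hi[1], itype, subtype))

    # --- ring-ring ----------------------------------------------------------
    ring_pairs = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            ra, na, pa, ca, va = rings[i]
            rb, nb, pb, cb, vb = rings[j]
            if ra is rb:
                continue
            d = _norm(ca - cb)
            if d > 6.0:
                continue
            theta = math.degrees(math.acos(max(-1.0, min(1.0, abs(float(np.dot(va, vb)))))))
            def offset(centroid, normal, other):
                v = other - centroid
                along = float(np.dot(v, normal))
                return math.sqrt(max(float(np.dot(v, v)) - along * along, 0.0))
            off = min(offset(ca, va, cb), offset(cb, vb, ca))
            if theta < 30.0:
                subtype = "FF_parallel" if off < 1.5 else "OF_offset"
            elif theta < 60.0:
                subtype = "ET_edge_tilted"
            else:
                def face(centroid, normal, pts):
                    dists = [(_norm(p - centroid), p) for p in pts]
                    _, closest = min(dists, key=lambda t: t[0])
                    v = closest - centroid
                    nv = _norm(v)
                    if nv < 1e-9:
                        return True
                    return math.degrees(math.asin(min(1.0, abs(float(np.dot(v / nv, normal)))))) > 45.0
                subtype = "EF_edge_face" if (face(ca, va, pb) or face(cb, vb, pa)) \
                    else "EE_edge_edge"
            ring_pairs.add((i, j))
            emit(ra, na, rb, nb, "ring_ring", subtype)

    # --- atom-ring ----------------------------------------------------------
    metal_ids = {id(m) for m in metals}
    ring_membership = [{(id(r[0]), n) for n in r[1]} for r in rings]
    paired = {}
    for i, j in ring_pairs:
        paired.setdefault(i, set()).add(j)
        paired.setdefault(j, set()).add(i)
    atom_ring_cover = set()
    for k, (rres, rnames, rpts, rcen, rnorm) in enumerate(rings):
        for res in residues:
            if res is rres or id(res) in metal_ids:
                continue
            for atom in res.atoms:
                if any((id(res), atom.name) in ring_membership[ok]
                       for ok in paired.get(k, ())):
                    continue
                v = atom.coords - rcen
                d = _norm(v)
                if d > 4.5 or d < 1e-6:
                    continue
                ang = math.degrees(math.acos(max(-1.0, min(1.0, abs(float(np.dot(v / d, rnorm)))))))
                if ang > 35.0:
                    continue
                ph = atom.pharmacophores
                if "positive" in ph:
                    sub = "cation_pi"
                elif "sulphur" in ph:
                    sub = "sulphur_pi"
                elif "hbond_donor" in ph:
                    sub = "donor_pi"
                elif atom.element == "C":
                    sub = "carbon_pi"
                else:
                    continue
                emit(res, (atom.name,), rres, rnames, "atom_ring", sub)
                for member in rnames:
                    atom_ring_cover.add(frozenset(((id(res), atom.name),
                                                   (id(rres), member))))

    ring_cover = set(atom_ring_cover)
    for i, j in ring_pairs:
        for ka in ring_membership[i]:
            for kb in ring_membership[j]:
                ring_cover.add(frozenset((ka, kb)))

    # --- ionic groups -------------------------------------------------------
    charged = []
    table = {"ARG": (["NE", "NH1", "NH2"], 1), "LYS": (["NZ"], 1),
             "HIS": (["ND1", "NE2"], 1), "ASP": (["OD1", "OD2"], -1),
             "GLU": (["OE1", "OE2"], -1)}
    for res in polymer:
        if res.aa3 in table:
            names, sign = table[res.aa3]
            if all(res.atom(n) for n in names):
                cen = np.mean([res.atom(n).coords for n in names], axis=0)
                charged.append((res, tuple(names), sign, cen))
    for lig in ligands:
        neg = [a for a in lig.atoms if "negative" in a.pharmacophores]
        if neg:
            adj = _intra_bonds(lig)
            left = {a.name: a for a in neg}
            while left:
                seed = sorted(left)[0]
                cluster = {seed}
                frontier = [seed]
                while frontier:
                    node = frontier.pop()
                    for nb in adj[node]:
                        for nb2 in adj[nb]:
                            if nb2 in left and nb2 not in cluster:
                                cluster.add(nb2)
                                frontier.append(nb2)
                atoms = [left.pop(n) for n in sorted(cluster)]
                cen = np.mean([a.coords for a in atoms], axis=0)
                charged.append((lig, tuple(a.name for a in atoms), -1, cen))
        for a in lig.atoms:
            if "positive" in a.pharmacophores:
                charged.append((lig, (a.name,), 1, a.coords))
    ionic_cover = set()
    for gi in range(len(charged)):
        for gj in range(gi + 1, len(charged)):
            ra, na, sa, ca = charged[gi]
            rb, nb, sb, cb = charged[gj]
            if ra is rb or sa * sb >= 0:
                continue
            if _norm(ca - cb) <= 4.0:
                emit(ra, na, rb, nb, "ionic", None)
                for x in na:
                    for y in nb:
                        ionic_cover.add(frozenset(((id(ra), x), (id(rb), y))))

    # --- helpers for pair typing -------------------------------------------
    def antecedent_angle_ok(res, donor, acc_coords):
        adj = _intra_bonds(res)
        coords = [res.atom(n).coords for n in adj.get(donor.name, ())
                  if res.atom(n) is not None]
        return any(_angle(c, donor.coords, acc_coords) >= 90.0 for c in coords)

    def carbonyl_oxygen(res, atom):
        if res.aa3 in T.SIDECHAIN_ATOMS:
            mapping = {"C": "O"}
            if res.aa3 == "ASN":
                mapping["CG"] = "OD1"
            if res.aa3 == "GLN":
                mapping["CD"] = "OE1"
            if res.aa3 in ("ASP", "GLU"):
                return None
            o_name = mapping.get(atom.name)
            o = res.atom(o_name) if o_name else None
            return None if o is None else o.coords
        if atom.element != "C":
            return None
        bonds = infer_bonds(res.atoms)
        idx = next(i for i, a in enumerate(res.atoms) if a.name == atom.name)
        oxy = []
        for i, j in bonds:
            if idx in (i, j):
                other = res.atoms[j if i == idx else i]
                if other.element == "O":
                    deg = sum(1 for k, l in bonds
                              if res.atoms[k] is other or res.atoms[l] is other)
                    if deg == 1:
                        oxy.append(other)
        return oxy[0].coords if len(oxy) == 1 else None

    # --- atom-pair scan -----------------------------------------------------
    for ri in range(len(residues)):
        for rj in range(ri + 1, len(residues)):
            res_a, res_b = residues[ri], residues[rj]
            for atom_a in res_a.atoms:
                for atom_b in res_b.atoms:
                    d = _norm(atom_a.coords - atom_b.coords)
                    if d > 5.0:
                        continue
                    key = frozenset(((id(res_a), atom_a.name),
                                     (id(res_b), atom_b.name)))
                    if key in excluded:
                        continue
                    a_metal = id(res_a) in metal_ids
                    b_metal = id(res_b) in metal_ids
                    if a_metal or b_metal:
                        if a_metal and b_metal:
                            continue
                        metal_res, matom = (res_a, atom_a) if a_metal else (res_b, atom_b)
                        other_res, oatom = (res_b, atom_b) if a_metal else (res_a, atom_a)
                        if d <= 3.0 and oatom.element in ("N", "O", "S"):
                            emit(metal_res, (matom.name,), other_res, (oatom.name,),
                                 "metal_coordination", None)
                        continue
                    if key in ionic_cover:
                        continue
                    hb = None
                    if d <= 3.5:
                        for dres, datom, ares, aatom in (
                                (res_a, atom_a, res_b, atom_b),
                                (res_b, atom_b, res_a, atom_a)):
                            if ("hbond_donor" in datom.pharmacophores
                                    and "hbond_acceptor" in aatom.pharmacophores
                                    and antecedent_angle_ok(dres, datom, aatom.coords)):
                                hb = (dres, datom, ares, aatom)
                                break
                    if hb is not None:
                        emit(hb[0], (hb[1].name,), hb[2], (hb[3].name,),
                             "hydrogen_bond", None)
                        continue
                    carb = None
                    if d <= 3.6:
                        for cres, catom, xres, xatom in (
                                (res_a, atom_a, res_b, atom_b),
                                (res_b, atom_b, res_a, atom_a)):
                            if catom.element != "C" or xatom.element not in ("O", "N"):
                                continue
                            o = carbonyl_oxygen(cres, catom)
                            if o is None:
                                continue
                            if abs(_angle(o, catom.coords, xatom.coords) - 109.0) <= 30.0:
                                carb = (cres, catom, xres, xatom)
                                break
                    if carb is not None:
                        emit(carb[0], (carb[1].name,), carb[2], (carb[3].name,),
                             "carbonyl", None)
                        continue
                    if key in ring_cover:
                        continue
                    vdw = (T.VDW_RADII.get(atom_a.element, 1.8)
                           + T.VDW_RADII.get(atom_b.element, 1.8))
                    if d <= vdw + 0.5:
                        emit(res_a, (atom_a.name,), res_b, (atom_b.name,),
                             "weak_hbond_vdw", None)
                    elif (d <= 4.5 and atom_a.element == "C" and atom_b.element == "C"
                          and "hydrophobic" in atom_a.pharmacophores
                          and "hydrophobic" in atom_b.pharmacophores):
                        emit(res_a, (atom_a.name,), res_b, (atom_b.name,),
                             "proximal_hydrophobic", None)
                    else:
                        emit(res_a, (atom_a.name,), res_b, (atom_b.name,),
                             "proximal_undefined", None)
    return records
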