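"""ddG estimation in three modes (monomer stability, interface, ligand
affinity) from two complementary scores plus a consensus:

* an environment-specific substitution-table (ESST) score: log-odds of the
  substitution conditioned on the residue's structural environment
  (secondary structure x solvent accessibility), relative to an
  environment-independent background, scaled to kcal/mol;
* a cutoff-scanning signature score: pharmacophore count vectors of the
  residue environment at increasing cutoff radii, fed to a packaged linear
  regressor trained on synthetic labelled mutations;
* a consensus: configurable weighted mean of the two.

Sign convention: negative ddG = destabilizing.  The classification bands are
stabilizing (ddG >= 0), slightly destabilizing (0 > ddG >= -2.00) and highly
destabilizing (ddG < -2.00 kcal/mol).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _tables as T
from ._geometry import dihedral
from .structure import Residue, ResidueId, StructureModel

AA_ORDER = T.STANDARD_AA1
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

SECONDARY_STRUCTURES = ("helix", "strand", "coil")
ACCESSIBILITIES = ("buried", "partial", "exposed")
DEFAULT_GRID = (4.0, 6.0, 8.0, 10.0)

_DATA_DIR = Path(__file__).parent / "data"


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Structural environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentClass:
    secondary_structure: str
    accessibility: str
    sidechain_hbond: bool = False

    def __post_init__(self):
        if self.secondary_structure not in SECONDARY_STRUCTURES:
            raise ScoringError(f"bad secondary structure {self.secondary_structure!r}")
        if self.accessibility not in ACCESSIBILITIES:
            raise ScoringError(f"bad accessibility {self.accessibility!r}")

    @property
    def key(self) -> str:
        return f"{self.secondary_structure}_{self.accessibility}"


def _to_biotite(structure: StructureModel):
    import biotite.structure as struc

    residues = structure.polymer_residues() + structure.ligands
    n = sum(len(r.atoms) for r in residues)
    arr = struc.AtomArray(n)
    i = 0
    for res in residues:
        for a in res.atoms:
            arr.coord[i] = a.coords
            arr.chain_id[i] = res.chain_id
            arr.res_id[i] = res.seq_num
            arr.ins_code[i] = res.icode
            arr.res_name[i] = res.aa3
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.hetero[i] = res.is_het
            i += 1
    return arr


def relative_solvent_accessibility(structure: StructureModel) -> dict[ResidueId, float]:
    """Per-residue RSA: Shrake-Rupley SASA (biotite) over the residue's heavy
    atoms divided by the residue type's theoretical maximum area."""
    import biotite.structure as struc

    arr = _to_biotite(structure)
    atom_sasa = struc.sasa(arr, vdw_radii="Single", point_number=300)
    atom_sasa = np.nan_to_num(atom_sasa)
    out: dict[ResidueId, float] = {}
    i = 0
    for res in structure.polymer_residues() + structure.ligands:
        n = len(res.atoms)
        total = float(atom_sasa[i:i + n].sum())
        i += n
        if res.is_het:
            continue
        max_asa = T.MAX_ASA.get(res.aa3)
        out[res.rid] = min(total / max_asa, 1.5) if max_asa else 1.0
    return out


def _backbone_dihedrals(structure: StructureModel, residue: Residue):
    chain = structure.chains.get(residue.chain_id, [])
    idx = next((i for i, r in enumerate(chain) if r is residue), None)
    if idx is None:
        return None, None
    phi = psi = None
    n, ca, c = (residue.atom(x) for x in ("N", "CA", "C"))
    if None in (n, ca, c):
        return None, None
    if idx > 0:
        prev_c = chain[idx - 1].atom("C")
        if prev_c is not None and np.linalg.norm(prev_c.coords - n.coords) <= 1.8:
            phi = dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
    if idx + 1 < len(chain):
        next_n = chain[idx + 1].atom("N")
        if next_n is not None and np.linalg.norm(c.coords - next_n.coords) <= 1.8:
            psi = dihedral(n.coords, ca.coords, c.coords, next_n.coords)
    return phi, psi


def _secondary_structure(phi, psi) -> str:
    if phi is None or psi is None:
        return "coil"
    if -120.0 <= phi <= -30.0 and -77.0 <= psi <= -5.0:
        return "helix"
    if -180.0 <= phi <= -45.0 and (psi >= 90.0 or psi <= -150.0):
        return "strand"
    return "coil"


def _sidechain_hbonded(structure: StructureModel, residue: Residue) -> bool:
    from .interactions import _hbond_record

    side = [a for a in residue.atoms
            if a.name not in T.BACKBONE_ATOMS
            and ({"hbond_donor", "hbond_acceptor"} & a.pharmacophores)]
    if not side:
        return False
    owners, coords = structure.atom_table()
    tree = cKDTree(coords)
    for a in side:
        for j in tree.query_ball_point(a.coords, r=3.5):
            res_b, atom_b = owners[j]
            if res_b is residue:
                continue
            if _hbond_record(residue, a, res_b, atom_b,
                             float(np.linalg.norm(a.coords - atom_b.coords))):
                return True
    return False


def classify_environment(structure: StructureModel, residue: Residue,
                         rsa: float | None = None,
                         with_hbond_flag: bool = True) -> EnvironmentClass:
    """Secondary structure from backbone dihedrals, accessibility from RSA
    (buried < 7%, partial 7-43%, exposed > 43%).  Chain-terminal residues
    with undefined dihedrals fall back to coil."""
    phi, psi = _backbone_dihedrals(structure, residue)
    ss = _secondary_structure(phi, psi)
    if rsa is None:
        rsa = relative_solvent_accessibility(structure).get(residue.rid, 1.0)
    if rsa < T.RSA_BURIED:
        acc = "buried"
    elif rsa <= T.RSA_EXPOSED:
        acc = "partial"
    else:
        acc = "exposed"
    hb = _sidechain_hbonded(structure, residue) if with_hbond_flag else False
    return EnvironmentClass(ss, acc, hb)


# ---------------------------------------------------------------------------
# Environment-specific substitution tables
# ---------------------------------------------------------------------------

@dataclass
class ESST:
    """Log-probability substitution tables per structural environment plus an
    environment-independent background, with a kcal/mol scale."""
    environments: dict[str, np.ndarray]  # key -> 20x20 log P(b|a)
    background: np.ndarray               # 20x20 log P(b|a)
    scale: float = 1.0
    pseudocount: float = 1.0

    def __post_init__(self):
        for key, mat in self.environments.items():
            if np.asarray(mat).shape != (20, 20) or not np.all(np.isfinite(mat)):
                raise ScoringError(f"bad ESST block {key!r}")
        if np.asarray(self.background).shape != (20, 20):
            raise ScoringError("bad ESST background block")

    def log_odds(self, wt: str, mut: str, env: EnvironmentClass) -> float:
        if wt not in AA_INDEX or mut not in AA_INDEX:
            raise ScoringError(f"non-standard amino acid in {wt!r}->{mut!r}")
        if env.key not in self.environments:
            raise ScoringError(f"ESST does not cover environment {env.key!r}")
        i, j = AA_INDEX[wt], AA_INDEX[mut]
        return float(self.environments[env.key][i, j] - self.background[i, j])

    def write(self, path: str | Path) -> None:
        lines = ["# ddgscan ESST",
                 f"# scale: {self.scale!r}",
                 f"# pseudocount: {self.pseudocount!r}",
                 f"# aa_order: {AA_ORDER}",
                 "> background"]
        def block(mat):
            return [" ".join(f"{x:.6f}" for x in row) for row in mat]
        lines += block(self.background)
        for key in sorted(self.environments):
            lines.append(f"> {key}")
            lines += block(self.environments[key])
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ESST":
        scale, pseudocount = 1.0, 1.0
        blocks: dict[str, list[list[float]]] = {}
        current = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# scale:"):
                scale = float(line.split(":", 1)[1])
            elif line.startswith("# pseudocount:"):
                pseudocount = float(line.split(":", 1)[1])
            elif line.startswith("#"):
                continue
            elif line.startswith(">"):
                current = line[1:].strip()
                blocks[current] = []
            else:
                blocks[current].append([float(x) for x in line.split()])
        background = np.array(blocks.pop("background"))
        envs = {k: np.array(v) for k, v in blocks.items()}
        return cls(environments=envs, background=background,
                   scale=scale, pseudocount=pseudocount)


def derive_esst(families: list[tuple[str, list[str], list[str]]],
                pseudocount: float = 1.0, scale: float = 1.0) -> ESST:
    """Derive an ESST from aligned homolog families.

    Each family is (ancestral/reference sequence, aligned homologs,
    per-column environment keys).  Counts of reference->observed amino-acid
    pairs are pooled per environment, turned into conditional probabilities
    with a pseudocount, and stored as log P; the background pools all
    environments.
    """
    envs = sorted({e for _, _, labels in families for e in labels})
    counts = {e: np.zeros((20, 20)) for e in envs}
    for ref, homologs, labels in families:
        if any(len(h) != len(ref) for h in homologs) or len(labels) != len(ref):
            raise ScoringError("family alignment frame is inconsistent")
        for j, (a, e) in enumerate(zip(ref, labels)):
            if a not in AA_INDEX:
                continue
            i = AA_INDEX[a]
            for h in homologs:
                b = h[j]
                if b in AA_INDEX:
                    counts[e][i, AA_INDEX[b]] += 1

    def to_logp(mat):
        smoothed = mat + pseudocount
        return np.log(smoothed / smoothed.sum(axis=1, keepdims=True))

    background = to_logp(sum(counts.values()))
    return ESST(environments={e: to_logp(c) for e, c in counts.items()},
                background=background, scale=scale, pseudocount=pseudocount)


def calibrate_scale(esst: ESST, substitutions: list[tuple[str, str, EnvironmentClass]],
                    target: float = -1.0) -> float:
    """Scale such that the mean raw log-odds of reference (destabilizing)
    substitutions maps to ``target`` kcal/mol."""
    raw = [esst.log_odds(w, m, e) for w, m, e in substitutions]
    mean = float(np.mean(raw))
    if abs(mean) < 1e-12:
        raise ScoringError("reference substitutions have zero mean log-odds")
    return target / mean


def esst_score(wt: str, mut: str, env: EnvironmentClass, table: ESST) -> float:
    """ddG (kcal/mol) = scale x [L_f(wt->mut | env) - L_u(wt->mut)]."""
    return table.scale * table.log_odds(wt, mut, env)


def default_esst() -> ESST:
    """The packaged toy ESST (derived from synthetic homolog families)."""
    return ESST.read(_DATA_DIR / "toy_esst.txt")


# ---------------------------------------------------------------------------
# Cutoff-scanning signatures
# ---------------------------------------------------------------------------

def _canonical_class_counts(aa3: str) -> np.ndarray:
    counts = np.zeros(len(T.PHARMACOPHORE_CLASSES))
    atoms = ["N", "CA", "C", "O"] + T.SIDECHAIN_ATOMS[aa3]
    for name in atoms:
        classes = T.pharmacophores_for(aa3, name) or set()
        for c in classes:
            counts[T.PHARMACOPHORE_CLASSES.index(c)] += 1
    return counts


@dataclass
class SignatureVector:
    values: np.ndarray
    feature_names: list[str]
    mode: str
    grid: tuple[float, ...]
    rsa: float
    metadata: dict = field(default_factory=dict)

    def as_dict(self):
        return dict(zip(self.feature_names, self.values))


def signature_feature_names(grid=DEFAULT_GRID) -> list[str]:
    names = []
    classes = T.PHARMACOPHORE_CLASSES
    for r in grid:
        names += [f"env_{c}_r{r:g}" for c in classes]
    for r in grid:
        for i, c1 in enumerate(classes):
            for c2 in classes[i:]:
                names.append(f"pair_{c1}_{c2}_r{r:g}")
    for r in grid:
        names += [f"partner_{c}_r{r:g}" for c in classes]
    names += [f"delta_{c}" for c in classes]
    names += ["rsa", "ph", "temperature"]
    return names


def compute_signature(structure: StructureModel, mutation, mode: str = "stability",
                      grid: tuple[float, ...] = DEFAULT_GRID,
                      mutant=None, rsa: float | None = None,
                      ph: float = 7.0, temperature: float = 25.0) -> SignatureVector:
    """Cutoff-scanning pharmacophore signature of a mutation site.

    Counts atoms per pharmacophore class within each cutoff radius of the
    site anchor (C-beta; C-alpha for Gly) over the wild-type structure, plus
    class-class pair counts (both atoms inside the shell and mutually within
    the radius), a partner channel (other-chain atoms in ppi mode,
    ligand/metal atoms in ligand mode) and the canonical pharmacophore
    difference vector between mutant and wild-type residue types.
    """
    if mode not in ("stability", "ppi", "ligand"):
        raise ScoringError(f"unknown mode {mode!r}")
    grid = tuple(float(g) for g in grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ScoringError("cutoff grid must be non-empty and strictly increasing")

    site = (mutation.chain, mutation.position, getattr(mutation, "icode", ""))
    residue = structure.get_residue(*site)
    if residue is None:
        raise ScoringError(f"mutation site {site} not in structure")
    anchor_atom = residue.atom("CB") or residue.atom("CA")
    if anchor_atom is None:
        raise ScoringError(f"{residue.label}: no anchor atom (CB/CA)")
    anchor = anchor_atom.coords

    classes = T.PHARMACOPHORE_CLASSES
    cidx = {c: k for k, c in enumerate(classes)}
    env_atoms, partner_atoms = [], []
    ligand_ids = {id(r) for r in structure.ligands} | {id(r) for r in structure.metals}
    for res in structure.all_residues():
        if res is residue:
            continue
        for a in res.atoms:
            is_partner = (
                (mode == "ppi" and not res.is_het and res.chain_id != mutation.chain)
                or (mode == "ligand" and id(res) in ligand_ids)
            )
            (partner_atoms if is_partner else env_atoms).append(a)

    def shell_counts(atoms, r):
        counts = np.zeros(len(classes))
        for a in atoms:
            if np.linalg.norm(a.coords - anchor) <= r:
                for c in a.pharmacophores:
                    counts[cidx[c]] += 1
        return counts

    values = []
    for r in grid:
        values.append(shell_counts(env_atoms, r))
    # pair counts over the primary environment
    pair_blocks = []
    all_env_coords = np.array([a.coords for a in env_atoms]) if env_atoms else np.empty((0, 3))
    if len(env_atoms):
        d_anchor = np.linalg.norm(all_env_coords - anchor, axis=1)
    for r in grid:
        block = np.zeros(len(classes) * (len(classes) + 1) // 2)
        if len(env_atoms):
            inside = np.where(d_anchor <= r)[0]
            sub = all_env_coords[inside]
            if len(inside) > 1:
                tree = cKDTree(sub)
                for ii, jj in tree.query_pairs(r=r):
                    a1, a2 = env_atoms[inside[ii]], env_atoms[inside[jj]]
                    for c1 in a1.pharmacophores:
                        for c2 in a2.pharmacophores:
                            k1, k2 = sorted((cidx[c1], cidx[c2]))
                            flat = k1 * len(classes) - k1 * (k1 - 1) // 2 + (k2 - k1)
                            block[flat] += 1
        pair_blocks.append(block)
    values += pair_blocks
    for r in grid:
        values.append(shell_counts(partner_atoms, r))

    if mutant is not None:
        mut_res = mutant.structure.get_residue(*site)
        delta = np.zeros(len(classes))
        for a in mut_res.atoms:
            for c in a.pharmacophores:
                delta[cidx[c]] += 1
        for a in residue.atoms:
            for c in a.pharmacophores:
                delta[cidx[c]] -= 1
    else:
        delta = (_canonical_class_counts(T.AA1_TO_AA3[mutation.mut_aa])
                 - _canonical_class_counts(T.AA1_TO_AA3[mutation.wt_aa]))
    values.append(delta)

    if rsa is None:
        rsa = relative_solvent_accessibility(structure).get(residue.rid, 1.0)
    values.append(np.array([rsa, ph, temperature]))

    vec = np.concatenate(values)
    return SignatureVector(values=vec, feature_names=signature_feature_names(grid),
                           mode=mode, grid=grid, rsa=float(rsa),
                           metadata={"site": site, "wt": mutation.wt_aa,
                                     "mut": mutation.mut_aa})


# ---------------------------------------------------------------------------
# Packaged signature regressor
# ---------------------------------------------------------------------------

def predict_ddg(signature: SignatureVector, model: dict) -> float:
    """Deterministic linear prediction from a packaged model fixture."""
    names = model["feature_names"]
    if list(signature.feature_names) != list(names):
        raise ScoringError("signature/model feature dimensionality mismatch")
    coef = np.asarray(model["coef"], dtype=float)
    if coef.shape != signature.values.shape:
        raise ScoringError("signature/model feature dimensionality mismatch")
    return float(np.dot(coef, signature.values) + float(model["intercept"]))


def synthetic_ddg_label(wt: str, mut: str, rsa: float, partner_contacts: float,
                        rng: np.random.Generator | None = None,
                        noise: float = 0.3) -> float:
    """Documented pseudo-energy used to label synthetic training mutations:
    burial-weighted packing, hydropathy and charge terms plus a partner-
    contact term and Gaussian noise.  Negative = destabilizing."""
    burial = 1.0 - min(rsa, 1.0)
    dvol = abs(T.AA_VOLUME[mut] - T.AA_VOLUME[wt])
    dhyd = T.AA_HYDROPATHY[wt] - T.AA_HYDROPATHY[mut]
    dchg = abs(T.AA_CHARGE[mut] - T.AA_CHARGE[wt])
    label = (-0.012 * dvol * burial
             - 0.12 * max(dhyd, 0.0) * burial
             - 0.45 * dchg * burial
             - 0.02 * partner_contacts * (1.0 if dvol > 40 else 0.0))
    if rng is not None and noise > 0:
        label += float(rng.normal(0.0, noise))
    return label


def train_signature_model(seed: int = 7, n_mutations: int = 160,
                          grid=DEFAULT_GRID, ridge: float = 1.0):
    """Train the packaged ridge regressor on synthetic labelled mutations.

    Training structures are synthetic pockets and dimers; labels come from
    :func:`synthetic_ddg_label`.  Returns (model dict, training table) where
    the model records coefficients, feature order, seed and the maximum
    absolute training residual.
    """
    from sklearn.linear_model import Ridge

    from .pipeline import MutationSpec
    from .synthetic import HelixSpec, make_dimer, make_pocket

    rng = np.random.default_rng(seed)
    structures = []
    pocket, _ = make_pocket(["hbond", "pi_stack", "metal", "proximal", "hbond"])
    structures.append(("ligand", pocket))
    seq = ["G"] * 18
    seq[7] = "S"
    seq[13] = "F"
    seq = "".join(seq)
    dimer, _, _ = make_dimer(HelixSpec(seq, chain_id="A"), HelixSpec(seq, chain_id="B"),
                             contacts=[(8, 8, "hbond"), (14, 14, "ring_stack")])
    structures.append(("ppi", dimer))

    rows, feats, labels = [], [], []
    for mode, st in structures:
        rsa_map = relative_solvent_accessibility(st)
        residues = st.polymer_residues()
        for _ in range(n_mutations // len(structures)):
            res = residues[int(rng.integers(0, len(residues)))]
            wt = res.aa1
            others = [aa for aa in T.STANDARD_AA1 if aa != wt]
            mut = others[int(rng.integers(0, len(others)))]
            spec = MutationSpec(chain=res.chain_id, position=res.seq_num,
                                wt_aa=wt, mut_aa=mut, source="user")
            sig = compute_signature(st, spec, mode=mode, grid=grid,
                                    rsa=rsa_map.get(res.rid, 1.0))
            partner = float(sum(sig.values[
                [i for i, n in enumerate(sig.feature_names)
                 if n.startswith("partner_") and n.endswith(f"r{grid[-1]:g}")]]))
            y = synthetic_ddg_label(wt, mut, sig.rsa, partner, rng=rng)
            feats.append(sig.values)
            labels.append(y)
            rows.append({"mode": mode, "chain": res.chain_id, "position": res.seq_num,
                         "wt": wt, "mut": mut, "rsa": round(sig.rsa, 4),
                         "label": round(y, 4)})
    X = np.array(feats)
    y = np.array(labels)
    reg = Ridge(alpha=ridge).fit(X, y)
    residuals = np.abs(reg.predict(X) - y)
    model = {
        "feature_names": signature_feature_names(grid),
        "coef": [float(c) for c in reg.coef_],
        "intercept": float(reg.intercept_),
        "seed": seed,
        "ridge_alpha": ridge,
        "n_training": len(y),
        "max_training_residual": float(residuals.max()),
        "grid": list(grid),
    }
    import pandas as pd
    return model, pd.DataFrame(rows)


def save_model(model: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model, indent=1) + "\n")


def load_model(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def default_model() -> dict:
    """The packaged signature-regressor fixture."""
    return load_model(_DATA_DIR / "signature_model.json")


# ---------------------------------------------------------------------------
# Consensus and classification
# ---------------------------------------------------------------------------

def consensus(ddg_esst: float | None, ddg_signature: float | None,
              weights: tuple[float, float] = (0.5, 0.5)) -> float:
    """Weighted mean of the two scores; one missing input passes the other
    through; both missing is an error."""
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or (w1 + w2) <= 0:
        raise ScoringError("weights must be non-negative with positive sum")
    if ddg_esst is None and ddg_signature is None:
        raise ScoringError("consensus requires at least one input score")
    if ddg_esst is None:
        return float(ddg_signature)
    if ddg_signature is None:
        return float(ddg_esst)
    return float((w1 * ddg_esst + w2 * ddg_signature) / (w1 + w2))


CLASS_LABELS = ("stabilizing", "slightly_destabilizing", "highly_destabilizing")


def classify_ddg(ddg: float) -> str:
    """Three-band classification: stabilizing (ddG >= 0), slightly
    destabilizing (0 > ddG >= -2.00), highly destabilizing (ddG < -2.00)."""
    if ddg is None or not math.isfinite(ddg):
        raise ScoringError(f"ddG must be finite, got {ddg!r}")
    if ddg >= 0.0:
        return "stabilizing"
    if ddg >= -2.0:
        return "slightly_destabilizing"
    return "highly_destabilizing"


@dataclass
class StabilityPrediction:
    mutation: "MutationSpec"  # noqa: F821 - defined in pipeline
    mode: str
    ddg_esst: float | None
    ddg_signature: float | None
    ddg_consensus: float
    class_label: str
    environment: EnvironmentClass | None = None
    n_lost: int = 0
    n_gained: int = 0
    n_retained: int = 0
    status: str = "ok"
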