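"""Mutation-table parsing, saturation enumeration and end-to-end
orchestration: for every mutation, build the mutant, diff the interaction
networks around the site, compute the environment- and signature-based ddG
scores per requested mode, combine them and classify.

Failures are isolated per mutation: a mutation that cannot be scored (for
example a position outside the modelled structure) is reported with status
"unscorable" or "failed" and never affects any other mutation's outputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import _tables as T
from .interactions import detect_interactions, diff_networks
from .mutant import RotamerLibrary, build_mutant
from .stability import (ESST, EnvironmentClass, StabilityPrediction,
                        classify_ddg, compute_signature, consensus,
                        default_esst, default_model, esst_score, predict_ddg,
                        relative_solvent_accessibility)
from .structure import SiteSelection, StructureModel

logger = logging.getLogger("ddgscan")

_PROTEIN_CHANGE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


class MutationParseError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """One substitution in one-letter protein-change notation."""
    chain: str
    position: int
    wt_aa: str
    mut_aa: str
    source: str = "user"
    icode: str = ""

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise MutationParseError(
                f"silent substitution {self.wt_aa}{self.position}{self.mut_aa}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in T.AA1_TO_AA3:
                raise MutationParseError(f"non-standard amino acid {aa!r}")

    @property
    def key(self):
        return (self.chain, self.position, self.icode, self.wt_aa, self.mut_aa)

    def __str__(self):
        return f"{self.wt_aa}{self.position}{self.mut_aa}.{self.chain}"


@dataclass
class MutationTable:
    mutations: list[MutationSpec] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        seen = {}
        unique = []
        for m in self.mutations:
            full_key = m.key + (m.source,)
            if full_key in seen:
                logger.warning("duplicate mutation %s (%s) collapsed", m, m.source)
                continue
            seen[full_key] = m
            unique.append(m)
        self.mutations = unique

    def __len__(self):
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)


def parse_protein_change(token: str) -> tuple[str, int, str]:
    """Parse "F162L" or "p.F162L" into (wt, position, mut)."""
    m = _PROTEIN_CHANGE.match(token.strip())
    if m is None:
        raise MutationParseError(f"malformed protein change {token!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def parse_mutation_list(path: str | Path,
                        structure: StructureModel | None = None,
                        chain_map: dict[str, str] | None = None,
                        offsets: dict[str, int] | None = None) -> MutationTable:
    """Read a CSV with columns gene_or_chain, protein_change[, source].

    ``chain_map`` maps gene names to chain ids (e.g. PDE6A -> A); ``offsets``
    holds per-chain integer shifts from sequence to structure numbering.
    When a structure is supplied the wild-type letter of each mutation is
    checked against it; a position absent from the structure passes through
    (it becomes "unscorable" downstream).
    """
    chain_map = chain_map or {}
    offsets = offsets or {}
    df = pd.read_csv(path)
    required = {"gene_or_chain", "protein_change"}
    if not required <= set(df.columns):
        raise MutationParseError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    specs = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            wt, pos, mut = parse_protein_change(str(row.protein_change))
        except MutationParseError as exc:
            raise MutationParseError(f"{path}: row {row_num}: {exc}") from exc
        chain = chain_map.get(str(row.gene_or_chain), str(row.gene_or_chain))
        pos += offsets.get(chain, 0)
        source = str(getattr(row, "source", "user") or "user")
        spec = MutationSpec(chain=chain, position=pos, wt_aa=wt, mut_aa=mut,
                            source=source)
        if structure is not None:
            res = structure.get_residue(chain, pos)
            if res is not None and res.aa1 != wt:
                raise MutationParseError(
                    f"{path}: row {row_num}: wild-type mismatch at {chain}{pos}: "
                    f"table says {wt}, structure has {res.aa3} ({res.aa1})")
        specs.append(spec)
    return MutationTable(specs, provenance=str(path))


def saturate(selection: SiteSelection, structure: StructureModel) -> MutationTable:
    """All 19 non-wild-type substitutions at every selected site."""
    if len(selection) == 0:
        logger.warning("saturate: empty selection")
        return MutationTable([], provenance="saturation (empty selection)")
    selection.validate(structure)
    specs = []
    for chain, pos, icode in selection:
        res = structure.get_residue(chain, pos, icode)
        wt = res.aa1
        if wt == "X":
            logger.warning("saturate: skipping non-standard residue %s", res.label)
            continue
        for mut in T.STANDARD_AA1:
            if mut != wt:
                specs.append(MutationSpec(chain=chain, position=pos, icode=icode,
                                          wt_aa=wt, mut_aa=mut, source="saturation"))
    return MutationTable(specs, provenance=f"saturation of {selection.label}")


def cross_reference(table_a: MutationTable, table_b: MutationTable) -> MutationTable:
    """Intersection on (chain, position, wt, mut) with merged source tags."""
    keys_b = {}
    for m in table_b:
        keys_b.setdefault(m.key, []).append(m.source)
    out = []
    for m in table_a:
        if m.key in keys_b:
            sources = sorted({m.source, *keys_b[m.key]})
            out.append(MutationSpec(chain=m.chain, position=m.position,
                                    icode=m.icode, wt_aa=m.wt_aa, mut_aa=m.mut_aa,
                                    source="+".join(sources)))
    return MutationTable(out, provenance="cross-reference")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    modes: tuple[str, ...] = ("stability",)
    grid: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0)
    interface_cutoff: float = 5.0
    ligand_id: str | None = None
    esst: ESST | None = None
    model: dict | None = None
    rotamer_library: RotamerLibrary | None = None
    consensus_weights: tuple[float, float] = (0.5, 0.5)
    chain_map: dict[str, str] = field(default_factory=dict)
    offsets: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    ph: float = 7.0
    temperature: float = 25.0

    def resolve(self) -> "PipelineConfig":
        if self.esst is None:
            self.esst = default_esst()
        if self.model is None:
            self.model = default_model()
        if self.rotamer_library is None:
            self.rotamer_library = RotamerLibrary.default()
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key-value text config (key = value per line, # comments)."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "modes":
                kwargs["modes"] = tuple(v.strip() for v in value.split(","))
            elif key == "grid":
                kwargs["grid"] = tuple(float(v) for v in value.split(","))
            elif key in ("interface_cutoff", "ph", "temperature"):
                kwargs[key] = float(value)
            elif key == "seed":
                kwargs["seed"] = int(value)
            elif key == "ligand_id":
                kwargs["ligand_id"] = value or None
            elif key == "esst":
                kwargs["esst"] = ESST.read(value)
            elif key == "model":
                from .stability import load_model
                kwargs["model"] = load_model(value)
            elif key == "chain_map":
                kwargs["chain_map"] = dict(p.split(":") for p in value.split(","))
            elif key == "offsets":
                kwargs["offsets"] = {k: int(v) for k, v in
                                     (p.split(":") for p in value.split(","))}
        return cls(**kwargs)


def run_pipeline(structure: StructureModel, mutations: MutationTable,
                 config: PipelineConfig | None = None) -> list[StabilityPrediction]:
    """Score every mutation in every requested mode.

    Per mutation: the mutant is built (fixed backbone, rotamer selection),
    wild-type and mutant interaction networks around the site are diffed,
    the ESST score (stability mode) and the signature score (all modes) are
    computed, combined into a consensus and classified.  Mutations at
    residues absent from the structure are reported as "unscorable".
    """
    config = (config or PipelineConfig()).resolve()
    missing_chains = {m.chain for m in mutations} - set(structure.chains)
    if missing_chains:
        raise ValueError(f"structure is missing mutated chain(s) "
                         f"{sorted(missing_chains)}")
    if not any(a.pharmacophores for r in structure.all_residues() for a in r.atoms):
        from .structure import assign_pharmacophores
        assign_pharmacophores(structure)

    rsa_map = relative_solvent_accessibility(structure)
    predictions: list[StabilityPrediction] = []
    for spec in mutations:
        site = (spec.chain, spec.position, spec.icode)
        residue = structure.get_residue(*site)
        if residue is None:
            for mode in config.modes:
                predictions.append(StabilityPrediction(
                    mutation=spec, mode=mode, ddg_esst=None, ddg_signature=None,
                    ddg_consensus=float("nan"), class_label="", environment=None,
                    status="unscorable"))
            continue
        if residue.aa1 != spec.wt_aa:
            for mode in config.modes:
                predictions.append(StabilityPrediction(
                    mutation=spec, mode=mode, ddg_esst=None, ddg_signature=None,
                    ddg_consensus=float("nan"), class_label="", environment=None,
                    status=f"wt_mismatch:{residue.aa1}"))
            continue
        try:
            predictions.extend(
                _score_one(structure, spec, site, residue, rsa_map, config))
        except Exception as exc:  # per-mutation isolation
            logger.exception("mutation %s failed", spec)
            for mode in config.modes:
                predictions.append(StabilityPrediction(
                    mutation=spec, mode=mode, ddg_esst=None, ddg_signature=None,
                    ddg_consensus=float("nan"), class_label="", environment=None,
                    status=f"failed:{type(exc).__name__}"))
    return predictions


def _score_one(structure, spec, site, residue, rsa_map, config):
    site_selection = SiteSelection([site], label=f"site_{spec}")
    mutant = build_mutant(structure, site, spec.mut_aa, config.rotamer_library)
    wt_net = detect_interactions(structure, focus=site_selection)
    mut_net = detect_interactions(mutant.structure, focus=site_selection)
    diff = diff_networks(wt_net, mut_net, site)

    rsa = rsa_map.get(residue.rid, 1.0)
    env = None
    out = []
    for mode in config.modes:
        if mode == "stability":
            from .stability import classify_environment
            env = classify_environment(structure, residue, rsa=rsa)
            ddg_e = esst_score(spec.wt_aa, spec.mut_aa, env, config.esst)
        else:
            ddg_e = None
        sig = compute_signature(structure, spec, mode=mode, grid=config.grid,
                                mutant=mutant, rsa=rsa, ph=config.ph,
                                temperature=config.temperature)
        ddg_s = predict_ddg(sig, config.model)
        ddg_c = consensus(ddg_e, ddg_s, config.consensus_weights)
        out.append(StabilityPrediction(
            mutation=spec, mode=mode, ddg_esst=ddg_e, ddg_signature=ddg_s,
            ddg_consensus=ddg_c, class_label=classify_ddg(ddg_c),
            environment=env, n_lost=len(diff.lost), n_gained=len(diff.gained),
            n_retained=len(diff.retained)))
    return out
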