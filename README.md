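# ddgscan

Saturation-mutagenesis stability scanning of protein structures.

`ddgscan` is a desk-scale, fully reproducible reimplementation of the
structure-based mutation-impact workflow used to analyse missense mutations in
multidomain enzymes such as the cGMP phosphodiesterase PDE6 heterodimer: given
a structure (PDB/mmCIF) with optional bound ligands and metal ions, it

1. **types non-covalent interatomic interactions** (hydrogen bonds, weak
   vdW/hydrogen bonds, ionic pairs, metal coordination, carbonyl contacts,
   ring–ring geometries: parallel / offset / edge-tilted / edge-edge /
   edge-face, atom–ring classes: carbon-π, donor-π, sulphur-π, cation-π,
   proximal hydrophobic and undefined contacts) and detects ligand-binding
   pockets and dimer-interface residue sets from heavy-atom contacts;
2. **builds mutant side chains** on the fixed wild-type backbone from
   ideal-geometry templates, selecting rotamers by χ-angle inheritance from
   the wild type plus a soft-sphere clash score;
3. **scores each mutation** (ΔΔG, kcal/mol; negative = destabilizing) in up
   to three modes — monomer stability, protein–protein interface, ligand
   affinity — with two complementary estimators and their consensus:
   * an **environment-specific substitution table (ESST)** score,
     `ΔΔG = s · [ln P(wt→mut | env) − ln P(wt→mut)]`, where the environment
     is secondary structure × relative solvent accessibility and the tables
     are derived from (synthetic) homolog families;
   * a **cutoff-scanning pharmacophore signature** score: counts of atom
     classes (hydrophobic, positive, negative, H-bond donor/acceptor,
     sulphur, aromatic, neutral) in shells of increasing radius around the
     mutation site, fed to a packaged linear regressor;
   * a configurable **weighted-mean consensus** of the two;
4. **classifies** every mutation into the standard ΔΔG bands — stabilizing
   (ΔΔG ≥ 0), slightly destabilizing (0 > ΔΔG ≥ −2.00) and highly
   destabilizing (ΔΔG < −2.00 kcal/mol) — and
5. **reports**: per-mutation result tables (CSV + JSON), interaction-network
   diffs (contacts lost / gained / retained upon mutation), band-count
   summaries and histograms, and UCSF-Chimera residue-attribute files for
   structure-mapped ΔΔG coloring.

A first-class synthetic-data module generates every fixture the pipeline
needs — ideal helices, dimers with engineered interface contacts, ligand
pockets with designed interactions, homolog families with controlled
substitution statistics, labelled mutation tables and diverged paralog
sequence pairs — so the complete workflow runs and is tested without any
external downloads.

## Worked example

Saturate the aromatic stacking residue of a synthetic ligand pocket and score
all 19 substitutions for monomer stability and ligand affinity:

```python
from ddgscan import (PipelineConfig, SiteSelection, classification_summary,
                     run_pipeline, saturate)
from ddgscan.synthetic import make_pocket

pocket, sites = make_pocket(["hbond", "pi_stack", "metal", "proximal", "hbond"])
mutations = saturate(SiteSelection([sites.ids[1]]), pocket)   # the stacking Phe
predictions = run_pipeline(pocket, mutations,
                           PipelineConfig(modes=("stability", "ligand")))
summary = classification_summary([p for p in predictions if p.mode == "ligand"])
print(f"{len(predictions)} predictions")
print(summary.counts)
worst = min(predictions, key=lambda p: p.ddg_consensus)
print(f"most destabilizing: {worst.mutation} [{worst.mode}] "
      f"ddG = {worst.ddg_consensus:.2f} kcal/mol ({worst.class_label}, "
      f"{worst.n_lost} contacts lost)")
```

prints

```
38 predictions
{'stabilizing': 2, 'slightly_destabilizing': 17, 'highly_destabilizing': 0}
most destabilizing: F20I.A [stability] ddG = -3.10 kcal/mol (highly_destabilizing, 6 contacts lost)
```

i.e. 19 substitutions × 2 scoring modes; in ligand-affinity mode most
substitutions of the stacking phenylalanine are slightly destabilizing, and
the most destabilizing single prediction is the buried-aromatic truncation
F20I in stability mode, which also severs six of the residue's native
contacts.

The same workflow is available from the shell:

```bash
ddgscan fixtures  --out fixtures --seed 0
ddgscan interactions --structure fixtures/pocket.pdb --ligand LIG --out net.csv
ddgscan saturate --structure fixtures/pocket.pdb --ligand LIG --out sat.csv
ddgscan run --structure fixtures/pocket.pdb --mutations sat.csv \
            --modes stability,ligand --out outdir
```

Real mutation tables are accepted as CSV with COSMIC-style one-letter
protein-change notation (`F162L` or `p.D600N`), a gene→chain map and optional
per-chain numbering offsets.

## Scope

The package consumes externally built structures; comparative modelling,
energy minimization and structure QC are out of scope, as are live database
queries (COSMIC/UniProt exports are parsed from files). The packaged ESST and
signature regressor are small, fully documented fixtures derived from
synthetic data — numerical parity with any external webserver predictor is
explicitly not claimed. See `docs/methods.md` for the model, its parameters
and its limitations.
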