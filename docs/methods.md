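# Methods

This note documents the models and procedures implemented in `ddgscan`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Structure model and atom typing

Structures are read with gemmi (PDB and mmCIF). Author residue numbering with
insertion codes is canonical throughout, matching the residue labels used in
structural mutation studies. Water is discarded; any other HET group of two
or more heavy atoms becomes a *ligand*, single-atom HET records become
*metals*. Alternate locations keep the highest-occupancy conformer (ties:
first in file). The pipeline operates on heavy atoms only — modelled
structures usually lack hydrogens — so hydrogen-bond geometry is approximated
through heavy-atom antecedents.

Every heavy atom carries a set of eight pharmacophore classes (hydrophobic,
positive, negative, H-bond acceptor, H-bond donor, sulphur, aromatic,
neutral). For the twenty standard residues this is a fixed lookup table
(`_tables.py`); typing is a pure function of (residue name, atom name).
Ligand atoms are typed by element plus connectivity heuristics: bonds are
inferred from covalent radii (+0.45 Å tolerance), aromatic rings are planar
5/6-cycles of C/N (max 0.15 Å out-of-plane), oxygens on phosphorus or in
carboxylate-like groups are negative, singly-bonded C–O oxygens keep donor
capability (hydroxyl-like). Atoms of unknown residues fall back to {neutral}
with a warning.

## Interaction typing

All residue-pair heavy-atom contacts are evaluated against fixed geometric
criteria; each qualifying pair (or ring pair) is emitted once with the most
specific applicable type, in the priority order metal_coordination > ionic >
hydrogen_bond > carbonyl > ring_ring > atom_ring > weak_hbond_vdw >
proximal_hydrophobic > proximal_undefined. The thresholds (all Å, degrees):

| type | criterion |
|---|---|
| hydrogen_bond | donor–acceptor ≤ 3.5; angle(antecedent–donor⋯acceptor) ≥ 90 for some covalent antecedent |
| weak_hbond_vdw | distance ≤ vdW-radius sum + 0.5 |
| ionic | opposite formal-charge group centroids ≤ 4.0 (Arg/Lys/His vs Asp/Glu side-chain groups; ligand charge moieties clustered by connectivity) |
| metal_coordination | metal–N/O/S ≤ 3.0 |
| carbonyl | carbonyl C ⋯ O/N nucleophile ≤ 3.6, O=C⋯X approach 109 ± 30 |
| ring_ring | centroid ≤ 6.0; subtype from interplanar angle θ (acute) and in-plane centroid offset: θ<30 ∧ offset<1.5 → FF_parallel; θ<30 ∧ offset≥1.5 → OF_offset; 30≤θ<60 → ET_edge_tilted; θ≥60 → EE_edge_edge unless either ring's closest partner atom approaches >45° out of its plane (EF_edge_face) |
| atom_ring | atom–centroid ≤ 4.5, ≤ 35° from the ring normal; class priority cation-π > sulphur-π > donor-π > carbon-π |
| proximal_hydrophobic | two hydrophobic carbons ≤ 4.5 |
| proximal_undefined | any remaining pair ≤ 5.0 |

These are published-convention-style values; the subtype grid for ring–ring
geometries is an interpretation of common usage, since the terms are rarely
given formal definitions. Intra-residue pairs are out of scope; atoms within
three covalent bonds across a peptide or disulphide link never pair. Atom
pairs already represented at group level (ionic) or ring level (ring_ring /
atom_ring) are excluded from weaker pair types, so no atom pair appears under
two types. His–metal contacts are reported as metal_coordination (the same
physical contact is sometimes rendered as an "ionic bond" in published
figures). Metals participate only in coordination records.

Interface residues are residues of one chain with any heavy atom within a
cutoff (default **5.0 Å**, a common contact-analysis convention) of the other
chain; ligand-binding residues have a typed record to the ligand or any heavy
atom within **4.5 Å** of a ligand heavy atom. Network diffs match records
touching the mutated site on (partner residue, type, subtype) as multisets;
geometry differences are ignored for matching, and structures must be
identical outside the site (1e-6 Å).

Water-mediated bridges and halogen bonds are not typed.

## Mutant side-chain construction

Mutants are built on the fixed wild-type backbone: template heavy-atom
geometry for the target residue comes from the Chemical Component Dictionary
bundled with biotite, superimposed on the site's N/CA/C; side-chain χ
dihedrals (standard definitions, degrees in (−180, 180]) are then set by
rotation about the χ axes. Candidate conformers come from a compact packaged
backbone-independent rotamer library (the most populated conformers with
coarse priors, normalized to 1 per amino acid). Selection rule:

1. χ-inheritance filter: candidates whose leading χ angles lie within 40° of
   the wild type's are preferred, trying the longest matching prefix first.
   Across *different* amino-acid types only χ1 is inherited — deeper χ angles
   are not chemically comparable between different side chains, and χ1-only
   transfer is what makes A→B→A round trips recover the wild-type conformer.
2. Among surviving candidates, minimize the clash score; ties (at 1e-9) go to
   the higher prior probability, then library order. The procedure is fully
   deterministic.

The clash score is a soft-sphere overlap: Σ max(0, r_vdW,a + r_vdW,b − d)²
over all non-bonded pairs of site side-chain atoms against the rest of the
structure (Bondi-style radii; 1–4 and closer pairs through the backbone
excluded). It is zero iff there is no van-der-Waals overlap.

No backbone or neighbor-side-chain relaxation is performed, and neighboring
side chains are not repacked; Pro is grafted as a rigid ring and Gly/Ala have
no conformers. Disulphides are not rebuilt.

## Structural environments and ESST scoring

Each residue's environment is (secondary structure × accessibility), with an
additional side-chain H-bond flag. Secondary structure comes from backbone
dihedrals: helix for φ ∈ [−120, −30] ∧ ψ ∈ [−77, −5], strand for
φ ∈ [−180, −45] ∧ (ψ ≥ 90 ∨ ψ ≤ −150), otherwise coil; chain-terminal
residues with undefined dihedrals are coil. Accessibility is relative solvent
accessibility — Shrake–Rupley SASA (biotite, 300 sphere points, deterministic)
normalized by the residue's theoretical maximum area (Tien et al. 2013
values) — with bands buried < 7 %, partial 7–43 %, exposed > 43 %.

Environment-specific substitution tables hold log conditional probabilities
ln P(b|a, env) per environment plus a pooled background ln P(b|a), derived
from aligned homolog families by counting reference→observed pairs per
environment with pseudocount 1. The stability score is

    ΔΔG_ESST = s · [ln P(mut | wt, env) − ln P(mut | wt)]   (kcal/mol)

The packaged toy table is derived from synthetic families
(`scripts/build_fixtures.py`, seed 11, 200 homologs, 40 columns per
environment); its scale s = 1.3755 was calibrated once so that five
canonical buried hydrophobic→charged substitutions score −1 kcal/mol on
average. The original lab-derived substitution tables are not shipped — the
derivation machinery plus the toy tables are.

## Cutoff-scanning signatures and the packaged regressor

The signature of a mutation is computed on the wild-type structure around an
anchor (Cβ; Cα for Gly), over a cutoff grid of **4, 6, 8, 10 Å** (a desk-scale
realization of cutoff scanning; configurable). Features, in fixed order: per
radius, counts of environment atoms per pharmacophore class (site residue
excluded); per radius, unordered class–class pair counts over environment
atoms that are both within the radius of the anchor and of each other (which
makes every count non-decreasing in the radius); per radius, a partner
channel — other-chain atoms in ppi mode, ligand+metal atoms in ligand mode,
empty in stability mode; the canonical pharmacophore-count difference vector
between mutant and wild-type residue types (zero for identity); and rsa, pH
and temperature passthroughs (defaults 7.0, 25 °C — no temperature/pH physics
is modelled; the fields only enter the regressor).

The regressor is a deliberately small packaged fixture: ridge regression
(α = 1) trained at fixture-build time (seed 7, 160 mutations) on synthetic
pocket and dimer structures, labelled by a documented pseudo-energy
(burial-weighted packing-volume, hydropathy and charge-burial terms plus a
partner-contact term and Gaussian noise, σ = 0.3 kcal/mol). The model file
records coefficients, feature order, seed and the maximum training residual;
the training table ships alongside it and every training row is regenerable
deterministically. Parity with externally trained webserver predictors is
not claimed, and published predictor outputs are used only as inputs to the
classification stage.

The consensus is a weighted mean of the ESST and signature scores (default
0.5/0.5 — the combination rule of published consensus predictors is not
documented, so a configurable weighted mean is the transparent choice); if
only one score exists for a mode (ESST applies to stability mode only), it
passes through.

Classification bands: stabilizing ΔΔG ≥ 0; slightly destabilizing
0 > ΔΔG ≥ −2.00; highly destabilizing ΔΔG < −2.00 kcal/mol. The −2.00
boundary is inclusive in the slightly-destabilizing band, 0 in the
stabilizing band.

## Pipeline, parsing and reporting

Mutation tables are CSV with COSMIC-style protein-change tokens (`F162L`,
`p.D600N`); gene→chain mapping is a configurable table (not hard-coded) and
sequence→structure numbering shifts are per-chain integer offsets (default
0). Wild-type letters are validated against the structure when one is
supplied; mutations at residues absent from the structure are reported as
"unscorable", not errors, and any per-mutation failure is isolated: it is
logged and reported in the row's status without affecting other mutations.
Saturation enumerates the 19 non-wild-type substitutions per selected site.
Duplicate table entries collapse with a warning. Two runs with the same
inputs and seed produce byte-identical outputs; no stage draws randomness at
scan time.

Summaries report per-band counts and percentages (count/n × 100, one decimal,
no renormalization — exact arithmetic is reported even where published
percentage sets are internally inconsistent). Histograms use left-closed
right-open bins with flagged under/overflow. Attribute files follow the UCSF
Chimera residue-attribute grammar exactly (`attribute:`, `match mode: 1-to-1`,
`recipient: residues`, then TAB-separated `:<seqnum>.<chain>\t<value>` lines);
the heat-map color convention (blue→white→red over [+max, −2]) is recorded as
a comment, not rendered.

## Synthetic data: what it emulates, and what it does not

* `make_helix` builds ideal α-helices (φ/ψ = −57/−47, Engh–Huber-style bond
  geometry) with side chains at the library's top rotamer. Measured
  properties: Cα–Cα ≈ 3.80 Å, i→i+4 O⋯N ≈ 3.1 Å.
* `make_dimer` emulates a two-helix dimer interface. Engineered contacts
  (Ser–Ser H-bond, Leu–Leu hydrophobic pair, Phe–Phe parallel stack) are
  realized by *geometric placement* of the contact side chains in the
  inter-helix gap: the side chain is rigidly positioned mid-gap, detached
  from its own backbone. This guarantees exact, verifiable ground truth
  (the build fails if any non-engineered residue crosses the cutoff) at the
  cost of local covalent plausibility at contact residues.
* `make_pocket` surrounds a toy purine-like ligand (aromatic 6-ring, amine,
  hydroxyl, phosphate-like tail) with full ideal residues placed so each
  listed interaction (H-bond 2.85 Å, π-stack 3.8 Å, Zn-bridged coordination
  2.05/2.15 Å, hydrophobic contact 4.0 Å) holds by construction. Pocket
  residues are spatially arranged around the ligand and are not a folded
  chain (they are numbered 10, 20, … so no peptide bonds are implied).
* `make_families` samples homolog columns independently from per-environment
  row-stochastic substitution matrices (diagonal retention 0.7, off-diagonal
  mass spread by environment-dependent acceptance weights), so derived
  tables have a known generating log-odds structure.
* `make_mutation_table` allocates class labels by largest remainder — exact,
  testable counts rather than multinomial noise.
* `make_paralog_pair` is a synthetic stand-in for a real diverged paralog
  pair: an ancestral sequence plus a derived copy with an exact substitution
  load and a few short indels, with the alignment-frame identity tracked as
  ground truth (defaults: 860 residues, 71.4 % identity, 3 indels of 6).

Passing tests on these fixtures establish that the geometric criteria,
detection stages, estimators and bookkeeping are implemented correctly and
deterministically. They do not establish predictive accuracy on real
structures: real side-chain packing, solvation, backbone relaxation and
homolog phylogeny are all richer than the generators, and the packaged
regressor/ESST are fixtures, not trained predictors.

## Numerical choices and problem sizes

Coordinates are Å; angles degrees; dihedral sign follows the standard
right-handed convention (validated against CCD reference residues). Rotamer
selection ties break at 1e-9 on the clash score. Identity alignments use
BLOSUM62 with gap open 10 / extend 0.5 (global), reproducing Clustal-scale
identities for ~70 %-identical paralogs; the identity denominator excludes
gap columns. The test and acceptance workloads use deliberately small
problem sizes chosen to exercise every code path — random structures ≤ 500
atoms for oracle equivalence (20 seeds), 200 homologs × 9 environments for
table recovery, 50 random cases for rotamer-enumeration agreement, and
19-fold saturation of a 5-residue pocket for the end-to-end scan. Statistical
recovery checks hold each cell to 3 binomial standard errors and bound the
count of 3σ excursions by its own binomial envelope, as appropriate for
~1500 simultaneous checks.

## Known limitations

* Heavy-atom-only H-bond geometry (no explicit hydrogens or donor-H angles).
* No water-mediated or halogen interactions; no solvation model.
* Fixed backbone, no neighbor repacking; rigid Pro; disulphides not rebuilt.
* pH and temperature are passthrough features, not physics.
* The ligand mode treats any non-water HET group uniformly — a cyclic
  nucleotide, a drug-like molecule and a crystallization additive are all
  "the ligand".
* The regressor and ESST are synthetic-data fixtures; absolute ΔΔG values
  are on a plausible scale but are not benchmarked against experimental
  thermodynamics.
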